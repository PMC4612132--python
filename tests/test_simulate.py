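"""The synthetic-data generator: planted truth, determinism, contracts."""

import pytest

from symtox.classify import classify_proteins
from symtox.simulate import (SimConfig, contig_sequences, generate_counts,
                             generate_genome_set, generate_metadata_table,
                             generate_pileups, write_genome_set)
from symtox.variants import call_variants


def test_truth_table_counts_match_config(small_bundle, small_sim_config):
    gs, truth = small_bundle
    cfg = small_sim_config
    assert len(gs.genomes) == cfg.n_focal_genomes + cfg.n_reference_genomes
    focal = truth[truth.genome_id == "F01"]
    assert (focal.category == "core").sum() == cfg.n_core_genes
    assert (focal.category == "specific").sum() == cfg.n_specific_genes
    for cls, copies, _ in cfg.trg_plant_spec:
        assert (focal.trg_class == cls).sum() == copies
    ref = truth[truth.genome_id == "A01"]
    assert (ref.category == "trg").sum() == 0
    assert (ref.category == "specific").sum() == 0


def test_empty_plant_yields_no_trg_calls():
    cfg = SimConfig(n_focal_genomes=1, n_reference_genomes=2,
                    n_core_genes=20, n_specific_genes=5, trg_plant_spec=[],
                    accessory_copies=0, mean_protein_len=100, rng_seed=5)
    gs, truth = generate_genome_set(cfg)
    assert (truth.trg_class != "").sum() == 0
    calls = classify_proteins(gs.proteins_of("F01"), gs.genes_of("F01"))
    assert [c for c in calls if c.trg_class != "RTX_accessory"] == []


def test_same_seed_reproduces_identical_files(tmp_path, small_sim_config):
    gs1, truth1 = generate_genome_set(small_sim_config)
    gs2, truth2 = generate_genome_set(small_sim_config)
    write_genome_set(gs1, truth1, tmp_path / "a")
    write_genome_set(gs2, truth2, tmp_path / "b")
    for name in ("F01.fna", "F01.faa", "F01.gff3", "truth.tsv"):
        assert ((tmp_path / "a" / name).read_bytes()
                == (tmp_path / "b" / name).read_bytes())


def test_distinct_seeds_differ():
    cfg1 = SimConfig(n_focal_genomes=1, n_reference_genomes=2,
                     n_core_genes=10, n_specific_genes=2, trg_plant_spec=[],
                     rng_seed=1)
    cfg2 = SimConfig(n_focal_genomes=1, n_reference_genomes=2,
                     n_core_genes=10, n_specific_genes=2, trg_plant_spec=[],
                     rng_seed=2)
    gs1, _ = generate_genome_set(cfg1)
    gs2, _ = generate_genome_set(cfg2)
    assert (gs1.proteins_of("F01")[0].residues
            != gs2.proteins_of("F01")[0].residues)


def test_excessive_divergence_rejected():
    with pytest.raises(ValueError, match="divergence"):
        SimConfig(trg_plant_spec=[("YD", 5, 0.7)])


def test_no_gene_shorter_than_minimum(small_bundle):
    gs, _ = small_bundle
    assert all(g.length_bp >= 150 for g in gs.genes)


def test_mobile_marker_planted_next_to_flagged_trg(small_bundle):
    gs, truth = small_bundle
    focal = truth[truth.genome_id == "F01"]
    flagged = focal.loc[focal.mobile_adjacent_flag, "gene_id"]
    genes = sorted(gs.genes_of("F01"), key=lambda g: g.start)
    order = {g.gene_id: i for i, g in enumerate(genes)}
    markers = set(focal.loc[focal.category == "mobile_marker", "gene_id"])
    for gid in flagged:
        i = order[gid]
        neighbors = {genes[j].gene_id
                     for j in (i - 1, i + 1) if 0 <= j < len(genes)}
        assert neighbors & markers


def test_contig_layout_consistent_with_gene_models(small_bundle):
    gs, _ = small_bundle
    contigs = contig_sequences(gs, "F01")
    from symtox.simulate import REVCOMP
    for g in gs.genes_of("F01")[:20]:
        segment = contigs[g.contig][g.start - 1:g.end]
        expected = (g.nucleotide_seq if g.strand == "+"
                    else g.nucleotide_seq.translate(REVCOMP)[::-1])
        assert segment == expected


def test_metadata_requires_minimum_group_size():
    with pytest.raises(ValueError):
        generate_metadata_table(SimConfig(n_genomes_per_lifestyle=1))


def test_metadata_planted_effect_shifts_normalized_counts():
    effect = 6.0
    cfg = SimConfig(n_genomes_per_lifestyle=30,
                    enrichment_effect={"intracellular": effect}, rng_seed=9)
    metadata, truth = generate_metadata_table(cfg)
    assert truth["intracellular"] == effect
    df = metadata.copy()
    df["trg_norm"] = (df[["YD", "RTX", "MARTX"]].sum(axis=1)
                      / df["total_genes"] * 1000)
    shifted = df[df.lifestyle == "intracellular"]["trg_norm"].mean()
    others = df[df.lifestyle != "intracellular"]["trg_norm"].mean()
    assert shifted - others == pytest.approx(effect, abs=1.5)


def test_pileups_without_signal_produce_no_variants(small_bundle):
    gs, truth = small_bundle
    cfg = SimConfig(n_focal_genomes=1, n_reference_genomes=4,
                    n_core_genes=30, n_specific_genes=15,
                    trg_plant_spec=[("YD", 6, 0.2), ("RTX", 3, 0.2),
                                    ("MARTX", 4, 0.2)],
                    mean_protein_len=120, rng_seed=11,
                    snp_rate=0.0, seq_error_rate=0.0, indel_rate=0.0)
    pile, _ = generate_pileups(gs, cfg, truth, "F01")
    calls = call_variants(pile)
    assert calls == []


def test_count_table_is_multinomial_over_all_genes(small_bundle,
                                                   small_sim_config):
    gs, truth = small_bundle
    counts, shares = generate_counts(gs, small_sim_config, truth, "F01")
    assert sum(counts.values()) == small_sim_config.total_reads
    assert set(counts) == {g.gene_id for g in gs.genes_of("F01")}
    assert shares["rubisco_gene"] in counts
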