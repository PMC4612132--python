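"""Coverage capping, variant calling, and SNP-density scoring."""

import numpy as np
import pandas as pd
import pysam
import pytest

from symtox.io import write_vcf
from symtox.model import GeneModel, VariantCall
from symtox.variants import (cap_coverage, call_variants, flag_variable_genes,
                             gene_snp_density)

from oracles import binom_tail


def pileup_frame(rows):
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "depth",
                                       "A", "C", "G", "T", "N", "indel"])


def test_deep_column_downsampled_to_cap():
    df = pileup_frame([("c", 1, "A", 400, 200, 200, 0, 0, 0, 0)])
    capped = cap_coverage(df, floor=5, cap=200, seed=0)
    assert capped.loc[0, "depth"] == 200
    # alt fraction stays near 0.5 (multinomial expectation, binomial CI)
    assert abs(capped.loc[0, "C"] / 200 - 0.5) < 0.12
    assert capped.loc[0, "depth_flag"] == "high_depth"


def test_shallow_column_marked_low_depth():
    df = pileup_frame([("c", 1, "A", 4, 4, 0, 0, 0, 0, 0)])
    capped = cap_coverage(df, floor=5, cap=200, seed=0)
    assert capped.loc[0, "depth_flag"] == "low_depth"
    calls = call_variants(capped)
    assert all(c.filter != "PASS" for c in calls)


def test_in_range_column_unchanged():
    df = pileup_frame([("c", 1, "A", 100, 98, 2, 0, 0, 0, 0)])
    capped = cap_coverage(df, floor=5, cap=200, seed=0)
    assert capped.loc[0, "A"] == 98 and capped.loc[0, "C"] == 2
    assert capped.loc[0, "depth_flag"] == ""


def test_no_alternate_reads_no_call():
    df = pileup_frame([("c", 1, "A", 50, 50, 0, 0, 0, 0, 0)])
    assert call_variants(df) == []


def test_balanced_site_passes_with_oracle_qual():
    df = pileup_frame([("c", 10, "A", 50, 25, 25, 0, 0, 0, 0)])
    calls = call_variants(df, error_rate=0.01)
    assert len(calls) == 1
    call = calls[0]
    assert call.filter == "PASS" and call.alt == "C"
    expected_qual = -10 * np.log10(binom_tail(25, 50, 0.01))
    assert call.qual == pytest.approx(expected_qual, rel=1e-6)
    assert call.qual > 20


def test_site_near_indel_filtered():
    df = pileup_frame([
        ("c", 100, "A", 50, 25, 25, 0, 0, 0, 0),
        ("c", 103, "G", 50, 0, 0, 50, 0, 0, 1),   # indel evidence 3 bp away
    ])
    calls = call_variants(df, indel_mask_bp=5)
    assert calls[0].filter == "near_indel"
    far = pileup_frame([
        ("c", 100, "A", 50, 25, 25, 0, 0, 0, 0),
        ("c", 110, "G", 50, 0, 0, 50, 0, 0, 1),   # 10 bp away, outside mask
    ])
    assert call_variants(far, indel_mask_bp=5)[0].filter == "PASS"


def test_n_reference_site_skipped():
    df = pileup_frame([("c", 1, "N", 50, 25, 25, 0, 0, 0, 0)])
    assert call_variants(df) == []


def test_raising_min_qual_never_adds_snps():
    rng = np.random.default_rng(0)
    rows = []
    for pos in range(1, 200):
        alt = int(rng.integers(0, 6))
        rows.append(("c", pos, "A", 50, 50 - alt, alt, 0, 0, 0, 0))
    df = pileup_frame(rows)
    gene = _gene("g1", 1, 199 * 3)
    prev = None
    for qual in (0, 10, 20, 40, 80):
        calls = call_variants(df, min_qual=qual)
        n = sum(c.filter == "PASS" for c in calls)
        if prev is not None:
            assert n <= prev
        prev = n


def _gene(gid, start, length, n_run=0):
    seq = "ATG" + "C" * (length - 6) + "TAA"
    if n_run:
        seq = seq[:10] + "N" * n_run + seq[10 + n_run:]
    return GeneModel(gene_id=gid, genome_id="g", contig="c", start=start,
                     end=start + length - 1, strand="+", nucleotide_seq=seq)


def _snp(pos):
    return VariantCall(contig="c", pos=pos, ref="C", alt="T", qual=50.0,
                       filter="PASS")


def test_density_worked_examples():
    # 1000 bp, 5 PASS SNPs, no Ns -> 5.0 per kb
    g1 = _gene("g1", 1, 1000)
    d = gene_snp_density([_snp(p) for p in (10, 20, 30, 40, 50)], [g1],
                         min_len=150)
    assert d[0].snps_per_kb == pytest.approx(5.0)
    # 600 bp with 100 Ns, 5 SNPs -> 5 / 0.5 kb = 10.0 per kb
    g2 = _gene("g2", 2000, 600, n_run=100)
    d = gene_snp_density([_snp(2000 + p) for p in (10, 20, 30, 40, 50)],
                         [g2], min_len=150)
    assert d[0].snps_per_kb == pytest.approx(10.0)
    # genes under 150 bp are not considered
    g3 = _gene("g3", 5000, 149)
    assert gene_snp_density([], [g3], min_len=150) == []


def test_scaffold_end_genes_excludable():
    genes = [_gene(f"g{i}", 1 + i * 1000, 900) for i in range(4)]
    d = gene_snp_density([], genes, min_len=150,
                         exclude_scaffold_end_genes=True)
    assert [g.gene_id for g in d] == ["g1", "g2"]


def test_flag_threshold_median_plus_sd():
    densities = [type("D", (), {"gene_id": f"g{i}", "snps_per_kb": v})()
                 for i, v in enumerate([1, 1, 1, 1, 10])]
    thr, flagged = flag_variable_genes(densities)
    assert thr.median == 1.0
    assert thr.sd == pytest.approx(np.std([1, 1, 1, 1, 10], ddof=1))
    assert thr.threshold == pytest.approx(1.0 + 4.0249, abs=1e-3)
    assert flagged == {"g4"}


def test_all_equal_densities_flag_nothing():
    densities = [type("D", (), {"gene_id": f"g{i}", "snps_per_kb": 2.0})()
                 for i in range(5)]
    thr, flagged = flag_variable_genes(densities)
    assert thr.threshold == 2.0
    assert flagged == set()


def test_vcf_output_parses_with_pysam(tmp_path):
    calls = [VariantCall("c1", 10, "A", "G", 55.0, "PASS", depth=50,
                         alt_count=20),
             VariantCall("c1", 40, "C", "T", 25.0, "near_indel", depth=45,
                         alt_count=8)]
    path = tmp_path / "out.vcf"
    write_vcf(calls, {"c1": 1000}, path)
    with pysam.VariantFile(str(path)) as vcf:
        records = list(vcf)
    assert len(records) == 2
    assert records[0].pos == 10 and records[0].alts == ("G",)
    assert records[0].info["DP"] == 50
    assert list(records[1].filter) == ["near_indel"]
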