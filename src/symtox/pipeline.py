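"""End-to-end pipeline: chain all analysis stages over one input bundle.

The manifest names the focal and reference genome sets plus optional
metadata / pileup / count inputs; the pipeline writes every stage's
tabular output into one directory and a deterministic JSON report
summarising the run.  Identical inputs and seed give a byte-identical
report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd

from . import io as sio
from .align import HitFilter, all_vs_all_hits
from .bsr import compute_bsr, partition_shared_unique
from .classify import classify_proteins
from .config import PipelineConfig
from .enrich import results_to_frame, run_enrichment
from .expression import records_to_frame, summarize_expression
from .hgt import codon_usage_profile, flag_hgt_genes
from .model import GenomeSet
from .network import (attach_trg_classes, build_graph, cluster_graph,
                      select_trg_neighborhood, write_graph)
from .simulate import (SimConfig, contig_sequences, focal_genomes,
                       generate_counts, generate_genome_set,
                       generate_metadata_table, generate_pileups,
                       reference_split, write_genome_set)
from .variants import (cap_coverage, call_variants, densities_to_frame,
                       flag_variable_genes, gene_snp_density)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _subset(gs: GenomeSet, genome_ids: list[str], set_id: str) -> GenomeSet:
    return GenomeSet(
        set_id=set_id, genomes=genome_ids,
        proteins=[p for p in gs.proteins if p.genome_id in genome_ids],
        genes=[g for g in gs.genes if g.genome_id in genome_ids])


def run_pipeline(config: PipelineConfig, gs: GenomeSet,
                 focal_ids: list[str], ref_a_ids: list[str],
                 ref_b_ids: list[str], outdir: str | Path,
                 metadata: pd.DataFrame | None = None,
                 pileups: dict[str, pd.DataFrame] | None = None,
                 counts: dict[str, dict[str, float]] | None = None,
                 reference_gene: dict[str, str] | None = None,
                 ) -> dict[str, Any]:
    """Run BSR partitioning, TRG classification, network construction,
    enrichment, SNP-density, HGT and expression stages; write artifacts to
    *outdir* and return the report dict (also written as report.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config": {k: v for k, v in sorted(vars(config).items())},
        "genomes": {g: n for g, n in sorted(gs.total_genes.items())},
    }
    ref_a = [p for p in gs.proteins if p.genome_id in ref_a_ids]
    ref_b = [p for p in gs.proteins if p.genome_id in ref_b_ids]

    # ---- BSR partitioning and TRG classification per focal genome
    venn_report: dict[str, Any] = {}
    trg_report: dict[str, Any] = {}
    all_trg_ids: dict[str, list[str]] = {}
    calls_by_genome: dict[str, list] = {}
    for genome in focal_ids:
        stage = f"bsr:{genome}"
        try:
            queries = gs.proteins_of(genome)
            bsr_a = compute_bsr(queries, ref_a, "refA")
            bsr_b = compute_bsr(queries, ref_b, "refB")
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError(stage, str(exc)) from exc
        pd.DataFrame([{
            "query_id": r.query_id, "reference_set_id": r.reference_set_id,
            "self_score": r.self_score, "best_score": r.best_score,
            "bsr": r.bsr} for r in bsr_a + bsr_b]).to_csv(
                outdir / f"bsr_{genome}.tsv", sep="\t", index=False)
        venn = partition_shared_unique(bsr_a, bsr_b,
                                       config.bsr_threshold_general, genome)
        venn_report[genome] = venn.counts

        try:
            calls = classify_proteins(queries, gs.genes_of(genome))
        except Exception as exc:
            raise StageError(f"classify:{genome}", str(exc)) from exc
        calls_by_genome[genome] = calls
        pd.DataFrame([{
            "protein_id": c.protein_id, "trg_class": c.trg_class,
            "mobile_adjacent": c.mobile_adjacent, "conflict": c.conflict,
        } for c in calls]).to_csv(outdir / f"trg_{genome}.tsv",
                                  sep="\t", index=False)
        all_trg_ids[genome] = sorted(c.protein_id for c in calls)
        by_class: dict[str, int] = {}
        for c in calls:
            by_class[c.trg_class] = by_class.get(c.trg_class, 0) + 1
        # TRG re-screen against the references at the relaxed cutoff
        trg_set = set(all_trg_ids[genome])
        rescreen = partition_shared_unique(
            [r for r in bsr_a if r.query_id in trg_set],
            [r for r in bsr_b if r.query_id in trg_set],
            config.bsr_threshold_trg, genome)
        trg_report[genome] = {
            "counts_by_class": dict(sorted(by_class.items())),
            "mobile_adjacent": sum(c.mobile_adjacent for c in calls),
            "unique_at_relaxed_bsr": len(rescreen.unique),
        }
    report["venn"] = venn_report
    report["trg"] = trg_report

    # ---- similarity network over the focal proteomes
    focal_proteins = [p for p in gs.proteins if p.genome_id in focal_ids]
    net_filter = HitFilter(min_query_coverage=config.hit_min_query_coverage,
                           min_similarity=config.hit_min_similarity,
                           max_evalue=config.hit_max_evalue_network)
    try:
        hits = all_vs_all_hits(focal_proteins, focal_proteins, net_filter)
    except Exception as exc:
        raise StageError("network", str(exc)) from exc
    sio.write_hits(hits, outdir / "network_hits.tsv")
    annotations = {g.gene_id: g.annotation for g in gs.genes}
    genome_of = {p.protein_id: p.genome_id for p in focal_proteins}
    graph = build_graph(hits, net_filter, annotations, genome_of)
    clusters = cluster_graph(graph)
    trg_annotations = [c for genome in focal_ids
                       for c in calls_by_genome[genome]]
    attach_trg_classes(graph, trg_annotations)
    hood = select_trg_neighborhood(graph, clusters, trg_annotations,
                                   config.network_max_steps)
    write_graph(graph, clusters, str(outdir / "network.tsv"))
    report["network"] = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_clusters": len(set(clusters.values())),
        "selected_clusters": {cid: {"distance": hood.selected[cid],
                                    "name": hood.names.get(cid, "")}
                              for cid in hood.cluster_ids},
    }

    # ---- lifestyle enrichment
    if metadata is not None and len(metadata):
        results = run_enrichment(metadata, n_perm=config.n_permutations,
                                 seed=config.rng_seed,
                                 factor=config.normalization_factor)
        results_to_frame(results).to_csv(outdir / "enrichment.tsv",
                                         sep="\t", index=False)
        report["enrichment"] = [{
            "method": r.method, "grouping": r.grouping,
            "response": r.response, "statistic": round(r.statistic, 6),
            "df": r.df, "p_value": r.p_value, "p_adjusted": r.p_adjusted,
        } for r in results]
    else:
        log.info("enrichment stage skipped: no metadata table provided")
        report["enrichment"] = "skipped: empty metadata"

    # ---- SNP density
    snp_report: dict[str, Any] = {}
    for genome, pile in sorted((pileups or {}).items()):
        try:
            capped = cap_coverage(pile, config.coverage_floor,
                                  config.coverage_cap, seed=config.rng_seed)
            calls = call_variants(capped, min_qual=config.min_variant_qual,
                                  indel_mask_bp=config.indel_mask_bp,
                                  coverage_floor=config.coverage_floor,
                                  coverage_cap=config.coverage_cap)
            contig_lengths = {c: len(s) for c, s in
                              contig_sequences(gs, genome).items()}
            sio.write_vcf(calls, contig_lengths,
                          outdir / f"variants_{genome}.vcf",
                          config.indel_mask_bp)
            densities = gene_snp_density(calls, gs.genes_of(genome),
                                         config.min_gene_length_bp)
            thr, flagged = flag_variable_genes(densities)
            densities_to_frame(densities, flagged).to_csv(
                outdir / f"snp_density_{genome}.tsv", sep="\t", index=False)
            snp_report[genome] = {
                "n_pass_snps": sum(c.filter == "PASS" for c in calls),
                "median_snps_per_kb": round(thr.median, 6),
                "sd_snps_per_kb": round(thr.sd, 6),
                "threshold": round(thr.threshold, 6),
                "n_flagged": len(flagged),
                "flagged": sorted(flagged),
            }
        except Exception as exc:
            raise StageError(f"snps:{genome}", str(exc)) from exc
    if snp_report:
        report["snp_density"] = snp_report

    # ---- codon-usage HGT screen
    hgt_report: dict[str, Any] = {}
    for genome in focal_ids:
        try:
            usages, profile = codon_usage_profile(gs.genes_of(genome))
            calls_h, summary = flag_hgt_genes(
                usages, profile, seed=config.rng_seed,
                trg_ids=all_trg_ids[genome])
        except Exception as exc:
            raise StageError(f"hgt:{genome}", str(exc)) from exc
        pd.DataFrame([{
            "gene_id": c.gene_id,
            "deviation_score": round(c.deviation_score, 6),
            "flagged": c.flagged} for c in calls_h]).to_csv(
                outdir / f"hgt_{genome}.tsv", sep="\t", index=False)
        hgt_report[genome] = {
            "fraction_flagged": round(summary["fraction_flagged"], 6),
            "fraction_flagged_trg": round(summary["fraction_flagged_trg"], 6)
            if summary["fraction_flagged_trg"] == summary["fraction_flagged_trg"]
            else None,
        }
    report["hgt"] = hgt_report

    # ---- expression summaries
    expr_report: dict[str, Any] = {}
    trg_class_of = {c.protein_id: c.trg_class for c in trg_annotations}
    for genome, table in sorted((counts or {}).items()):
        ref_gene = (reference_gene or {}).get(genome)
        try:
            records, class_summary = summarize_expression(
                table, trg_class_of, ref_gene)
        except Exception as exc:
            raise StageError(f"express:{genome}", str(exc)) from exc
        records_to_frame(records).to_csv(outdir / f"expression_{genome}.tsv",
                                         sep="\t", index=False)
        expr_report[genome] = {
            row["trg_class"]: {"n_expressed": int(row["n_expressed"]),
                               "percent_of_mrna": round(
                                   float(row["percent_of_mrna"]), 6)}
            for _, row in class_summary.iterrows()}
    if expr_report:
        report["expression"] = expr_report

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def run_synthetic_pipeline(config: PipelineConfig, sim: SimConfig,
                           outdir: str | Path) -> dict[str, Any]:
    """Generate a full synthetic bundle and run every stage on it."""
    outdir = Path(outdir)
    gs, truth = generate_genome_set(sim)
    write_genome_set(gs, truth, outdir / "input")
    focal = focal_genomes(gs)
    ref_a_ids, ref_b_ids = reference_split(gs)
    metadata, _ = generate_metadata_table(sim)
    metadata.to_csv(outdir / "input" / "metadata.tsv", sep="\t", index=False)
    pileups = {}
    counts = {}
    reference_gene = {}
    for genome in focal:
        pile, _ = generate_pileups(gs, sim, truth, genome)
        sio.write_pileups(pile, outdir / "input" / f"pileup_{genome}.tsv")
        pileups[genome] = pile
        table, shares = generate_counts(gs, sim, truth, genome)
        pd.Series(table).rename("count").to_csv(
            outdir / "input" / f"counts_{genome}.tsv", sep="\t",
            index_label="gene_id")
        counts[genome] = table
        reference_gene[genome] = shares["rubisco_gene"]
    return run_pipeline(config, gs, focal, ref_a_ids, ref_b_ids, outdir,
                        metadata=metadata, pileups=pileups, counts=counts,
                        reference_gene=reference_gene)
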