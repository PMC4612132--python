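"""Population SNP-density scoring from mapped-read pileups.

The upstream contract on the pileups is that reads were uniquely mapped at
>90% identity (read mapping itself is out of scope here).  Depth is
normalized to the published window (cap 200 by seeded multinomial
downsampling, floor 5 by exclusion).  Variants are called with a pooled
binomial site test — bacterial populations are not diploid, so a diploid
haplotype caller is replaced by a documented population-level test:
qual = -10 log10 P(X >= alt_count | X ~ Binomial(depth, error_rate)).
PASS requires qual above the confidence threshold, depth inside the
normalization window, and distance > mask from any indel evidence.

Per-gene densities are SNPs per kb of N-corrected length (gene length
minus unknown-sequence bases); genes under 150 bp are excluded.  A gene is
flagged highly variable when its density strictly exceeds the median plus
one sample standard deviation of all included genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import GeneModel, GeneVariability, VariantCall

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
DEFAULT_ERROR_RATE = 0.01


def cap_coverage(pileups: pd.DataFrame, floor: int = 5, cap: int = 200,
                 seed: int = 0) -> pd.DataFrame:
    """Normalize pileup depth into [floor, cap].

    Columns deeper than ``cap`` are downsampled multinomially (seeded) to
    exactly ``cap`` reads; columns shallower than ``floor`` are marked
    ``low_depth`` and excluded from calling.  Returns a copy with updated
    base counts, a recomputed ``depth`` and a ``depth_flag`` column
    ("", "low_depth", or "high_depth" for downsampled columns).
    """
    df = pileups.copy().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    counts = df[list(BASES) + ["N"]].to_numpy(dtype=np.int64)
    depth = counts.sum(axis=1)
    flags = np.full(len(df), "", dtype=object)
    flags[depth < floor] = "low_depth"
    over = np.flatnonzero(depth > cap)
    for i in over:
        p = counts[i] / depth[i]
        counts[i] = rng.multinomial(cap, p)
        flags[i] = "high_depth"
    df[list(BASES) + ["N"]] = counts
    df["depth"] = counts.sum(axis=1)
    df["depth_flag"] = flags
    return df


def call_variants(pileups: pd.DataFrame,
                  min_qual: float = 20.0,
                  error_rate: float = DEFAULT_ERROR_RATE,
                  indel_mask_bp: int = 5,
                  coverage_floor: int = 5,
                  coverage_cap: int = 200) -> list[VariantCall]:
    """Pooled binomial site test on capped pileups.

    Sites with an N reference are skipped.  The alternate allele is the
    most abundant non-reference base; multi-allelic sites therefore count
    as one SNP position.
    """
    df = pileups
    indel_positions: dict[str, np.ndarray] = {}
    if "indel" in df.columns:
        for contig, sub in df[df["indel"] > 0].groupby("contig"):
            indel_positions[contig] = sub["pos"].to_numpy()
    counts = df[list(BASES)].to_numpy(dtype=np.int64)
    depth = df["depth"].to_numpy(dtype=np.int64)
    refs = df["ref"].to_numpy()
    flags = (df["depth_flag"].to_numpy() if "depth_flag" in df.columns
             else np.full(len(df), "", dtype=object))
    calls: list[VariantCall] = []
    base_index = {b: i for i, b in enumerate(BASES)}
    contigs = df["contig"].to_numpy()
    positions = df["pos"].to_numpy(dtype=np.int64)
    for i in range(len(df)):
        ref = refs[i]
        if ref not in base_index:
            continue  # unknown reference base
        row = counts[i].copy()
        row[base_index[ref]] = 0
        alt_count = int(row.max())
        if alt_count == 0:
            continue
        alt = BASES[int(row.argmax())]
        d = int(depth[i])
        # survival function includes the observed count
        p_tail = stats.binom.sf(alt_count - 1, d, error_rate)
        qual = -10.0 * np.log10(max(p_tail, 1e-300))
        if flags[i] == "low_depth" or d < coverage_floor:
            filt = "low_depth"
        elif d > coverage_cap:
            filt = "high_depth"
        elif qual < min_qual:
            filt = "low_qual"
        else:
            near = indel_positions.get(contigs[i])
            if near is not None and np.abs(near - positions[i]).min() <= indel_mask_bp:
                filt = "near_indel"
            else:
                filt = "PASS"
        calls.append(VariantCall(
            contig=str(contigs[i]), pos=int(positions[i]), ref=str(ref),
            alt=alt, qual=float(qual), filter=filt,
            depth=d, alt_count=alt_count))
    return calls


@dataclass
class VariabilityThreshold:
    median: float
    sd: float

    @property
    def threshold(self) -> float:
        return self.median + self.sd


def gene_snp_density(variants: Sequence[VariantCall],
                     gene_models: Sequence[GeneModel],
                     min_len: int = 150,
                     exclude_scaffold_end_genes: bool = False,
                     genome_id: Optional[str] = None
                     ) -> list[GeneVariability]:
    """Assign PASS SNPs to genes by coordinate and compute SNPs per kb.

    Density uses the N-corrected length (length minus unknown bases);
    genes shorter than ``min_len`` bp, or with zero effective length, are
    excluded.  ``exclude_scaffold_end_genes`` drops the first and last
    gene of each contig (terminal genes can accumulate artefactual SNPs).
    """
    genes = [g for g in gene_models
             if genome_id is None or g.genome_id == genome_id]
    if exclude_scaffold_end_genes:
        by_contig: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_contig.setdefault(g.contig, []).append(g)
        keep: set[str] = set()
        for contig_genes in by_contig.values():
            contig_genes.sort(key=lambda g: g.start)
            for g in contig_genes[1:-1]:
                keep.add(g.gene_id)
        genes = [g for g in genes if g.gene_id in keep]
    pass_positions: dict[str, np.ndarray] = {}
    for contig in {g.contig for g in genes}:
        pos = sorted(v.pos for v in variants
                     if v.filter == "PASS" and v.contig == contig)
        pass_positions[contig] = np.asarray(pos, dtype=np.int64)
    out: list[GeneVariability] = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.length_bp < min_len:
            continue
        if g.length_bp - g.n_bp <= 0:
            log.warning("gene %s: effective length 0, excluded", g.gene_id)
            continue
        pos = pass_positions.get(g.contig, np.empty(0, dtype=np.int64))
        n_snps = int(np.count_nonzero((pos >= g.start) & (pos <= g.end)))
        out.append(GeneVariability(gene_id=g.gene_id, length_bp=g.length_bp,
                                   n_bp=g.n_bp, snp_count=n_snps))
    return out


def flag_variable_genes(densities: Sequence[GeneVariability]
                        ) -> tuple[VariabilityThreshold, set[str]]:
    """Flag genes whose SNPs/kb strictly exceed median + 1 sample SD."""
    if len(densities) < 2:
        raise ValueError("need at least two genes to set a threshold")
    values = np.array([d.snps_per_kb for d in densities])
    thr = VariabilityThreshold(median=float(np.median(values)),
                               sd=float(np.std(values, ddof=1)))
    flagged = {d.gene_id for d in densities if d.snps_per_kb > thr.threshold}
    return thr, flagged


def densities_to_frame(densities: Sequence[GeneVariability],
                       flagged: set[str] | None = None) -> pd.DataFrame:
    flagged = flagged or set()
    return pd.DataFrame([{
        "gene_id": d.gene_id, "length_bp": d.length_bp, "n_bp": d.n_bp,
        "snp_count": d.snp_count, "snps_per_kb": d.snps_per_kb,
        "flagged": d.gene_id in flagged,
    } for d in densities])
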