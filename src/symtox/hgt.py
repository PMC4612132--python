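"""Codon-usage screening for horizontally acquired genes.

Recently transferred genes retain the codon bias of their donor.  The
detector conditions on amino-acid composition — codon frequencies are
modelled *within* synonymous families — so it responds to codon bias, not
protein composition.  The per-gene statistic is a length-normalized
multinomial log-likelihood ratio of the gene's codon counts under its own
(MLE) conditional frequencies versus the genome-wide profile:

    score = (1/n) * sum_c  n_c * ln( p_gene(c | aa) / p_genome(c | aa) )

summed over sense codons in families with more than one codon.  The flag
cutoff is calibrated empirically per gene: null replicates are built by
resampling the gene's own per-family codon totals from the genome profile
(matched length *and* amino-acid composition, seeded) — the null score of a
gene depends strongly on its length (the overfitting term of the
likelihood ratio scales as 1/n), so a single pooled cutoff would flag
short genes and miss long ones.  A gene is flagged when its score exceeds
the m-th largest of its n_null null scores with m = fpr_target*(n_null+1),
which gives an exact false-positive rate of fpr_target under the null by
exchangeability.  Genes shorter than 30 codons inherit the genome profile
and are never flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

from .model import GeneModel

log = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[11]
CODONS = sorted(_TABLE.forward_table)            # 61 sense codons
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AA_OF_CODON = [_TABLE.forward_table[c] for c in CODONS]
FAMILIES: dict[str, np.ndarray] = {}
for _aa in sorted(set(AA_OF_CODON)):
    FAMILIES[_aa] = np.array([i for i, a in enumerate(AA_OF_CODON) if a == _aa])
MULTI_FAMILIES = {aa: idx for aa, idx in FAMILIES.items() if len(idx) > 1}

MIN_CODONS_FOR_PROFILE = 30
PROFILE_PSEUDOCOUNT = 0.5


@dataclass
class CodonUsage:
    gene_id: str
    counts: np.ndarray        # (61,) sense-codon counts
    codon_count: int

    def conditional_freqs(self) -> np.ndarray:
        """Frequencies normalized within each synonymous family."""
        freqs = np.zeros_like(self.counts, dtype=float)
        for idx in FAMILIES.values():
            total = self.counts[idx].sum()
            if total > 0:
                freqs[idx] = self.counts[idx] / total
            else:
                freqs[idx] = 1.0 / len(idx)
        return freqs


@dataclass
class HgtCall:
    gene_id: str
    deviation_score: float
    flagged: bool


def gene_codon_counts(gene: GeneModel) -> CodonUsage:
    """Count sense codons of a strand-corrected CDS; internal stops skipped."""
    seq = gene.nucleotide_seq.upper()
    counts = np.zeros(len(CODONS), dtype=np.int64)
    n_codons = len(seq) // 3
    for i in range(n_codons - 1):  # exclude the terminal (stop) codon
        codon = seq[3 * i:3 * i + 3]
        if codon in CODON_INDEX:
            counts[CODON_INDEX[codon]] += 1
        elif "N" not in codon:
            log.warning("gene %s: internal stop codon at codon %d skipped",
                        gene.gene_id, i + 1)
    return CodonUsage(gene_id=gene.gene_id, counts=counts,
                      codon_count=int(counts.sum()))


def codon_usage_profile(genes: Sequence[GeneModel]
                        ) -> tuple[list[CodonUsage], np.ndarray]:
    """Per-gene codon usages plus the pooled genome conditional profile.

    The genome profile is computed from codon counts pooled over all genes
    (with a small pseudocount so no sense codon has zero frequency) and
    normalized within synonymous families.
    """
    if len(genes) < 2:
        raise ValueError("genome profile needs at least two genes")
    usages = [gene_codon_counts(g) for g in genes]
    pooled = np.sum([u.counts for u in usages], axis=0) + PROFILE_PSEUDOCOUNT
    profile = np.zeros(len(CODONS))
    for idx in FAMILIES.values():
        profile[idx] = pooled[idx] / pooled[idx].sum()
    return usages, profile


def deviation_score(counts: np.ndarray, genome_profile: np.ndarray) -> float:
    """Length-normalized within-family log-likelihood ratio (nats/codon)."""
    total = 0.0
    n = 0
    for idx in MULTI_FAMILIES.values():
        fam = counts[idx]
        n_fam = fam.sum()
        if n_fam == 0:
            continue
        p_gene = fam / n_fam
        nz = fam > 0
        total += float(np.sum(fam[nz] * np.log(p_gene[nz] / genome_profile[idx][nz])))
        n += int(n_fam)
    return total / n if n else 0.0


def _gene_null_scores(usage: CodonUsage, genome_profile: np.ndarray,
                      n_null: int, rng: np.random.Generator) -> np.ndarray:
    """Null scores for one gene: its per-family codon totals resampled from
    the genome profile (length and amino-acid composition held fixed)."""
    from scipy.special import xlogy
    totals = np.zeros(n_null)
    n_codons = 0
    for idx in MULTI_FAMILIES.values():
        n_fam = int(usage.counts[idx].sum())
        if n_fam == 0:
            continue
        p = genome_profile[idx]
        draws = rng.multinomial(n_fam, p, size=n_null)  # (n_null, k)
        contrib = (xlogy(draws, draws / n_fam) - xlogy(draws, p)).sum(axis=1)
        totals += contrib
        n_codons += n_fam
    return totals / n_codons if n_codons else totals


def flag_hgt_genes(usages: Sequence[CodonUsage], genome_profile: np.ndarray,
                   fpr_target: float = 0.05, seed: int = 0,
                   n_null: int = 199,
                   trg_ids: Iterable[str] = ()
                   ) -> tuple[list[HgtCall], dict[str, float]]:
    """Flag atypical-codon-usage genes at a per-gene calibrated cutoff.

    Returns the per-gene calls and summary fractions: ``fraction_flagged``
    over genes long enough to score, and ``fraction_flagged_trg`` over the
    subset named in ``trg_ids`` (NaN when empty).
    """
    if not 0.0 < fpr_target < 1.0:
        raise ValueError("fpr_target must be in (0, 1)")
    rng = np.random.default_rng(seed)
    m = max(1, int(round(fpr_target * (n_null + 1))))
    calls = []
    cutoffs = []
    for u in usages:
        score = deviation_score(u.counts, genome_profile)
        flagged = False
        if u.codon_count >= MIN_CODONS_FOR_PROFILE:
            null = np.sort(_gene_null_scores(u, genome_profile, n_null, rng))
            cutoff = float(null[-m])
            cutoffs.append(cutoff)
            flagged = score > cutoff
        calls.append(HgtCall(gene_id=u.gene_id, deviation_score=score,
                             flagged=flagged))
    scored = [c for c, u in zip(calls, usages)
              if u.codon_count >= MIN_CODONS_FOR_PROFILE]
    trg_ids = set(trg_ids)
    trg_calls = [c for c in scored if c.gene_id in trg_ids]
    summary = {
        "cutoff": float(np.mean(cutoffs)) if cutoffs else float("nan"),
        "fraction_flagged": (sum(c.flagged for c in scored) / len(scored)
                             if scored else float("nan")),
        "fraction_flagged_trg": (sum(c.flagged for c in trg_calls) / len(trg_calls)
                                 if trg_calls else float("nan")),
    }
    return calls, summary
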