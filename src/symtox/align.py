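"""Exact local alignment, hit filtering, and all-vs-all searches.

The aligner is an exact affine-gap Smith-Waterman (Biopython's
PairwiseAligner) with BLAST defaults: BLOSUM62, gap existence 11, extension
1 — a gap of length k costs 11 + k.  E-values come from the Karlin-Altschul
formula with the published gapped constants for this scoring system
(lambda = 0.267, K = 0.041); bitscores are (lambda*S - ln K) / ln 2.

"Similarity" follows BLAST terminology: the percentage of aligned residue
pairs with a positive substitution score ("positives"), not identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .model import AlignmentHit, ProteinSeq

GAP_OPEN = 11      # gap existence cost; first gap residue costs GAP_OPEN + GAP_EXTEND
GAP_EXTEND = 1
KA_LAMBDA = 0.267  # gapped Karlin-Altschul constants for BLOSUM62 11/1
KA_K = 0.041

_MATRIX = substitution_matrices.load("BLOSUM62")


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _MATRIX
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def evalue_from_score(raw_score: float, m: int, n: int) -> float:
    """Karlin-Altschul expect value for raw score S in an m x n search space."""
    return KA_K * m * n * math.exp(-KA_LAMBDA * raw_score)


def bitscore_from_score(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2)


def min_score_for_evalue(max_evalue: float, m: int, n: int) -> float:
    """Smallest raw score whose e-value is <= max_evalue (inverse of the above)."""
    return (math.log(KA_K * m * n) - math.log(max_evalue)) / KA_LAMBDA


@dataclass
class HitFilter:
    """Predicates a hit must satisfy to be retained.

    Coverage is tested on the query ("at least half of the length"), with
    >= by default; similarity is strict > as printed (">25%"); e-values are
    <=.  The subject-side coverage is recorded on every hit so the choice
    remains auditable.
    """

    min_query_coverage: float = 0.5
    min_similarity: float = 25.0
    max_evalue: Optional[float] = 1e-5
    coverage_strict: bool = False

    def passes(self, hit: AlignmentHit) -> bool:
        if self.coverage_strict:
            if not hit.query_coverage > self.min_query_coverage:
                return False
        elif not hit.query_coverage >= self.min_query_coverage:
            return False
        if not hit.percent_similarity > self.min_similarity:
            return False
        if self.max_evalue is not None and not hit.evalue <= self.max_evalue:
            return False
        return True


def local_align(seq_a: str, seq_b: str,
                aligner: Align.PairwiseAligner | None = None,
                query_id: str = "query", subject_id: str = "subject",
                search_space_n: int | None = None) -> Optional[AlignmentHit]:
    """Optimal local alignment of two protein sequences.

    Returns None when the best local score is not positive.  The e-value
    search space defaults to len(a) x len(b); all-vs-all searches pass the
    pooled subject size instead.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner()
    alignments = aligner.align(seq_a, seq_b)
    if alignments.score <= 0:
        return None
    aln = alignments[0]
    q_blocks, s_blocks = aln.aligned
    identical = positive = aligned_pairs = 0
    columns = 0
    gapopen = 0
    prev_q_end = prev_s_end = None
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        if prev_q_end is not None:
            q_gap = qs - prev_q_end
            s_gap = ss - prev_s_end
            columns += q_gap + s_gap
            gapopen += (q_gap > 0) + (s_gap > 0)
        for i in range(qe - qs):
            a, b = seq_a[qs + i], seq_b[ss + i]
            score = _MATRIX[a, b]
            identical += a == b
            positive += score > 0
            aligned_pairs += 1
        columns += qe - qs
        prev_q_end, prev_s_end = qe, se
    raw = float(alignments.score)
    n = search_space_n if search_space_n is not None else len(seq_b)
    q_start, q_end = int(q_blocks[0][0]) + 1, int(q_blocks[-1][1])
    s_start, s_end = int(s_blocks[0][0]) + 1, int(s_blocks[-1][1])
    return AlignmentHit(
        query_id=query_id, subject_id=subject_id,
        raw_score=raw, bitscore=bitscore_from_score(raw),
        evalue=evalue_from_score(raw, len(seq_a), n),
        percent_identity=100.0 * identical / aligned_pairs,
        percent_similarity=100.0 * positive / aligned_pairs,
        query_coverage=(q_end - q_start + 1) / len(seq_a),
        subject_coverage=(s_end - s_start + 1) / len(seq_b),
        query_start=q_start, query_end=q_end,
        subject_start=s_start, subject_end=s_end,
        length=columns, mismatch=aligned_pairs - identical, gapopen=gapopen)


def self_score(seq: str, aligner: Align.PairwiseAligner | None = None) -> float:
    if aligner is None:
        aligner = make_aligner()
    return float(aligner.score(seq, seq))


def all_vs_all_hits(query_set: Sequence[ProteinSeq],
                    subject_set: Sequence[ProteinSeq],
                    hit_filter: HitFilter | None = None,
                    ) -> list[AlignmentHit]:
    """All-vs-all local alignment search with the published hit filter.

    Self-hits (identical protein ids) are excluded so overlapping sets can
    be searched against themselves.  A score-only pass prunes pairs that
    cannot reach the e-value ceiling before any traceback is computed.
    """
    if not query_set or not subject_set:
        raise ValueError("both sequence sets must be non-empty")
    if hit_filter is None:
        hit_filter = HitFilter()
    aligner = make_aligner()
    total_subject_residues = sum(len(s) for s in subject_set)
    hits: list[AlignmentHit] = []
    for q in query_set:
        if hit_filter.max_evalue is not None:
            cutoff = min_score_for_evalue(
                hit_filter.max_evalue, len(q), total_subject_residues)
        else:
            cutoff = 0.0
        for s in subject_set:
            if q.protein_id == s.protein_id:
                continue
            score = aligner.score(q.residues, s.residues)
            if score <= 0 or score < cutoff:
                continue
            hit = local_align(q.residues, s.residues, aligner,
                              query_id=q.protein_id, subject_id=s.protein_id,
                              search_space_n=total_subject_residues)
            if hit is not None and hit_filter.passes(hit):
                hits.append(hit)
    return hits
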