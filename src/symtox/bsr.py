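"""BLAST-score-ratio gene partitioning.

The BSR of a query against a reference set is the best raw local-alignment
score of the query against any reference protein divided by the query's
self-alignment score.  BSR >= 0.4 marks a gene as shared with the reference
set; the relaxed 0.2 cutoff is used when re-screening toxin-related genes.
Under BLOSUM62 (positive, row-maximal diagonal) the ratio lies in [0, 1].
"""

from __future__ import annotations

from typing import Sequence

from .align import make_aligner
from .model import BsrRecord, ProteinSeq, VennPartition


def compute_bsr(query_set: Sequence[ProteinSeq],
                reference_set: Sequence[ProteinSeq],
                reference_set_id: str = "ref") -> list[BsrRecord]:
    """One BsrRecord per query; best_score is 0 when nothing aligns.

    Ties for the best reference hit keep the lexicographically smallest
    subject id, making the record deterministic.
    """
    aligner = make_aligner()
    records = []
    for q in query_set:
        self_score = float(aligner.score(q.residues, q.residues))
        best_score = 0.0
        best_subject = None
        for s in sorted(reference_set, key=lambda p: p.protein_id):
            if s.protein_id == q.protein_id:
                continue
            score = float(aligner.score(q.residues, s.residues))
            if score > best_score:
                best_score = score
                best_subject = s.protein_id
        records.append(BsrRecord(
            query_id=q.protein_id, reference_set_id=reference_set_id,
            self_score=self_score, best_score=best_score,
            best_subject_id=best_subject))
    return records


def partition_shared_unique(bsr_vs_ref_a: Sequence[BsrRecord],
                            bsr_vs_ref_b: Sequence[BsrRecord],
                            threshold: float,
                            genome_id: str = "") -> VennPartition:
    """Partition queries into shared-with-A/B/both/unique at a BSR cutoff (>=)."""
    a = {r.query_id: r for r in bsr_vs_ref_a}
    b = {r.query_id: r for r in bsr_vs_ref_b}
    if set(a) != set(b):
        raise ValueError("BSR inputs cover different query universes")
    shared_both, a_only, b_only, unique = [], [], [], []
    for qid in sorted(a):
        in_a = a[qid].bsr >= threshold
        in_b = b[qid].bsr >= threshold
        if in_a and in_b:
            shared_both.append(qid)
        elif in_a:
            a_only.append(qid)
        elif in_b:
            b_only.append(qid)
        else:
            unique.append(qid)
    return VennPartition(genome_id=genome_id, shared_both=shared_both,
                         shared_a_only=a_only, shared_b_only=b_only,
                         unique=unique)
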