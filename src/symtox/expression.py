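"""Transcriptome expression summaries for toxin-related genes.

Consumes a per-gene read-count table (read trimming, rRNA removal and
mapping are upstream contracts).  Reports each gene's fraction of mRNA
(raw-count fraction by default; upper-quartile-normalized fractions behind
a flag), its upper-quartile-normalized expression, and its expression
relative to a named reference gene — conventionally the Calvin-cycle
carboxylase RuBisCO, giving "expressed at x times RuBisCO" ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class ExpressionRecord:
    gene_id: str
    read_count: float
    normalized_expression: float   # count / upper quartile of nonzero counts
    fraction_of_mrna: float        # percent
    rel_to_reference: float
    trg_class: str = ""


def summarize_expression(counts: Mapping[str, float],
                         gene_classes: Mapping[str, str] | None = None,
                         reference_gene_id: str | None = None,
                         use_normalized_fractions: bool = False
                         ) -> tuple[list[ExpressionRecord], pd.DataFrame]:
    """Per-gene expression records plus per-class summaries.

    Class summaries give, per TRG class, the summed percent of mRNA and the
    number of expressed (count > 0) genes.  Fractions over all genes sum to
    100% by construction.
    """
    gene_classes = dict(gene_classes or {})
    ids = sorted(counts)
    values = np.array([counts[g] for g in ids], dtype=float)
    if (values < 0).any():
        raise ValueError("read counts must be non-negative")
    total = values.sum()
    if total <= 0:
        raise ValueError("count table is empty")
    nonzero = values[values > 0]
    uq = float(np.percentile(nonzero, 75))
    normalized = values / uq if uq > 0 else values
    if reference_gene_id is not None:
        if reference_gene_id not in counts:
            raise ValueError(f"reference gene {reference_gene_id!r} absent")
        ref_value = (normalized[ids.index(reference_gene_id)]
                     if use_normalized_fractions
                     else counts[reference_gene_id])
        if ref_value <= 0:
            raise ValueError(
                f"reference gene {reference_gene_id!r} has zero count; "
                "relative expression undefined")
    basis = normalized if use_normalized_fractions else values
    fractions = 100.0 * basis / basis.sum()
    records = []
    for i, gid in enumerate(ids):
        rel = ((normalized[i] if use_normalized_fractions else values[i])
               / ref_value) if reference_gene_id is not None else float("nan")
        records.append(ExpressionRecord(
            gene_id=gid, read_count=float(values[i]),
            normalized_expression=float(normalized[i]),
            fraction_of_mrna=float(fractions[i]),
            rel_to_reference=float(rel),
            trg_class=gene_classes.get(gid, "")))
    rows = []
    for cls in sorted({c for c in gene_classes.values() if c}):
        members = [r for r in records if r.trg_class == cls]
        rows.append({
            "trg_class": cls,
            "n_genes": len(members),
            "n_expressed": sum(r.read_count > 0 for r in members),
            "percent_of_mrna": sum(r.fraction_of_mrna for r in members),
        })
    return records, pd.DataFrame(rows, columns=["trg_class", "n_genes",
                                                "n_expressed",
                                                "percent_of_mrna"])


def records_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": r.gene_id, "read_count": r.read_count,
        "normalized_expression": r.normalized_expression,
        "fraction_of_mrna": r.fraction_of_mrna,
        "rel_to_reference": r.rel_to_reference,
        "trg_class": r.trg_class,
    } for r in records])
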