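"""Lifestyle-enrichment statistics on normalized TRG counts.

Per-genome TRG counts are normalized by the genome's gene total and scaled
by 1000 ("TRGs per 1000 genes").  Group comparisons use the Kruskal-Wallis
rank test (chi-square approximation, midrank ties), Mann-Whitney-Wilcoxon
post hoc tests (exact by enumeration for small samples, normal
approximation with tie and continuity correction otherwise), and a one-way
PERMANOVA on Euclidean distances with seeded label permutations.  p-values
within one invocation family are Bonferroni-corrected.

Strains of one species are treated as independent rows throughout.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import TestResult, bonferroni

TRG_CLASSES = ("YD", "RTX", "MARTX")


def normalize_counts(counts: Sequence[float], total_genes: int,
                     factor: float = 1000.0) -> np.ndarray:
    """TRG count per class, per ``factor`` genes (exact arithmetic)."""
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    return np.asarray(counts, dtype=float) / total_genes * factor


def add_normalized_columns(metadata: pd.DataFrame,
                           factor: float = 1000.0) -> pd.DataFrame:
    """Append ``<class>_norm`` and ``trg_norm`` columns to a metadata table."""
    df = metadata.copy()
    present = [c for c in TRG_CLASSES if c in df.columns]
    for cls in present:
        df[f"{cls}_norm"] = df[cls] / df["total_genes"] * factor
    if present:
        df["trg_norm"] = df[present].sum(axis=1) / df["total_genes"] * factor
    return df


def kruskal_wallis(values: Sequence[float], groups: Sequence,
                   grouping: str = "", response: str = "") -> TestResult:
    """Kruskal-Wallis one-way rank ANOVA; df = k - 1, p from chi-square."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs n >= 2")
    if np.ptp(values) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    return TestResult(method="kruskal_wallis", statistic=float(h),
                      df=len(labels) - 1, p_value=float(p), p_adjusted=None,
                      grouping=grouping, response=response)


EXACT_MW_MAX_N = 16


def mann_whitney(values_a: Sequence[float], values_b: Sequence[float],
                 mode: str = "auto", grouping: str = "",
                 response: str = "") -> TestResult:
    """Two-sided Mann-Whitney-Wilcoxon U test.

    mode: "exact" (full enumeration of labelings; requires no ties for an
    exact null), "approx" (normal approximation with tie and continuity
    correction), or "auto" (exact when n_a + n_b <= 16 and tie-free).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups need n >= 1")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        u = len(a) * len(b) / 2.0
        return TestResult(method="mann_whitney", statistic=u, df=None,
                          p_value=1.0, p_adjusted=None,
                          grouping=grouping, response=response)
    if mode == "auto":
        mode = ("exact" if len(pooled) <= EXACT_MW_MAX_N and not has_ties
                else "approx")
    if mode == "exact":
        method = "exact"
    elif mode == "approx":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(method="mann_whitney", statistic=float(res.statistic),
                      df=None, p_value=float(min(res.pvalue, 1.0)),
                      p_adjusted=None, grouping=grouping, response=response)


def permanova(response_matrix: np.ndarray, groups: Sequence,
              n_perm: int = 9999, seed: int = 0,
              grouping: str = "", response: str = "") -> TestResult:
    """One-way PERMANOVA with Euclidean distances and label permutations.

    Sums of squares come from the squared-distance identity
    SS = sum_{i<j} d_ij^2 / n applied to the total and within-group parts;
    pseudo-F = (SS_among / (k-1)) / (SS_within / (n-k)).  The p-value is
    (1 + #{F_perm >= F_obs}) / (1 + n_perm) over seeded permutations of the
    group labels, so it is reproducible bit-exact for a given seed.
    """
    x = np.atleast_2d(np.asarray(response_matrix, dtype=float))
    if x.shape[0] == 1 and len(np.asarray(groups)) > 1:
        x = x.T
    groups = np.asarray(groups)
    n = x.shape[0]
    if len(groups) != n:
        raise ValueError("groups length must match response rows")
    labels, group_idx = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups to permute")
    sizes = np.bincount(group_idx)
    if sizes.min() < 2:
        raise ValueError("every group needs n >= 2")
    diff = x[:, None, :] - x[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n

    def ss_within(idx: np.ndarray) -> float:
        ssw = 0.0
        for g in range(k):
            rows = np.flatnonzero(idx == g)
            if len(rows) > 1:
                sub = d2[np.ix_(rows, rows)]
                ssw += sub[np.triu_indices(len(rows), k=1)].sum() / len(rows)
        return ssw

    def pseudo_f(idx: np.ndarray) -> float:
        ssw = ss_within(idx)
        ssa = ss_total - ssw
        if ssw <= 0:
            return 0.0 if ssa <= 0 else np.inf
        return (ssa / (k - 1)) / (ssw / (n - k))

    f_obs = pseudo_f(group_idx)
    if ss_total <= 0:  # all rows identical
        return TestResult(method="permanova", statistic=0.0, df=k - 1,
                          p_value=1.0, p_adjusted=None,
                          grouping=grouping, response=response)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(group_idx)
        if pseudo_f(perm) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return TestResult(method="permanova", statistic=float(f_obs), df=k - 1,
                      p_value=float(p), p_adjusted=None,
                      grouping=grouping, response=response)


def run_enrichment(metadata: pd.DataFrame,
                   tests: Sequence[str] = ("lifestyle", "pathogen", "biofilm",
                                           "taxonomy"),
                   n_perm: int = 9999, seed: int = 0,
                   factor: float = 1000.0) -> list[TestResult]:
    """Run the full enrichment battery on a genome metadata table.

    Kruskal-Wallis per TRG class (and the summed TRG count) for each
    categorical factor; PERMANOVA on the per-class normalized vector at
    each taxonomy level, Bonferroni-corrected within the taxonomy family;
    Mann-Whitney post hoc on significant lifestyle tests, comparing each
    lifestyle against the rest.
    """
    df = add_normalized_columns(metadata, factor=factor)
    results: list[TestResult] = []
    responses = [f"{c}_norm" for c in TRG_CLASSES if f"{c}_norm" in df] + \
                (["trg_norm"] if "trg_norm" in df else [])
    for factor_name in tests:
        if factor_name == "taxonomy":
            continue
        if factor_name not in df.columns:
            continue
        groups = df[factor_name]
        if groups.nunique() < 2 or groups.value_counts().min() < 2:
            continue
        for resp in responses:
            kw = kruskal_wallis(df[resp], groups,
                                grouping=factor_name, response=resp)
            results.append(kw)
            if kw.p_value < 0.05 and groups.nunique() > 2:
                for level in sorted(groups.unique()):
                    mask = groups == level
                    if mask.sum() < 1 or (~mask).sum() < 1:
                        continue
                    results.append(mann_whitney(
                        df.loc[mask, resp], df.loc[~mask, resp],
                        grouping=f"{factor_name}:{level}_vs_rest",
                        response=resp))
    if "taxonomy" in tests:
        tax_results = []
        matrix_cols = [f"{c}_norm" for c in TRG_CLASSES if f"{c}_norm" in df]
        for level_i, level in enumerate(("tax_class", "tax_order", "tax_family")):
            if level not in df.columns:
                continue
            groups = df[level]
            counts = groups.value_counts()
            keep = groups.isin(counts[counts >= 2].index)
            if keep.sum() < 4 or groups[keep].nunique() < 2:
                continue
            tax_results.append(permanova(
                df.loc[keep, matrix_cols].to_numpy(), groups[keep],
                n_perm=n_perm, seed=seed + level_i,
                grouping=level, response="trg_vector"))
        results.extend(bonferroni(tax_results))
    return results


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "method": r.method, "grouping": r.grouping, "response": r.response,
        "statistic": r.statistic, "df": r.df,
        "p_value": r.p_value, "p_adjusted": r.p_adjusted,
    } for r in results])
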