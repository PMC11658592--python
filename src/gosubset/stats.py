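"""Comparative statistics: what makes a term pair separable?

Relates the pairwise classifier scores to similarity measures of the same
term pairs (sequence identity aggregates, semantic similarity, annotation
overlap, sample-count difference): a normality screen decides between a
one-sided two-sample t-test and a Mann-Whitney U rank test for the
low-F1 vs high-F1 group comparison, p-values are corrected by
Benjamini-Hochberg, and monotone association is measured by Spearman rank
correlation.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: columns of a pair-feature table (one row per evaluated, unmasked pair)
PAIR_FEATURE_COLUMNS = [
    "term_i", "term_j", "test_f1", "train_f1",
    "mean_identity", "median_identity", "min_identity", "max_identity",
    "semantic_similarity", "overlap", "count_diff",
]


def pair_feature_table(results, table, seqs, graph, params=None) -> pd.DataFrame:
    """Assemble the per-pair comparison table from pipeline outputs.

    ``results`` are :class:`~gosubset.paireval.PairResult` objects; sequence
    identities are aggregated over the protein cross-product of each pair,
    semantic similarity is the Wang score, overlap the shared-protein count.
    """
    from gosubset.simmatrix import term_sequence_similarity, wang_similarity

    cache: dict = {}
    rows = []
    for r in results:
        idents = {
            agg: term_sequence_similarity(r.term_i, r.term_j, table, seqs, agg=agg, _cache=cache)
            for agg in ("mean", "median", "min", "max")
        }
        rows.append({
            "term_i": r.term_i,
            "term_j": r.term_j,
            "test_f1": r.macro_f1,
            "train_f1": r.train_f1,
            "mean_identity": idents["mean"],
            "median_identity": idents["median"],
            "min_identity": idents["min"],
            "max_identity": idents["max"],
            "semantic_similarity": wang_similarity(r.term_i, r.term_j, graph),
            "overlap": r.n_shared,
            "count_diff": abs((r.n_unique_i + r.n_shared) - (r.n_unique_j + r.n_shared)),
        })
    return pd.DataFrame(rows, columns=PAIR_FEATURE_COLUMNS)


def split_by_f1(tbl: pd.DataFrame, threshold: float = 0.75, min_group: int = 30,
                column: str = "test_f1") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition pairs into low (< threshold) and high (>= threshold) F1 groups."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    low = tbl[tbl[column] < threshold]
    high = tbl[tbl[column] >= threshold]
    for name, grp in (("low", low), ("high", high)):
        if len(grp) < min_group:
            logger.warning("%s-F1 group has only %d pairs (< %d); tests may be unreliable", name, len(grp), min_group)
    return low, high


def is_normal(values: Sequence[float], statistic_threshold: float = 0.9) -> bool:
    """Shapiro-Wilk screen on the test *statistic* (not its p-value)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3 or np.ptp(values) == 0:
        return False
    return float(sps.shapiro(values).statistic) > statistic_threshold


def two_group_tests(low: Sequence[float], high: Sequence[float], normal: bool) -> dict[str, float]:
    """One-sided two-sample p-values for both tail directions.

    ``normal=True`` uses Welch's t-test; otherwise a Mann-Whitney U rank
    test (exact enumeration when the combined sample is below 25 and
    tie-free, midrank normal approximation with tie correction otherwise).
    Keys: "less" (low group tends smaller) and "greater".
    """
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    if len(low) < 3 or len(high) < 3:
        raise ValueError("both groups need at least 3 observations")
    if np.ptp(low) == 0 and np.ptp(high) == 0 and low[0] == high[0]:
        logger.warning("both groups constant and equal; degenerate p = 1")
        return {"less": 1.0, "greater": 1.0}
    out = {}
    for alt in ("less", "greater"):
        if normal:
            out[alt] = float(sps.ttest_ind(low, high, equal_var=False, alternative=alt).pvalue)
        else:
            combined = np.concatenate([low, high])
            exact = len(combined) < 25 and len(np.unique(combined)) == len(combined)
            out[alt] = float(
                sps.mannwhitneyu(low, high, alternative=alt, method="exact" if exact else "asymptotic").pvalue
            )
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on midranks); nan when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def per_term_scores(matrix, levels: Mapping[str, int], counts: Mapping[str, int]) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-term mean pair score and its rank correlations with level and count.

    The mean for a term runs over its defined (unmasked, off-diagonal) pairs;
    terms without any defined pair are excluded with a warning.
    """
    rows = []
    for i, t in enumerate(matrix.terms):
        defined = [matrix.values[i, j] for j in range(len(matrix.terms)) if j != i and not matrix.mask[i, j]]
        if not defined:
            logger.warning("term %s has no defined pair; excluded from per-term scores", t)
            continue
        rows.append({"term": t, "mean_f1": float(np.mean(defined)),
                     "level": levels[t], "count": counts[t]})
    df = pd.DataFrame(rows, columns=["term", "mean_f1", "level", "count"])
    corr = {
        "level": rank_correlation(df["mean_f1"], df["level"]) if len(df) >= 3 else float("nan"),
        "count": rank_correlation(df["mean_f1"], df["count"]) if len(df) >= 3 else float("nan"),
    }
    return df, corr


def comparative_analysis(tbl: pd.DataFrame, threshold: float = 0.75) -> pd.DataFrame:
    """Full low-vs-high comparison over every similarity variable.

    For each variable: normality screen, the appropriate one-sided tests in
    both directions, BH correction across all tests, plus Spearman
    correlations with train and test F1. Returns a tidy frame with one row
    per (variable, tail).
    """
    low, high = split_by_f1(tbl, threshold)
    variables = [c for c in tbl.columns if c not in ("term_i", "term_j", "test_f1")]
    rows = []
    for var in variables:
        normal = is_normal(tbl[var])
        if len(low) < 3 or len(high) < 3:
            logger.warning("group below 3 pairs; skipping tests for %s", var)
            tails = {"less": float("nan"), "greater": float("nan")}
        else:
            tails = two_group_tests(low[var], high[var], normal)
        for tail, p in tails.items():
            rows.append({
                "variable": var,
                "normal": normal,
                "test": "t" if normal else "mannwhitneyu",
                "tail": tail,
                "p_raw": p,
                "spearman_test_f1": rank_correlation(tbl[var], tbl["test_f1"]),
                "spearman_train_f1": rank_correlation(tbl[var], tbl["train_f1"]),
            })
    out = pd.DataFrame(rows)
    defined = out["p_raw"].notna()
    out["p_adjusted"] = float("nan")
    if defined.any():
        out.loc[defined, "p_adjusted"] = bh_adjust(out.loc[defined, "p_raw"].to_numpy())
    out["significant"] = out["p_adjusted"] < 0.05
    return out
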