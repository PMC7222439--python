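"""Concordance scoring of ATC gene sets and survival stratification.

The cumulative ATC score of a sample is the sum, over a gene set, of that
gene's expression z-score (population-SD convention) — a "cumulative
normalized expression" that is invariant to per-gene affine rescaling.
Samples ranked by this score yield ATC-prone (top n) and ATC-less (bottom n)
groups for rearrangement contrasts, or a median split for Kaplan-Meier /
log-rank survival comparison.  Gene-gene correlation profiles (expression
and copy-number layers, genes in genomic order) provide the concordance
diagnostics.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "correlation_profile",
    "cumulative_score",
    "logrank_test",
    "select_extreme_samples",
    "split_by_median",
]


def cumulative_score(expression: pd.DataFrame, gene_set) -> pd.Series:
    """Per-sample cumulative normalized expression over ``gene_set``.

    Each gene row is z-scored across samples (mean 0, population SD 1) and
    the z-scores are summed per sample.  Zero-variance genes contribute 0
    (with a warning).
    """
    gene_set = list(gene_set)
    missing = [g for g in gene_set if g not in expression.index]
    if missing:
        raise ValueError(f"gene set members absent from expression matrix: {missing[:5]}...")
    sub = expression.loc[gene_set].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s) contribute 0 to the cumulative score", stacklevel=2)
    z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(z.sum(axis=0), index=expression.columns, name="atc_score")


def select_extreme_samples(scores: pd.Series, n_top: int = 15) -> pd.DataFrame:
    """Label the top/bottom ``n_top`` samples by score as prone / less.

    Returns a frame (index = sample) with columns score, rank (1 = highest)
    and group in {prone, less, middle}.  Ties break deterministically by
    sample id.  Requires at least ``2 * n_top`` samples.
    """
    if len(scores) < 2 * n_top:
        raise ValueError(f"need >= {2 * n_top} samples to pick {n_top} prone and {n_top} less; got {len(scores)}")
    df = scores.rename("score").rename_axis("sample").reset_index()
    df = df.sort_values(["score", "sample"], ascending=[False, True], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    group = np.full(len(df), "middle", dtype=object)
    group[:n_top] = "prone"
    group[len(df) - n_top:] = "less"
    df["group"] = group
    return df.set_index("sample")


def correlation_profile(expression: pd.DataFrame, genes_in_order, samples=None) -> pd.DataFrame:
    """Symmetric pairwise Pearson matrix of genes in genomic order.

    ``samples`` optionally restricts to a subset (e.g. the 10 samples with
    the highest cumulative score) before correlating.  Zero-variance genes
    yield NaN rows/columns (undefined, excluded from summaries); the
    diagonal is 1 for well-defined genes.
    """
    genes_in_order = list(genes_in_order)
    sub = expression.loc[genes_in_order]
    if samples is not None:
        sub = sub[list(samples)]
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 samples for a correlation profile")
    arr = sub.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(arr)
    flat = arr.std(axis=1) == 0
    mat[flat, :] = np.nan
    mat[:, flat] = np.nan
    np.fill_diagonal(mat, np.where(flat, np.nan, 1.0))
    return pd.DataFrame(mat, index=genes_in_order, columns=genes_in_order)


class LogrankResult(NamedTuple):
    statistic: float  # chi-square, 1 df
    pvalue: float
    n_a: int
    n_b: int


def logrank_test(times, events, groups) -> LogrankResult:
    """Two-group log-rank test of survival curves.

    ``groups`` is a boolean/two-level label vector.  Returns the chi-square
    statistic (1 df) and p-value.  With no observed events anywhere the
    test is undefined and (nan, nan) is returned.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two groups, got {list(uniq)}")
    in_a = groups == uniq[0]
    if in_a.all() or (~in_a).all():
        raise ValueError("both groups must be nonempty")
    if events.sum() == 0:
        return LogrankResult(float("nan"), float("nan"), int(in_a.sum()), int((~in_a).sum()))
    res = _ll_logrank(times[in_a], times[~in_a], event_observed_A=events[in_a], event_observed_B=events[~in_a])
    return LogrankResult(float(res.test_statistic), float(res.p_value), int(in_a.sum()), int((~in_a).sum()))


def split_by_median(scores: pd.Series) -> pd.Series:
    """Median split: score > median -> 'high', score <= median -> 'low'."""
    scores = pd.Series(scores)
    if len(scores) < 2:
        raise ValueError("need >= 2 samples for a median split")
    med = float(scores.median())
    return pd.Series(np.where(scores.to_numpy() > med, "high", "low"), index=scores.index, name="group")
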