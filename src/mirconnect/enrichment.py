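"""Predicted-target processing and method-comparison statistics.

TargetScan-style site scores are aggregated per (miRNA, gene) pair into a
total context score — only non-positive site scores contribute, and a family's
aggregate prediction is the minimum (most negative) member total.  Two
method-level comparisons are built on top: the per-miRNA log2 ratio of
negative vs positive correlator counts (with a one-sided two-sample
Kolmogorov–Smirnov test between methods), and the neg/pos ratio curve over the
top-k predicted pairs ranked by prediction strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import CorrelationTable

__all__ = [
    "RatioCurve",
    "total_context_score",
    "aggregate_site_scores",
    "family_aggregate_prediction",
    "neg_pos_log2_ratio",
    "neg_pos_log2_ratios",
    "ks_one_sided",
    "prediction_ratio_curve",
    "default_k_grid",
]


def default_k_grid() -> list[int]:
    """Top-50 to top-500 predicted pairs in steps of 50."""
    return list(range(50, 501, 50))


@dataclass
class RatioCurve:
    """Negative-to-positive correlation-count ratios over a top-k grid."""

    table: pd.DataFrame  # columns: k, n_negative, n_positive, ratio, flagged
    method: str = ""

    def __post_init__(self) -> None:
        k = self.table["k"].to_numpy()
        if not np.all(np.diff(k) > 0):
            raise ValueError("k grid must be strictly increasing")
        if (self.table["ratio"] < 0).any():
            raise ValueError("ratios must be non-negative")

    @property
    def ratios(self) -> np.ndarray:
        return self.table["ratio"].to_numpy()

    @property
    def k_values(self) -> np.ndarray:
        return self.table["k"].to_numpy()


def total_context_score(site_scores: Iterable[float]) -> float | None:
    """Sum of the non-positive site context scores; ``None`` when no site
    qualifies (the pair is dropped from predictions)."""
    keep = [s for s in site_scores if s <= 0]
    if not keep:
        return None
    return float(sum(keep))


def aggregate_site_scores(sites: pd.DataFrame) -> pd.DataFrame:
    """Collapse site-level rows (mirna, gene, context_score) into unique
    (mirna, gene, total_context_score) pairs."""
    if "total_context_score" in sites.columns:
        out = sites[["mirna", "gene", "total_context_score"]].copy()
        if out.duplicated(subset=["mirna", "gene"]).any():
            raise ValueError("duplicate (mirna, gene) pair in aggregated predictions")
        return out
    rows = []
    for (mirna, gene), grp in sites.groupby(["mirna", "gene"], sort=True):
        total = total_context_score(grp["context_score"])
        if total is not None:
            rows.append({"mirna": mirna, "gene": gene, "total_context_score": total})
    return pd.DataFrame(rows, columns=["mirna", "gene", "total_context_score"])


def family_aggregate_prediction(member_totals: Mapping[str, float]) -> float:
    """Family prediction = the minimum (most negative) member total."""
    if not member_totals:
        raise ValueError("family has no member predictions")
    return float(min(member_totals.values()))


def neg_pos_log2_ratio(
    values: pd.Series | np.ndarray,
    cutoff: float = 0.0,
    pseudocount: float = 1.0,
) -> tuple[float, bool]:
    """log2(negative count / positive count) of one miRNA's correlation values.

    A gene counts as negative/positive when its value is strictly below
    ``-cutoff`` / above ``cutoff`` (``nan`` sentinels excluded).  When either
    count is zero the pseudocount is added to both sides and the result is
    flagged.  Returns ``(log2_ratio, flagged)``.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    neg = float((v < -cutoff).sum())
    pos = float((v > cutoff).sum())
    flagged = neg == 0 or pos == 0
    if flagged:
        neg += pseudocount
        pos += pseudocount
    return float(np.log2(neg / pos)), flagged


def neg_pos_log2_ratios(
    tables: Mapping[str, CorrelationTable],
    column: str = "spcc",
    cutoff: float = 0.0,
    normalize: bool = False,
) -> pd.Series:
    """Per-miRNA log2(neg/pos) ratios for one method across a panel.

    With ``normalize=True`` sPCC-scale columns are divided by the pattern
    count first so one cutoff is comparable across methods.
    """
    out = {}
    for mirna, table in tables.items():
        vals = table.values(column)
        if normalize and column in ("spcc", "rspcc") and table.n_patterns:
            vals = vals / table.n_patterns
        out[mirna], _ = neg_pos_log2_ratio(vals, cutoff=cutoff)
    return pd.Series(out).sort_index()


def ks_one_sided(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """One-sided two-sample KS test that A is stochastically larger than B.

    The statistic is D+ = sup_x [F_B(x) - F_A(x)]; the p-value is the
    asymptotic one-sided bound exp(-2 D+^2 * n_a n_b / (n_a + n_b)).
    Returns ``(D, p)``.
    """
    a = np.sort(np.asarray(sample_a, float))
    b = np.sort(np.asarray(sample_b, float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / a.size
    fb = np.searchsorted(b, grid, side="right") / b.size
    d = float(np.max(fb - fa))
    d = max(d, 0.0)
    ne = a.size * b.size / (a.size + b.size)
    p = float(min(1.0, np.exp(-2.0 * d * d * ne)))
    return d, p


def prediction_ratio_curve(
    predictions: pd.DataFrame,
    tables: Mapping[str, CorrelationTable],
    column: str = "spcc",
    k_grid: Sequence[int] | None = None,
    rank_direction: str = "ascending",
    pseudocount: float = 1.0,
    method: str = "",
) -> RatioCurve:
    """Neg/pos correlation-count ratios among the top-k predicted pairs.

    ``predictions`` holds (mirna, gene, total_context_score) rows.  The
    strongest prediction is the most negative total score, so the default
    ranking is ascending by score; ties break by (mirna, gene) name.  At each
    k the correlation values of the top-k pairs are counted by sign (pairs
    with no correlation value are skipped); a zero positive count is reported
    with the pseudocount and flagged.
    """
    if rank_direction not in ("ascending", "descending"):
        raise ValueError("rank_direction must be 'ascending' or 'descending'")
    if k_grid is None:
        k_grid = default_k_grid()
    ranked = predictions.sort_values(
        ["total_context_score", "mirna", "gene"],
        ascending=[rank_direction == "ascending", True, True],
        kind="stable",
    )
    # correlation value per predicted pair, nan when unavailable
    vals = np.full(len(ranked), np.nan)
    for i, (mirna, gene) in enumerate(zip(ranked["mirna"], ranked["gene"])):
        table = tables.get(mirna)
        if table is not None and gene in table.data.index:
            vals[i] = table.data.at[gene, column]
    rows = []
    for k in k_grid:
        v = vals[:k]
        v = v[np.isfinite(v)]
        n_neg = int((v < 0).sum())
        n_pos = int((v > 0).sum())
        flagged = n_pos == 0
        ratio = n_neg / (n_pos if n_pos else pseudocount)
        rows.append(
            {"k": k, "n_negative": n_neg, "n_positive": n_pos,
             "ratio": float(ratio), "flagged": flagged}
        )
    return RatioCurve(table=pd.DataFrame(rows), method=method)
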