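"""Scoring miRNAs and their functional clusters against gene signatures.

Counts how many genes of a signature (EMT epithelial/mesenchymal sets, c-MYC
induced/repressed sets, ribosomal proteins) fall among a miRNA's positive or
negative correlators — either by membership in the top-N correlator lists or by
a symmetric correlation-value cutoff — and turns the counts into net scores and
the epithelial/mesenchymal (E/M) factor:

    E/M = (neg M - pos M) + (pos E - neg E)

Cluster-level enrichment uses a two-sided Wilcoxon rank-sum test of each
cluster's scores against all other miRNAs, with midranks and exact enumeration
at small sizes.  Host-gene pairs and HOX-like gene blocks provide positive
controls: a co-transcribed miRNA should correlate positively with its host
gene, and the miRNA encoded inside a gene block should top that block's
cumulative-score ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterAssignment
from .correlate import top_correlators
from .data import CorrelationTable, GeneSignature, HostPairTable

__all__ = [
    "SignatureCounts",
    "count_gene_set",
    "count_signature_correlators",
    "net_score",
    "em_factor",
    "rank_by_factor",
    "rank_sum_test",
    "significance_tier",
    "cluster_enrichment",
    "host_pair_correlations",
    "hox_cumulative_scores",
    "EXACT_ENUM_LIMIT",
]

#: largest number of rank assignments enumerated exactly by the rank-sum test
EXACT_ENUM_LIMIT = 200_000


@dataclass(frozen=True)
class SignatureCounts:
    """Signature genes found among positive/negative correlators, by direction."""

    pos_up: int = 0
    neg_up: int = 0
    pos_down: int = 0
    neg_down: int = 0


def count_gene_set(
    genes: Sequence[str],
    values: pd.Series,
    mode: str = "threshold",
    cutoff: float = 1.0,
    top_n: int = 2000,
) -> tuple[int, int]:
    """(positive, negative) correlator counts for a direction-less gene set.

    ``threshold`` mode counts genes with value strictly > cutoff (positive) or
    < -cutoff (negative); values inside [-cutoff, cutoff] are uncounted.
    ``topn`` mode counts membership in the top-``top_n`` positive/negative
    correlator lists.  Genes absent from ``values`` count as neither.
    """
    if mode == "threshold":
        present = values.reindex(genes).dropna()
        return int((present > cutoff).sum()), int((present < -cutoff).sum())
    if mode == "topn":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pos = set(top_correlators(values, n=top_n, sign="positive"))
            neg = set(top_correlators(values, n=top_n, sign="negative"))
        gene_set = set(genes)
        return len(gene_set & pos), len(gene_set & neg)
    raise ValueError("mode must be 'threshold' or 'topn'")


def count_signature_correlators(
    signature: GeneSignature,
    corr: CorrelationTable | pd.Series,
    mode: str = "threshold",
    cutoff: float = 1.0,
    top_n: int = 2000,
    column: str = "spcc",
) -> SignatureCounts:
    """Per-direction correlator counts of a signature for one miRNA."""
    values = corr.values(column) if isinstance(corr, CorrelationTable) else corr
    pos_up, neg_up = count_gene_set(signature.up_genes, values, mode, cutoff, top_n)
    pos_down, neg_down = count_gene_set(signature.down_genes, values, mode, cutoff, top_n)
    return SignatureCounts(pos_up=pos_up, neg_up=neg_up, pos_down=pos_down, neg_down=neg_down)


def net_score(n_positive: int, n_negative: int) -> int:
    """Positively correlating count minus negatively correlating count."""
    return int(n_positive) - int(n_negative)


def em_factor(counts: SignatureCounts) -> int:
    """(neg M - pos M) + (pos E - neg E); E = up genes, M = down genes."""
    return (counts.neg_down - counts.pos_down) + (counts.pos_up - counts.neg_up)


def rank_by_factor(factors: Mapping[str, float]) -> list[str]:
    """miRNAs sorted by factor, descending; ties break by name."""
    return [m for m, _ in sorted(factors.items(), key=lambda kv: (-kv[1], kv[0]))]


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value with midranks.

    The null distribution is enumerated exactly when the number of rank
    assignments C(n1+n2, n1) is at most ``EXACT_ENUM_LIMIT``; otherwise the
    normal approximation with tie correction is used.  Degenerate inputs
    (all values identical) give p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    n1, n2 = x.size, y.size
    n = n1 + n2
    if comb(n, min(n1, n2)) <= EXACT_ENUM_LIMIT:
        k = min(n1, n2)
        target = w if n1 <= n2 else float(ranks.sum() - w)  # sum for the smaller group
        sums = np.fromiter(
            (sum(c) for c in combinations(ranks, k)), dtype=float, count=comb(n, k)
        )
        tol = 1e-9
        p_le = float((sums <= target + tol).mean())
        p_ge = float((sums >= target - tol).mean())
        return min(1.0, 2.0 * min(p_le, p_ge))
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (w - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def significance_tier(p: float) -> str:
    """Tier labels matching the red/orange/yellow convention."""
    if p < 1e-4:
        return "0.0001"
    if p < 1e-3:
        return "0.001"
    if p < 1e-2:
        return "0.01"
    return "ns"


def cluster_enrichment(
    scores: Mapping[str, float],
    clusters: ClusterAssignment,
) -> pd.DataFrame:
    """Rank-sum enrichment of each functional cluster's scores vs the rest.

    Returns one row per cluster with n, median score, two-sided p and tier.
    """
    labels = clusters.labels
    missing = sorted(set(labels) - set(scores))
    if missing:
        raise KeyError(f"no score for miRNAs {missing[:3]}")
    all_names = list(labels)
    if len(set(labels.values())) < 2:
        raise ValueError("need at least 2 clusters")
    rows = []
    for label in sorted(set(labels.values())):
        inside = [scores[m] for m in all_names if labels[m] == label]
        outside = [scores[m] for m in all_names if labels[m] != label]
        if not outside:
            raise ValueError(f"cluster {label!r} contains every miRNA")
        p = rank_sum_test(inside, outside)
        rows.append(
            {
                "cluster": label,
                "n": len(inside),
                "median_score": float(np.median(inside)),
                "p_value": p,
                "tier": significance_tier(p),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def host_pair_correlations(
    pairs: HostPairTable,
    tables: Mapping[str, CorrelationTable],
    cutoff: float = 0.2,
    dpcc_cutoff: float | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-pair sPCC/dPCC of miRNAs with their host genes, plus sign counts.

    The summary counts use the normalised sPCC (sPCC / n_patterns) so a single
    cutoff (0.2 by default) serves both methods; the sign test is strict
    (> cutoff positive, < -cutoff negative, the rest neutral).  Pairs whose
    miRNA or gene is absent are flagged ``missing`` and excluded from counts.
    """
    rows = []
    counts = {"positive": 0, "negative": 0, "neutral": 0, "missing": 0}
    for mirna, gene in pairs.pairs:
        row: dict[str, object] = {"mirna": mirna, "host_gene": gene}
        table = tables.get(mirna)
        if table is None or gene not in table.data.index:
            row["status"] = "missing"
            counts["missing"] += 1
            rows.append(row)
            continue
        spcc = float(table.data.at[gene, "spcc"]) if "spcc" in table.data.columns else np.nan
        dpcc = float(table.data.at[gene, "dpcc"]) if "dpcc" in table.data.columns else np.nan
        norm = spcc / table.n_patterns if table.n_patterns else np.nan
        row.update(spcc=spcc, spcc_normalized=norm, dpcc=dpcc)
        if not np.isfinite(norm):
            row["status"] = "missing"
            counts["missing"] += 1
        elif norm > cutoff:
            row["status"] = "positive"
            counts["positive"] += 1
        elif norm < -cutoff:
            row["status"] = "negative"
            counts["negative"] += 1
        else:
            row["status"] = "neutral"
            counts["neutral"] += 1
        rows.append(row)
    return pd.DataFrame(rows), counts


def hox_cumulative_scores(
    gene_clusters: Mapping[str, Sequence[str]],
    tables: Mapping[str, CorrelationTable],
    column: str = "spcc",
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Cumulative per-(miRNA, gene-block) scores and per-block miRNA rankings.

    The cumulative score of a miRNA for a block is the sum of its per-gene
    correlation values over the block members; genes absent from a table
    contribute 0 (with a warning).  Rankings are descending, ties broken by
    miRNA name.
    """
    scores: dict[str, dict[str, float]] = {}
    for block, genes in gene_clusters.items():
        if len(genes) == 0:
            warnings.warn(f"gene block {block!r} is empty; scores are 0")
        for mirna, table in tables.items():
            vals = table.values(column).reindex(genes)
            n_missing = int(vals.isna().sum())
            if n_missing:
                warnings.warn(
                    f"{n_missing} gene(s) of block {block!r} absent for {mirna!r}"
                )
            scores.setdefault(mirna, {})[block] = float(vals.fillna(0.0).sum())
    df = pd.DataFrame.from_dict(scores, orient="index").sort_index()
    rankings = {
        block: [m for m, _ in sorted(df[block].items(), key=lambda kv: (-kv[1], kv[0]))]
        for block in df.columns
    }
    return df, rankings
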