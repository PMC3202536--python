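"""The in-silico titration statistic and its controls.

For one miRNA profile across a panel of samples, samples are ranked from highest
to lowest miRNA expression and nested "patterns" are formed: pattern ``m`` holds
the ``m`` most-expressing samples, pattern ``m+1`` adds the next one, and so on
until all samples are included.  A Pearson correlation (PCC) between the miRNA
and a gene is computed within every pattern and the values are added up — the
summed PCC (sPCC).  Because the top samples sit in every pattern, they are
implicitly up-weighted, mimicking a titration of the miRNA.  The direct PCC
(dPCC) is the ordinary all-sample correlation; the randomized sPCC (rsPCC)
repeats the summation over random sample orderings (10 by default, averaged)
as a negative control for the titration design.

Per-probe statistics are averaged per gene across microarray platforms; the
undefined-result sentinel throughout is ``nan``.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import CorrelationTable, ExpressionMatrix, MiRNAProfile, ProbeGeneMap

__all__ = [
    "PatternSeries",
    "pearson",
    "build_patterns",
    "summed_pcc",
    "randomized_spcc",
    "direct_pcc",
    "pattern_pccs",
    "collapse_and_average",
    "top_correlators",
    "correlate_profile",
    "correlate_panel",
    "DEFAULT_MIN_SIZE",
    "DEFAULT_MIN_PAIRS",
    "DEFAULT_N_REPS",
    "DEFAULT_TOP_N",
]

DEFAULT_MIN_SIZE = 30   #: initial pattern size (top half of a 59-sample panel)
DEFAULT_MIN_PAIRS = 10  #: minimum complete pairs for a single PCC
DEFAULT_N_REPS = 10     #: randomized orderings averaged by the rsPCC
DEFAULT_TOP_N = 2000    #: correlator genes kept per sign (~10% of the genome)

_VAR_TOL = 1e-12


@dataclass(frozen=True)
class PatternSeries:
    """Nested sample subsets in descending miRNA-expression order.

    ``order`` ranks sample indices from highest to lowest expression; pattern
    ``k`` (k = 0 .. n_patterns-1) is ``order[: min_size + k]``, so each pattern
    is a strict superset of the previous and the last covers all samples.
    """

    order: np.ndarray
    min_size: int

    @property
    def n_samples(self) -> int:
        return self.order.size

    @property
    def n_patterns(self) -> int:
        return self.n_samples - self.min_size + 1

    def pattern(self, k: int) -> np.ndarray:
        if not 0 <= k < self.n_patterns:
            raise IndexError(f"pattern {k} out of range")
        return self.order[: self.min_size + k]

    def __iter__(self) -> Iterator[np.ndarray]:
        for k in range(self.n_patterns):
            yield self.pattern(k)


def build_patterns(
    profile: MiRNAProfile | np.ndarray,
    min_size: int = DEFAULT_MIN_SIZE,
    sample_ids: Sequence[str] | None = None,
) -> PatternSeries:
    """Rank samples by miRNA expression (highest first) and build nested patterns.

    Ties are broken by sample ID (or index) in lexicographic order so the
    ranking — and everything downstream — is deterministic.  Missing miRNA
    values rank last.
    """
    values = profile.values if isinstance(profile, MiRNAProfile) else np.asarray(profile, float)
    n = values.size
    if n < min_size:
        raise ValueError(f"{n} samples but min_size={min_size}")
    key = np.where(np.isfinite(values), values, -np.inf)
    tiebreak = np.array([str(s) for s in sample_ids]) if sample_ids is not None \
        else np.arange(n)
    # lexsort: last key is primary; negate for descending expression
    order = np.lexsort((tiebreak, -key))
    return PatternSeries(order=order, min_size=min_size)


def pearson(x: np.ndarray, y: np.ndarray, min_pairs: int = DEFAULT_MIN_PAIRS) -> float:
    """Product-moment correlation over complete pairs; ``nan`` when undefined.

    Pairs where either value is missing are dropped.  Fewer than ``min_pairs``
    complete pairs, or zero variance in either vector, yields ``nan``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < max(min_pairs, 2):
        return float("nan")
    xs = x[ok] - x[ok].mean()
    ys = y[ok] - y[ok].mean()
    vx = float(xs @ xs)
    vy = float(ys @ ys)
    if vx <= _VAR_TOL * n or vy <= _VAR_TOL * n:
        return float("nan")
    r = float(xs @ ys) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def direct_pcc(
    profile: MiRNAProfile | np.ndarray,
    gene_values: np.ndarray,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> float:
    """All-sample PCC (the standard single-correlation analysis)."""
    values = profile.values if isinstance(profile, MiRNAProfile) else profile
    return pearson(values, gene_values, min_pairs=min_pairs)


def summed_pcc(
    profile: MiRNAProfile | np.ndarray,
    gene_values: np.ndarray,
    patterns: PatternSeries,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> float:
    """Sum of the per-pattern PCCs.

    Patterns whose PCC is undefined are skipped; if fewer than half the
    patterns are defined the whole sPCC is reported as ``nan``.
    """
    values = profile.values if isinstance(profile, MiRNAProfile) else np.asarray(profile, float)
    gene_values = np.asarray(gene_values, float)
    rs = np.array([pearson(values[p], gene_values[p], min_pairs) for p in patterns])
    n_eff = int(np.isfinite(rs).sum())
    if n_eff < patterns.n_patterns / 2 or n_eff == 0:
        return float("nan")
    return float(np.nansum(rs))


def randomized_spcc(
    profile: MiRNAProfile | np.ndarray,
    gene_values: np.ndarray,
    min_size: int = DEFAULT_MIN_SIZE,
    n_reps: int = DEFAULT_N_REPS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    orderings: Sequence[np.ndarray] | None = None,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> float:
    """Mean summed PCC over randomly ordered samples (negative control).

    ``orderings`` may pin the sample orderings explicitly (e.g. the true
    expression ranking, in which case a single replicate equals the sPCC);
    otherwise ``n_reps`` uniform random permutations are drawn from ``rng`` or
    ``seed``.
    """
    values = profile.values if isinstance(profile, MiRNAProfile) else np.asarray(profile, float)
    n = values.size
    if orderings is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        if n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        orderings = [rng.permutation(n) for _ in range(n_reps)]
    reps = []
    for order in orderings:
        series = PatternSeries(order=np.asarray(order), min_size=min_size)
        reps.append(summed_pcc(values, gene_values, series, min_pairs=min_pairs))
    reps = np.asarray(reps, float)
    if not np.isfinite(reps).any():
        return float("nan")
    return float(np.nanmean(reps))


# ---------------------------------------------------------------------------
# vectorised engine


def pattern_pccs(
    x: np.ndarray,
    G: np.ndarray,
    patterns: PatternSeries,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> np.ndarray:
    """PCC of ``x`` with every row of ``G`` inside every pattern.

    Returns an (n_rows, n_patterns) matrix.  Because patterns are nested
    prefixes of one sample ordering, all pattern statistics come from a single
    pass of prefix sums over the reordered columns — missing values excluded
    pairwise.
    """
    x = np.asarray(x, float)
    G = np.atleast_2d(np.asarray(G, float))
    order = patterns.order
    xo = x[order]
    Go = G[:, order]
    # global centering improves conditioning; PCC is shift-invariant per pattern
    xo = xo - np.nanmean(xo) if np.isfinite(xo).any() else xo
    mu = np.nanmean(np.where(np.isfinite(Go), Go, np.nan), axis=1, keepdims=True)
    Go = Go - np.where(np.isfinite(mu), mu, 0.0)

    valid = np.isfinite(Go) & np.isfinite(xo)[None, :]
    Xv = np.where(valid, xo[None, :], 0.0)
    Gv = np.where(valid, Go, 0.0)
    ends = np.arange(patterns.min_size - 1, patterns.n_samples)
    n = np.cumsum(valid, axis=1)[:, ends].astype(float)
    sx = np.cumsum(Xv, axis=1)[:, ends]
    sy = np.cumsum(Gv, axis=1)[:, ends]
    sxx = np.cumsum(Xv * Xv, axis=1)[:, ends]
    syy = np.cumsum(Gv * Gv, axis=1)[:, ends]
    sxy = np.cumsum(Xv * Gv, axis=1)[:, ends]

    with np.errstate(invalid="ignore", divide="ignore"):
        n_safe = np.maximum(n, 1.0)
        vx = sxx - sx * sx / n_safe
        vy = syy - sy * sy / n_safe
        cov = sxy - sx * sy / n_safe
        denom = np.sqrt(np.maximum(vx, 0.0) * np.maximum(vy, 0.0))
        r = cov / denom
    bad = (n < max(min_pairs, 2)) | (vx <= _VAR_TOL * n_safe) | (vy <= _VAR_TOL * n_safe)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    return r


def _spcc_from_patterns(R: np.ndarray, n_patterns: int) -> np.ndarray:
    """Apply the skip policy along the pattern axis of a PCC matrix."""
    n_eff = np.isfinite(R).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s = np.nansum(R, axis=1)
    s = np.where((n_eff < n_patterns / 2) | (n_eff == 0), np.nan, s)
    return s


def collapse_and_average(
    per_probe_values: Mapping[str, pd.Series],
    probe_map: ProbeGeneMap,
    mode: str = "probe",
) -> tuple[pd.Series, pd.Series]:
    """Average per-probe statistics into per-gene values across platforms.

    ``mode="probe"`` (default) takes a flat unweighted mean over every defined
    probe-level value across all platforms; ``mode="platform"`` averages within
    each platform first and then across platform means.  Undefined (``nan``)
    probes are excluded; a gene with no defined probe anywhere is absent from
    the output.  Returns ``(gene_values, n_probes_used)``.
    """
    if mode not in ("probe", "platform"):
        raise ValueError("mode must be 'probe' or 'platform'")
    frames = []
    for platform, series in per_probe_values.items():
        pmap = probe_map.for_platform(platform)
        genes = series.index.map(pmap.get)
        df = pd.DataFrame({"gene": genes, "value": series.to_numpy(), "platform": platform})
        frames.append(df[df["gene"].notna()])
    if not frames:
        return pd.Series(dtype=float), pd.Series(dtype=int)
    combined = pd.concat(frames, ignore_index=True)
    defined = combined[np.isfinite(combined["value"])]
    n_probes = defined.groupby("gene")["value"].size()
    if mode == "probe":
        values = defined.groupby("gene")["value"].mean()
    else:
        per_platform = defined.groupby(["gene", "platform"])["value"].mean()
        values = per_platform.groupby("gene").mean()
    values = values.sort_index()
    return values, n_probes.reindex(values.index).astype(int)


def top_correlators(
    values: pd.Series,
    n: int = DEFAULT_TOP_N,
    sign: str = "positive",
) -> list[str]:
    """Genes with the ``n`` strongest correlations of the requested sign.

    Positive: genes with value > 0 sorted descending; negative: value < 0
    sorted ascending.  Ties break by gene name.  If fewer than ``n`` genes of
    that sign exist, all are returned with a warning.
    """
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    vals = values.dropna()
    if sign == "positive":
        vals = vals[vals > 0]
        vals = vals.sort_index().sort_values(ascending=False, kind="stable")
    else:
        vals = vals[vals < 0]
        vals = vals.sort_index().sort_values(ascending=True, kind="stable")
    if len(vals) < n:
        warnings.warn(
            f"only {len(vals)} {sign} correlators available (requested {n})",
            stacklevel=2,
        )
    return list(vals.index[:n])


def _profile_rng(seed: int | None, name: str) -> np.random.Generator:
    """Per-profile generator so rsPCC draws do not depend on iteration order."""
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng([0 if seed is None else seed, tag])


def correlate_profile(
    profile: MiRNAProfile,
    mrna_matrices: Sequence[ExpressionMatrix],
    probe_map: ProbeGeneMap,
    sample_ids: Sequence[str],
    methods: Sequence[str] = ("spcc", "dpcc"),
    min_size: int = DEFAULT_MIN_SIZE,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    n_reps: int = DEFAULT_N_REPS,
    seed: int | None = None,
    collapse: str = "probe",
) -> CorrelationTable:
    """Full per-gene correlation table for one miRNA (or family) profile.

    ``sample_ids`` names the samples the profile's values are ordered by; every
    mRNA matrix must cover the same samples (any column order).  Methods may be
    any subset of ``{"spcc", "dpcc", "rspcc"}``; rsPCC requires a seed for the
    random orderings.
    """
    for m in methods:
        if m not in ("spcc", "dpcc", "rspcc"):
            raise ValueError(f"unknown method {m!r}")
    if "rspcc" in methods and seed is None:
        raise ValueError("rspcc requires a seed")
    patterns = build_patterns(profile, min_size=min_size, sample_ids=sample_ids)
    rng = _profile_rng(seed, profile.name)
    orderings = [rng.permutation(patterns.n_samples) for _ in range(n_reps)] \
        if "rspcc" in methods else []

    per_method: dict[str, dict[str, pd.Series]] = {m: {} for m in methods}
    for matrix in mrna_matrices:
        missing = sorted(set(sample_ids) - set(matrix.sample_ids))
        if missing:
            raise ValueError(
                f"platform {matrix.platform!r} lacks samples {missing[:3]}"
            )
        col_idx = [matrix.sample_ids.index(s) for s in sample_ids]
        G = matrix.values[:, col_idx]
        probe_index = pd.Index(matrix.entity_ids)
        R = pattern_pccs(profile.values, G, patterns, min_pairs=min_pairs)
        if "spcc" in methods:
            per_method["spcc"][matrix.platform] = pd.Series(
                _spcc_from_patterns(R, patterns.n_patterns), index=probe_index
            )
        if "dpcc" in methods:
            # the last pattern spans all samples: its PCC is the direct PCC
            per_method["dpcc"][matrix.platform] = pd.Series(R[:, -1], index=probe_index)
        if "rspcc" in methods:
            reps = np.empty((G.shape[0], n_reps))
            for j, order in enumerate(orderings):
                series = PatternSeries(order=order, min_size=min_size)
                Rj = pattern_pccs(profile.values, G, series, min_pairs=min_pairs)
                reps[:, j] = _spcc_from_patterns(Rj, series.n_patterns)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(reps, axis=1)
            per_method["rspcc"][matrix.platform] = pd.Series(mean, index=probe_index)

    data: dict[str, pd.Series] = {}
    n_probes: pd.Series | None = None
    for m in methods:
        values, counts = collapse_and_average(per_method[m], probe_map, mode=collapse)
        data[m] = values
        if n_probes is None:
            n_probes = counts
    df = pd.DataFrame(data)
    if n_probes is not None:
        df["n_probes_used"] = n_probes.reindex(df.index)
    return CorrelationTable(mirna=profile.name, data=df, n_patterns=patterns.n_patterns)


def correlate_panel(
    profiles: Sequence[MiRNAProfile],
    mrna_matrices: Sequence[ExpressionMatrix],
    probe_map: ProbeGeneMap,
    sample_ids: Sequence[str],
    **kwargs,
) -> dict[str, CorrelationTable]:
    """Correlation tables for a list of profiles, keyed by miRNA name."""
    return {
        p.name: correlate_profile(p, mrna_matrices, probe_map, sample_ids, **kwargs)
        for p in profiles
    }
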