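"""Synthetic cell-line-panel generator with planted, titration-shaped structure.

The generator emulates the situation the titration statistic was designed for:
a steady-state panel (59 cell lines, 4 microarray platforms with redundant
probes, a miRNA detection limit) in which a miRNA's suppression of its effector
genes is visible only in the cells that actually express the miRNA highly.

Planted structure, per miRNA:

* **Titration-suppressed genes.** In samples whose (standardised, log-scale)
  miRNA expression ``z`` exceeds its ``q``-quantile ``t``, a suppressed gene is
  pulled down by ``-u * (z - t)`` (``u`` = per-pair strength).  In the
  remaining samples the gene is governed by other regulation: high independent
  variance plus an offset chosen so the structural part of the all-sample
  covariance between gene and miRNA cancels exactly.  The all-sample (direct)
  correlation is therefore ~0 while the top-expression patterns see a clean
  negative correlation — the contrast the summed statistic exploits.
* **Host genes** co-transcribed with their miRNA (a global linear term), and a
  HOX-like co-expressed gene block tied to one miRNA.
* **An epithelial/mesenchymal signature block** driven by a latent factor that
  also drives a designated miRNA family (positively) and one miRNA
  (negatively).
* **Seed families** whose members share a common expression driver and a
  common suppressed gene block.

Everything is reproducible from the config seed alone.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .data import (
    CorrelationTable,
    ExpressionMatrix,
    GeneSignature,
    HostPairTable,
    ProbeGeneMap,
)

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "SyntheticDataset",
    "generate",
    "enrichment_panel_config",
    "predictions_from_truth",
    "truth_report",
]


def enrichment_panel_config(seed: int) -> "SyntheticConfig":
    """A smaller panel tuned for prediction-ratio-curve analyses.

    Noise parameters match the default panel; the miRNA count and the
    suppressed-set size are chosen so the ~500 planted predicted pairs span
    the whole suppression-strength gradient without saturating at the top of
    the ranking, and the base strength equals the noise standard deviation.
    """
    return SyntheticConfig(
        seed=seed,
        n_mirnas=18,
        n_genes=1000,
        singleton_pool_size=500,
        n_suppressed_per_mirna=28,
        suppression_beta=1.0,
        suppression_strength_range=(0.25, 2.0),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic panel.  ``seed`` is required."""

    seed: int
    n_samples: int = 59
    n_platforms: int = 4
    n_mirnas: int = 60           #: analysis miRNAs (well detectable)
    n_low_mirnas: int = 2        #: miRNAs planted below the detection limit
    n_genes: int = 1900
    probes_per_gene: tuple[int, int] = (1, 3)  # uniform inclusive range per platform
    noise_sd: float = 1.0        #: per-gene-per-sample measurement/biology noise
    probe_noise_sd: float = 0.5  #: extra independent noise per probe replicate
    other_regulation_sd: float = 1.0  #: gene variance in samples not expressing the miRNA
    detection_limit: float = 1.0      #: log2 expression below this is undetectable
    suppression_q: float = 0.5        #: suppression active above this miRNA quantile
    suppression_beta: float = 1.5     #: base strength scale (comparable to noise_sd)
    suppression_strength_range: tuple[float, float] = (0.75, 2.0)
    n_suppressed_per_mirna: int = 30
    n_families: int = 2
    family_size: int = 3
    family_member_noise: float = 0.3
    n_host_pairs: int = 10
    host_alpha: float = 0.8      #: co-transcription coefficient
    hox_block_size: int = 8
    hox_alpha: float = 0.9
    n_epithelial_genes: int = 25
    n_mesenchymal_genes: int = 25
    signature_gamma: float = 1.2  #: latent-factor loading of signature genes
    singleton_pool_size: int = 1300
    overlapping_suppression: bool = True  #: singletons may share pool targets
    missing_rate: float = 0.01   #: random missing cells per mRNA platform

    def __post_init__(self) -> None:
        for name in (
            "n_samples", "n_platforms", "n_mirnas", "n_genes",
            "n_suppressed_per_mirna", "n_families", "family_size",
            "n_host_pairs", "hox_block_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.suppression_q < 1.0:
            raise ValueError("suppression_q must lie in [0, 1)")
        need = (
            self.n_families * self.n_suppressed_per_mirna
            + self.singleton_pool_size + self.n_host_pairs + self.hox_block_size
            + self.n_epithelial_genes + self.n_mesenchymal_genes
        )
        if self.n_genes < need:
            raise ValueError(f"n_genes={self.n_genes} < {need} required by planted blocks")
        n_special = self.n_families * self.family_size + 2 + self.n_host_pairs
        if self.n_mirnas < n_special:
            raise ValueError(f"n_mirnas={self.n_mirnas} too small for planted roles ({n_special})")

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PlantedTruth:
    """Ground truth of every planted relationship in a generated panel."""

    fingerprint: str
    suppressed: dict[str, dict[str, float]]      # mirna -> {gene: strength u}
    families: dict[str, list[str]]               # family name -> member miRNAs
    host_pairs: list[tuple[str, str]]
    hox_mirna: str
    hox_blocks: dict[str, list[str]]
    signature: GeneSignature
    epithelial_mirnas: list[str]
    mesenchymal_mirnas: list[str]
    latent: np.ndarray
    low_mirnas: list[str] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    mirna_matrix: ExpressionMatrix
    mrna_matrices: list[ExpressionMatrix]
    probe_map: ProbeGeneMap
    truth: PlantedTruth

    @property
    def host_pair_table(self) -> HostPairTable:
        return HostPairTable(list(self.truth.host_pairs))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the panel: miRNA matrix, per-platform mRNA matrices with probe
    redundancy, probe->gene map and the planted truth."""
    rng = np.random.default_rng(config.seed)
    c = config
    samples = [f"CL{i + 1:02d}" for i in range(c.n_samples)]

    # ---- miRNA roles -----------------------------------------------------
    mirnas = [f"mir-{i + 1:03d}" for i in range(c.n_mirnas)]
    fam_members: dict[str, list[str]] = {}
    cursor = 0
    for f in range(c.n_families):
        fam_members[f"fam-{f + 1}"] = mirnas[cursor : cursor + c.family_size]
        cursor += c.family_size
    mesenchymal = [mirnas[cursor]]; cursor += 1
    hox_mirna = mirnas[cursor]; cursor += 1
    host_mirnas = mirnas[cursor : cursor + c.n_host_pairs]
    low_mirnas = [f"mir-low-{i + 1}" for i in range(c.n_low_mirnas)]

    # ---- latent structure and miRNA expression ---------------------------
    latent = rng.normal(size=c.n_samples)  # epithelial(+)/mesenchymal(-) factor
    x = np.empty((c.n_mirnas, c.n_samples))
    for i, m in enumerate(mirnas):
        x[i] = rng.normal(size=c.n_samples)
    # family members share a driver; family 1 is the epithelial family
    for f, (fname, members) in enumerate(fam_members.items()):
        driver = latent if f == 0 else rng.normal(size=c.n_samples)
        for m in members:
            i = mirnas.index(m)
            x[i] = driver + c.family_member_noise * rng.normal(size=c.n_samples)
    x[mirnas.index(mesenchymal[0])] = -latent + c.family_member_noise * rng.normal(
        size=c.n_samples
    )
    # normalized log2 expression levels (real-time-PCR-derived values are
    # ct-based, i.e. log-scale); the detection limit lives on the same scale
    mu = rng.uniform(3.0, 7.0, size=c.n_mirnas)
    log2_expr = mu[:, None] + x
    low = rng.normal(-2.0, 1.0, size=(c.n_low_mirnas, c.n_samples))
    mirna_values = np.vstack([log2_expr, low])
    mirna_matrix = ExpressionMatrix(
        entity_ids=mirnas + low_mirnas,
        sample_ids=samples,
        values=mirna_values,
        platform="synthetic-qpcr",
        value_kind="abundance",
    )
    z = np.vstack([_standardize(row) for row in x])  # standardised log-scale expression

    # ---- gene layout -----------------------------------------------------
    genes = [f"G{i + 1:04d}" for i in range(c.n_genes)]
    pos = 0

    def take(k: int) -> list[str]:
        nonlocal pos
        out = genes[pos : pos + k]
        pos += k
        return out

    family_blocks = {f: take(c.n_suppressed_per_mirna) for f in fam_members}
    pool = take(c.singleton_pool_size)
    host_genes = take(c.n_host_pairs)
    hox_block = take(c.hox_block_size)
    e_genes = take(c.n_epithelial_genes)
    m_genes = take(c.n_mesenchymal_genes)

    # ---- planted suppression pairs ---------------------------------------
    lo, hi = c.suppression_strength_range
    suppressed: dict[str, dict[str, float]] = {}
    in_family = {m for ms in fam_members.values() for m in ms}
    n_taken = 0
    for m in mirnas:
        if m in in_family:
            block = next(b for f, b in family_blocks.items() if m in fam_members[f])
            targets = list(block)
        elif c.overlapping_suppression:
            targets = sorted(rng.choice(pool, size=c.n_suppressed_per_mirna, replace=False))
        else:
            # disjoint slices: every planted pair has exactly one suppressor
            if n_taken + c.n_suppressed_per_mirna > len(pool):
                raise ValueError("singleton pool too small for disjoint suppression")
            targets = pool[n_taken : n_taken + c.n_suppressed_per_mirna]
            n_taken += c.n_suppressed_per_mirna
        suppressed[m] = {
            g: float(c.suppression_beta * rng.uniform(lo, hi)) for g in targets
        }

    # ---- gene expression -------------------------------------------------
    gene_idx = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(0.0, 1.0, size=c.n_genes)
    G = np.tile(baseline[:, None], (1, c.n_samples))
    G += c.noise_sd * rng.normal(size=(c.n_genes, c.n_samples))

    for mi, m in enumerate(mirnas):
        zm = z[mi]
        if c.suppression_q <= 0.0:
            t = zm.min()
            active = np.ones(c.n_samples, dtype=bool)
        else:
            t = float(np.quantile(zm, c.suppression_q))
            active = zm > t
        inactive = ~active
        # offset cancelling the structural all-sample covariance exactly
        denom = float(zm[inactive].sum())
        slope_cov = float(((zm[active] - t) * zm[active]).sum())
        delta_unit = slope_cov / denom if inactive.any() and denom != 0.0 else 0.0
        for g, u in suppressed[m].items():
            gi = gene_idx[g]
            G[gi, active] -= u * (zm[active] - t)
            if inactive.any():
                G[gi, inactive] += u * delta_unit
                G[gi, inactive] += c.other_regulation_sd * rng.normal(size=int(inactive.sum()))

    for m, g in zip(host_mirnas, host_genes):
        G[gene_idx[g]] += c.host_alpha * z[mirnas.index(m)]
    for g in hox_block:
        G[gene_idx[g]] += c.hox_alpha * z[mirnas.index(hox_mirna)]
    for g in e_genes:
        G[gene_idx[g]] += c.signature_gamma * latent
    for g in m_genes:
        G[gene_idx[g]] -= c.signature_gamma * latent

    # ---- platforms with probe redundancy and missing cells ---------------
    mrna_matrices: list[ExpressionMatrix] = []
    map_rows = []
    plo, phi = c.probes_per_gene
    for p in range(c.n_platforms):
        platform = f"P{p + 1}"
        probe_ids: list[str] = []
        rows: list[np.ndarray] = []
        counts = rng.integers(plo, phi + 1, size=c.n_genes)
        for gi, g in enumerate(genes):
            for j in range(int(counts[gi])):
                probe = f"{platform}:{g}:{j + 1}"
                probe_ids.append(probe)
                rows.append(G[gi] + c.probe_noise_sd * rng.normal(size=c.n_samples))
                map_rows.append({"probe": probe, "gene": g, "platform": platform})
        values = np.vstack(rows)
        if c.missing_rate > 0:
            holes = rng.random(values.shape) < c.missing_rate
            values = np.where(holes, np.nan, values)
        mrna_matrices.append(
            ExpressionMatrix(
                entity_ids=probe_ids,
                sample_ids=samples,
                values=values,
                platform=platform,
                value_kind="log2ratio",
            )
        )

    truth = PlantedTruth(
        fingerprint=c.fingerprint(),
        suppressed=suppressed,
        families={f: list(ms) for f, ms in fam_members.items()},
        host_pairs=list(zip(host_mirnas, host_genes)),
        hox_mirna=hox_mirna,
        hox_blocks={"HOXSYN": list(hox_block)},
        signature=GeneSignature(
            name="EMT_SYN",
            members={**{g: "up" for g in e_genes}, **{g: "down" for g in m_genes}},
        ),
        epithelial_mirnas=list(fam_members["fam-1"]),
        mesenchymal_mirnas=mesenchymal,
        latent=latent,
        low_mirnas=low_mirnas,
    )
    return SyntheticDataset(
        config=c,
        mirna_matrix=mirna_matrix,
        mrna_matrices=mrna_matrices,
        probe_map=ProbeGeneMap(pd.DataFrame(map_rows)),
        truth=truth,
    )


def predictions_from_truth(
    truth: PlantedTruth,
    seed: int = 0,
    score_scale: float = 0.25,
    score_noise_sd: float = 0.02,
) -> pd.DataFrame:
    """A TargetScan-style prediction table for the planted suppressed pairs.

    Prediction strength tracks the planted suppression strength: the total
    context score is ``-score_scale * u`` plus a little noise (clipped to stay
    non-positive), so ranking by score recovers the strength ordering up to
    noise.
    """
    rng = np.random.default_rng([seed, 0x7A6])
    rows = []
    for mirna in sorted(truth.suppressed):
        for gene, u in sorted(truth.suppressed[mirna].items()):
            score = -score_scale * u + score_noise_sd * rng.normal()
            rows.append(
                {"mirna": mirna, "gene": gene,
                 "total_context_score": float(min(score, -1e-3))}
            )
    return pd.DataFrame(rows)


def truth_report(
    truth: PlantedTruth,
    results: Mapping[str, object],
    top_n: int = 100,
    host_cutoff: float = 0.2,
) -> dict[str, object]:
    """Recovery metrics of pipeline outputs against the planted truth.

    ``results`` must carry the dataset ``fingerprint`` plus any of:
    ``tables`` (mirna -> CorrelationTable) and ``clusters``
    (a ClusterAssignment).  Reported metrics: per-method precision/recall of
    planted suppressed genes within the negative top-``top_n`` correlator
    lists, the planted host-pair positive fraction at ``host_cutoff`` on the
    normalised sPCC scale, and the purity of the cluster assignment with
    respect to the planted families.  Metrics whose planted sets are empty are
    ``None`` rather than zero.
    """
    if results.get("fingerprint") != truth.fingerprint:
        raise ValueError("results were not computed on this synthetic dataset")
    from .correlate import top_correlators  # local import avoids cycle at module load
    from .signatures import host_pair_correlations

    report: dict[str, object] = {}
    tables: Mapping[str, CorrelationTable] | None = results.get("tables")  # type: ignore[assignment]
    if tables:
        methods = [c for c in ("spcc", "dpcc", "rspcc")
                   if c in next(iter(tables.values())).data.columns]
        for method in methods:
            tps = fns = fps = 0
            any_planted = False
            for mirna, table in tables.items():
                planted = set(truth.suppressed.get(mirna, {}))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    neg = set(top_correlators(table.values(method), n=top_n, sign="negative"))
                if not planted:
                    continue
                any_planted = True
                tps += len(planted & neg)
                fns += len(planted - neg)
                fps += len(neg - planted)
            if any_planted:
                report[f"{method}_recall"] = tps / (tps + fns) if tps + fns else None
                report[f"{method}_precision"] = tps / (tps + fps) if tps + fps else None
            else:
                report[f"{method}_recall"] = None
                report[f"{method}_precision"] = None
        if truth.host_pairs:
            _, counts = host_pair_correlations(
                HostPairTable(list(truth.host_pairs)), tables, cutoff=host_cutoff
            )
            scored = counts["positive"] + counts["negative"] + counts["neutral"]
            report["host_positive_fraction"] = (
                counts["positive"] / scored if scored else None
            )
        else:
            report["host_positive_fraction"] = None
    clusters: ClusterAssignment | None = results.get("clusters")  # type: ignore[assignment]
    if clusters is not None:
        report["family_cluster_purity"] = _family_purity(truth.families, clusters)
    return report


def _family_purity(
    families: Mapping[str, Sequence[str]], clusters: ClusterAssignment
) -> float | None:
    members = [(m, f) for f, ms in families.items() for m in ms]
    if not members:
        return None
    by_cluster: dict[str, list[str]] = {}
    for m, f in members:
        by_cluster.setdefault(clusters.labels[m], []).append(f)
    correct = sum(
        max(fams.count(f) for f in set(fams)) for fams in by_cluster.values()
    )
    return correct / len(members)
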