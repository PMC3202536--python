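"""End-to-end orchestration: read inputs, correlate, cluster, score, export.

The pipeline replaces a database/web deployment with flat TSV exports: one
correlation table per miRNA (and family) under ``correlations/``, top-list,
overlap, cluster, signature and enrichment tables beside it, and a
``manifest.json`` recording the config hash, seed and record counts so a rerun
with the same config reproduces identical outputs.  :func:`query` provides the
searchable surface — genes for a miRNA, or miRNAs for a gene list.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (
    DEFAULT_SHARE_THRESHOLD,
    dendrogram_newick,
    functional_clusters,
    overlap_matrix,
    pca_scores,
)
from .correlate import (
    DEFAULT_MIN_PAIRS,
    DEFAULT_MIN_SIZE,
    DEFAULT_N_REPS,
    DEFAULT_TOP_N,
    correlate_panel,
    top_correlators,
)
from .data import (
    CorrelationTable,
    ExpressionMatrix,
    ProbeGeneMap,
    detectability_filter,
    read_correlation_table,
    read_expression_matrix,
    read_gene_signature,
    read_host_pairs,
    read_predictions,
    read_probe_gene_map,
    read_seed_families,
    write_correlation_table,
)
from .enrichment import aggregate_site_scores, neg_pos_log2_ratios, prediction_ratio_curve
from .families import build_family_profile, default_aggregation, families_from_seed_table
from .signatures import (
    cluster_enrichment,
    count_signature_correlators,
    em_factor,
    host_pair_correlations,
    net_score,
)

log = logging.getLogger("mirconnect")

__all__ = ["RunConfig", "run_full_analysis", "analyze", "query", "load_tables"]


@dataclass
class RunConfig:
    """File paths and parameters for a full run."""

    out_dir: str
    mirna_path: str
    mrna_paths: list[str]
    platforms: list[str]
    probe_map_path: str
    value_kind: str = "abundance"
    methods: tuple[str, ...] = ("spcc", "dpcc")
    min_size: int = DEFAULT_MIN_SIZE
    min_pairs: int = DEFAULT_MIN_PAIRS
    min_detect_samples: int = 30
    detection_limit: float | None = None
    top_n: int = DEFAULT_TOP_N
    n_reps: int = DEFAULT_N_REPS
    seed: int | None = None
    cluster_sign: str = "positive"
    share_threshold: float = DEFAULT_SHARE_THRESHOLD
    collapse: str = "probe"
    host_cutoff: float = 0.2
    signature_mode: str = "threshold"  # or "topn"
    signature_cutoff: float = 1.0
    seed_table_path: str | None = None
    signature_paths: list[str] = field(default_factory=list)
    host_pairs_path: str | None = None
    predictions_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def validate(self) -> None:
        for p in [self.mirna_path, self.probe_map_path, *self.mrna_paths]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if len(self.mrna_paths) != len(self.platforms):
            raise ValueError("mrna_paths and platforms differ in length")
        if "rspcc" in self.methods and self.seed is None:
            raise ValueError("rspcc requested but no seed set")
        for opt in (self.seed_table_path, self.host_pairs_path, self.predictions_path,
                    *self.signature_paths):
            if opt is not None and not Path(opt).exists():
                raise FileNotFoundError(opt)


def run_full_analysis(config: RunConfig) -> Path:
    """Validate, load the inputs and run :func:`analyze`.

    On any stage failure a ``FAILED`` marker naming the stage is left in the
    output directory (partial outputs preserved) and the error propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mirna = read_expression_matrix(config.mirna_path, platform="mirna",
                                   value_kind=config.value_kind)
    mrna = [
        read_expression_matrix(p, platform=plat, value_kind="log2ratio")
        for p, plat in zip(config.mrna_paths, config.platforms)
    ]
    probe_map = read_probe_gene_map(config.probe_map_path)
    seed_table = read_seed_families(config.seed_table_path) if config.seed_table_path else None
    signatures = [read_gene_signature(p) for p in config.signature_paths]
    host_pairs = read_host_pairs(config.host_pairs_path) if config.host_pairs_path else None
    predictions = (
        aggregate_site_scores(read_predictions(config.predictions_path))
        if config.predictions_path else None
    )
    return analyze(
        mirna, mrna, probe_map, config,
        seed_table=seed_table, signatures=signatures,
        host_pairs=host_pairs, predictions=predictions,
    )


def analyze(
    mirna: ExpressionMatrix,
    mrna: Sequence[ExpressionMatrix],
    probe_map: ProbeGeneMap,
    config: RunConfig,
    seed_table: Mapping[str, str] | None = None,
    signatures: Sequence = (),
    host_pairs=None,
    predictions: pd.DataFrame | None = None,
) -> Path:
    """The in-memory pipeline core; writes all exports under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    counts: dict[str, int] = {}
    t0 = time.time()
    try:
        stage = "detectability"
        profiles = detectability_filter(
            mirna, limit=config.detection_limit, min_samples=config.min_detect_samples
        )
        counts["mirnas_detectable"] = len(profiles)
        log.info("detectability: %d/%d miRNAs pass", len(profiles), mirna.n_entities)

        stage = "families"
        if seed_table is not None:
            fams = families_from_seed_table(
                seed_table,
                detectable=[p.name for p in profiles],
                aggregation=default_aggregation(mirna.value_kind),
            )
            pd.DataFrame(
                [(f.family_name, m) for f in fams for m in f.members],
                columns=["family", "mirna"],
            ).to_csv(out / "families.tsv", sep="\t", index=False)
            profiles = profiles + [
                build_family_profile(mirna, f, limit=config.detection_limit) for f in fams
            ]
            counts["families"] = len(fams)

        stage = "correlate"
        tables = correlate_panel(
            profiles, mrna, probe_map, mirna.sample_ids,
            methods=tuple(config.methods), min_size=config.min_size,
            min_pairs=config.min_pairs, n_reps=config.n_reps,
            seed=config.seed, collapse=config.collapse,
        )
        corr_dir = out / "correlations"
        corr_dir.mkdir(exist_ok=True)
        for name, table in tables.items():
            write_correlation_table(table, corr_dir / f"{name}.tsv")
        counts["correlation_tables"] = len(tables)

        stage = "toplists"
        primary = config.methods[0]
        top_lists: dict[str, dict[str, list[str]]] = {"positive": {}, "negative": {}}
        rows = []
        for name, table in tables.items():
            for sign in ("positive", "negative"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lst = top_correlators(table.values(primary), n=config.top_n, sign=sign)
                top_lists[sign][name] = lst
                rows.extend(
                    {"mirna": name, "sign": sign, "rank": i + 1, "gene": g}
                    for i, g in enumerate(lst)
                )
        pd.DataFrame(rows).to_csv(out / "toplists.tsv", sep="\t", index=False)

        stage = "cluster"
        assignment = None
        if len(tables) >= 2:
            mat = overlap_matrix(top_lists[config.cluster_sign], denom=config.top_n)
            mat.to_frame().to_csv(out / "overlap.tsv", sep="\t")
            assignment = functional_clusters(mat, config.share_threshold)
            pd.Series(assignment.labels, name="cluster").rename_axis("mirna").to_csv(
                out / "clusters.tsv", sep="\t"
            )
            (out / "dendrogram.nwk").write_text(dendrogram_newick(mat))
            scores, ev = pca_scores(mat)
            scores.rename_axis("mirna").to_csv(out / "pca.tsv", sep="\t")
            counts["clusters"] = assignment.n_clusters

        stage = "signatures"
        for sig in signatures:
            recs = []
            for name, table in tables.items():
                sc = count_signature_correlators(
                    sig, table, mode=config.signature_mode,
                    cutoff=config.signature_cutoff, top_n=config.top_n,
                    column=primary,
                )
                recs.append(
                    {"mirna": name, "pos_up": sc.pos_up, "neg_up": sc.neg_up,
                     "pos_down": sc.pos_down, "neg_down": sc.neg_down,
                     "net_up": net_score(sc.pos_up, sc.neg_up),
                     "em_factor": em_factor(sc)}
                )
            df = pd.DataFrame(recs).set_index("mirna")
            df.to_csv(out / f"signature.{sig.name}.tsv", sep="\t")
            if assignment is not None and assignment.n_clusters >= 2:
                enr = cluster_enrichment(df["em_factor"].to_dict(), assignment)
                enr.to_csv(out / f"signature.{sig.name}.enrichment.tsv", sep="\t")

        stage = "host_pairs"
        if host_pairs is not None:
            table, summary = host_pair_correlations(
                host_pairs, tables, cutoff=config.host_cutoff
            )
            table.to_csv(out / "host_pairs.tsv", sep="\t", index=False)
            counts.update({f"host_{k}": v for k, v in summary.items()})

        stage = "enrichment"
        if predictions is not None:
            ratios = neg_pos_log2_ratios(tables, column=primary)
            ratios.rename("log2_neg_pos").rename_axis("mirna").to_csv(
                out / "neg_pos_ratios.tsv", sep="\t"
            )
            curve = prediction_ratio_curve(predictions, tables, column=primary,
                                           method=primary)
            curve.table.to_csv(out / "ratio_curve.tsv", sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "counts": counts,
            "runtime_s": round(time.time() - t0, 3),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise
    return out


def load_tables(corr_dir: str | Path) -> dict[str, CorrelationTable]:
    """Load every exported correlation table under a directory."""
    corr_dir = Path(corr_dir)
    if corr_dir.name != "correlations" and (corr_dir / "correlations").is_dir():
        corr_dir = corr_dir / "correlations"
    return {
        (t := read_correlation_table(p)).mirna: t
        for p in sorted(corr_dir.glob("*.tsv"))
    }


def query(
    corr_dir: str | Path,
    mirnas: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
    sign: str = "both",
    limit: int | None = None,
    column: str | None = None,
) -> pd.DataFrame:
    """Look up correlators of miRNAs, or miRNAs correlating with genes.

    With ``mirnas`` given, returns their per-gene records; with ``genes``
    given (and no miRNA), returns every miRNA table row mentioning those
    genes.  ``sign`` filters on the primary column; rows are ordered by
    absolute value (descending, name tie-break) and truncated to ``limit``.
    Unknown identifiers yield an empty result with a warning.
    """
    if sign not in ("both", "positive", "negative"):
        raise ValueError("sign must be both/positive/negative")
    tables = load_tables(corr_dir)
    if column is None:
        any_table = next(iter(tables.values()), None)
        column = "spcc" if any_table is not None and "spcc" in any_table.data.columns \
            else "dpcc"
    rows = []
    if mirnas is not None:
        for m in mirnas:
            if m not in tables:
                warnings.warn(f"unknown miRNA {m!r}")
                continue
            df = tables[m].data.copy()
            if genes is not None:
                df = df.loc[df.index.intersection(genes)]
            df = df.reset_index().rename(columns={"index": "gene"})
            df.insert(0, "mirna", m)
            rows.append(df)
    elif genes is not None:
        for m, table in tables.items():
            hit = table.data.loc[table.data.index.intersection(genes)]
            if len(hit):
                hit = hit.reset_index().rename(columns={"index": "gene"})
                hit.insert(0, "mirna", m)
                rows.append(hit)
        if not rows:
            warnings.warn("no queried gene found in any table")
    else:
        raise ValueError("give mirnas and/or genes")
    if not rows:
        return pd.DataFrame(columns=["mirna", "gene", column])
    out = pd.concat(rows, ignore_index=True)
    out = out[np.isfinite(out[column])]
    if sign == "positive":
        out = out[out[column] > 0]
    elif sign == "negative":
        out = out[out[column] < 0]
    out = out.sort_values(by=["mirna", "gene"], kind="stable")
    out = out.sort_values(
        by=[column], key=lambda s: -s.abs(), kind="stable"
    ).reset_index(drop=True)
    if limit is not None:
        out = out.head(limit)
    return out
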