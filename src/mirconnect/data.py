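"""Domain types and tab-separated readers/writers.

Everything the correlation engine consumes or emits is a plain TSV: expression
matrices (entities x samples), probe->gene maps, gene signatures, miRNA/host-gene
pairs, target-prediction tables and per-miRNA correlation tables.  Missing values
are encoded as empty cells, ``NA`` or ``NaN`` on input and written back as ``NA``;
they are carried as ``numpy.nan`` internally and are never zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MiRNAProfile",
    "ProbeGeneMap",
    "GeneSignature",
    "HostPairTable",
    "CorrelationTable",
    "VALUE_KINDS",
    "NA_TOKENS",
    "read_expression_matrix",
    "write_expression_matrix",
    "detectability_filter",
    "read_probe_gene_map",
    "write_probe_gene_map",
    "read_gene_signature",
    "write_gene_signature",
    "read_host_pairs",
    "write_host_pairs",
    "read_seed_families",
    "read_predictions",
    "read_correlation_table",
    "write_correlation_table",
]

VALUE_KINDS = ("abundance", "log2ratio")

#: tokens accepted as missing on read; ``NA`` is always written.
NA_TOKENS = ("", "NA", "NaN", "nan")

# column-name mapping between in-memory correlation tables and their TSV headers
_CORR_FILE_COLS = {
    "spcc": "sPCC",
    "dpcc": "dPCC",
    "rspcc": "rsPCC",
    "n_probes_used": "n_probes_used",
    "predicted_target": "predicted_target",
}
_CORR_MEM_COLS = {v: k for k, v in _CORR_FILE_COLS.items()}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """An entities x samples numeric table with a platform tag.

    ``values`` is a float array where ``nan`` marks a missing measurement.
    ``value_kind`` is ``"abundance"`` (e.g. normalised real-time-PCR derived
    levels; higher = more expressed) or ``"log2ratio"`` (signed array ratios).
    """

    entity_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    platform: str = ""
    value_kind: str = "abundance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entity_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) < 2:
            raise ValueError("an expression matrix needs at least 2 samples")
        _check_unique(self.entity_ids, f"entity ID on platform {self.platform!r}")
        _check_unique(self.sample_ids, "sample ID")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {VALUE_KINDS}")
        self._index = {e: i for i, e in enumerate(self.entity_ids)}

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, entity: str) -> np.ndarray:
        try:
            return self.values[self._index[entity]]
        except KeyError:
            raise KeyError(f"entity {entity!r} not in matrix {self.platform!r}") from None

    def __contains__(self, entity: str) -> bool:
        return entity in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, platform: str = "", value_kind: str = "abundance"
    ) -> "ExpressionMatrix":
        return cls(
            entity_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            platform=platform,
            value_kind=value_kind,
        )


@dataclass
class MiRNAProfile:
    """One miRNA's per-sample values plus a detectability mask."""

    name: str
    values: np.ndarray
    detectable: np.ndarray
    n_detectable: int = field(default=-1)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.detectable = np.asarray(self.detectable, dtype=bool)
        if self.values.shape != self.detectable.shape:
            raise ValueError("values and detectable mask differ in length")
        n = int(self.detectable.sum())
        if self.n_detectable == -1:
            self.n_detectable = n
        elif self.n_detectable != n:
            raise ValueError("n_detectable inconsistent with mask")
        if not np.all(np.isfinite(self.values[self.detectable])):
            raise ValueError(f"profile {self.name!r} has non-finite detectable values")

    @property
    def n_samples(self) -> int:
        return self.values.size


@dataclass
class ProbeGeneMap:
    """probe -> gene symbol assignments, per platform.

    A probe maps to at most one gene within its platform; a gene may have many
    probes and may appear on several platforms.
    """

    table: pd.DataFrame  # columns: probe, gene, platform

    def __post_init__(self) -> None:
        need = {"probe", "gene", "platform"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"probe map needs columns {sorted(need)}")
        dup = self.table.duplicated(subset=["probe", "platform"])
        if dup.any():
            bad = self.table.loc[dup, "probe"].iloc[0]
            raise ValueError(f"probe {bad!r} mapped more than once on its platform")

    def for_platform(self, platform: str) -> dict[str, str]:
        sub = self.table[self.table["platform"] == platform]
        return dict(zip(sub["probe"], sub["gene"]))

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())


@dataclass
class GeneSignature:
    """A named gene list with per-gene direction labels.

    ``direction`` is ``"up"`` (epithelial / induced) or ``"down"``
    (mesenchymal / repressed).
    """

    name: str
    members: dict[str, str]

    def __post_init__(self) -> None:
        for g, d in self.members.items():
            if d not in ("up", "down"):
                raise ValueError(f"direction for {g!r} must be 'up' or 'down', got {d!r}")

    @property
    def up_genes(self) -> list[str]:
        return [g for g, d in self.members.items() if d == "up"]

    @property
    def down_genes(self) -> list[str]:
        return [g for g, d in self.members.items() if d == "down"]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class HostPairTable:
    """Unique (miRNA, host gene) pairs for co-transcription validation."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("host pairs must be unique")


@dataclass
class CorrelationTable:
    """Per-gene correlation records for one miRNA (or miRNA family).

    ``data`` is indexed by gene symbol with a subset of the columns
    ``spcc``, ``dpcc``, ``rspcc``, ``n_probes_used``, ``predicted_target``.
    ``n_patterns`` is the number of nested sample patterns the sPCC summed
    (``n_samples - min_size + 1``); the normalised statistic ``spcc / n_patterns``
    lives on the ordinary [-1, 1] correlation scale.
    """

    mirna: str
    data: pd.DataFrame
    n_patterns: int | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene in correlation table")

    def values(self, column: str = "spcc") -> pd.Series:
        if column not in self.data.columns:
            raise KeyError(f"column {column!r} not computed for {self.mirna!r}")
        return self.data[column]

    def normalized_spcc(self) -> pd.Series:
        if self.n_patterns is None:
            raise ValueError("n_patterns unknown; cannot normalise sPCC")
        return self.data["spcc"] / self.n_patterns


# ---------------------------------------------------------------------------
# expression matrix IO


def read_expression_matrix(
    path: str | Path, platform: str = "", value_kind: str = "abundance"
) -> ExpressionMatrix:
    """Read a TSV whose first row holds sample names and first column entity IDs."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    _check_unique(samples, f"sample column in {path.name}")
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str,
        na_values=list(NA_TOKENS), keep_default_na=False,
    )
    ids = [str(i) for i in raw.index]
    _check_unique(ids, f"entity ID in {path.name}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path.name} at entity {ids[r]!r}, "
            f"sample {raw.columns[c]!r}: {raw.iat[r, c]!r}"
        )
    return ExpressionMatrix.from_frame(numeric, platform=platform, value_kind=value_kind)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", na_rep="NA")


def detectability_filter(
    matrix: ExpressionMatrix,
    limit: float | None = None,
    min_samples: int = 30,
) -> list[MiRNAProfile]:
    """Keep miRNAs detectable in at least ``min_samples`` samples.

    A sample is detectable when its value is present and, if ``limit`` is given,
    at or above it.  With ``limit=None`` any non-missing value counts as
    detectable.  Order of the input matrix is preserved and the operation is
    idempotent on the surviving profiles.
    """
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    if min_samples > matrix.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {matrix.n_samples} samples present"
        )
    out: list[MiRNAProfile] = []
    for name, row in zip(matrix.entity_ids, matrix.values):
        finite = np.isfinite(row)
        mask = finite if limit is None else finite & (row >= limit)
        if int(mask.sum()) >= min_samples:
            out.append(MiRNAProfile(name=name, values=row, detectable=mask))
    return out


# ---------------------------------------------------------------------------
# small-table IO


def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ProbeGeneMap(df[["probe", "gene", "platform"]])


def write_probe_gene_map(pmap: ProbeGeneMap, path: str | Path) -> None:
    pmap.table.to_csv(path, sep="\t", index=False)


def read_gene_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "direction"}.issubset(df.columns):
        raise ValueError("signature TSV needs columns gene, direction")
    members: dict[str, str] = {}
    for g, d in zip(df["gene"], df["direction"]):
        if g in members:
            raise ValueError(f"gene {g!r} listed twice in signature")
        members[g] = d
    return GeneSignature(name=name or Path(path).stem, members=members)


def write_gene_signature(sig: GeneSignature, path: str | Path) -> None:
    pd.DataFrame(
        {"gene": list(sig.members), "direction": list(sig.members.values())}
    ).to_csv(path, sep="\t", index=False)


def read_host_pairs(path: str | Path) -> HostPairTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mirna", "host_gene"}.issubset(df.columns):
        raise ValueError("host pair TSV needs columns mirna, host_gene")
    return HostPairTable(list(zip(df["mirna"], df["host_gene"])))


def write_host_pairs(pairs: HostPairTable, path: str | Path) -> None:
    pd.DataFrame(pairs.pairs, columns=["mirna", "host_gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_seed_families(path: str | Path) -> dict[str, str]:
    """Read a seed-family table (columns: mirna, family) as a mirna->family map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mirna", "family"}.issubset(df.columns):
        raise ValueError("seed table needs columns mirna, family")
    if df["mirna"].duplicated().any():
        bad = df.loc[df["mirna"].duplicated(), "mirna"].iloc[0]
        raise ValueError(f"miRNA {bad!r} assigned to more than one family")
    return dict(zip(df["mirna"], df["family"]))


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a prediction TSV; site-level or pre-aggregated, detected by header.

    Returns a frame with columns ``mirna, gene`` plus either ``context_score``
    (site-level, one row per site) or ``total_context_score`` (aggregated).
    """
    df = pd.read_csv(path, sep="\t")
    if "total_context_score" in df.columns:
        score_col = "total_context_score"
    elif "context_score" in df.columns:
        score_col = "context_score"
    else:
        raise ValueError(
            "prediction TSV needs a context_score or total_context_score column"
        )
    if not {"mirna", "gene"}.issubset(df.columns):
        raise ValueError("prediction TSV needs columns mirna, gene")
    out = df[["mirna", "gene", score_col]].copy()
    if not np.all(np.isfinite(out[score_col].to_numpy(dtype=float))):
        raise ValueError("prediction scores must be finite")
    return out


# ---------------------------------------------------------------------------
# correlation-table IO


def write_correlation_table(table: CorrelationTable, path: str | Path) -> None:
    """Write one miRNA's correlation table; absent statistics are omitted,
    never zero-filled.  Header comment lines preserve the miRNA name and the
    pattern count so the table round-trips."""
    path = Path(path)
    cols = [c for c in _CORR_FILE_COLS if c in table.data.columns]
    df = table.data[cols].rename(columns=_CORR_FILE_COLS)
    with path.open("w") as fh:
        fh.write(f"# mirna={table.mirna}\n")
        if table.n_patterns is not None:
            fh.write(f"# n_patterns={table.n_patterns}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", index=True, index_label="gene")


def read_correlation_table(path: str | Path) -> CorrelationTable:
    path = Path(path)
    mirna = path.stem
    n_patterns: int | None = None
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "mirna":
                mirna = val.strip()
            elif key.strip() == "n_patterns":
                n_patterns = int(val)
    df = pd.read_csv(
        path, sep="\t", skiprows=skip, index_col="gene",
        na_values=list(NA_TOKENS), keep_default_na=False,
    )
    df = df.rename(columns=_CORR_MEM_COLS)
    df.index.name = None
    return CorrelationTable(mirna=mirna, data=df, n_patterns=n_patterns)
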