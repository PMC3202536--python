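"""Aggregation of individual miRNAs into seed-family profiles.

miRNAs sharing a seed sequence are combined into one family profile before
correlation: abundance-style data (e.g. real-time-PCR derived levels) are
averaged per sample, log2-ratio array data are summed per sample.  Custom
families — like the combined miR-200abc/141/429 group — are just extra rows of
the seed table; no sequence analysis happens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data import ExpressionMatrix, MiRNAProfile

__all__ = [
    "FamilyDefinition",
    "default_aggregation",
    "build_family_profile",
    "families_from_seed_table",
]

AGGREGATIONS = ("average", "sum")


@dataclass(frozen=True)
class FamilyDefinition:
    family_name: str
    members: tuple[str, ...]
    aggregation: str = "average"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.family_name!r} has no members")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")


def default_aggregation(value_kind: str) -> str:
    """Aggregation convention bound to the data kind: abundance data are
    averaged, log2-ratio data are summed."""
    return "average" if value_kind == "abundance" else "sum"


def build_family_profile(
    matrix: ExpressionMatrix,
    fam: FamilyDefinition,
    limit: float | None = None,
) -> MiRNAProfile:
    """Aggregate member rows of ``matrix`` into one family profile.

    ``average`` takes the per-sample mean over members with missing values
    excluded; ``sum`` adds per-sample values treating a missing value as an
    absent member.  A sample where every member is missing stays missing.  The
    detectability mask marks samples where at least one member is detectable
    (non-missing, and at/above ``limit`` when given).
    """
    rows = []
    for m in fam.members:
        if m not in matrix:
            raise KeyError(f"family member {m!r} absent from expression matrix")
        rows.append(matrix.row(m))
    sub = np.vstack(rows)
    finite = np.isfinite(sub)
    any_present = finite.any(axis=0)
    with np.errstate(invalid="ignore"):
        if fam.aggregation == "average":
            values = np.where(any_present, np.nansum(sub, axis=0), np.nan)
            values = values / np.where(any_present, finite.sum(axis=0), 1)
        else:
            values = np.where(any_present, np.nansum(sub, axis=0), np.nan)
    det = finite if limit is None else finite & (np.where(finite, sub, -np.inf) >= limit)
    mask = det.any(axis=0)
    return MiRNAProfile(name=fam.family_name, values=values, detectable=mask)


def families_from_seed_table(
    seed_table: Mapping[str, str],
    detectable: Iterable[str] | None = None,
    min_members: int = 2,
    aggregation: str = "average",
) -> list[FamilyDefinition]:
    """One FamilyDefinition per seed family with enough qualifying members.

    ``detectable`` restricts members to miRNAs that passed the detectability
    gate; families falling below ``min_members`` qualifying members are
    dropped.  Families come back sorted by name for determinism.
    """
    keep = None if detectable is None else set(detectable)
    groups: dict[str, list[str]] = {}
    for mirna, family in seed_table.items():
        if keep is not None and mirna not in keep:
            continue
        groups.setdefault(family, []).append(mirna)
    out = [
        FamilyDefinition(family_name=f, members=tuple(sorted(ms)), aggregation=aggregation)
        for f, ms in groups.items()
        if len(ms) >= min_members
    ]
    return sorted(out, key=lambda d: d.family_name)
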