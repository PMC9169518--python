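"""Sample-by-compound concentration matrices and profile summaries.

A :class:`ProfileMatrix` pairs a nonnegative samples × compounds value block
(mg/L for calibrated compounds, raw peak area for screened candidates) with
per-sample metadata (species, pomelo subgroup, cultivar, region, harvest
year). It is the common currency between quantitation, chemometrics and the
authenticity models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SPECIES = ("orange", "mandarin", "grapefruit", "pomelo")
SUBGROUPS = ("none", "SG", "WG")

META_COLUMNS = ["sample_id", "species", "subgroup", "cultivar", "region",
                "harvest_year"]


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    species: str
    cultivar: str
    region: str = "unknown"
    harvest_year: int = 0
    subgroup: str = "none"

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ProfileError(f"unknown species {self.species!r}")
        if self.subgroup not in SUBGROUPS:
            raise ProfileError(f"unknown subgroup {self.subgroup!r}")
        if self.subgroup != "none" and self.species != "pomelo":
            raise ProfileError("only pomelo samples carry an SG/WG subgroup")


@dataclass(frozen=True)
class ProfileMatrix:
    """Samples × compounds matrix with metadata and per-column value kinds."""

    metas: tuple[SampleMeta, ...]
    columns: tuple[str, ...]
    values: np.ndarray
    value_kind: Mapping[str, str] = field(default_factory=dict)
    flags: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.metas), len(self.columns)):
            raise ProfileError(
                f"value block shape {values.shape} does not match "
                f"{len(self.metas)} samples x {len(self.columns)} columns"
            )
        if np.any(values < 0):
            raise ProfileError("profile values must be nonnegative")
        if len(set(self.columns)) != len(self.columns):
            raise ProfileError("duplicate column labels")
        ids = [m.sample_id for m in self.metas]
        if len(set(ids)) != len(ids):
            raise ProfileError("duplicate sample ids")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "metas", tuple(self.metas))
        object.__setattr__(self, "columns", tuple(self.columns))

    @property
    def n_samples(self) -> int:
        return len(self.metas)

    def to_frame(self) -> pd.DataFrame:
        meta_frame = pd.DataFrame([
            {
                "sample_id": m.sample_id, "species": m.species,
                "subgroup": m.subgroup, "cultivar": m.cultivar,
                "region": m.region, "harvest_year": m.harvest_year,
            }
            for m in self.metas
        ])
        value_frame = pd.DataFrame(self.values, columns=list(self.columns))
        return pd.concat([meta_frame, value_frame], axis=1)

    def select(self, columns: Sequence[str]) -> "ProfileMatrix":
        missing = [c for c in columns if c not in self.columns]
        if missing:
            raise ProfileError(f"missing compound columns: {missing}")
        idx = [self.columns.index(c) for c in columns]
        return ProfileMatrix(
            metas=self.metas,
            columns=tuple(columns),
            values=self.values[:, idx],
            value_kind={c: self.value_kind.get(c, "concentration")
                        for c in columns},
        )

    def subset(self, mask: Sequence[bool]) -> "ProfileMatrix":
        mask = np.asarray(mask, dtype=bool)
        return ProfileMatrix(
            metas=tuple(m for m, keep in zip(self.metas, mask) if keep),
            columns=self.columns,
            values=self.values[mask],
            value_kind=dict(self.value_kind),
        )


def assemble_matrix(
    quant_results: Iterable[tuple[str, str, float, Iterable[str]]],
    metas: Sequence[SampleMeta],
    columns: Sequence[str],
    value_kind: Optional[Mapping[str, str]] = None,
) -> ProfileMatrix:
    """Build a ProfileMatrix from (sample_id, compound_id, value, flags) rows.

    Missing (sample, compound) results count as not detected; not-detected
    and below-LOD entries are set to 0 while below-LOQ entries keep their
    value, with the flag preserved in a side table.
    """
    col_index = {c: j for j, c in enumerate(columns)}
    row_index = {m.sample_id: i for i, m in enumerate(metas)}
    values = np.zeros((len(metas), len(columns)))
    flag_rows = []
    seen: set[tuple[str, str]] = set()
    for sample_id, compound_id, value, flags in quant_results:
        if compound_id not in col_index:
            continue
        if sample_id not in row_index:
            raise ProfileError(f"result for unknown sample {sample_id!r}")
        key = (sample_id, compound_id)
        if key in seen:
            raise ProfileError(f"duplicate result for {key}")
        seen.add(key)
        flags = set(flags)
        if "below_LOD" in flags:
            entry = 0.0
        else:
            entry = float(value)
        values[row_index[sample_id], col_index[compound_id]] = entry
        if flags:
            flag_rows.append({
                "sample_id": sample_id, "compound_id": compound_id,
                "flags": ";".join(sorted(flags)),
            })
    flag_table = pd.DataFrame(flag_rows,
                              columns=["sample_id", "compound_id", "flags"])
    return ProfileMatrix(
        metas=tuple(metas), columns=tuple(columns), values=values,
        value_kind=dict(value_kind or {}), flags=flag_table,
    )


def relative_weight(matrix: ProfileMatrix) -> tuple[ProfileMatrix, dict[str, float]]:
    """Per-compound normalization across samples: column maximum set to 1.0.

    All-zero columns stay all-zero. Returns the normalized matrix and the
    per-column maxima used.
    """
    maxima = matrix.values.max(axis=0)
    scaled = matrix.values.copy()
    nonzero = maxima > 0
    scaled[:, nonzero] = scaled[:, nonzero] / maxima[nonzero]
    maxima_map = {c: float(m) for c, m in zip(matrix.columns, maxima)}
    return (
        ProfileMatrix(metas=matrix.metas, columns=matrix.columns, values=scaled,
                      value_kind=dict(matrix.value_kind)),
        maxima_map,
    )


def cultivar_averages(
    matrix: ProfileMatrix,
    grouping: Sequence[str] = ("cultivar", "region", "harvest_year"),
) -> ProfileMatrix:
    """Group means over cultivar/region/harvest-year key combinations.

    One output row per distinct key combination, averaging each compound
    column arithmetically; species/subgroup must be constant within a group.
    """
    allowed = {"cultivar", "region", "harvest_year"}
    bad = set(grouping) - allowed
    if bad:
        raise ProfileError(f"unknown grouping keys: {sorted(bad)}")
    if matrix.n_samples == 0:
        raise ProfileError("cannot average an empty matrix")
    frame = matrix.to_frame()
    keys = list(grouping)
    grouped = frame.groupby(keys, sort=True, as_index=False)
    metas: list[SampleMeta] = []
    rows: list[np.ndarray] = []
    for i, (_, group) in enumerate(grouped):
        if group["species"].nunique() > 1 or group["subgroup"].nunique() > 1:
            raise ProfileError("grouping mixes species or subgroups")
        first = group.iloc[0]
        metas.append(SampleMeta(
            sample_id=f"avg_{i}",
            species=first["species"],
            subgroup=first["subgroup"],
            cultivar=first["cultivar"] if "cultivar" in keys else "pooled",
            region=first["region"] if "region" in keys else "pooled",
            harvest_year=int(first["harvest_year"]) if "harvest_year" in keys else 0,
        ))
        rows.append(group[list(matrix.columns)].mean().to_numpy())
    return ProfileMatrix(
        metas=tuple(metas), columns=matrix.columns,
        values=np.vstack(rows), value_kind=dict(matrix.value_kind),
    )
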