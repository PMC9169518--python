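"""Compound library for citrus OHA profiling.

The catalog holds 39 known, calibrated oxygenated heterocyclic aglycones
(OHAs) — methoxyflavones (MF), coumarins and furanocoumarins (FC) — plus 13
tentatively screened candidates identified only by their spectra, retention
indices and fluorescence ratios. Candidates carry no mg/L calibration and are
reported as peak areas.

Chromatographic and spectral metadata (retention time, UV/emission maxima,
fluorescence monitor pair and ratio) of the 39 calibrated compounds are
SYNTHETIC library values derived from substitution-class landmarks; the
calibration parameters and the complete candidate table are the published
ones. See :mod:`citrusauth._tables`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import _tables

FAMILIES = ("MF", "coumarin", "FC")
FL_MONITOR_NM = (400, 450, 500)
UV_MONITOR_NM = (250, 270, 330)

UV_WINDOW = (210.0, 400.0)
EMISSION_WINDOW = (340.0, 560.0)

# Catalog rows are stored verbatim; one published fluorescence R² (0.9986)
# sits just under the 0.999 construction threshold, so validation of stored
# curves uses a slightly wider floor than curve *fitting* does.
STORED_R2_FLOOR = 0.998


class CatalogError(ValueError):
    """Raised when a catalog file or record violates the schema."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Through-origin calibration: response = slope * concentration (mg/L)."""

    slope: float
    r_squared: float
    range_low: float
    range_high: float
    lod: float
    loq: float
    correction_factor: Optional[float] = None  # stored verbatim, unused

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CatalogError(f"calibration slope must be > 0, got {self.slope}")
        if self.r_squared < STORED_R2_FLOOR:
            raise CatalogError(
                f"calibration r_squared {self.r_squared} below floor {STORED_R2_FLOOR}"
            )
        if not self.lod < self.loq:
            raise CatalogError(f"LOD ({self.lod}) must be < LOQ ({self.loq})")
        if self.range_low >= self.range_high:
            raise CatalogError("calibration range_low must be < range_high")

    def concentration(self, response: float) -> float:
        return response / self.slope


@dataclass(frozen=True)
class CompoundRecord:
    """One catalog entry: a known OHA ("1"–"39") or candidate ("I"–"XIII")."""

    id: str
    name: str
    family: str
    substitution_class: str
    uv_maxima: tuple[float, ...]
    emission_max: Optional[float]
    fluoresces: bool
    fl_monitor_pair: Optional[tuple[int, int]]
    fl_ratio: Optional[float]
    retention_time: Optional[float]
    retention_index: Optional[float]
    quant_channel: tuple[str, int]
    uv_calibration: Optional[CalibrationCurve] = None
    fl_calibration: Optional[CalibrationCurve] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise CatalogError(f"{self.id}: unknown family {self.family!r}")
        if not self.uv_maxima:
            raise CatalogError(f"{self.id}: uv_maxima must be nonempty")
        lo, hi = UV_WINDOW
        for nm in self.uv_maxima:
            if not lo <= nm <= hi:
                raise CatalogError(f"{self.id}: UV maximum {nm} nm outside {UV_WINDOW}")
        if self.emission_max is not None:
            elo, ehi = EMISSION_WINDOW
            if not elo <= self.emission_max <= ehi:
                raise CatalogError(
                    f"{self.id}: emission maximum {self.emission_max} nm "
                    f"outside {EMISSION_WINDOW}"
                )
        if self.fl_ratio is not None and self.fl_ratio < 1.0:
            raise CatalogError(f"{self.id}: fl_ratio must be >= 1 (highest/second)")
        if not self.fluoresces and self.fl_calibration is not None:
            raise CatalogError(
                f"{self.id}: non-fluorescing compound cannot carry FL calibration"
            )
        if self.fl_monitor_pair is not None:
            hi_nm, second_nm = self.fl_monitor_pair
            if hi_nm not in FL_MONITOR_NM or second_nm not in FL_MONITOR_NM:
                raise CatalogError(f"{self.id}: FL pair must use {FL_MONITOR_NM}")

    @property
    def is_candidate(self) -> bool:
        return not self.id.isdigit()

    @property
    def calibration(self) -> Optional[CalibrationCurve]:
        detector, _ = self.quant_channel
        return self.uv_calibration if detector == "UV" else self.fl_calibration


def quant_channel_for(
    family: str, substitution_class: str, override: Optional[tuple[str, int]] = None
) -> tuple[str, int]:
    """Default quantitation channel by family and substitution class.

    MFs and coumarins are quantified by UV at 330 nm, mono-substituted
    (5- or 8-) FCs at 250 nm and 5,8-disubstituted FCs at 270 nm. A
    per-compound catalog override takes precedence.
    """
    if override is not None:
        return override
    if family in ("MF", "coumarin"):
        return ("UV", 330)
    if family == "FC":
        if "5,8-diOR" in substitution_class:
            return ("UV", 270)
        return ("UV", 250)
    raise CatalogError(f"unknown family {family!r}")


def _monitor_pair_for_emission(emission_max: float) -> tuple[int, int]:
    """Closest two monitored wavelengths to an emission maximum."""
    ordered = sorted(FL_MONITOR_NM, key=lambda nm: (abs(nm - emission_max), nm))
    return ordered[0], ordered[1]


def _curve(values: Optional[tuple]) -> Optional[CalibrationCurve]:
    if values is None:
        return None
    lo, hi, slope, r2, lod, loq, cf = values
    return CalibrationCurve(
        slope=slope, r_squared=r2, range_low=lo, range_high=hi,
        lod=lod, loq=loq, correction_factor=cf,
    )


def build_default_catalog() -> list[CompoundRecord]:
    """Construct the packaged 52-record catalog (39 known + 13 candidates).

    Known compounds get synthetic retention times (evenly spread over the
    elution window) and synthetic spectral maxima: the class landmark bands
    shifted by 4 nm per within-class rank, so same-class compounds remain
    spectrally distinguishable. Candidate rows are transcribed verbatim.
    """
    records: list[CompoundRecord] = []
    class_rank: dict[str, int] = {}
    for k, (cid, name, family, subclass, uv_cal, fl_cal) in enumerate(
        _tables.KNOWN_CALIBRATIONS
    ):
        rank = class_rank.get(subclass, 0)
        class_rank[subclass] = rank + 1
        base_uv, base_em = _tables.CLASS_LANDMARKS[subclass]
        shift = 4.0 * rank
        uv_maxima = tuple(nm + shift for nm in base_uv)
        fl_curve = _curve(fl_cal)
        fluoresces = fl_curve is not None and base_em is not None
        emission = base_em + shift if fluoresces else None
        pair = _monitor_pair_for_emission(emission) if fluoresces else None
        ratio = round(1.3 + 0.25 * rank, 2) if fluoresces else None
        records.append(
            CompoundRecord(
                id=cid,
                name=name,
                family=family,
                substitution_class=subclass,
                uv_maxima=uv_maxima,
                emission_max=emission,
                fluoresces=fluoresces,
                fl_monitor_pair=pair,
                fl_ratio=ratio,
                retention_time=9.5 + 0.95 * k,
                retention_index=None,
                quant_channel=quant_channel_for(family, subclass),
                uv_calibration=_curve(uv_cal),
                fl_calibration=fl_curve,
            )
        )
    for cid, rt, ri, uv, em, pair, ratio, subclass in _tables.CANDIDATE_ROWS:
        family = _tables.CANDIDATE_FAMILIES[cid]
        records.append(
            CompoundRecord(
                id=cid,
                name=f"candidate {cid}",
                family=family,
                substitution_class=subclass,
                uv_maxima=tuple(float(nm) for nm in uv),
                emission_max=float(em),
                fluoresces=True,
                fl_monitor_pair=pair,
                fl_ratio=ratio,
                retention_time=rt,
                retention_index=float(ri) if ri is not None else None,
                quant_channel=quant_channel_for(family, subclass),
            )
        )
    return records


# ---------------------------------------------------------------------------
# CSV persistence

_CSV_COLUMNS = [
    "id", "name", "family", "substitution_class", "uv_maxima", "emission_max",
    "fl_monitor_high", "fl_monitor_second", "fl_ratio", "rt_min", "ri",
    "quant_detector", "quant_wavelength",
    "uv_slope", "uv_r2", "uv_range_low", "uv_range_high", "uv_lod", "uv_loq",
    "cf_uv",
    "fl_slope", "fl_r2", "fl_range_low", "fl_range_high", "fl_lod", "fl_loq",
    "cf_fl",
]

_NA = "NA"


def _fmt(value) -> str:
    if value is None:
        return _NA
    if isinstance(value, (int, float)):
        return repr(float(value))  # stable through a write/read cycle
    return str(value)


def _parse_float(text: str, row: int, column: str) -> Optional[float]:
    if text == _NA or text == "":
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise CatalogError(f"row {row}, column {column!r}: bad number {text!r}") from exc


def write_catalog(records: Sequence[CompoundRecord], path: str | Path) -> None:
    """Write the catalog CSV (one row per compound, missing values as NA)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(_CSV_COLUMNS)
        for rec in records:
            uv_cal = rec.uv_calibration
            fl_cal = rec.fl_calibration
            row = [
                rec.id, rec.name, rec.family, rec.substitution_class,
                ";".join(_fmt(nm) for nm in rec.uv_maxima),
                _fmt(rec.emission_max),
                _fmt(rec.fl_monitor_pair[0]) if rec.fl_monitor_pair else _NA,
                _fmt(rec.fl_monitor_pair[1]) if rec.fl_monitor_pair else _NA,
                _fmt(rec.fl_ratio), _fmt(rec.retention_time),
                _fmt(rec.retention_index),
                rec.quant_channel[0], str(rec.quant_channel[1]),
            ]
            for cal in (uv_cal, fl_cal):
                if cal is None:
                    row.extend([_NA] * 7)
                else:
                    row.extend([
                        _fmt(cal.slope), _fmt(cal.r_squared),
                        _fmt(cal.range_low), _fmt(cal.range_high),
                        _fmt(cal.lod), _fmt(cal.loq),
                        _fmt(cal.correction_factor),
                    ])
            writer.writerow(row)


def _curve_from_row(row: dict, idx: int, prefix: str) -> Optional[CalibrationCurve]:
    slope = _parse_float(row[f"{prefix}_slope"], idx, f"{prefix}_slope")
    if slope is None:
        return None
    return CalibrationCurve(
        slope=slope,
        r_squared=_parse_float(row[f"{prefix}_r2"], idx, f"{prefix}_r2"),
        range_low=_parse_float(row[f"{prefix}_range_low"], idx, f"{prefix}_range_low"),
        range_high=_parse_float(row[f"{prefix}_range_high"], idx, f"{prefix}_range_high"),
        lod=_parse_float(row[f"{prefix}_lod"], idx, f"{prefix}_lod"),
        loq=_parse_float(row[f"{prefix}_loq"], idx, f"{prefix}_loq"),
        correction_factor=_parse_float(row[f"cf_{prefix}"], idx, f"cf_{prefix}"),
    )


def load_catalog(path: str | Path) -> list[CompoundRecord]:
    """Load a catalog CSV, validating every record's invariants."""
    path = Path(path)
    if not path.exists():
        raise CatalogError(f"catalog file not found: {path}")
    records: list[CompoundRecord] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise CatalogError(f"catalog file {path} is empty")
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise CatalogError(f"catalog missing columns: {sorted(missing)}")
        for idx, row in enumerate(reader, start=2):
            uv_text = row["uv_maxima"]
            if not uv_text or uv_text == _NA:
                raise CatalogError(f"row {idx}: uv_maxima is required")
            uv_maxima = tuple(
                _parse_float(part, idx, "uv_maxima") for part in uv_text.split(";")
            )
            hi_nm = _parse_float(row["fl_monitor_high"], idx, "fl_monitor_high")
            second_nm = _parse_float(row["fl_monitor_second"], idx, "fl_monitor_second")
            pair = (int(hi_nm), int(second_nm)) if hi_nm is not None else None
            emission = _parse_float(row["emission_max"], idx, "emission_max")
            try:
                records.append(
                    CompoundRecord(
                        id=row["id"],
                        name=row["name"],
                        family=row["family"],
                        substitution_class=row["substitution_class"],
                        uv_maxima=uv_maxima,
                        emission_max=emission,
                        fluoresces=emission is not None,
                        fl_monitor_pair=pair,
                        fl_ratio=_parse_float(row["fl_ratio"], idx, "fl_ratio"),
                        retention_time=_parse_float(row["rt_min"], idx, "rt_min"),
                        retention_index=_parse_float(row["ri"], idx, "ri"),
                        quant_channel=(row["quant_detector"],
                                       int(row["quant_wavelength"])),
                        uv_calibration=_curve_from_row(row, idx, "uv"),
                        fl_calibration=_curve_from_row(row, idx, "fl"),
                    )
                )
            except CatalogError:
                raise
            except (KeyError, ValueError) as exc:
                raise CatalogError(f"row {idx}: {exc}") from exc
    if not records:
        raise CatalogError(f"catalog file {path} holds no records")
    ids = [rec.id for rec in records]
    if len(set(ids)) != len(ids):
        raise CatalogError("duplicate compound ids in catalog")
    return records


def catalog_index(records: Sequence[CompoundRecord]) -> dict[str, CompoundRecord]:
    return {rec.id: rec for rec in records}
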