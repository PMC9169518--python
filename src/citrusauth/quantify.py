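"""Calibration and quantitation of OHA peaks.

Calibration curves are through-origin least squares (response = slope ·
concentration) built from seven standard levels; the highest level is
dropped iteratively until the linear correlation R² reaches 0.999. LOD and
LOQ follow the S/N = 3 and 10 definitions. Sample responses are corrected
multiplicatively by the psoralen internal-standard drift ratio and divided
by the 9-fold SPE concentration factor to report mg/L in the original juice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .catalog import CalibrationCurve, CompoundRecord

R2_THRESHOLD = 0.999
MIN_POINTS = 5
CONCENTRATION_FACTOR = 9.0


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationPoint:
    concentration: float  # mg/L
    response: float  # area units
    snr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise QuantError("calibration concentrations must be positive")
        if self.response < 0:
            raise QuantError("calibration responses must be nonnegative")


@dataclass(frozen=True)
class QuantResult:
    compound_id: str
    concentration: float  # mg/L in original juice
    concentrate_concentration: float  # mg/L in the 9x concentrate
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class RecoveryReport:
    surrogate: str
    spiked: float
    measured_mean: float
    recovery: float  # %
    intraday_rsd: float  # %
    interday_rsd: float  # %


def _through_origin_fit(conc: np.ndarray, resp: np.ndarray) -> tuple[float, float]:
    slope = float(np.dot(conc, resp) / np.dot(conc, conc))
    if resp.std() == 0 or conc.std() == 0:
        raise QuantError("degenerate calibration data (constant responses)")
    r = float(np.corrcoef(conc, resp)[0, 1])
    return slope, r * r


def fit_calibration(points: Sequence[CalibrationPoint],
                    r2_threshold: float = R2_THRESHOLD,
                    min_points: int = MIN_POINTS) -> CalibrationCurve:
    """Through-origin calibration with top-level truncation.

    While R² of the fit stays below the threshold and more than
    ``min_points`` levels remain, the highest concentration level is
    dropped (the linear range ends where linearity degrades).
    """
    pts = sorted(points, key=lambda p: p.concentration)
    if len(pts) < min_points:
        raise QuantError(f"need at least {min_points} calibration points")
    if len({p.concentration for p in pts}) != len(pts):
        raise QuantError("calibration concentrations must be distinct")
    while True:
        conc = np.array([p.concentration for p in pts])
        resp = np.array([p.response for p in pts])
        slope, r2 = _through_origin_fit(conc, resp)
        if r2 >= r2_threshold:
            break
        if len(pts) <= min_points:
            raise QuantError(
                f"calibration failure: R²={r2:.5f} < {r2_threshold} at "
                f"{len(pts)} points"
            )
        pts = pts[:-1]
    noise = _residual_sd(conc, resp, slope)
    lod, loq = estimate_lod_loq(noise, slope) if noise > 0 else (0.0, 0.0)
    return CalibrationCurve(
        slope=slope, r_squared=r2, range_low=float(conc[0]),
        range_high=float(conc[-1]), lod=lod, loq=max(loq, lod + 1e-12),
    )


def _residual_sd(conc: np.ndarray, resp: np.ndarray, slope: float) -> float:
    resid = resp - slope * conc
    if len(resid) <= 1:
        return 0.0
    return float(resid.std(ddof=1))


def estimate_lod_loq(noise_sd: float, slope: float) -> tuple[float, float]:
    """LOD and LOQ at signal-to-noise 3 and 10."""
    if slope <= 0:
        raise QuantError("slope must be positive")
    if noise_sd < 0:
        raise QuantError("noise SD must be nonnegative")
    return 3.0 * noise_sd / slope, 10.0 * noise_sd / slope


def quantify_peak(
    area: float,
    record: CompoundRecord,
    is_ratio: float = 1.0,
    concentration_factor: float = CONCENTRATION_FACTOR,
) -> QuantResult:
    """Concentration in original juice from a peak area on the quant channel.

    ``is_ratio`` is nominal/observed internal-standard response; it corrects
    detector drift multiplicatively. Flags are set against the calibration's
    LOD/LOQ and linear range on the concentrate scale.
    """
    if is_ratio <= 0:
        raise QuantError("internal-standard ratio must be positive")
    if area < 0:
        raise QuantError("area must be nonnegative")
    curve = record.calibration
    if curve is None:
        raise QuantError(
            f"compound {record.id} has no calibration on its quantitation "
            "channel; report its response peak area instead"
        )
    concentrate = area / curve.slope * is_ratio
    flags = set()
    if concentrate < curve.lod:
        flags |= {"below_LOD", "below_LOQ"}
    elif concentrate < curve.loq:
        flags.add("below_LOQ")
    if concentrate > curve.range_high:
        flags.add("above_range")
    return QuantResult(
        compound_id=record.id,
        concentration=concentrate / concentration_factor,
        concentrate_concentration=concentrate,
        flags=frozenset(flags),
    )


def recovery_report(
    surrogate: str,
    spiked: float,
    replicate_measurements: Sequence[Sequence[float]],
) -> RecoveryReport:
    """Recovery and precision summary from per-day replicate measurements.

    Recovery is grand mean / spiked level; intraday RSD is the mean of the
    per-day relative standard deviations; interday RSD is the RSD of the
    day means.
    """
    if spiked <= 0:
        raise QuantError("spike level must be positive")
    if len(replicate_measurements) < 2:
        raise QuantError("need at least two days of measurements")
    days = [np.asarray(day, dtype=float) for day in replicate_measurements]
    if any(day.size < 2 for day in days):
        raise QuantError("need at least two replicates per day")
    all_values = np.concatenate(days)
    grand_mean = float(all_values.mean())
    day_means = np.array([day.mean() for day in days])
    intraday = float(np.mean([
        day.std(ddof=1) / day.mean() * 100 if day.mean() != 0 else 0.0
        for day in days
    ]))
    interday = float(day_means.std(ddof=1) / day_means.mean() * 100
                     if day_means.mean() != 0 else 0.0)
    return RecoveryReport(
        surrogate=surrogate,
        spiked=spiked,
        measured_mean=grand_mean,
        recovery=grand_mean / spiked * 100.0,
        intraday_rsd=intraday,
        interday_rsd=interday,
    )
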