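"""Chromatographic peak identification.

Identification of an OHA peak rests on three independent lines of evidence,
each gated separately:

1. conforming degree of the full UV (and, for fluorescing compounds,
   emission) spectrum against the library standard;
2. the fluorescence peak-height ratio between the monitored emission
   channels (400/450/500 nm), a compact numeric fingerprint;
3. the retention index (RI) computed against a C8–C14 alkylarylketone
   anchor ladder, where the anchor of the ketone with n carbons is assigned
   index 100·n and a peak's RI is interpolated linearly inside its bracket.

A match is accepted only when exactly one library record passes every
applicable gate; zero or multiple survivors yield no match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .catalog import CompoundRecord
from .spectra import (
    SpectrumTrace,
    spectrum_conformity,
    synthetic_emission_trace,
    synthetic_uv_trace,
)


class PeakError(ValueError):
    pass


@dataclass(frozen=True)
class AnchorSeries:
    """Retention times of the alkylarylketone ladder (carbon number -> min)."""

    ketones: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.ketones) < 2:
            raise PeakError("anchor series needs at least two ketones")
        carbons = [c for c, _ in self.ketones]
        times = [t for _, t in self.ketones]
        if sorted(carbons) != carbons or len(set(carbons)) != len(carbons):
            raise PeakError("anchor carbon numbers must be strictly increasing")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise PeakError("anchor retention times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for _, t in self.ketones])

    @property
    def carbons(self) -> np.ndarray:
        return np.array([c for c, _ in self.ketones])


def compute_retention_index(rt: float, anchors: AnchorSeries) -> Optional[float]:
    """Bracketed linear retention index; None outside the anchor window.

    For t_n <= rt <= t_{n+1}: RI = 100·n + 100·(rt − t_n)/(t_{n+1} − t_n).
    Compounds eluting before the first ketone (or after the last) have no
    defined index.
    """
    times = anchors.times
    carbons = anchors.carbons
    if rt < times[0] or rt > times[-1]:
        return None
    j = int(np.searchsorted(times, rt, side="right")) - 1
    j = min(j, len(times) - 2)
    n, t_n = carbons[j], times[j]
    n1, t_n1 = carbons[j + 1], times[j + 1]
    frac = (rt - t_n) / (t_n1 - t_n)
    return 100.0 * n + 100.0 * (n1 - n) * frac


def backfit_anchor_times(
    pairs: Sequence[tuple[float, float]], low_carbon: int, high_carbon: int
) -> tuple[float, float]:
    """Recover bracket anchor times from (rt, RI) observations.

    Fits RI = a + b·rt by least squares over points lying in one bracket and
    inverts at RI = 100·low_carbon and 100·high_carbon. Used to reconstruct
    an anchor ladder from published index values when the ketone times
    themselves are not reported.
    """
    pts = np.asarray(pairs, dtype=float)
    if pts.shape[0] < 2:
        raise PeakError("need at least two (rt, RI) pairs")
    b, a = np.polyfit(pts[:, 0], pts[:, 1], 1)
    if b <= 0:
        raise PeakError("retention index must increase with retention time")
    t_low = (100.0 * low_carbon - a) / b
    t_high = (100.0 * high_carbon - a) / b
    return t_low, t_high


def fl_peak_ratio(heights: Mapping[int, float]) -> tuple[int, int, float]:
    """Highest / second-highest monitored fluorescence response.

    Returns (highest nm, second nm, ratio >= 1); ties break toward the
    shorter wavelength occupying the "highest" slot.
    """
    positive = [(nm, h) for nm, h in heights.items() if h > 0]
    if len(positive) < 2:
        raise PeakError("need at least two positive fluorescence heights")
    # sort by height descending, then wavelength ascending for ties
    ranked = sorted(positive, key=lambda item: (-item[1], item[0]))
    (hi_nm, hi_h), (sec_nm, sec_h) = ranked[0], ranked[1]
    return hi_nm, sec_nm, hi_h / sec_h


@dataclass(frozen=True)
class ChromatogramPeak:
    """A detected peak with per-channel responses and optional full spectra."""

    rt: float
    uv_spectrum: Optional[SpectrumTrace] = None
    em_spectrum: Optional[SpectrumTrace] = None
    heights: Mapping[int, float] = field(default_factory=dict)
    areas: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise PeakError("retention time must be positive")
        for label, mapping in (("heights", self.heights), ("areas", self.areas)):
            if any(v < 0 for v in mapping.values()):
                raise PeakError(f"{label} must be nonnegative")

    @property
    def fluoresces(self) -> bool:
        return any(self.heights.get(nm, 0.0) > 0 for nm in (400, 450, 500))


@dataclass(frozen=True)
class MatchGates:
    """Acceptance thresholds for the three identification prongs."""

    uv_conformity: float = 0.99
    em_conformity: float = 0.98
    ri_delta: float = 15.0
    ratio_rel_tol: float = 0.25


@dataclass(frozen=True)
class IdentificationResult:
    peak: ChromatogramPeak
    matched_id: Optional[str]
    ambiguous: bool = False
    candidates: tuple[str, ...] = ()
    scores: Mapping[str, float] = field(default_factory=dict)
    deduced_class: Optional[str] = None


def _record_ri(record: CompoundRecord, anchors: AnchorSeries) -> Optional[float]:
    if record.retention_index is not None:
        return record.retention_index
    if record.retention_time is None:
        return None
    return compute_retention_index(record.retention_time, anchors)


def _passes_gates(
    peak: ChromatogramPeak,
    peak_ri: Optional[float],
    record: CompoundRecord,
    anchors: AnchorSeries,
    gates: MatchGates,
) -> Optional[dict]:
    scores: dict[str, float] = {}
    if peak.uv_spectrum is not None:
        ref_uv = synthetic_uv_trace(record.uv_maxima, record.family)
        uv_score = spectrum_conformity(peak.uv_spectrum, ref_uv)
        scores["uv_conformity"] = uv_score
        if uv_score < gates.uv_conformity:
            return None
    rec_ri = _record_ri(record, anchors)
    if peak_ri is not None and rec_ri is not None:
        delta = abs(peak_ri - rec_ri)
        scores["ri_delta"] = delta
        if delta > gates.ri_delta:
            return None
    if record.fluoresces and peak.fluoresces:
        if peak.em_spectrum is not None and record.emission_max is not None:
            ref_em = synthetic_emission_trace(record.emission_max)
            em_score = spectrum_conformity(peak.em_spectrum, ref_em)
            scores["em_conformity"] = em_score
            if em_score < gates.em_conformity:
                return None
        if record.fl_ratio is not None and record.fl_monitor_pair is not None:
            hi_nm, sec_nm, ratio = fl_peak_ratio(peak.heights)
            rel = abs(ratio - record.fl_ratio) / record.fl_ratio
            scores["ratio_delta"] = rel
            if (hi_nm, sec_nm) != record.fl_monitor_pair or rel > gates.ratio_rel_tol:
                return None
    elif record.fluoresces != peak.fluoresces:
        # one fluoresces, the other does not: incompatible identities
        return None
    return scores


def identify_peak(
    peak: ChromatogramPeak,
    catalog: Sequence[CompoundRecord],
    anchors: AnchorSeries,
    gates: MatchGates = MatchGates(),
) -> IdentificationResult:
    """Match a peak against the library; unique gate survivor or no match."""
    peak_ri = compute_retention_index(peak.rt, anchors)
    survivors: list[tuple[str, dict]] = []
    for record in catalog:
        scores = _passes_gates(peak, peak_ri, record, anchors, gates)
        if scores is not None:
            survivors.append((record.id, scores))
    deduced = None
    if peak.uv_spectrum is not None:
        maxima = trace_maxima(peak.uv_spectrum)
        if maxima:
            em_max = (trace_maxima(peak.em_spectrum, top=1)[0]
                      if peak.em_spectrum is not None else None)
            deduced = _safe_classify(maxima, em_max)
    if len(survivors) == 1:
        rec_id, scores = survivors[0]
        return IdentificationResult(peak, rec_id, scores=scores,
                                    deduced_class=deduced)
    return IdentificationResult(
        peak, None, ambiguous=len(survivors) > 1,
        candidates=tuple(rec_id for rec_id, _ in survivors),
        deduced_class=deduced,
    )


def trace_maxima(trace: Optional[SpectrumTrace], top: int = 6,
                 min_rel_height: float = 0.15) -> list[float]:
    """Local maxima of a trace, sorted by wavelength (at most ``top`` bands)."""
    if trace is None or trace.wavelengths.size < 3:
        return []
    inten = trace.intensities
    wl = trace.wavelengths
    idx = [i for i in range(1, len(wl) - 1)
           if inten[i] >= inten[i - 1] and inten[i] > inten[i + 1]
           and inten[i] >= min_rel_height]
    idx = sorted(idx, key=lambda i: -inten[i])[:top]
    return sorted(float(wl[i]) for i in idx)


def _safe_classify(maxima: list[float], em_max: Optional[float]) -> Optional[str]:
    from .spectra import classify_spectrum

    try:
        return classify_spectrum(sorted(maxima), em_max)
    except Exception:
        return None
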