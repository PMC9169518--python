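"""UV and fluorescence-emission spectrum handling.

Full spectra are the primary identity evidence in DAD/FLD peak
identification: a sample peak is compared to a library standard by the
"conforming degree" of its whole spectrum, implemented here as the Pearson
correlation of the max-normalized traces on a common 1-nm grid.

The module also encodes the empirical spectra-to-structure rules used to
place unknown OHAs into substitution classes: band positions of coumarins,
furanocoumarins (FCs) and methoxyflavones (MFs) shift in characteristic ways
with the number and position of -OR / -OH substituents (e.g. 7-hydroxylation
strongly red-shifts a coumarin's emission maximum; mono-substituted FCs show
their large UV shoulder near 250 nm and 5,8-disubstituted FCs near 270 nm;
5-hydroxylation quenches fluorescence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

UV_GRID = (210.0, 400.0)
EMISSION_GRID = (340.0, 560.0)

# Half-width of each landmark window, nm.
WINDOW = 7.0


class SpectrumError(ValueError):
    """Raised for invalid spectral traces or degenerate comparisons."""


@dataclass(frozen=True)
class SpectrumTrace:
    """A max-normalized spectrum on a strictly increasing wavelength grid."""

    axis: str  # "UV" or "emission"
    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if self.axis not in ("UV", "emission"):
            raise SpectrumError(f"unknown axis {self.axis!r}")
        if wl.ndim != 1 or wl.shape != inten.shape:
            raise SpectrumError("wavelengths/intensities must be matching 1-d arrays")
        if wl.size and np.any(np.diff(wl) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if np.any(inten < 0):
            raise SpectrumError("intensities must be nonnegative")
        lo, hi = UV_GRID if self.axis == "UV" else EMISSION_GRID
        if wl.size and (wl[0] < lo or wl[-1] > hi):
            raise SpectrumError(f"{self.axis} grid outside [{lo}, {hi}] nm")
        peak = inten.max() if inten.size else 0.0
        if peak > 0:
            inten = inten / peak
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", inten)


def make_trace(axis: str, wavelengths: Sequence[float],
               intensities: Sequence[float]) -> SpectrumTrace:
    return SpectrumTrace(axis, np.asarray(wavelengths, float),
                         np.asarray(intensities, float))


def resample(trace: SpectrumTrace, grid: np.ndarray) -> np.ndarray:
    """Linear interpolation of the trace onto a 1-nm grid, renormalized."""
    values = np.interp(grid, trace.wavelengths, trace.intensities)
    peak = values.max()
    return values / peak if peak > 0 else values


def spectrum_conformity(sample: SpectrumTrace, reference: SpectrumTrace) -> float:
    """Conforming degree of two spectra: Pearson r on the overlap, clipped to [0, 1]."""
    if sample.axis != reference.axis:
        raise SpectrumError(
            f"cannot compare {sample.axis} spectrum to {reference.axis} spectrum"
        )
    lo = max(sample.wavelengths[0], reference.wavelengths[0])
    hi = min(sample.wavelengths[-1], reference.wavelengths[-1])
    if hi <= lo:
        raise SpectrumError("spectra have disjoint wavelength supports")
    grid = np.arange(lo, hi + 0.5, 1.0)
    a = resample(sample, grid)
    b = resample(reference, grid)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise SpectrumError("flat spectrum: conformity undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return min(max(r, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Synthetic trace construction (Gaussian bands at catalog maxima)

UV_BAND_SIGMA = 6.0
EMISSION_BAND_SIGMA = 10.0


def gaussian_bands(grid: np.ndarray, centers: Sequence[float],
                   amplitudes: Sequence[float], sigma: float) -> np.ndarray:
    total = np.zeros_like(grid)
    for c, a in zip(centers, amplitudes):
        total += a * np.exp(-0.5 * ((grid - c) / sigma) ** 2)
    peak = total.max()
    return total / peak if peak > 0 else total

def synthetic_uv_trace(uv_maxima: Sequence[float], family: str) -> SpectrumTrace:
    """Deterministic UV trace for a catalog entry.

    FCs carry their tallest band at the 243–277 nm shoulder; coumarins and
    MFs at the longest-wavelength band.
    """
    maxima = sorted(uv_maxima)
    amplitudes = [0.55] * len(maxima)
    main_idx = len(maxima) - 1
    if family == "FC":
        for i, nm in enumerate(maxima):
            if 243 <= nm <= 277:
                main_idx = i
                break
    amplitudes[main_idx] = 1.0
    grid = np.arange(UV_GRID[0], UV_GRID[1] + 0.5, 1.0)
    return SpectrumTrace("UV", grid,
                         gaussian_bands(grid, maxima, amplitudes, UV_BAND_SIGMA))


def synthetic_emission_trace(emission_max: float) -> SpectrumTrace:
    grid = np.arange(EMISSION_GRID[0], EMISSION_GRID[1] + 0.5, 1.0)
    return SpectrumTrace(
        "emission", grid, gaussian_bands(grid, [emission_max], [1.0],
                                         EMISSION_BAND_SIGMA)
    )


# ---------------------------------------------------------------------------
# Substitution-class screening rules


def _near(value: float, landmark: float, half_width: float = WINDOW) -> bool:
    return abs(value - landmark) <= half_width


def classify_spectrum(uv_maxima: Sequence[float],
                      emission_max: Optional[float]) -> str:
    """Deduce an OHA substitution class from UV maxima and the emission maximum.

    ``uv_maxima`` must be sorted ascending; the longest-wavelength band is
    treated as the main absorbance peak. Falls back to "uncategorized FC" /
    "uncategorized C" when no landmark rule fires.
    """
    maxima = [float(nm) for nm in uv_maxima]
    if not maxima:
        raise SpectrumError("uv_maxima must be nonempty")
    if sorted(maxima) != maxima:
        raise SpectrumError("uv_maxima must be sorted ascending")
    main = maxima[-1]
    shoulders = maxima[:-1]
    em = emission_max

    # Furanocoumarins: large shoulder near 250 (mono-substituted) or 270 nm
    # (5,8-disubstituted), smaller main peak near 310 nm.
    if 295 <= main <= 320:
        if any(_near(s, 270) for s in shoulders):
            return "5,8-diOR FC"
        if any(_near(s, 250) for s in shoulders):
            if em is None:
                return "5-OH FC"  # 5-hydroxylation quenches fluorescence
            return "5-OR FC" if main >= 305 else "8-OR FC"

    # Methoxyflavones: band-II shoulder(s) at 240–280 nm, far-red emission;
    # 5-hydroxylation red-shifts UV and quenches emission.
    if em is None and main >= 350:
        return "5-OH MF"
    if em is not None and em >= 500 and 318 <= main <= 335:
        mf_shoulders = [s for s in shoulders if 235 <= s <= 285]
        if len(mf_shoulders) >= 2:
            return "3',4'-diOMe MF"
        if len(mf_shoulders) == 1:
            return "4'-OMe MF"

    # Coumarins.
    if em is not None:
        if main >= 336 and 454 <= em <= 468:
            return "6-OR,7-OH C"
        if 336 <= main <= 350 and _near(em, 422):
            return "6,7-diOR C"
        if 316 <= main <= 330 and _near(em, 395):
            if any(_near(s, 256) for s in shoulders):
                return "7-OR,8-R C"
            return "7-OR C"
        # The ~260 nm shoulder separates 5-OR,7-OH from plain 7-OH coumarins,
        # whose main UV band sits in the same window.
        if (321 <= main <= 338 and em >= 455
                and any(252 <= s <= 269 for s in shoulders)):
            return "5-OR,7-OH C"
        # A double shoulder in the 245–265 nm region marks 5,7-disubstitution.
        if (319 <= main <= 333 and 430 <= em <= 460
                and sum(245 <= s <= 265 for s in shoulders) >= 2):
            return "5,7-diOR C"
        if 316 <= main <= 330 and _near(em, 461):
            return "7-OH C"

    return "uncategorized FC" if 295 <= main <= 320 else "uncategorized C"
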