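"""Zone-restricted ("partial") polynomial fluorescence-background removal.

Fluorescence under a Raman spectrum of biological tissue is broad and
smooth, and over the fingerprint region it is well described by a low-order
polynomial. Fitting that polynomial to the *whole* spectrum would drag the
baseline up into the Raman bands; instead the fit is restricted to zones
that carry fluorescence only, and the resulting polynomial is evaluated and
subtracted over the full working window.

Defaults reproduce the reference protocol for corneal measurements:

* fit zones 400–450, 800–1200 and 1600–1800 cm⁻¹ (fluorescence only);
* the water-band zone 1550–1650 cm⁻¹ excluded from the fit;
* polynomial degree 5;
* subtraction window 400–1700 cm⁻¹.

All intervals are closed on both ends. The fit uses a basis conditioned on
the fit window mapped to [−1, 1]; raw cm⁻¹ powers up to 1800⁵ would make a
degree-5 Vandermonde system numerically hostile.

Negative post-subtraction intensities are preserved, not clipped: the
morphological top-hat stage that follows is what guarantees non-negativity,
and clipping here would bias it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .errors import (
    ContractError,
    EmptySelectionError,
    UnderdeterminedError,
    WindowError,
)
from .io import Spectrum

__all__ = [
    "ZoneSet",
    "PolynomialBaseline",
    "select_channels",
    "fit_partial_polynomial",
    "subtract_baseline",
    "DEFAULT_FIT_ZONES",
    "WATER_EXCLUDE_ZONES",
    "DISSECTION_ZONES",
    "DEFAULT_WINDOW",
    "DEFAULT_DEGREE",
]


@dataclass(frozen=True)
class ZoneSet:
    """Ordered list of closed ``[low, high]`` wavenumber intervals (cm⁻¹)."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self):
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        for low, high in ivs:
            if not low < high:
                raise ContractError(f"zone [{low}, {high}] needs low < high")
        lows = [iv[0] for iv in ivs]
        if lows != sorted(lows):
            raise ContractError("zones must be sorted by lower bound")
        # touching endpoints (450–750 after 350–450) are allowed; real overlap is not
        for (_, h1), (l2, _) in zip(ivs, ivs[1:]):
            if l2 < h1:
                raise ContractError("zones must not overlap")

    @classmethod
    def from_string(cls, text: str) -> "ZoneSet":
        """Parse ``"400-450,800-1200"`` into a ZoneSet; empty string → no zones."""
        text = text.strip()
        if not text:
            return cls(())
        intervals = []
        for part in text.split(","):
            low, _, high = part.partition("-")
            intervals.append((float(low), float(high)))
        return cls(tuple(intervals))

    def contains(self, values) -> np.ndarray:
        """Boolean mask: which values fall inside any interval (closed)."""
        v = np.asarray(values, dtype=float)
        mask = np.zeros(v.shape, dtype=bool)
        for low, high in self.intervals:
            mask |= (v >= low) & (v <= high)
        return mask


#: Fluorescence-only zones used to determine the polynomial coefficients.
DEFAULT_FIT_ZONES = ZoneSet(((400.0, 450.0), (800.0, 1200.0), (1600.0, 1800.0)))
#: Water-band zone excluded from the fit.
WATER_EXCLUDE_ZONES = ZoneSet(((1550.0, 1650.0),))
#: Presentation-only dissection of the spectrum; plays no computational role.
DISSECTION_ZONES = ZoneSet(
    ((350.0, 450.0), (450.0, 750.0), (750.0, 1250.0), (1250.0, 1650.0), (1650.0, 1800.0))
)
#: Window over which the fitted background is subtracted.
DEFAULT_WINDOW = (400.0, 1700.0)
DEFAULT_DEGREE = 5


@dataclass(frozen=True)
class PolynomialBaseline:
    """Fitted background polynomial.

    ``coefficients`` are in the power basis on ``domain`` mapped to [−1, 1]
    (constant term first); ``window`` is the cm⁻¹ range the baseline may be
    subtracted over; ``fit_rms`` is the RMS residual over the fit channels.
    """

    coefficients: tuple[float, ...]
    domain: tuple[float, float]
    window: tuple[float, float]
    fit_rms: float

    def __post_init__(self):
        if not self.window[0] < self.window[1]:
            raise ContractError("window low must be < high")

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, wavenumbers) -> np.ndarray:
        """Evaluate the baseline at the given wavenumbers."""
        poly = Polynomial(np.asarray(self.coefficients), domain=self.domain)
        return poly(np.asarray(wavenumbers, dtype=float))


def select_channels(axis, include: ZoneSet, exclude: ZoneSet | None = None) -> np.ndarray:
    """Indices whose wavenumber lies in an include zone and no exclude zone.

    Intervals are closed, so exclusion removes its boundary channels too.
    """
    w = np.asarray(axis, dtype=float)
    if not np.all(np.diff(w) > 0):
        raise ContractError("axis must be strictly increasing")
    mask = include.contains(w)
    if exclude is not None:
        mask &= ~exclude.contains(w)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise EmptySelectionError("zone selection left no channels to fit")
    return idx


def fit_partial_polynomial(
    spectrum: Spectrum,
    fit_zones: ZoneSet = DEFAULT_FIT_ZONES,
    exclude_zones: ZoneSet | None = WATER_EXCLUDE_ZONES,
    degree: int = DEFAULT_DEGREE,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> PolynomialBaseline:
    """Least-squares polynomial over the selected fluorescence-only channels.

    The fit sees nothing outside the selected channels, so Raman bands (or
    any perturbation) supported entirely outside the fit zones cannot move a
    single coefficient.
    """
    if degree < 0:
        raise ContractError("degree must be >= 0")
    idx = select_channels(spectrum.wavenumbers, fit_zones, exclude_zones)
    if idx.size < degree + 1:
        raise UnderdeterminedError(
            f"{idx.size} fit channels cannot determine a degree-{degree} polynomial"
        )
    x = spectrum.wavenumbers[idx]
    y = spectrum.intensities[idx]
    poly = Polynomial.fit(x, y, deg=degree)  # fits on the domain mapped to [-1, 1]
    resid = y - poly(x)
    return PolynomialBaseline(
        coefficients=tuple(float(c) for c in poly.coef),
        domain=(float(poly.domain[0]), float(poly.domain[1])),
        window=(float(window[0]), float(window[1])),
        fit_rms=float(np.sqrt(np.mean(resid**2))),
    )


def subtract_baseline(spectrum: Spectrum, baseline: PolynomialBaseline) -> Spectrum:
    """Subtract the fitted background over the baseline's window.

    The output axis is the input axis restricted (closed) to the window;
    channels outside are dropped. Negative results are preserved.
    """
    low, high = baseline.window
    keep = (spectrum.wavenumbers >= low) & (spectrum.wavenumbers <= high)
    if not np.any(keep):
        raise WindowError(
            f"baseline window [{low}, {high}] does not intersect the axis"
        )
    w = spectrum.wavenumbers[keep]
    y = spectrum.intensities[keep] - baseline(w)
    meta = {**spectrum.meta, "baseline_window": f"{low}-{high}"}
    return Spectrum(w, y, meta)
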