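"""1-D grayscale morphology with flat structuring elements.

Erosion and dilation are windowed minimum and maximum; opening
(erode-then-dilate) slides a flat window under the signal and so estimates
the baseline beneath any feature narrower than the window; the top-hat
transform (signal minus opening) keeps those narrow features on a
non-negative, flat background. Applied after polynomial background
subtraction, the top-hat removes the broad instrumental structure that a
global polynomial cannot follow, while Raman bands — far narrower than the
window — pass through essentially unchanged.

Boundary policy is edge replication: windows are clipped to the valid
range, which never fabricates values beyond the recorded spectrum ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ContractError
from .io import Spectrum

__all__ = [
    "StructuringElement",
    "erode",
    "dilate",
    "opening",
    "tophat",
    "suggest_half_width",
]


@dataclass(frozen=True)
class StructuringElement:
    """Flat sliding window of ``2 * half_width + 1`` channels."""

    half_width: int

    def __post_init__(self):
        if not isinstance(self.half_width, (int, np.integer)) or self.half_width < 1:
            raise ContractError(f"half_width must be an integer >= 1, got {self.half_width}")

    @property
    def size(self) -> int:
        return 2 * int(self.half_width) + 1


def _check(signal, se: StructuringElement) -> np.ndarray:
    s = np.asarray(signal, dtype=float)
    if s.ndim != 1:
        raise ContractError("signal must be 1-D")
    if se.size > s.size:
        raise ContractError(
            f"window of {se.size} channels exceeds signal length {s.size}"
        )
    return s


def erode(signal, se: StructuringElement) -> np.ndarray:
    """Windowed minimum centred on each channel (clipped at the edges)."""
    s = _check(signal, se)
    return ndimage.minimum_filter1d(s, size=se.size, mode="nearest")


def dilate(signal, se: StructuringElement) -> np.ndarray:
    """Windowed maximum centred on each channel (clipped at the edges)."""
    s = _check(signal, se)
    return ndimage.maximum_filter1d(s, size=se.size, mode="nearest")


def opening(signal, se: StructuringElement) -> np.ndarray:
    """Erosion followed by dilation: baseline under features narrower than the window."""
    return dilate(erode(signal, se), se)


def tophat(signal, se: StructuringElement) -> np.ndarray:
    """Signal minus its opening; elementwise >= 0.

    Since the opening only ever selects values of the signal itself, the
    difference is non-negative exactly, not merely to rounding.
    """
    s = _check(signal, se)
    return s - opening(s, se)


def suggest_half_width(spectrum: Spectrum, max_peak_fwhm: float) -> StructuringElement:
    """Heuristic window size from the widest Raman band to preserve.

    ``half_width = ceil(1.5 * max_peak_fwhm / channel spacing)``, clipped to
    ``[1, (n - 1) / 2]``. At 1.5 FWHM of half-window the opening under a
    Gaussian band drops below ~0.2% of its apex, so the band survives the
    top-hat essentially intact, while structure broader than roughly three
    window widths is flattened. This is a documented heuristic, not the
    optimisation procedure of the morphological-baseline literature.
    """
    if not max_peak_fwhm > 0:
        raise ContractError(f"max_peak_fwhm must be > 0, got {max_peak_fwhm}")
    spacing = float(np.median(np.diff(spectrum.wavenumbers)))
    half = math.ceil(1.5 * max_peak_fwhm / spacing)
    half = max(1, min(half, (len(spectrum) - 1) // 2))
    return StructuringElement(half_width=int(half))
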