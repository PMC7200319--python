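"""Cosmic-ray spike detection and repair by inter-frame comparison.

A cosmic ray deposits charge in a handful of CCD channels of a single
exposure, so a spike appears at a wavenumber in one frame but not the
others. Comparing the frames of one measurement therefore detects spikes
reliably, and the corrupted channels can be repaired from the clean frames
— which is exactly why despiking must run *before* frame averaging, where a
spike would survive as a spurious peak.

Detection flags frame ``f`` at channel ``c`` when the intensity exceeds the
per-channel median by more than ``k`` robust standard deviations. The
robust scale at a channel is the scaled median absolute deviation (MAD)
across frames, floored by a pooled robust scale estimated from every
residual in the stack: with the usual 2–4 frames per measurement a
per-channel MAD alone is estimated from too few samples to set a stable
threshold, while the pooled scale is estimated from thousands of residuals.
A further absolute floor of 1e-9 × the stack's dynamic range guards against
identically repeated frames. Only positive excursions are flagged — cosmic
events add charge.

The single-frame fallback (running-median residual thresholding) is NOT the
inter-frame method; it exists only for measurements where a single exposure
is all there is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import CapabilityError, ContractError, UnrecoverableChannelError
from .io import FrameStack, Spectrum

__all__ = ["SpikeMask", "detect_spikes", "repair_spikes", "despike_single_frame"]

#: Consistency factor making the MAD estimate sigma for Gaussian noise.
MAD_SCALE = 1.4826

#: Default robust-z threshold: far beyond noise, far below cosmic-ray amplitudes.
DEFAULT_K = 8.0


@dataclass(frozen=True)
class SpikeMask:
    """Boolean matrix of spike-corrupted (frame, channel) entries."""

    flags: np.ndarray
    threshold_used: float

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def flagged_pairs(self):
        """(frame index, channel index) pairs, row-major order."""
        return list(zip(*np.nonzero(self.flags)))


def detect_spikes(
    stack: FrameStack, k: float = DEFAULT_K, scale_floor: float | None = None
) -> SpikeMask:
    """Flag positive per-channel outliers across frames.

    Parameters
    ----------
    stack
        At least two frames of one measurement.
    k
        Robust-deviation multiplier (> 0).
    scale_floor
        Absolute lower bound on the robust scale. Default: 1e-9 × the
        stack's dynamic range. Pass ``0.0`` to make detection exactly
        invariant under affine rescaling of the stack.
    """
    if stack.n_frames < 2:
        raise CapabilityError(
            "inter-frame despiking needs >= 2 frames; use despike_single_frame"
        )
    if not k > 0:
        raise ContractError(f"k must be > 0, got {k}")
    frames = stack.frames
    if scale_floor is None:
        scale_floor = 1e-9 * float(np.ptp(frames))
    center = np.median(frames, axis=0)
    resid = frames - center
    per_channel = MAD_SCALE * np.median(np.abs(resid), axis=0)
    # Pooled scale: with an odd frame count the median frame's residuals are
    # identically zero and carry no scale information, so take the quantile
    # that is the median of the remaining residuals' distribution.
    n = frames.shape[0]
    q = (n + 1) / (2 * n) if n % 2 else 0.5
    pooled = MAD_SCALE * float(np.quantile(np.abs(resid), q))
    scale = np.maximum(np.maximum(per_channel, pooled), scale_floor)
    flags = resid > k * scale
    dead = np.flatnonzero(flags.all(axis=0))
    if dead.size:
        raise UnrecoverableChannelError(dead.tolist())
    return SpikeMask(flags=flags, threshold_used=float(k))


def repair_spikes(stack: FrameStack, mask: SpikeMask) -> FrameStack:
    """Replace flagged entries by the median of the unflagged frames there.

    Unflagged entries are copied bit-identically. With a single clean donor
    the replacement is that donor's value, matching the manual practice of
    taking the same wavenumber from another frame.
    """
    flags = np.asarray(mask.flags, dtype=bool)
    if flags.shape != stack.frames.shape:
        raise ContractError(
            f"mask shape {flags.shape} != frames shape {stack.frames.shape}"
        )
    dead = np.flatnonzero(flags.all(axis=0))
    if dead.size:
        raise UnrecoverableChannelError(dead.tolist())
    repaired = stack.frames.copy()
    for c in np.flatnonzero(flags.any(axis=0)):
        donors = stack.frames[~flags[:, c], c]
        repaired[flags[:, c], c] = np.median(donors)
    meta = {**stack.meta, "spike_repairs": str(int(flags.sum()))}
    return FrameStack(stack.wavenumbers, repaired, meta)


def despike_single_frame(
    spectrum: Spectrum, window: int = 7, k: float = DEFAULT_K, rel_floor: float = 0.01
) -> Spectrum:
    """Fallback despiking for a lone frame via running-median residuals.

    Channels whose residual from a running median of ``window`` channels
    exceeds ``k`` robust deviations (of the residual distribution) are
    replaced by that local median. The robust scale is floored by
    ``rel_floor`` × the spectrum's dynamic range: on a nearly noiseless
    spectrum most running-median residuals vanish identically and a pure
    MAD scale would collapse to zero, turning every genuine band apex into
    a "spike". This is not the inter-frame method and cannot distinguish a
    one-channel-wide band from a cosmic ray.
    """
    if window % 2 == 0 or window < 3:
        raise ContractError(f"window must be odd and >= 3, got {window}")
    if not k > 0:
        raise ContractError(f"k must be > 0, got {k}")
    y = spectrum.intensities
    local_med = ndimage.median_filter(y, size=window, mode="nearest")
    resid = y - local_med
    floor = rel_floor * float(np.ptp(y)) if np.ptp(y) > 0 else 1e-12
    scale = max(MAD_SCALE * float(np.median(np.abs(resid))), floor)
    bad = resid > k * scale
    out = y.copy()
    out[bad] = local_med[bad]
    return spectrum.with_intensities(out, spike_repairs=int(bad.sum()))
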