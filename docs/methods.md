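# Methods

`ramanclean` implements a four-stage correction chain for multi-frame
confocal Raman measurements of biological samples, where the Raman signal
of interest sits on a fluorescence background that can be orders of
magnitude more intense, on top of broad instrument-related structure, and
is occasionally hit by cosmic-ray spikes. The stages run in a fixed order
that follows from the physics of the artefacts:

1. **Inter-frame despiking.** Cosmic rays strike random CCD channels of a
   single exposure, so a spike is present in one frame and absent from the
   others. Despiking must precede averaging — an averaged-in spike is
   indistinguishable from a narrow Raman band.
2. **Frame averaging.** The per-channel arithmetic mean of the frames,
   reducing detector noise by √N.
3. **Partial polynomial background subtraction.** A degree-5 polynomial is
   least-squares fitted to fluorescence-only zones and subtracted over the
   working window.
4. **Morphological top-hat.** Signal minus its grayscale opening removes
   the broad instrumental structure a global polynomial cannot follow,
   and leaves the narrow Raman bands on a non-negative, flat base.

A configuration that asks for a different ordering is rejected rather than
silently reordered; individual stages can be disabled.

## Despiking

For a stack of N ≥ 2 frames, channel *c* of frame *f* is flagged when

    I(f, c) − median_f I(f, c)  >  k · s(c)

with default k = 8. Only positive excursions are flagged: cosmic events
add charge, and negative outliers are left to the user.

The robust scale *s(c)* is the scaled (×1.4826) median absolute deviation
across frames at that channel, floored by two quantities:

* a **pooled robust scale** — the scaled quantile of |frame − channel
  median| over the whole stack, using quantile (N+1)/2N for odd N (the
  median frame's residuals are identically zero and carry no scale
  information) and the median for even N. Typical measurements have only
  2–4 frames; a per-channel MAD from 3 samples is just the smaller of two
  noise gaps and sets absurdly variable thresholds, while the pooled
  estimate uses thousands of residuals. The pooled floor is what brings
  the false-positive rate down to the Gaussian tail the threshold implies
  (zero observed false flags in 4.4 × 10⁵ entries over 200 trials).
* an **absolute floor** of 10⁻⁹ × the stack's dynamic range, so identical
  repeated frames (a zero-MAD degenerate case common in synthetic data)
  do not flag everything. Passing `scale_floor=0` makes detection exactly
  invariant under affine rescaling of the stack.

Flagged entries are replaced by the median of the *unflagged* frames at
the same wavenumber — deterministic, seed-free, and identical to "copy
the value from another frame" when exactly one donor exists. A channel
flagged in every frame has no donor and raises an error instead of
guessing. Unflagged entries are copied bit-identically, and re-running
detection on repaired data yields an empty mask (a fixed point) on all
fixtures.

`despike_single_frame` is a documented fallback for measurements with one
exposure only: channels whose residual from a running median exceeds k
robust deviations are replaced by that local median. Its scale is floored
at 1% of the spectrum's dynamic range, because on a nearly noiseless
spectrum the running-median residuals vanish almost everywhere and a pure
MAD scale would collapse to zero and flag genuine band apexes. The
consequence is explicit: this fallback ignores "spikes" smaller than
k × 1% ≈ 8% of the dynamic range, and it cannot distinguish a genuine
one-channel-wide band from a cosmic ray. It is not the inter-frame method.

## Partial polynomial background

The polynomial is fitted only to channels inside the fluorescence-only
zones **400–450, 800–1200 and 1600–1800 cm⁻¹**, minus the water-band
exclusion **1550–1650 cm⁻¹** (all intervals closed; because the exclusion
is closed, channel 1650 itself is excluded and the last fit zone
effectively starts at the next channel). The fitted polynomial is then
evaluated and subtracted over the working window **400–1700 cm⁻¹**; the
output axis is restricted to that window. The dissection zones
(350–450, 450–750, 750–1250, 1250–1650, 1650–1800 cm⁻¹) are exposed as
`DISSECTION_ZONES` for annotation but play no computational role.

Degree 5 is the fixed default; no automatic degree selection is
attempted. Fitting uses `numpy.polynomial.Polynomial.fit`, which maps the
fit support to [−1, 1] before building the Vandermonde system — raw cm⁻¹
powers up to 1800⁵ span 16 orders of magnitude and would destroy the
conditioning of a degree-5 fit. Coefficients are stored in that
conditioned basis. Consequences that the tests assert:

* a noiseless input inside the model class is recovered to < 10⁻⁸ of its
  dynamic range over the whole window;
* the fit is linear in the data and completely blind to any perturbation
  supported outside the fit channels (coefficients match exactly, since
  the solver never sees those channels);
* with i.i.d. noise of scale σ the baseline RMSE over the window stays
  below 3σ (in practice ≈ 0.25σ; the gaps 450–800 and 1200–1550 cm⁻¹ are
  interpolated inside the fit support's convex hull, so the error is not
  badly amplified there).

Negative post-subtraction intensities are preserved. Clipping would bias
the morphology stage; the top-hat is what guarantees non-negativity.

## Morphological top-hat

Erosion and dilation are windowed minimum and maximum with a flat
structuring element of 2·h+1 channels; opening is erosion followed by
dilation; the top-hat is signal − opening. Because the opening only ever
selects values of the signal itself, the top-hat is non-negative exactly,
not merely to rounding, and it is invariant under constant offsets.
Boundaries use edge replication (windows clipped to the valid range),
which never fabricates values beyond the recorded ends; the working
window 400–1700 cm⁻¹ has already trimmed the unreliable edges.

The implementation delegates to `scipy.ndimage` min/max filters; the test
suite holds it bitwise-equal to an independent brute-force windowed scan,
so any replacement algorithm must reproduce the same extrema exactly.

**Window width.** `suggest_half_width` sets h = ⌈1.5 · FWHM_max / Δ⌉
channels (Δ = channel spacing), clipped to [1, (n−1)/2], from the widest
Raman band to be preserved (default FWHM_max = 30 cm⁻¹, a typical Raman
linewidth, giving h = 23 at 2 cm⁻¹ spacing). At 1.5 FWHM of half-window,
the opening under a Gaussian band is below ~0.2% of its apex, so the band
passes essentially intact; smooth structure with period beyond roughly
three window widths is attenuated more than tenfold, since the residual
under the opening scales as the curvature × (window/2)². This is a
stated heuristic, not the width-optimisation procedure described in the
morphological-baseline literature, and it is always user-overridable.

## Synthetic measurements

The generator composes each frame additively: degree-5 polynomial
background + Gaussian bands + single sinusoid ripple + i.i.d. Gaussian
noise (fresh draw per frame) + per-(frame, channel) spikes, on the
350–1800 cm⁻¹, 2 cm⁻¹-step axis of the target instrument. The ground
truth carries every component separately; the stored noise is the
realised residual frames − deterministic components, so the composition
identity holds bitwise. Everything is reproducible from one seed.

The `paperlike_fixture` freezes one realistic condition set: a curved
positive background of ≈ 2000 counts; four bands (centres 500, 620, 1300,
1450 cm⁻¹; FWHM 12–30 cm⁻¹; heights 300–500 counts) placed *outside* the
fluorescence-only fit zones, which is precisely the situation the zone
design assumes of real tissue spectra; ripple of period 800 cm⁻¹ and
amplitude 25 counts (≈ 1% of background — broad instrumental structure,
clearly in the baseline regime of a 94 cm⁻¹ morphology window); noise
σ = 20 counts for a background-to-noise ratio of about 100:1; and two
cosmic-ray spikes of 40–120σ in distinct frames at seed-chosen channels
inside the working window. Passing `ripple=False` yields a bitwise
noise-matched twin without the ripple, which is how ripple suppression is
measured causally: the pipeline is run on both twins and the output
difference is projected onto the injected waveform over peak-free
channels. (A naive projection of the final spectrum alone conflates
noise-induced polynomial-fit wander — which has ripple-frequency content
by chance — with genuine ripple leakage.)

What the generator does **not** emulate: Poisson/shot noise and its
intensity dependence, CCD dark current and etaloning, Lorentzian/Voigt
lineshapes, multi-channel cosmic-ray tracks, wavenumber-calibration
error, and fluorescence photobleaching between frames. Passing tests
therefore demonstrate the algorithmic contracts under additive Gaussian
conditions, not performance on any particular instrument's data.

## Numerical choices and degenerate inputs

* Axes are normalised to strictly ascending order on read; duplicate
  wavenumbers are an error, not silently merged.
* Spectra require ≥ 7 channels (a degree-5 fit needs 6 points, plus one
  of margin).
* Zone intervals may touch at an endpoint (the dissection zones do) but
  may not overlap.
* A fit with fewer selected channels than degree+1 coefficients, an
  empty zone selection, a subtraction window disjoint from the axis, and
  a morphology window longer than the signal are all distinct, named
  errors rather than NaN results.
* Pipeline failures carry the stage name; no partial output files are
  written on failure.

## Problem sizes

The test suite and the acceptance script regenerate everything they
measure: 500 random vectors for the morphology oracle, 100 replicates
for the noisy-baseline statistics, 200 seeded three-frame measurements
(726 channels each) for despiking sensitivity/specificity, and single
seeded measurements for the end-to-end checks. The full suite runs in a
few seconds on one CPU.

## Known limitations

* The despiking threshold assumes frame-to-frame registration; drifting
  samples (photobleaching, movement) violate the shared-median premise.
* Heteroscedastic (shot-noise-dominated) stacks weaken the pooled-scale
  floor's calibration; the per-channel MAD term still adapts, but the
  false-positive guarantee is derived for homoscedastic noise.
* The single-frame fallback is insensitive by design (see above).
* Fit zones are fixed wavenumber intervals; samples with Raman bands
  inside 800–1200 cm⁻¹ need user-adjusted zones, which the config and CLI
  expose.
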