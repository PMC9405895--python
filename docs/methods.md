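# Methods

This note documents the models, conventions and numerical choices behind
`rtpcflow`, and what the synthetic ground truth does and does not establish
about real data.

## Flow quantification model

Phase-contrast MRI encodes through-plane velocity linearly in the image
phase: v = VENC·φ/π (cm/s), with velocities beyond ±VENC wrapping by 2·VENC
(aliasing). The scanner's phase-scaling convention is not modelled; ingest
assumes radians, and exporters using scaled integers must convert at read
time. Upward (head-ward) velocities are positive; because only venous
signals are analyzed, all velocities are multiplied by −1 so venous flow
reads positive.

**Background phase.** Residual background phase is estimated per frame as
the mean phase over the no-flow area (NFA) and subtracted inside the vessel
ROI before conversion. The per-frame choice also cancels slow scanner phase
drift exactly; a time-averaged variant (`time_average=True`) models a single
static offset instead. Spatial (2-D polynomial) eddy-current correction is
out of scope.

**Segmentation.** The threshold is half the mean of the 25 brightest pixels
inside the user box — a full-width-half-maximum-style criterion that adapts
to the vessel's peak signal. "Brighter than the threshold" is strict (>),
ties among the 25 brightest are resolved by stable sort order, region
growing uses 4-connectivity (conservative against diagonal leakage between
adjacent vessels), and boxes are half-open with 0-based row-major pixel
coordinates. The reference frame (the "highest-flow" frame on which the
operator would segment) is chosen as the frame maximizing mean |phase| in
the box — a proxy needed because flow itself is not yet computed at that
point. The NFA replaces an operator's hand-drawn static-tissue region with
a dilation ring (default band: 2–5 dilation steps from the vessel) that
excludes any supra-threshold pixel, so a neighbouring vessel cannot leak
into the background estimate. Mask propagation over frames offers both
plausible readings of an operator "copying and adjusting" masks: verbatim
copy, and per-frame re-segmentation seeded at the previous frame's centroid
with fallback to copy when re-segmentation fails.

**Aliasing.** Pixels deviating from the in-mask median by more than VENC
receive one ±2·VENC correction toward the median. A single pass stalls when
a near-majority of pixels is aliased (the median itself is corrupted), so
the pass is iterated with a freshly computed median until stable; each pixel
is corrected at most once. This recovers peak velocities up to ~1.5×VENC
for parabolic profiles; beyond that the aliased fraction approaches half
the vessel and a median reference is no longer meaningful.

**Flow.** Q(t) [mL/s] = mean velocity over the frame's mask [cm/s] × mask
area [mm²] / 100, with the per-frame mask area (consistent with propagated
masks; the per-acquisition report also carries the reference-frame area).

## Spectral analysis

The 60 s flow signal is detrended with a least-squares polynomial of order 4
(removes the zero-frequency pile-up; the residual is orthogonal to all
monomials up to the order). The PSD is a single-taper Hann periodogram:
60 s of data need the full 1/60 Hz ≈ 0.017 Hz resolution to separate the
breathing peak from low-frequency remnants, so Welch averaging is off by
default. The raw density is rescaled so its trapezoidal integral over
[0, fs/2] equals the detrended-signal variance; this absorbs the window's
power loss and makes band powers exact variance fractions (Parseval
convention), which keeps NAUC in [0, 1] up to spectral leakage.
"Whole-signal variance" therefore means the variance *after* detrending —
the only reading under which NAUC ≤ 1 holds. Non-uniform frame times are
linearly resampled to the nominal frame interval first.

Peak search windows default to 0.10–0.50 Hz (HF) and 0.60–3.0 Hz (VHF);
when measured breathing/heart rates are available the windows shrink to
rate ± 0.15 Hz and rate ± 0.30 Hz, which prevents a taller second cardiac
harmonic from capturing the VHF peak. Argmax ties resolve to the lowest
frequency.

The respiratory band is fixed at [0.15, 0.35] Hz by default, reading the
band's definition as "from 0.15 Hz (below the peak) to 0.35 Hz (above the
peak)" — consistent with the 0.15–0.35 Hz band-pass used for waveform
display; the peak-relative alternative [hf−0.15, hf+0.35] is available via
`band_mode="peak-relative"`. The cardiac band is 0.5 Hz wide, centered at
the VHF peak. Bands are clipped to (0, fs/2) and must remain disjoint; an
overlap (e.g. a VHF peak found at 0.45 Hz) raises an error, flagging an
implausible peak rather than silently integrating overlapping power.

## Physiological rates

Average breathing and heart rates are computed by counting peaks —
(n_peaks − 1) / elapsed time between first and last peak — matching the
semantics of "average rate over the acquisition". Minimum peak separations
encode physiological ceilings (breathing ≤ 40/min → 1.5 s; heart
≤ 180/min → 0.33 s); the prominence threshold is half the interquartile
range of the lightly smoothed signal (50 ms moving average), which makes
the estimate invariant to gain and DC offset. A spectral-argmax estimate
would be a valid alternative; peak counting was chosen and the tests
cross-check it against the generator's programmed rates.

## Group statistics

Indices are compared across breathing modes with the Friedman test on
within-subject ranks (tie-corrected rank-sum form, df = k−1, chi-square
upper tail). Post-hoc pairwise contrasts use Conover's least-significant-
difference on ranks: t = |R_j − R_l| / sqrt(2(n·A − ΣR_j²)/((n−1)(k−1)))
with (n−1)(k−1) degrees of freedom — algebraically the LSD of a two-way
ANOVA on the within-block ranks, whose variance term reduces to the exact
null variance n·k(k+1)/6 without ties. When every block ranks the
conditions identically the error variance is zero and any non-zero rank-sum
difference is reported as p → 0 (the LSD limit). Correctness is gated by a
within-block permutation oracle of the same studentized statistic rather
than trusted from the formula. Pairwise p values are adjusted with
Benjamini–Hochberg, by default within each index's family of three
comparisons (mirroring a per-row report layout); a global family is
available. Note that BH adjustment is *not* idempotent — re-adjusting an
adjusted vector inflates it further — so adjusted values are computed once
from raw p values only. Descriptives are median [min, max], appropriate for
n = 16.

## Synthetic ground truth

The waveform generator emulates the qualitative structure of venous flow:

Q(t) = q0 + drift(t) + (1 + m·sin(2πf_r t))·Σ_h a_h cos(2πh f_c t + φ_h)
      + b·sin(2πf_r t + ψ) + ε_t

with defaults q0 = 5 mL/s, cardiac fundamental f_c = 1.2 Hz and harmonic
amplitudes (1.0, 0.3, 0.1) mL/s, respiratory rate f_r = 0.25 Hz with
additive amplitude b = 0.6 mL/s, white noise 0.3 mL/s, 58.5 ms sampling,
60 s duration. These place the free-breathing indices near NAUC(R) ≈ 0.22
and NAUC(C) ≈ 0.62 with mean flows and variances in the physiological range
for the neck veins. The respiratory influence has both an additive term (b)
and an optional amplitude-modulation term (m), because real waveforms show
baseline-level and envelope effects; closed-form expected indices
(`theoretical_indices`) are only claimed for m = 0:

V = Σ a_h²/2 + b²/2 + σ²,  NAUC(R) = (b²/2 + σ²·w_r)/V,
NAUC(C) = (a1²/2 + σ²·w_c)/V,

where w are band-width fractions of the Nyquist range (harmonics 2–3 fall
outside the 0.5 Hz cardiac band by construction of the parameter bounds).

The image phantom paints a circular vessel (radius 3.5 mm, i.e. ~5 pixels)
with a pulsatile parabolic profile v(ρ) = 2·v̄(t)(1 − (ρ/R)²) into the
acquisition geometry, with configurable background phase offset, Gaussian
phase/magnitude noise (adequate in the high-SNR regime of segmented
vessels; Rician noise is not modelled), slow in-plane drift, and natural
aliasing when |v| > VENC. A pixel belongs to the vessel when its centre
lies inside the circle; consequently the boundary ring carries near-zero
velocities and the pipeline's mean flow underestimates the generator's Q by
the area ratio πR²/A_raster ≈ 3–4% at the default radius. This
rasterization bias is a property of the phantom, not of the measurement
chain, and bounds the end-to-end flow-recovery tolerance (5%).

The cohort generator draws subject-level lognormal random effects (CV 25%
on mean flow, 30% on respiratory and cardiac amplitudes) and personal rates
(breathing 0.2–0.3 Hz, heart 1.0–1.4 Hz), then applies breathing-mode
effects: paced-normal breathing raises the respiratory amplitude ×1.3;
paced-deep breathing doubles it, lowers mean flow ×0.7 and slows breathing
×0.9. These produce group medians moving from NAUC(R) ≈ 0.2 (free) to
≈ 0.55 (deep) with the ratio median crossing 1 in deep breathing.

**What passing tests do not show.** The generator has no beat-to-beat rate
variability, no respiratory-phase asymmetry (inspiration vs expiration), no
through-plane motion, no partial-volume or k-space/parallel-imaging
artefacts, and stationary amplitudes within an acquisition. Recovery of its
parameters demonstrates the correctness of the measurement chain, not the
physiological accuracy of any particular real-world acquisition.

## Problem sizes and determinism

All generators are bit-reproducible given (params, seed); per-subject seeds
derive from `numpy.random.SeedSequence` spawning. The test suite and the
acceptance script use: one full 60 s phantom per image-level check (1026
frames of 96×128), 10 s phantoms where only the offset estimator is probed,
100 waveform seeds for spectral recovery, 2,000 null tables for Friedman
calibration, 10⁵ resamples for the Durbin–Conover permutation oracle, and
200 cohort repetitions (16 subjects × 3 modes each) for the design-level
power check — sizes at which the Monte-Carlo error of each check is well
below its tolerance.

## Known limitations

- The aliasing correction assumes the majority of vessel pixels are
  unaliased; it is not a spatial phase-unwrapping algorithm.
- The NFA ring automates what is a manual, anatomy-aware choice in
  practice; near complex anatomy a hand-drawn NFA may differ.
- The Durbin–Conover t approximation deviates from its exact permutation
  null by up to ~0.03 in the mid-p range at n = 6; at n = 16 and for small
  p the approximation is accurate.
- DICOM ingest is not implemented; data enter as NIfTI pairs with a JSON
  sidecar carrying VENC, pixel spacing, frame interval and start time.
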