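# Methods

## Signal model

Excitation is a periodic square pulse train: frequency `F`, duty cycle `D`,
on-time `D/F`, off-time `(1−D)/F`. Probe emission is modeled as a plateau of
amplitude `A` while the source is on (the default "instantaneous rise";
an exponential rise `A(1−e^(−t/τ))` is available) and a monoexponential decay
`A'·e^(−(t−t_off)/τ)` after each off edge. The light a frame collects is the
exact piecewise integral of this trace over its exposure window `[t, t+s)`;
all rendering and frame-intensity simulation uses the closed form, so
simulator output is analytic up to quantization and injected noise. The
steady-state plateau assumption means re-excitation resets the emission
level; this is adequate whenever the validity rule `(1−D)/F ≥ 3τ` holds,
which the package checks rather than assumes.

## Timing calculus

All relations live in `vchopper.timing`:

| quantity | formula | meaning |
|---|---|---|
| `f_real` | `f ± σ` | actual camera rate; `σ` is the drift magnitude (fps) |
| `Δt` | `σ/(f·f_real)` | exposure phase slip per frame |
| `m` | `f/gcd(f,F)` | camera frames between gated frames |
| `Δt_n` | `(n−1)·m·Δt` | gating delay of the n-th gated frame |
| `F_max` | `(1−D)/(k·τ)` | pulse-rate bound; completeness factor `k` defaults to 3 |
| `s_max` | `(1−D)/F` | strict exposure bound |
| `T_min` | `(1−D)·f/(σ·F)` | video length for one full off-window sweep |

`T_min` follows from the slip rate: the gating delay advances by `Δt` per
frame, i.e. `Δt·f_real ≈ σ/f` seconds of delay per second of video, so
sweeping the off window `(1−D)/F` takes `(1−D)·f/(σF)`. A brute-force
schedule simulation (explicit interval containment, no modular arithmetic)
confirms this in the test suite.

Non-integer rates in `m` are rationalized on a 1 mHz grid (both rates scaled
by 1000 and rounded; a pair off that grid beyond 1e−6 relative raises an
error). The shutter rule is strict (`s == (1−D)/F` is flagged): equality
means the exposure abuts the next pulse. Durations in reports are rounded to
3 significant figures; internal values keep full precision. Delay ladders
quoted in reports are formed from the 3-significant-figure `Δt`, matching the
measurement precision of the drift itself.

## Gated phase classes

A subtlety the delay ladder alone hides: the `m` exposure phase classes are
spaced `1/(mF)` apart within the pulse period, and when the off window is
wider than that spacing, *two* classes can be gated in the same pulse period.
The assembled delay sequence is then the interleaving of `m` ladders with
different offsets, not a single ladder. Assembly therefore computes each
gated frame's delay directly from schedule geometry —
`((k/f_real) mod (1/F)) − D/F` for frame `k` — and sorts by it. This reduces
exactly to `Δt_n = (n−1)·m·Δt` per class, handles both drift directions
without special-casing (no reversal step; the phase arithmetic already
orders delays correctly when `f_real > f`), and lets repeated sweeps of a
long recording land on equal delays, where frames are averaged. Frames whose
labels claim "gated" but whose geometric delay falls outside `[0, (1−D)/F − s]`
are misclassified partial-overlap frames and are discarded with a warning.
Delays are reported absolutely (the smallest observed delay is below one
gated step when a full sweep exists); the exponential fit is shift-invariant
in the delay origin, so `τ` is unaffected by the unknown sub-step offset.

## Drift estimation

When `σ` is not supplied (no container metadata), it is estimated from the
classified frames by a coarse-to-fine grid search: a candidate `(σ, sign)`
predicts from geometry which frames should be gated, and the candidate
maximizing agreement with the observed gated/non-gated pattern wins
(geomspace grid 0.003–0.5 fps, two local refinement passes, ~0.1% final
resolution). Matching the binary pattern rather than correlating intensities
is deliberate: correlation scores admit stroboscopic aliases (a wrong `σ`
that still lines up run interiors), while run *lengths* pin the true value.
The drift sign is then chosen as the one under which geometric delays
anti-correlate with gated log-intensities (a decay); the mirror hypothesis
decoheres or reverses the trend. On noise-free synthetic stacks the
estimator recovers `σ ∈ [0.01, 0.3]` fps within 5% for both signs and both
tested pulse configurations.

## Classification

Gated frames are far darker than source-on frames (which carry substrate
autofluorescence), so the pipeline default is a deterministic threshold on
frame means, with Otsu's method on the (bimodal) mean histogram; a constant
or unimodal series yields a warning and all-zero labels. Partial-overlap
frames form a brightness continuum between the classes; whichever side of
the threshold they fall on, the geometric delay check in assembly removes
any that leak through as "gated", so classification errors at the boundary
are one-sided and harmless.

The conv-net classifier mirrors the automated workflow: 128×128 grayscale
input, three blocks of 3×3 convolution (8/16/32 filters) → batch norm →
ReLU → 2×2 max pool, a flattened dense layer with 100 hidden nodes (batch
norm, ReLU, dropout 0.5), and a two-class softmax; RMSprop at learning rate
1e−4, batch size 32, cross-entropy loss, early stopping on validation loss
(patience 3, minimum meaningful improvement 1e-3, max 6 epochs — the
synthetic frame classes separate within one or two epochs, so a longer
budget only sharpens confidence at real cost on one CPU). Filter counts and the epoch
budget are this package's choices, sized as the smallest standard stack
matching the described layer sequence and a single-CPU numpy implementation;
convolutions are im2col matrix products in float32. Training runs the
three-stage schedule (train/validate with early stopping; refit on
train+validation for the best epoch count and evaluate on the test split;
refit on everything for the deployable model) on a stratified 60/20/20
split. Batch-norm running statistics use a cumulative average for the first
batches before switching to exponential decay, so models trained for very
few steps still normalize correctly at inference. Metrics follow the
gated-positive convention: TP counts gated frames classified correctly;
sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`; empty denominators are
reported as NaN with a flag rather than raising.

## Lifetime fitting

Two estimators over the virtual decay sequence:

- **log-linear** (vectorized over pixels): subtract a background estimate
  (median of the last 10% of delays, or a supplied dark value), keep only the
  *leading contiguous run* of points more than 3 robust-noise units above
  background, and weighted-least-squares the log intensities with weights
  proportional to the subtracted intensity. The leading-run rule matters: a
  monotone decay that has reached the noise floor contributes only censored
  up-fluctuations afterwards, which would otherwise flatten the slope and
  inflate `τ` severely. The robust noise level is 1.4826×MAD of late-delay
  residuals, falling back to their standard deviation when quantization
  collapses the MAD to zero.
- **nls** (default): `A·e^(−t/τ) + B` by Levenberg–Marquardt, seeded by the
  log-linear estimate, background term included by default because real
  gated frames retain residual autofluorescence (a `B = 0` variant exists).

Per-pixel failures (non-decaying, non-positive, `τ` beyond 100× the delay
span, non-convergence) are masked, never raised. Pixels whose peak excursion
above background is below `snr_threshold` (default 3) robust-noise units are
masked before fitting. ROI statistics report mean, sample SD, CV = SD/mean
and a histogram over valid pixels. All delays are seconds in, `τ` seconds
out; microsecond values are display formatting.

## Synthetic phantoms and what they do (not) show

The generator emulates the study conditions: a two-shape phantom (disc +
triangle; ground-truth lifetimes default 168.4 µs and 512.3 µs) imaged at
50 Hz / 40% duty / 30 fps (drift 0.02 fps) / 1/350 s exposure, and a
three-region phantom (figure, ground strip, small disc; defaults 510.4,
169.3, 78.3 µs) at 30 Hz pulses, 30 fps, 1/500 s. Substrate
autofluorescence is short-lived and contributes only during source-on
overlap. The digital gain anchors the brightest *gated* pixel at 60% of full
scale, so source-on frames may clip — as in real recordings exposed for the
gated emission; the saturation warning therefore inspects gated frames only.
Noise is Poisson shot noise (4 photons per digital number) followed by
Gaussian read noise (1 DN), then quantization to 8 or 16 bits; the camera
noise figures are this package's assumption, not a measured calibration, so
noisy-case tolerances (10% recovery, CV ≤ 10%) are checks of pipeline
robustness, not predictions of any specific camera. An optional rolling
shutter offsets each row's exposure start by `row × skew`; frames with any
row overlapping the source-on interval are conservatively labeled class 1.
No optics (PSF, vignetting), demosaicing or codec artifacts are simulated,
so passing tests say nothing about motion, focus or compression effects on
real videos.

Test problem sizes are chosen to exercise complete sweeps at modest cost:
48×48 phantoms, one-sweep noise-free videos (19 s / 31 s) and two-to-three-
sweep noisy videos (55 s / 65 s); classifier training uses 800 frames per
class at the two-shape settings with per-video randomized lifetimes and
amplitudes.

## Known limitations

- Monoexponential model only; mixed-τ pixels fit to an intermediate value
  (verified against a brute-force fit of the analytic mixture).
- Drift is assumed constant within one recording.
- Drift estimation needs at least ~two modulation envelopes of video and a
  detectable intensity modulation; an exactly locked camera (`σ = 0`) is a
  hard error for the virtual-chopper path.
- Raw video container decoding is out of scope; inputs are frame directories
  or multi-page TIFF with a JSON manifest.
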