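# Methods

This note documents the models, parameter choices, and numerical decisions
behind `chewcount`, and what the synthetic evaluation does and does not
demonstrate.

## Signal model

One chew is one up-down mandible cycle.  The observable is the mean
Euclidean distance ED_t from the 11 chin/jawline landmarks to the upper-left
corner (u, v) of the face bounding box, sampled once per frame.  The corner
is re-read from each frame's own box — the box tracks the face, so
whole-head translation shifts box and landmarks together and cancels
exactly.  Units are pixels throughout; ED depends on face size and camera
distance, which is harmless because every threshold downstream is relative.
Optional face-size normalisation exists but is off by default.

Frames with failed detection are flagged, never dropped.  The signal
builder fills gaps by linear interpolation (default) or hold-last, records
them in a missing-sample mask, and refuses tracks with more than 50%
invalid frames.  Which policy real recordings need depends on the detector;
interpolation is the neutral choice for isolated dropouts.

## Smoothing branches

**Low-pass filter.**  A linear-phase FIR low-pass designed at minimum order
for its spec (Kaiser-window design via `kaiserord`), applied
forward-backward (`filtfilt`) so the output is zero-phase: peak sample
indices map directly to frame times with no group-delay correction.
Defaults: passband edge 1 Hz, stopband edge 5 Hz, 40 dB stopband and ≤1 dB
passband deviation *end-to-end* (each pass is designed at half the dB).
The deliberately gentle transition is a physical necessity, not sloppiness:
chew rates run up to ≈2.3 Hz at fast speed, so a sharp 1→2 Hz transition
would annihilate exactly the oscillation being counted.  With the adaptive
(relative) peak threshold, a partially attenuated chew band still counts
correctly, while noise above 5 Hz is suppressed ≥40 dB.  All edges and
attenuations are configurable; an optional `resample_hz` first resamples
the signal (polyphase) for users who want a fixed design rate such as
50 Hz.

**Discrete wavelet decomposition.**  An L-level dyadic cascade of
Daubechies 4-tap ('db2', the classic D4) analysis filters with periodized
extension, making the transform orthogonal: reconstruction is exact to
rounding, and coefficient energy equals signal energy exactly when the
length is divisible by 2^L.  Each level halves the band; after L levels the
approximation covers 0 … fs/2^(L+1).

The level count adapts to chewing speed: `select_dwd_levels` returns the
smallest L whose approximation band edge fs/2^(L+1) is at or below the
speed's chew-band upper edge.  The default band table is slow ≤ 1 Hz,
normal ≤ 2 Hz, fast ≤ 3.75 Hz; at 30 fps this gives L = 4 (band 0–0.94 Hz),
L = 3 (0–1.875 Hz) and L = 2 (0–3.75 Hz) respectively.  The fast edge is
the one genuinely open choice: fast chews reach 2.3 Hz, so the approximation
band must extend past 2.3 Hz or the chewing component itself aliases out of
the band — hence 3.75 Hz (the closest achievable dyadic edge at 30 fps)
rather than a value between 2 and 3 that the rule would turn into the same
too-narrow 1.875 Hz band.  The table is fully configurable.

Peak counting operates on the decimated final-level approximation
coefficient series (at fs/2^L).  The alternative — counting on the
full-rate reconstruction of the approximation — was evaluated and rejected
as the default: the 4-tap scaling function is jagged, and the projection it
generates carries spurious micro-maxima that inflate counts severalfold.
It remains available (`dwd_count_on="reconstruction"`) for use with longer,
smoother wavelets.

## Peak counting

Candidates are strict local maxima (greater than both immediate
neighbours); flat-topped plateaus therefore yield no peak, a documented
consequence of the strict rule.  Thresholding is two-stage: all candidates
are found first, then MPH = d × mean(candidate heights) is applied, with
d = 1/2 for LPF at every speed and for DWD-slow, 1/3 for DWD-normal, and
1/4 for DWD-fast — the divisor loosens as mandible displacement (and hence
peak height relative to noise) shrinks with speed.

Heights are measured above a running-minimum baseline (10 s window,
disableable) rather than as raw signal values, which makes the count
invariant both to the arbitrary ED baseline and to multiplying the whole
signal by any positive constant, and robust to slow drift.

Bite exclusion: taking a bite produces an excursion several times larger
than a chew cycle.  A candidate whose topographic prominence exceeds
2.5 × the median prominence of the retained peaks is labelled `bite` and
discounted; the median is recomputed after each removal round so multiple
bites cannot mask one another.  By default bites are excluded *before* the
MPH average (configurable), so a few huge excursions do not inflate the
threshold.  The 2.5 factor is a design choice — bites are described only
qualitatively in the field — and is config-exposed.

## Evaluation

AE = |actual − measured|, MAPE = mean(AE/actual)×100%, RMSE =
√(mean squared error), computed against a gold standard defined as the
*unrounded* mean of the annotators' counts per clip.  Bland-Altman limits
use bias ± 1.96 × sample SD (ddof = 1).  ICC defaults to ICC(2,1) — two-way
random effects, absolute agreement, single rater — because annotators are
treated as interchangeable; ICC(3,1) is selectable.  The implementation is
the standard two-way ANOVA decomposition and is cross-checked against an
independent statistics package in the tests.

## Synthetic data

The generator emulates the study population the method targets: one-minute
clips at 30 fps, chew rates drawn per speed from slow 0.6–0.9 Hz, normal
1–2 Hz, fast 2–2.3 Hz (spanning the 0.4–2.3 Hz range observed in real
chewing).  Each clip is laid out cycle by cycle:

* chew cycles: asymmetric raised-cosine bumps (peak at 40% of the cycle —
  jaws close faster than they open), per-cycle rate jitter ±5% and
  amplitude jitter ±15% around a 6 px amplitude;
* bites: 2 per clip, 3× chew amplitude, 1.2 s duration, followed by a 1 s
  pause;
* one 1 s swallow pause;
* noise: white Gaussian, SD = 15% of chew amplitude, plus sinusoidal
  baseline drift (1.5 px, 20 s period) standing in for slow head motion.

Ground truth (chew count, per-chew peak times, bite times, pause intervals)
is recorded exactly as planted.  Landmark tracks embed the same series
geometrically: point p sits at distance c_p·ED_t along a fixed ray from the
box corner with mean(c_p) = 1, so the rebuilt signal equals the planted one
to rounding; optional whole-head random-walk translation and per-frame
dropout are layered on top.  All randomness flows from one integer seed
through PCG64.

What this does **not** show: robustness to real detector error structure
(landmark jitter is neither white nor stationary in practice), facial
expressions, talking, pose changes, or food-texture effects.  Passing the
synthetic study demonstrates the signal-processing and counting chain is
correct under the stated signal model, not field performance.

## Problem sizes and numerics

The simulation study uses 100 clips per speed per branch (60 s × 30 fps =
1800 samples each), chosen as a population size comparable to a realistic
study while keeping the full suite in seconds.  Filter measurements use
60 s tones and DFT amplitude readout at the probe frequency; wavelet
round-trip tolerance is 1e-8 relative (observed ≈1e-15).  Degenerate
inputs are handled explicitly: empty images, out-of-bounds rectangles,
constant signals (no peaks → count 0 with a warning), constant rating
matrices (ICC undefined → error), zero gold-standard counts (MAPE
undefined → error).

## Known limitations

* No pretrained face/landmark models ship with the package; real-video use
  requires plugging a detector backend (any model exposing the two-method
  contract).  Container decoding is likewise delegated — frame directories
  and in-memory frame iterables are supported natively.
* The MPH divisors assume the speed label is known per clip, as in
  speed-instructed recordings; no automatic speed classification is
  attempted.
* Counting, not segmentation: per-chew onset/offset times and durations are
  out of scope.
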