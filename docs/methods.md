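# Methods

## Problem and approach

Gait partitioning assigns each instant of a walking trial to stance or swing
by locating two events per cycle and side: foot contact and foot off. The
laboratory gold standard reads these off the vertical ground reaction force
(GRF); wearable alternatives must find them in accelerometer signals whose
morphology varies strongly across patients. This package takes a few-shot
route: a human marks one swing interval on one channel (a *hint*), and a
quantized template of that interval is matched across recordings. No
population model is learned; all generalization comes from the template
library that the reinforcement loop grows one hint at a time.

## The matcher, step by step

**Conditioning.** Accelerometer channels are FFT low-pass smoothed and then
Kolmogorov–Zurbenko (KZ) filtered. KZ(m, k) is the k-fold iterated centred
moving average of window m; its effective kernel is near-Gaussian with
σ ≈ √(k(m²−1)/12) samples. Defaults m = 5, k = 3 at 100 Hz (σ ≈ 2.4 samples,
24 ms) suppress sample noise while leaving ~0.4 s swing transients intact.
Edges are reflect-padded: zero-padding would pull the first/last samples
toward zero and bias the first and last event estimates. The FFT smoother
zeroes rFFT bins above 15 Hz (gait content sits below ~10 Hz). Every IIR
filter in the package runs forward–backward (zero phase) because the product
being validated is *event timing*; a causal filter's group delay would shift
every event systematically.

**Quantization.** The conditioned channel is digitized into L = 16 uniform
bins spanning its own 1st–99th percentile (outliers clip into the end bins).
Because both the template and any target recording are quantized over their
*own* percentile range, templates transfer across subjects and sensors
without explicit amplitude normalization. A globally negated channel is
handled by mirroring the template codes (`polarity="auto"` tries both
orientations and keeps whichever matches more cycles at lower mean
distance) — walking-direction polarity flips in laboratory accelerometry
otherwise double the hint budget.

**Fuzzy Hamming matching.** The template symbols are slid across the signal
at stride one sample and at length scale factors {0.8, 0.9, 1.0, 1.1, 1.2}
(the template is linearly resampled per scale). The per-symbol cost is
min(|Δbin|, 2)/2: 0 for an exact bin match, ½ for adjacent bins, 1 beyond.
This graded cost is what makes the distance tolerant of amplitude noise: a
plain Hamming distance would charge full price for one-bin flips, which
sensor noise produces constantly.

**Acceptance threshold.** Windows with distance ≤ 0.45 become candidates.
This default is a calibration on conditioned synthetic accelerometry: a
*correct* match does not score 0 — adjacent-bin noise flips contribute a
floor of ≈ 0.2 and 2–3 % step-time variability misaligns transient edges for
another ≈ 0.1–0.2 — while template-vs-baseline (stance) windows score ≥ 0.6.
The measured gap across seeds is [≈0.42, ≈0.63]; 0.45 sits at its lower edge
so that marginal true matches are admitted and the non-overlap selection can
still discard them in favour of better ones. With very clean signals a
stricter threshold (0.2–0.3) works equally well; the parameter is exposed.

**Cycle selection.** Candidates are taken best-first (distance, then earlier
start); one is kept iff, dilated by a 0.10 s refractory gap, it intersects no
kept interval. Greedy selection is deterministic and in practice recovers the
maximum-count subset on gait-like candidate sets (periodic, similar
lengths); it is *not* a global optimizer and the tests assert exactly the
guarantees it has (feasibility, maximality, best-candidate retention,
distance-optimality at equal count).

**Refinement and convergence.** The template is re-estimated as the
pointwise median (robust to one bad match) of the matched instances, each
resampled to the median matched length, re-quantized on the existing bin
grid; match → select → refine repeats until the selected boundary sample
indices are identical between iterations (change < 1 sample) or 20
iterations. On all fixtures convergence takes ≤ 5 iterations. If the first
pass selects nothing, a `NoMatchError` asks for a new hint rather than
guessing.

**Events and escalation.** Each swing interval maps to foot-off (start) and
foot-contact (end). Predicted events are matched to the nearest same-type
ground-truth event within 0.5 s; absolute differences are pooled over both
event types. A dataset *escalates* when any matched error exceeds 0.060 s:
it joins the training set and contributes one new hint. In the automated
loop the hint is the escalating dataset's first ground-truth swing interval
— an explicit, seed-free stand-in for the human GUI annotation step, which
makes the loop testable end to end. The loop terminates when a full pass
over non-training datasets produces no escalation (or everything is in
training); hint count over total steps is reported as the training fraction.

## Unsupervised first pass

A diagonal-covariance Gaussian HMM (6 states by default, within the 5–10
range such segmenters produce on gait data) is fit by EM on per-sample
features (lightly smoothed value, first difference, 0.25 s windowed RMS),
with 10 seeded restarts keeping the best likelihood, tolerance 1e-4, ≤ 200
iterations. Restarts whose likelihood history decreases are discarded;
constant inputs short-circuit to a single state. Decoded state-change times
are advisory boundaries shown alongside hints; they never constrain the
matcher. The heavier accelerometer conditioning is deliberately *not* used
for features, as it smears state edges by several samples.

## Ground truth and reference computations

* **Force plate:** contact at the first sample where vertical GRF exceeds
  10 N sustained ≥ 50 ms; foot-off at the first sample below 10 N likewise.
  The 10 N rule is the laboratory convention; the 50 ms debounce makes it
  well-defined on chattering plates without moving the reported crossing
  time (always the first sample of the sustained run, at single-sample
  resolution — no sub-sample interpolation).
* **Synchronization** of dual-stream recordings maximizes the
  cross-correlation of the conditioned magnitude signals over a ±2 s lag
  window, with parabolic sub-sample refinement; this aligns all step peaks
  simultaneously and is antisymmetric by construction.
* **Spatio-temporal parameters:** step length is the 3D inter-malleolus
  distance at each foot contact; gait speed is net ASIS displacement over
  elapsed time (net, not path length, so marker jitter cannot inflate it on
  straight walkway trials); steps are counted as prominence-filtered extrema
  (≥ 0.2 × IQR, ≥ 0.3 s apart) of the left−right ankle AP-distance signal,
  each maximum or minimum being one step. Summary tables average per-step
  values within a trial, then across trials per (subject, condition); grand
  Mean/std rows use the unweighted mean and the sample (n−1) standard
  deviation with pairwise-complete handling of missing cells — the
  convention that reproduces the reference cohort tables exactly.
* **EMG:** 20–450 Hz fourth-order Butterworth band-pass (upper edge clipped
  to 0.45 × rate with a warning when the sampling rate cannot hold 450 Hz),
  full-wave rectification, 10 Hz fourth-order low-pass; cycles run contact →
  next ipsilateral contact and are linearly resampled to the conventional
  101-point %-gait-cycle grid. Amplitudes stay in input units.

## The synthetic generator

`synthetic_gait` emulates a straight-walkway trial of a slow, impaired
walker. One commanded event timeline drives every channel, so ground truth
is exact by construction: per-cycle durations are 1/cadence jittered with a
coefficient of variation (default 3 %) *shared by both sides* (the left side
runs half a cycle out of phase, so the phase offset cannot drift into the
other side's swing); event times snap to the 1 ms force-plate grid. Defaults
describe a slow impaired adult: cadence 1.0 cycles/s, stance fraction 0.60,
step length 0.45 m, speed 0.90 m/s, accelerometer noise 0.15 m/s².

Channel construction: the accelerometer carries two positive
Gaussian-windowed transients per swing (push-off amplitude 2, heel-strike 3
m/s²; widths σ = 0.11/0.08 of swing duration, i.e. ≈ 30–45 ms — narrower
transients are not resolvable at 100 Hz, where a one-sample misalignment
saturates the mismatch cost) on a noise-only stance baseline. The GRF is a
smooth double-bump loading curve that equals 10 N exactly at the commanded
contact/off instants, so threshold detection reproduces truth to one sample.
Ankle markers hold in stance and advance two step lengths per swing with a
cosine profile; the inter-malleolus distance at every contact equals the
commanded step length, and a terminal marker-only "feet together"
repositioning closes the trial so that the final landing registers as a
countable extremum (it transfers no load, hence no event and no step). EMG
is band-limited noise gated to late stance. All randomness flows through one
`numpy` generator seeded per spec.

What the generator does **not** emulate: pathological morphology variation
within a trial (drop-foot shapes, shuffling), soft-tissue and mounting
artifacts, baseline drift, marker occlusion, asymmetric left/right timing
beyond the shared jitter, or EMG crosstalk. Passing tests therefore
demonstrate that the pipeline is correct and self-consistent under its
stated signal model — not that the matcher's accuracy transfers to any
particular patient population.

## Problem sizes and numerical choices

The end-to-end checks use a 10-subject cohort (seeds `seed..seed+9`),
cadence drawn uniformly from 0.7–1.2 steps/s and stance fraction from
0.55–0.65 per subject, 10 landings per side (≈ 20 steps per subject, 200
total) — a scale at which the whole reinforcement loop runs in well under a
minute while spanning the cadence range that forces the loop to escalate
(one donor template scaled ±20 % cannot cover 0.7–1.2 steps/s, so 1–4
additional hints are typically created). Ties in cycle selection break
toward earlier starts; label permutation in HMM evaluation is resolved by
greedy confusion-matrix assignment; text I/O rounds to 9 significant digits
and round-trips within that precision; degenerate inputs (constant traces,
empty cycles, empty candidate lists) return defined results or typed errors
rather than guesses.

## Known limitations

* Matching is accelerometer-only; EMG channels are partitioned by the
  resulting events, not matched directly.
* The template is one-dimensional: multi-channel hints are matched per
  channel and merged, not fused.
* Greedy non-overlap selection can in principle drop a cycle that a global
  optimizer would keep (two good matches blocked by one better overlapping
  one).
* The automated hint in the reinforcement loop uses ground-truth swing
  intervals; with a human in the loop the hint quality — and hence the hint
  budget — will differ.
* Scale factors quantize template length to 10 % steps; between-step
  duration variability beyond ±20 % of any library template escalates by
  design rather than stretching further.
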