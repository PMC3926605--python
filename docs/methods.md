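# Methods

## Problem and data model

Drowsiness detection is treated as a binary classification of 30-s windows of
30-Hz driving-simulator signals. A `Session` is one driver-hour of four
synchronized channels: lateral lane position (m, measured from the right lane
boundary to the vehicle center, increasing leftward), steering-wheel angle
(deg, positive anticlockwise), heading error (deg, positive toward the left
boundary) and eye-closure fraction in [0, 1]. The road is a 3.75-m lane
driven by a 2.25-m-wide truck, so the physical lane-exit lines sit at
x_L = 2.625 m and x_R = 1.125 m with the lane center at 1.875 m.

Ground truth is a supervised Karolinska Sleepiness Scale: the driver
self-rates every 300 s, the rating is binarized (1–6 alert, 8–9 drowsy,
7 discarded to keep the classes separated), and three expert votes finalize
the label by majority. The expert majority is final — the binarized rating is
advisory input to the experts — because divergences between raw and
supervised ratings are an expected feature of the protocol. Each retained
interval expands into ten 30-s windows carrying its label; these
(window, label) data points are the classification units throughout.

## Indicators

All indicators are scalar functions of one 30-s window (n = 900 samples),
oriented so that larger means drowsier:

* `STD_*` — sample standard deviation with the n−1 denominator.
* `MSE_*` — identical formula with the window mean replaced by a fixed
  reference p (lane center 1.875 m for lateral position, 0° for heading
  error). The n−1 denominator and the square root are kept so the statistic
  reduces exactly to `STD` when p equals the window mean.
* `Lanex` — fraction of samples strictly outside the virtual lane (x_R, x_L);
  boundary samples count as inside (strict inequalities).
* TLC — per-sample time to line crossing from the first-derivative
  approximation: distance to the line ahead of the motion divided by lateral
  speed; zero speed saturates at `tlc_max`, positions outside the virtual
  lane give 0, everything is clamped to [0, tlc_max]. The trigonometric
  exact TLC is deliberately not implemented; the derivative approximation is
  the standard practice. `TLC_5s` counts samples 1..n−1 below the alarm level
  a (the last sample is excluded as the summation limit prescribes);
  `TLC_avg` is the negated mean so its sign matches the drowsier-is-larger
  convention.
* `RSWM` — fraction of steering-speed samples 2..n exceeding d in magnitude.
  Sample 1 is excluded because the backward-difference derivative pads it.
* `PERCLOS` — fraction of the window with eye closure above 0.8, after
  removing blink episodes. Consecutive above-threshold samples form an
  episode; episodes no longer than `blink_max` are blinks and removed.

Derivatives use a first-order backward difference scaled by the sample rate,
with the first element duplicated — simple, causal, and adequate at 30 Hz.
When a whole session is processed the derivative is computed once over the
session so interior windows see true differences at their first sample.

Defaults follow the literature: p = 1.875 m / 0°, physical lane lines,
a = 5 s, d = 125°/s, closure threshold 0.8. Two values the sources leave
open are fixed here: `tlc_max` = 30 s (one full window; only the relative
ordering of saturated samples matters) and `blink_max` = 0.5 s (a duration
criterion; typical blinks last 0.1–0.4 s). Both are exposed in the parameter
set. Closure episodes truncated by window edges are kept when their visible
duration exceeds `blink_max`, so long drowsy closures are not lost at window
boundaries. A second shipped preset carries the optimized parameter values
reported for the original study (p = 1.865 m / −1.2°, x_L = 2.27 m,
x_R = 1.42 m, a = 6.4 s, d = 13°/s).

## Objective, split and optimization

A threshold T turns an indicator into a classifier (drowsy iff value > T;
equality is alert). Scores are per subject — sensitivity TP/(TP+FN),
specificity TN/(TN+FP) — and the objective f averages (sens+spec)/2 over
subjects. A subject missing one class in the evaluated slice has an undefined
ratio and is excluded from the average with a warning (such subjects exist:
one generated driver is nearly immune to sleep deprivation).

The holdout split is 60/20/20 train/validation/test, stratified by subject
and label, allocated by largest-remainder rounding, and performed at the
interval level so sibling windows never leak across subsets (a window-level
mode exists behind a flag for sensitivity analysis). Splits are deterministic
under their seed.

The GA is real-coded: tournament selection (size 3), blend (BLX-α)
crossover, per-gene Gaussian mutation with σ = 10% of the gene range,
elitism of one, population 50, up to 100 generations with early stop after
20 generations without validation-f improvement. The decision threshold T is
a gene like any other, searched jointly with the indicator parameters; its
bounds derive from the training-value range at base parameters. The shipped
optimized preset (with its best grid-searched training threshold) is injected
into the initial population, so the search result never scores below that
reference candidate. Fitness ties break by smaller normalized L2 distance to
the search-box center, then by candidate index, making runs reproducible
bit for bit. For indicators evaluated at literature defaults ("unoptimized"),
T still must come from somewhere: it is grid-searched on the training split
over value midpoints (≤ 512 candidates), since the threshold sits inside the
optimization loop by construction.

GA fitness evaluation is vectorized with per-window sufficient statistics
(row sums/sum-squares for the RMS indicators, precomputed TLC series for the
alarm count, sorted nothing — plain boolean reductions for Lanex/RSWM), so a
full search over ~1,900 training windows takes seconds.

## Fusion network

Each selected indicator contributes its value in the window ending at the
decision time k and in the windows shifted 1, 2 and 3 s earlier (computed
from a 1-s-step indicator series), giving 4 inputs per indicator. Vectors
whose lags would precede the session start are dropped. The network is a
single sigmoid hidden layer (default 10 units) with one sigmoid output;
features are z-scored with constants learned on the training split only,
because raw units (counts vs fractions vs meters) would otherwise saturate
the sigmoids. Training minimizes binary cross-entropy (the natural pairing
with a sigmoid output) by full-batch L-BFGS with analytic gradients, keeping
the weights with the best validation loss and stopping after 25 stagnant
iterations (cap 500). Initialization is deterministic under the seed. The
output decision threshold is 0.5 (score 0.5 exactly is alert, by the strict
inequality); a validation-optimal threshold is available behind a flag. A
hidden-size sweep over 5..100 in steps of 5 reports validation ROC AUC and f
per size and recommends the argmax-AUC size.

## Synthetic cohorts

The generator reproduces the study protocol — 9 drivers × (1 NSD + 2 WSD)
one-hour sessions at 30 Hz, a label every 300 s (324 intervals, ~3%
discarded as simulator data loss, kept in the timeline under a `discarded`
label) — and signal statistics conditioned on a latent per-interval
drowsiness level in [0, 1] (drowsy truth: level > 0.5):

* NSD levels stay low; WSD levels drift upward with time on task, scaled by
  a fixed per-driver susceptibility (two drivers nearly immune, one highly
  susceptible). The defaults put the cohort drowsy share near the reported
  0.291 (measured 0.27–0.30 across seeds).
* Lateral position is a mean-reverting (Ornstein–Uhlenbeck, θ = 0.3 s⁻¹)
  process around the lane center whose stationary deviation rises from
  ≈0.20 m (alert) to ≈0.30 m (drowsy), with a per-interval variability
  factor so sibling windows correlate. Drowsy windowed SDLP exceeds alert by
  ≥ 20% on every tested seed.
* Heading error is a smoothed, scaled lateral-velocity proxy plus noise,
  clipped to the plausible −10°…6° range — correlated with the lateral
  channel as alert steering behavior implies.
* Steering is a slow two-sinusoid curvature-following component (range well
  inside the reported −120°…90°) plus micro-corrections whose amplitude
  shrinks with drowsiness and sporadic 0.3–0.8-s corrective turns whose rate
  grows with it — so the rapid-movement fraction at the optimized 13°/s
  threshold separates the classes while the 125°/s default sees almost
  nothing, as reported.
* Eye closure is a blink process (0.1–0.35-s full closures, excluded by the
  PERCLOS blink rule) plus slow closure episodes with a per-window
  closed-time budget: ≤ 0.095·30 s when alert (windowed PERCLOS stays within
  the reported alert 0–0.11 range) and 0.055–0.45 of the window when drowsy
  (the reported 0.05–0.50 drowsy range). About 20% of drowsy intervals are
  "weak expressors" whose eye signal overlaps the alert range — without this
  the eye channel is unrealistically perfect and fusion has nothing to add.
* KSS ratings map the latent level to the 9-point scale with the ambiguous
  rating 7 at level 0.5 (so the discard rule removes genuinely boundary
  intervals), plus observation noise; each expert vote flips the truth
  independently with probability 0.05.

What the generator does **not** emulate: vehicle dynamics (tires, friction,
speed variation), real road curvature statistics, eye-tracker measurement
artifacts, inter-channel couplings beyond the lateral→heading link, and
circadian structure. Passing tests therefore demonstrate that the pipeline
recovers planted statistical structure of the reported kind — not field
performance on real drivers.

A separate benchmark generator plants virtual lane lines: alert windows are
hard-clipped 0.04 m inside the lines and drowsy windows make brief 0.02–0.08-m
excursions beyond one line, alternating sides window by window. By
construction the objective is maximal only when both searched lines lie
within ≈ ±0.1 m of the planted ones, making GA parameter recovery testable.

## Numerical choices and degenerate inputs

Windows must contain ≥ 2 samples (≥ 1 where a mean suffices); a series
shorter than one window yields an empty window list rather than an error;
non-integer window sample counts are parameter errors. Indicator evaluators
use float64 accumulators; the algebraic RMS expansion used inside the GA
loop agrees with the two-pass kernel to ~1e-12 relative and the kernels are
the ground truth the tests compare against. Session CSV round-trips are
exact to 1e-9 (10 significant digits); HDF5 round-trips are bit-exact. The
permutation control reports the mean over three label permutations to keep
the chance estimate stable.

## Scale of the shipped experiments

The default end-to-end run uses the full protocol scale (27 driver-hours,
~2,900–3,000 data points after discards) and completes in about half a
minute; unit tests use smaller cohorts (3–4 drivers) where full scale adds
nothing to the property under test.

## Known limitations

* The absolute classification scores on synthetic cohorts are properties of
  the generator's calibration, not predictions of real-world accuracy; only
  the qualitative structure (eye closure best single indicator, optimization
  not hurting, fusion on top, chance at 0.5) is asserted.
* The GA optimizes one indicator at a time; no joint optimization across
  indicators or multi-objective fronts.
* Training the fuser uses L-BFGS rather than scaled conjugate gradient; both
  are full-batch quasi-Newton-style minimizers of the same loss, and the
  contract (deterministic under seed, early stop on validation loss) is what
  the rest of the pipeline relies on.
* Per-driver personalized models are intentionally out of scope (too few
  data points per driver; overfitting risk), as are recurrent architectures
  and real-time streaming.
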