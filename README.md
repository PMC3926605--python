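# drowsefuse

Non-intrusive driver-drowsiness detection from fused, optimized indicators.

Drowsy driving multiplies crash risk severalfold, and the practical way to
detect it in real time is to watch what sensors already in (or on) the car can
see: the driver's eyes and the vehicle's trajectory. `drowsefuse` implements a
complete detection pipeline of that kind for researchers working with driving
simulator (or simulator-like) recordings:

* **Windowed indicators** over 30-s spans of 30-Hz signals — PERCLOS
  (percentage of eye closure beyond 80%, excluding blinks), SDLP-style
  standard deviations (`STD_lp`, `STD_sw`, `STD_he`), RMS deviations from a
  reference (`MSE_lp`, `MSE_he`), the lane-exit fraction (`Lanex`),
  time-to-line-crossing statistics (`TLC_5s`, `TLC_avg`) and the rapid
  steering-wheel movement fraction (`RSWM`).
* **Supervised-KSS ground truth** — Karolinska Sleepiness Scale self-ratings
  every 5 min, binarized (1–6 alert, 8–9 drowsy, 7 discarded) and finalized
  by a majority vote of three expert assessments.
* **Stochastic optimization** — a real-coded genetic algorithm tunes each
  indicator's free parameters (virtual lane-line positions, alarm levels,
  speed thresholds, RMS references) jointly with its decision threshold T.
* **Neural-network fusion** — a feed-forward network with one sigmoid hidden
  layer (10 units) and a sigmoid output combines four lagged values
  I(k−t), t = 0…3 s, of each selected indicator into one alert/drowsy call.

Because the original simulator recordings are not publicly available, the
package ships a first-class synthetic cohort generator that reproduces the
study protocol (9 drivers × 3 one-hour sessions at 30 Hz, with/without sleep
deprivation in 2:1 hour proportion, labels every 300 s, ≈29% drowsy) and the
reported signal statistics, so the whole pipeline runs end to end with no
downloads.

## The objective

A single indicator becomes a classifier via a threshold (Drowsy iff
Indicator > T). Performance is scored per subject *i* with drowsy as the
positive class,

    Γᵢˢᵉⁿˢ = TP / (TP + FN),    Γᵢˢᵖᵉᶜ = TN / (TN + FP),

and summarized over the N subjects as

    f = (1/N) Σᵢ (Γᵢˢᵉⁿˢ + Γᵢˢᵖᵉᶜ) / 2  ∈ [0, 1],

with 0.5 the chance level. Both the GA and the fusion reports maximize and
report this f, using a 60/20/20 train/validation/test holdout split at the
300-s interval level (so the ten 30-s sibling windows of one label never
straddle subsets).

## Worked example

```bash
drowsefuse run --seed 0 --out results/
```

runs the full experiment on the default synthetic cohort — generate 27 h of
sessions, score all ten indicators at literature-default parameters,
GA-optimize the five parametrized ones, train the FFNN fuser on nine
indicator combinations, and run a label-permutation control — and prints:

```
best single indicator: PERCLOS (f = 0.887)
best fused combination: PERCLOS + TLC_opti (f = 0.925)
chance control f = 0.466
reports written to results/
```

Reading those numbers: the eye-closure indicator is the strongest single
predictor (f = 0.887 on held-out test intervals), fusing it with an optimized
driving indicator adds roughly four points (0.925), and permuting the labels
collapses performance to chance (≈ 0.5), confirming the signal is real. The
CSV reports in `results/` give the full three-column
(specificity, sensitivity, f) tables per indicator and combination, for all
users and for the spotlight subject with the most drowsiness, and every row
satisfies f = (sens + spec)/2 exactly.

The same pieces are available as a library:

```python
from drowsefuse import (CohortConfig, generate_cohort, holdout_split,
                        SplitSpec, ga_optimize, GAConfig)

cohort = generate_cohort(CohortConfig(), seed=0)
splits = holdout_split(cohort.dataset, SplitSpec(seed=0))
params, val_f = ga_optimize("Lanex", splits["train"], splits["validation"],
                            GAConfig(seed=0))
print(params.x_L, params.x_R, params.threshold, val_f)
```

## Layout

| module | contents |
| --- | --- |
| `drowsefuse.signal_core` | `Session` data model, windowing, derivatives, CSV/HDF5 I/O |
| `drowsefuse.indicators` | the ten indicator kernels, per-session series, parameter presets |
| `drowsefuse.ground_truth` | KSS binarization, expert voting, window-level label expansion |
| `drowsefuse.optimize` | threshold classifier, objective f, holdout split, real-coded GA |
| `drowsefuse.fusion` | lagged features, FFNN training/prediction, hidden-size sweep |
| `drowsefuse.synthetic` | cohort generator and parameter-recovery benchmark data |
| `drowsefuse.pipeline` | end-to-end experiment, report bundle, published-arithmetic checks |

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
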