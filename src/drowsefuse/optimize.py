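"""Threshold classification, the sensitivity/specificity objective, holdout
splitting and GA search over indicator parameters.

A single indicator becomes a binary classifier through a scalar threshold T
(drowsy iff indicator > T).  Performance is the per-subject balanced score

    f = (1/N) * sum_i (sens_i + spec_i) / 2

averaged over subjects with both classes present; 0.5 is chance level, 1 is
perfect.  The genetic algorithm searches the indicator's tunable constants
jointly with T to maximize f on the training split, reporting f on the
validation split.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .ground_truth import WindowDataset
from .indicators import OPTIMIZABLE, IndicatorParams, compute_window_value, tlc_series

__all__ = [
    "ConfusionMatrix",
    "SubjectScore",
    "SplitSpec",
    "GAConfig",
    "classify_threshold",
    "confusion",
    "sens_spec",
    "objective_f",
    "largest_remainder_allocation",
    "holdout_split",
    "IndicatorEvaluator",
    "grid_search_threshold",
    "score_dataset",
    "ga_optimize",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with drowsy as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class SubjectScore:
    """Per-subject sensitivity and specificity; NaN marks an undefined ratio."""

    subject_id: str
    sensitivity: float
    specificity: float

    @property
    def defined(self) -> bool:
        return not (np.isnan(self.sensitivity) or np.isnan(self.specificity))

    @property
    def f(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0


def classify_threshold(values: np.ndarray, threshold: float) -> np.ndarray:
    """Drowsy iff indicator value strictly exceeds the threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(values) > threshold


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionMatrix:
    """Count TP/FP/TN/FN for boolean predictions against boolean truth."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def sens_spec(cm: ConfusionMatrix, subject_id: str = "") -> SubjectScore:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP).

    A subject with an empty class gets NaN for the corresponding ratio and a
    warning; such subjects are excluded from the objective average.
    """
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    sens = cm.tp / pos if pos else float("nan")
    spec = cm.tn / neg if neg else float("nan")
    if pos == 0 or neg == 0:
        warnings.warn(
            f"subject {subject_id or '<?>'} is missing one class "
            f"(pos={pos}, neg={neg}); score undefined",
            stacklevel=2,
        )
    return SubjectScore(subject_id, sens, spec)


def objective_f(scores: Sequence[SubjectScore]) -> float:
    """Mean over subjects of (sensitivity + specificity)/2.

    Subjects with an undefined ratio are excluded from the average.
    """
    if len(scores) == 0:
        raise ValueError("objective_f requires at least one subject score")
    defined = [s for s in scores if s.defined]
    if not defined:
        raise ValueError("no subject has both classes present; objective undefined")
    return float(np.mean([s.f for s in defined]))


# ---------------------------------------------------------------------------
# holdout split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions, split at the interval level by default
    so the ten sibling windows of one 300-s interval never straddle subsets."""

    train: float = 0.60
    validation: float = 0.20
    test: float = 0.20
    seed: int = 0
    unit: str = "interval"  # or "window"

    def __post_init__(self) -> None:
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.unit not in ("interval", "window"):
            raise ValueError("split unit must be 'interval' or 'window'")

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.train, self.validation, self.test)


def largest_remainder_allocation(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer sizes summing to ``n`` that best honor ``fractions``
    (largest-remainder rounding; ties go to the earlier fraction)."""
    quotas = np.asarray(fractions, dtype=float) * n
    floors = np.floor(quotas).astype(int)
    short = n - int(floors.sum())
    order = np.argsort(-(quotas - floors), kind="stable")
    for k in order[:short]:
        floors[k] += 1
    return floors.tolist()


def holdout_split(
    dataset: WindowDataset,
    spec: SplitSpec = SplitSpec(),
) -> dict[str, WindowDataset]:
    """Deterministic stratified holdout split.

    Units (intervals by default) are grouped by (subject, label), each group
    shuffled with the split seed and allocated by largest remainder, so both
    classes of every subject appear in every subset whenever counts allow.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.unit == "interval":
        unit_ids = dataset.interval_ids
    else:
        unit_ids = np.arange(len(dataset))
    uniq, first_idx = np.unique(unit_ids, return_index=True)
    unit_subject = dataset.subject_ids[first_idx]
    unit_label = dataset.labels[first_idx]
    n_units = len(uniq)
    if n_units < 5:
        warnings.warn(f"only {n_units} split units; best-effort split", stacklevel=2)

    assignment = np.empty(n_units, dtype=int)  # 0=train, 1=val, 2=test
    for subj in np.unique(unit_subject):
        for lab in (False, True):
            grp = np.flatnonzero((unit_subject == subj) & (unit_label == lab))
            if len(grp) == 0:
                continue
            grp = rng.permutation(grp)
            sizes = largest_remainder_allocation(len(grp), spec.fractions)
            assignment[grp[: sizes[0]]] = 0
            assignment[grp[sizes[0] : sizes[0] + sizes[1]]] = 1
            assignment[grp[sizes[0] + sizes[1] :]] = 2

    unit_to_subset = dict(zip(uniq.tolist(), assignment.tolist()))
    point_subset = np.array([unit_to_subset[u] for u in unit_ids.tolist()])
    names = ("train", "validation", "test")
    return {name: dataset.subset(np.flatnonzero(point_subset == i)) for i, name in enumerate(names)}


# ---------------------------------------------------------------------------
# fast indicator evaluation over a WindowDataset
# ---------------------------------------------------------------------------


def _row_derivative(w: np.ndarray, rate: float) -> np.ndarray:
    out = np.empty_like(w)
    out[:, 1:] = np.diff(w, axis=1) * rate
    out[:, 0] = out[:, 1]
    return out


class IndicatorEvaluator:
    """Vectorized evaluation of one indicator over every window of a dataset.

    Per-window sufficient statistics are precomputed once so that repeated
    evaluation at different parameter values (the GA inner loop) is cheap.
    """

    def __init__(self, name: str, dataset: WindowDataset, base: IndicatorParams | None = None):
        self.name = name
        self.base = base if base is not None else IndicatorParams.defaults(name)
        if self.base.name != name:
            raise ValueError("params/indicator name mismatch")
        self.truth = dataset.labels
        self.subject_ids = dataset.subject_ids
        subjects, self.subj_idx = np.unique(dataset.subject_ids, return_inverse=True)
        self.subjects = subjects
        rate = dataset.sample_rate
        from .indicators import INDICATOR_CHANNEL

        w = dataset.channels[INDICATOR_CHANNEL[name]].astype(np.float64)
        n = w.shape[1]
        self._n = n
        if name in ("STD_lp", "STD_sw", "STD_he"):
            self._fixed = np.sqrt(np.sum((w - w.mean(axis=1, keepdims=True)) ** 2, axis=1) / (n - 1))
        elif name in ("MSE_lp", "MSE_he"):
            self._s1 = w.sum(axis=1)
            self._s2 = np.sum(w * w, axis=1)
        elif name == "Lanex":
            self._w = w.astype(np.float32)
        elif name in ("TLC_5s", "TLC_avg"):
            speed = _row_derivative(w, rate)
            tlc = np.empty_like(w)
            for i in range(len(w)):
                tlc[i] = tlc_series(w[i], speed[i], self.base.x_L, self.base.x_R, self.base.tlc_max)
            if name == "TLC_avg":
                self._fixed = -tlc.mean(axis=1)
            else:
                self._tlc_head = tlc[:, :-1].astype(np.float32)
        elif name == "RSWM":
            self._abs_speed = np.abs(_row_derivative(w, rate)[:, 1:]).astype(np.float32)
        elif name == "PERCLOS":
            from .indicators import perclos

            self._fixed = np.array(
                [perclos(row, self.base.closure_threshold, self.base.blink_max, rate) for row in
                 dataset.channels["eye_closure"].astype(np.float64)]
            )
        else:  # pragma: no cover
            raise ValueError(f"unknown indicator {name!r}")

    def values(self, **params: float) -> np.ndarray:
        """Indicator value per window at the given free-parameter values."""
        name = self.name
        if name in ("STD_lp", "STD_sw", "STD_he", "TLC_avg", "PERCLOS"):
            return self._fixed
        if name in ("MSE_lp", "MSE_he"):
            p = params.get("p", self.base.p)
            n = self._n
            ss = self._s2 - 2.0 * p * self._s1 + n * p * p
            return np.sqrt(np.maximum(ss, 0.0) / (n - 1))
        if name == "Lanex":
            x_L = params.get("x_L", self.base.x_L)
            x_R = params.get("x_R", self.base.x_R)
            return ((self._w > x_L) | (self._w < x_R)).mean(axis=1)
        if name == "TLC_5s":
            a = params.get("a", self.base.a)
            return (self._tlc_head < a).sum(axis=1).astype(float)
        if name == "RSWM":
            d = params.get("d", self.base.d)
            return (self._abs_speed > d).mean(axis=1)
        raise ValueError(name)  # pragma: no cover

    def f_at_threshold(self, values: np.ndarray, threshold: float) -> float:
        """Objective f of the threshold classifier over this dataset's subjects."""
        return _fast_f(values > threshold, self.truth, self.subj_idx, len(self.subjects))


def _fast_f(preds: np.ndarray, truth: np.ndarray, subj_idx: np.ndarray, n_subj: int) -> float:
    tp = np.bincount(subj_idx[preds & truth], minlength=n_subj)
    fn = np.bincount(subj_idx[~preds & truth], minlength=n_subj)
    tn = np.bincount(subj_idx[~preds & ~truth], minlength=n_subj)
    fp = np.bincount(subj_idx[preds & ~truth], minlength=n_subj)
    pos = tp + fn
    neg = tn + fp
    ok = (pos > 0) & (neg > 0)
    if not ok.any():
        return float("nan")
    sens = tp[ok] / pos[ok]
    spec = tn[ok] / neg[ok]
    return float(np.mean((sens + spec) / 2.0))


def score_dataset(
    values: np.ndarray,
    threshold: float,
    dataset: WindowDataset,
) -> tuple[list[SubjectScore], float]:
    """Per-subject scores and objective f of a threshold classifier."""
    preds = classify_threshold(values, threshold)
    scores = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for subj in np.unique(dataset.subject_ids):
            m = dataset.subject_ids == subj
            scores.append(sens_spec(confusion(preds[m], dataset.labels[m]), subj))
    return scores, objective_f(scores)


def grid_search_threshold(
    values: np.ndarray,
    dataset: WindowDataset,
    max_candidates: int = 512,
) -> tuple[float, float]:
    """Best threshold T on this (training) dataset, maximizing objective f.

    Candidates are midpoints between consecutive distinct values plus a
    point below the minimum (everything drowsy); thinned to at most
    ``max_candidates``.  Returns (T, f); ties go to the smallest T.
    """
    uniq = np.unique(values)
    if len(uniq) == 1:
        cands = np.array([uniq[0] - 1.0])
    else:
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        cands = np.concatenate([[uniq[0] - (uniq[1] - uniq[0])], mids])
    if len(cands) > max_candidates:
        idx = np.unique(np.linspace(0, len(cands) - 1, max_candidates).astype(int))
        cands = cands[idx]
    subjects, subj_idx = np.unique(dataset.subject_ids, return_inverse=True)
    best_t, best_f = cands[0], -np.inf
    for t in cands:
        f = _fast_f(values > t, dataset.labels, subj_idx, len(subjects))
        if np.isnan(f):
            continue
        if f > best_f + 1e-15:
            best_t, best_f = float(t), f
    return best_t, best_f


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------


@dataclass
class GAConfig:
    """Real-coded GA: tournament selection (size 3), blend crossover,
    Gaussian mutation, elitism, early stop on stagnant validation f."""

    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 0.25
    blend_alpha: float = 0.5
    mutation_sigma: float = 0.1  # fraction of each gene's range
    tournament_size: int = 3
    patience: int = 20
    seed: int = 0
    bounds: dict = field(default_factory=dict)  # per-gene overrides

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("GA rates must lie in [0, 1]")


def ga_optimize(
    name: str,
    train: WindowDataset,
    validation: WindowDataset,
    config: GAConfig = GAConfig(),
    base: IndicatorParams | None = None,
) -> tuple[IndicatorParams, float]:
    """Maximize objective f on the training split over the indicator's free
    parameters and its decision threshold T (searched jointly).

    The optimized-parameter preset shipped with the package is injected into
    the initial population so the returned candidate never scores below it.
    Deterministic under ``config.seed``.  Returns the best parameters (with
    ``threshold`` set) and their objective f on the validation split.
    """
    if not (train.labels.any() and (~train.labels).any()):
        raise ValueError("training data must contain both classes")
    base = base if base is not None else IndicatorParams.defaults(name)
    gene_names = list(OPTIMIZABLE.get(name, ()))
    ev_train = IndicatorEvaluator(name, train, base)
    ev_val = IndicatorEvaluator(name, validation, base)

    # threshold bounds derived from the training value range at base params
    v0 = ev_train.values()
    lo, hi = float(v0.min()), float(v0.max())
    span = hi - lo if hi > lo else 1.0
    bounds: dict[str, tuple[float, float]] = {}
    for g in gene_names:
        if g in config.bounds:
            bounds[g] = tuple(config.bounds[g])
        elif g in base.bounds:
            bounds[g] = tuple(base.bounds[g])
        else:
            raise ValueError(f"no search bounds for parameter {g!r}")
    bounds["threshold"] = tuple(config.bounds.get("threshold", (lo - 0.05 * span, hi + 0.05 * span)))
    genes = gene_names + ["threshold"]
    lo_b = np.array([bounds[g][0] for g in genes])
    hi_b = np.array([bounds[g][1] for g in genes])
    if np.any(hi_b <= lo_b):
        raise ValueError("empty parameter bounds")
    center = (lo_b + hi_b) / 2.0
    scale = hi_b - lo_b

    def clip(x: np.ndarray) -> np.ndarray:
        x = np.clip(x, lo_b, hi_b)
        # keep the virtual lane ordered when both lines are searched
        if "x_L" in gene_names and "x_R" in gene_names:
            i, j = genes.index("x_L"), genes.index("x_R")
            if x[i] <= x[j]:
                xi, xj = max(x[i], x[j]), min(x[i], x[j])
                x[i] = min(max(xi, xj + 1e-6), hi_b[i])
                x[j] = max(min(xj, x[i] - 1e-6), lo_b[j])
        return x

    def fitness(x: np.ndarray) -> float:
        params = dict(zip(gene_names, x[:-1]))
        f = ev_train.f_at_threshold(ev_train.values(**params), x[-1])
        return -np.inf if np.isnan(f) else f

    rng = np.random.default_rng(config.seed)
    pop = rng.uniform(lo_b, hi_b, size=(config.population_size, len(genes)))
    # inject the shipped optimized preset with its best training threshold
    preset = IndicatorParams.table2_optimized(name)
    preset_genes = [getattr(preset, g) for g in gene_names]
    pv = ev_train.values(**dict(zip(gene_names, preset_genes)))
    preset_t, _ = grid_search_threshold(pv, train)
    pop[0] = clip(np.array(preset_genes + [preset_t]))
    for i in range(len(pop)):
        pop[i] = clip(pop[i])

    fits = np.array([fitness(x) for x in pop])

    def better(i: int, j: int) -> bool:
        """Is individual i strictly preferable to j (fitness, then centrality)?"""
        if fits[i] != fits[j]:
            return fits[i] > fits[j]
        di = np.linalg.norm((pop[i] - center) / scale)
        dj = np.linalg.norm((pop[j] - center) / scale)
        if di != dj:
            return di < dj
        return i < j

    best_val_f = -np.inf
    stagnant = 0
    for _gen in range(config.generations):
        # elitism: carry the best individual over unchanged
        best_i = 0
        for i in range(1, len(pop)):
            if better(i, best_i):
                best_i = i
        new_pop = [pop[best_i].copy()]
        while len(new_pop) < config.population_size:
            idx = rng.integers(0, len(pop), size=config.tournament_size)
            p1 = idx[np.argmax(fits[idx])]
            idx = rng.integers(0, len(pop), size=config.tournament_size)
            p2 = idx[np.argmax(fits[idx])]
            a, b = pop[p1].copy(), pop[p2].copy()
            if rng.random() < config.crossover_rate:
                gamma = (1 + 2 * config.blend_alpha) * rng.random(len(genes)) - config.blend_alpha
                child = gamma * a + (1 - gamma) * b
            else:
                child = a
            mut = rng.random(len(genes)) < config.mutation_rate
            child = child + mut * rng.normal(0.0, config.mutation_sigma * scale)
            new_pop.append(clip(child))
        pop = np.array(new_pop)
        fits = np.array([fitness(x) for x in pop])

        best_i = 0
        for i in range(1, len(pop)):
            if better(i, best_i):
                best_i = i
        params = dict(zip(gene_names, pop[best_i][:-1]))
        val_f = ev_val.f_at_threshold(ev_val.values(**params), pop[best_i][-1])
        if val_f > best_val_f + 1e-12:
            best_val_f = val_f
            stagnant = 0
        else:
            stagnant += 1
        if stagnant >= config.patience:
            break

    best_i = 0
    for i in range(1, len(pop)):
        if better(i, best_i):
            best_i = i
    best = pop[best_i]
    result = base.replace(
        **{g: float(v) for g, v in zip(gene_names, best[:-1])},
        threshold=float(best[-1]),
    )
    result.bounds = {g: tuple(bounds[g]) for g in gene_names}
    params = dict(zip(gene_names, best[:-1]))
    val_f = ev_val.f_at_threshold(ev_val.values(**params), best[-1])
    return result, float(val_f)
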