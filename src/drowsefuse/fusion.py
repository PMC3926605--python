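"""Lagged-indicator features and the feed-forward neural-network fuser.

Each selected indicator contributes four inputs to the network: its value in
the 30-s window ending at the decision time k and in the three windows shifted
1 s earlier (I(k−t), t = 0..3 s), adding short-term memory to the decision.
The network has one sigmoid hidden layer (10 units by default) and a single
sigmoid output in [0, 1]; a score above 0.5 is called drowsy.

Training minimizes binary cross-entropy with a full-batch quasi-Newton
optimizer (L-BFGS) and early-stops on validation loss.  Features are z-scored
with constants learned on the training split only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .indicators import IndicatorSeries
from .optimize import SubjectScore, confusion, objective_f, sens_spec

__all__ = [
    "LaggedFeatureVector",
    "FusionModel",
    "lagged_features",
    "stack_features",
    "train_ffnn",
    "predict",
    "hidden_size_sweep",
    "evaluate_combination",
]

DEFAULT_LAGS = (0.0, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class LaggedFeatureVector:
    """Features for one decision point: 4 lagged values per indicator."""

    t_end: float
    values: np.ndarray  # (4 * n_indicators,)
    label: bool | None = None  # drowsy = True


def lagged_features(
    series_list: Sequence[IndicatorSeries],
    decision_times: np.ndarray,
    labels: np.ndarray | None = None,
    lags: Sequence[float] = DEFAULT_LAGS,
) -> list[LaggedFeatureVector]:
    """Assemble lagged feature vectors from 1-s-step indicator series.

    ``decision_times`` are window end times (s) of the labeled data points.
    A vector is dropped when any lag would need a window starting before the
    session start.  Feature order is indicator-major, lag-minor.
    """
    if len(series_list) == 0:
        raise ValueError("at least one indicator series is required")
    steps = []
    for s in series_list:
        if len(s) < 2:
            raise ValueError("indicator series too short for lagged features")
        step = float(np.median(np.diff(s.t_end)))
        if abs(step - 1.0) > 1e-9:
            raise ValueError(f"lagged features require series at 1-s step, got {step} s")
        steps.append(step)
    out: list[LaggedFeatureVector] = []
    for j, k in enumerate(np.asarray(decision_times, dtype=float)):
        feats = np.empty(len(series_list) * len(lags))
        ok = True
        for si, s in enumerate(series_list):
            for li, t in enumerate(lags):
                idx = int(round((k - t - s.t_end[0]) / 1.0))
                if idx < 0 or idx >= len(s):
                    ok = False
                    break
                feats[si * len(lags) + li] = s.values[idx]
            if not ok:
                break
        if ok:
            out.append(LaggedFeatureVector(float(k), feats, None if labels is None else bool(labels[j])))
    return out


def stack_features(vectors: Sequence[LaggedFeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    """Stack vectors into (X, y) arrays; y is boolean (drowsy = True)."""
    X = np.array([v.values for v in vectors])
    y = np.array([bool(v.label) for v in vectors])
    return X, y


@dataclass
class FusionModel:
    """Single-hidden-layer sigmoid network with z-score input normalization."""

    w_hidden: np.ndarray  # (hidden, dim)
    b_hidden: np.ndarray  # (hidden,)
    w_out: np.ndarray  # (hidden,)
    b_out: float
    feat_mean: np.ndarray  # (dim,)
    feat_std: np.ndarray  # (dim,)
    decision_threshold: float = 0.5

    @property
    def input_dim(self) -> int:
        return self.w_hidden.shape[1]

    @property
    def hidden_size(self) -> int:
        return self.w_hidden.shape[0]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid output scores in (0, 1); rows of X are raw feature vectors."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ValueError(f"feature dimension {X.shape[1]} != model input dimension {self.input_dim}")
        Z = (X - self.feat_mean) / self.feat_std
        H = expit(Z @ self.w_hidden.T + self.b_hidden)
        return expit(H @ self.w_out + self.b_out)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out,
            "feat_mean": self.feat_mean.tolist(),
            "feat_std": self.feat_std.tolist(),
            "decision_threshold": self.decision_threshold,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FusionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            w_hidden=np.array(d["w_hidden"]),
            b_hidden=np.array(d["b_hidden"]),
            w_out=np.array(d["w_out"]),
            b_out=float(d["b_out"]),
            feat_mean=np.array(d["feat_mean"]),
            feat_std=np.array(d["feat_std"]),
            decision_threshold=float(d["decision_threshold"]),
        )


def _unpack(theta: np.ndarray, dim: int, hidden: int):
    i = 0
    w1 = theta[i : i + hidden * dim].reshape(hidden, dim); i += hidden * dim
    b1 = theta[i : i + hidden]; i += hidden
    w2 = theta[i : i + hidden]; i += hidden
    b2 = theta[i]
    return w1, b1, w2, b2


def _loss_grad(theta: np.ndarray, Z: np.ndarray, y: np.ndarray, hidden: int, l2: float):
    """Binary cross-entropy and its analytic gradient for the 1-hidden-layer net."""
    n, dim = Z.shape
    w1, b1, w2, b2 = _unpack(theta, dim, hidden)
    H = expit(Z @ w1.T + b1)  # (n, hidden)
    logits = H @ w2 + b2
    # stable BCE on logits: softplus(logits) - y*logits
    loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits)) + 0.5 * l2 * float(theta @ theta)
    p = expit(logits)
    delta_out = (p - y) / n  # (n,)
    g_w2 = H.T @ delta_out
    g_b2 = float(delta_out.sum())
    delta_h = np.outer(delta_out, w2) * H * (1.0 - H)  # (n, hidden)
    g_w1 = delta_h.T @ Z
    g_b1 = delta_h.sum(axis=0)
    grad = np.concatenate([g_w1.ravel(), g_b1, g_w2, [g_b2]]) + l2 * theta
    return loss, grad


def train_ffnn(
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    hidden: int = 10,
    seed: int = 0,
    max_epochs: int = 500,
    patience: int = 25,
    l2: float = 1e-6,
) -> FusionModel:
    """Train the fusion network; deterministic under ``seed``.

    When a validation set is given, training keeps the weights with the best
    validation cross-entropy and stops after ``patience`` iterations without
    improvement.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not (y.any() and (y == 0).any()):
        raise ValueError("training data must contain both classes")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)
    Z = (X - mean) / std
    n, dim = Z.shape
    rng = np.random.default_rng(seed)
    theta0 = np.concatenate([
        rng.normal(0.0, 1.0 / np.sqrt(dim), size=hidden * dim),
        np.zeros(hidden),
        rng.normal(0.0, 1.0 / np.sqrt(hidden), size=hidden),
        [0.0],
    ])

    has_val = X_val is not None and len(X_val) > 0
    if has_val:
        Zv = (np.asarray(X_val, dtype=float) - mean) / std
        yv = np.asarray(y_val, dtype=float).ravel()

    state = {"best_theta": theta0.copy(), "best_val": np.inf, "stale": 0}

    def callback(theta):
        if not has_val:
            return
        val_loss, _ = _loss_grad(theta, Zv, yv, hidden, 0.0)
        if val_loss < state["best_val"] - 1e-12:
            state["best_val"] = val_loss
            state["best_theta"] = theta.copy()
            state["stale"] = 0
        else:
            state["stale"] += 1
        if state["stale"] >= patience:
            raise StopIteration

    try:
        res = minimize(
            _loss_grad,
            theta0,
            args=(Z, y, hidden, l2),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_epochs},
            callback=callback,
        )
        final_theta = res.x
    except StopIteration:
        final_theta = state["best_theta"]

    if has_val:
        final_loss, _ = _loss_grad(final_theta, Zv, yv, hidden, 0.0)
        theta = state["best_theta"] if state["best_val"] <= final_loss else final_theta
    else:
        theta = final_theta
    w1, b1, w2, b2 = _unpack(theta, dim, hidden)
    return FusionModel(w1.copy(), b1.copy(), w2.copy(), float(b2), mean, std)


def predict(model: FusionModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores in (0, 1) and binary classes (drowsy iff score > threshold)."""
    scores = model.forward(X)
    return scores, scores > model.decision_threshold


def hidden_size_sweep(
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    sizes: Sequence[int] = tuple(range(5, 101, 5)),
    seed: int = 0,
    **train_kwargs,
) -> tuple[list[dict], int]:
    """Train at each hidden size and report validation ROC AUC and f at the
    0.5 decision threshold.  Returns (rows, recommended size = argmax AUC)."""
    from sklearn.metrics import roc_auc_score

    rows = []
    for size in sizes:
        model = train_ffnn(X, y, X_val, y_val, hidden=size, seed=seed, **train_kwargs)
        scores = model.forward(X_val)
        auc = float(roc_auc_score(y_val, scores))
        cm = confusion(scores > 0.5, y_val.astype(bool))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc = sens_spec(cm)
        rows.append({"hidden": int(size), "val_auc": auc, "val_f": sc.f})
    best = int(rows[int(np.argmax([r["val_auc"] for r in rows]))]["hidden"])
    return rows, best


def _split_scores(
    preds: np.ndarray, truth: np.ndarray, subjects: np.ndarray
) -> tuple[list[SubjectScore], float]:
    scores = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for subj in np.unique(subjects):
            m = subjects == subj
            scores.append(sens_spec(confusion(preds[m], truth[m]), subj))
    return scores, objective_f(scores)


def evaluate_combination(
    indicator_names: Sequence[str],
    feature_splits: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    hidden: int = 10,
    seed: int = 0,
    **train_kwargs,
) -> dict:
    """Train on the train split, early-stop on validation, report on test.

    ``feature_splits`` maps 'train'/'validation'/'test' to (X, y, subject_ids).
    The report gives overall per-subject-averaged sensitivity, specificity and
    f plus per-subject rows, mirroring the usual three-column layout.
    """
    if len(indicator_names) == 0:
        raise ValueError("empty indicator combination")
    Xtr, ytr, _ = feature_splits["train"]
    Xv, yv, _ = feature_splits["validation"]
    Xte, yte, subj_te = feature_splits["test"]
    model = train_ffnn(Xtr, ytr, Xv, yv, hidden=hidden, seed=seed, **train_kwargs)
    _, preds = predict(model, Xte)
    scores, f = _split_scores(preds, yte.astype(bool), subj_te)
    defined = [s for s in scores if s.defined]
    report = {
        "indicators": list(indicator_names),
        "overall": {
            "sensitivity": float(np.mean([s.sensitivity for s in defined])),
            "specificity": float(np.mean([s.specificity for s in defined])),
            "f": f,
        },
        "per_subject": {
            s.subject_id: {"sensitivity": s.sensitivity, "specificity": s.specificity,
                           "f": s.f if s.defined else float("nan")}
            for s in scores
        },
    }
    return report, model
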