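"""Outcome prediction: selected-edge features -> epsilon-SVR -> LOOCV estimate.

The motor outcome is the UPDRS-III improvement rate, defined as
(pre-op med-off score - post-op med-on score) / pre-op med-off score:
the proportional reduction of the off-medication baseline achieved under
stimulation plus medication.  Features are the Fisher-z connectivity
values of the group-difference edges.  Features and label are min-max
scaled to [-1, 1], an RBF-kernel epsilon-SVR is trained with grid-searched
(C, gamma, epsilon), and performance is the leave-one-out cross-validated
Pearson r and MSE between predicted and actual improvement.

Two scaling modes:

* ``"full-sample"`` fits the min-max scaling on all subjects before
  cross-validation, matching the common (leaky) practice of published
  LIBSVM workflows;
* ``"leakage-safe"`` refits the scaling inside every training fold, so the
  held-out subject's feature values and label never influence its own
  prediction.  The difference between the two modes on null data is an
  estimate of the optimism the leak buys.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVR

from .connectivity import ZFCMatrix
from .stats import pearson_test

__all__ = [
    "improvement_rate",
    "MinMaxScale",
    "FeatureMatrix",
    "SVRConfig",
    "PredictionResult",
    "build_feature_matrix",
    "loocv_svr_grid",
    "evaluate_predictions",
]


def improvement_rate(pre_off: float, post_on: float) -> float:
    """(pre_off - post_on) / pre_off; negative if the score worsened.

    Not clipped: a clinical analysis must see worsening as a negative
    rate (only the synthetic generator clips, because it *constructs*
    proportions).
    """
    if pre_off <= 0:
        raise ValueError(f"pre-op med-off score must be > 0, got {pre_off}")
    if post_on < 0:
        raise ValueError(f"post-op med-on score must be >= 0, got {post_on}")
    return (pre_off - post_on) / pre_off


@dataclass
class MinMaxScale:
    """Invertible per-column min-max map onto [-1, 1]."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray, names: list[str] | None = None) -> "MinMaxScale":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        lo, hi = x.min(axis=0), x.max(axis=0)
        degenerate = np.flatnonzero(hi == lo)
        if degenerate.size:
            labels = [names[i] if names else str(i) for i in degenerate]
            raise ValueError(f"constant feature(s), cannot scale: {labels}")
        return cls(lo=lo, hi=hi)

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return 2.0 * (x - self.lo) / (self.hi - self.lo) - 1.0

    def inverse(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return (s + 1.0) / 2.0 * (self.hi - self.lo) + self.lo


@dataclass
class FeatureMatrix:
    """Subjects x selected-edge zFC features, plus labels, pre-scaling."""

    X: np.ndarray  # (n_subjects, n_edges), raw zFC
    y: np.ndarray  # (n_subjects,), raw improvement rates
    feature_names: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).reshape(-1)
        if self.X.shape[0] != self.y.size:
            raise ValueError("feature rows != label count")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("missing entries in features or labels")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        df["improvement_rate"] = self.y
        return df


def build_feature_matrix(
    zfc_pd: list[ZFCMatrix],
    selected_edges: list[tuple[int, int]],
    labels: np.ndarray,
    subject_ids: list[str] | None = None,
) -> FeatureMatrix:
    """Extract the selected lower-triangle edges' zFC as the design matrix."""
    if not selected_edges:
        raise ValueError("no selected edges: nothing to predict from")
    labels = np.asarray(labels, dtype=float).reshape(-1)
    if len(zfc_pd) != labels.size:
        raise ValueError("one label per subject required")
    names = [f"roi{i}-roi{j}" for i, j in selected_edges]
    X = np.empty((len(zfc_pd), len(selected_edges)))
    for s, m in enumerate(zfc_pd):
        for e, (i, j) in enumerate(selected_edges):
            if i not in m.roi_ids or j not in m.roi_ids:
                raise ValueError(f"edge roi{i}-roi{j} absent from subject matrix")
            X[s, e] = m.edge_value(i, j)
    if subject_ids is None:
        subject_ids = [f"sub-{s:02d}" for s in range(len(zfc_pd))]
    fm = FeatureMatrix(X=X, y=labels, feature_names=names, subject_ids=list(subject_ids))
    # fail fast on unscalable features with the edge name in the message
    MinMaxScale.fit(fm.X, names)
    return fm


def _default_grid() -> tuple[list, list, list]:
    c = [2.0**k for k in range(-5, 26, 2)]
    g = [2.0**k for k in range(-25, 4, 2)]
    p = [0.1, 0.2, 0.3, 0.4, 0.5]
    return c, g, p


@dataclass
class SVRConfig:
    """Grid-search space for the RBF epsilon-SVR.

    Defaults span C in 2^-5..2^25, gamma in 2^-25..2^3 (step 2 on the
    exponent) and epsilon in 0.1..0.5 — wide enough to contain the optima
    that LIBSVM grid searches typically land on for n ~ 30 problems.
    """

    C_grid: list[float] = field(default_factory=lambda: _default_grid()[0])
    gamma_grid: list[float] = field(default_factory=lambda: _default_grid()[1])
    epsilon_grid: list[float] = field(default_factory=lambda: _default_grid()[2])
    scaling_mode: str = "full-sample"  # or "leakage-safe"
    max_iter: int = 20_000  # caps libsvm work in pathological grid corners

    def __post_init__(self) -> None:
        if not (self.C_grid and self.gamma_grid and self.epsilon_grid):
            raise ValueError("empty hyperparameter grid")
        if any(c <= 0 for c in self.C_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("C and gamma must be positive")
        if any(e < 0 for e in self.epsilon_grid):
            raise ValueError("epsilon must be >= 0")
        if self.scaling_mode not in ("full-sample", "leakage-safe"):
            raise ValueError(f"unknown scaling mode {self.scaling_mode!r}")

    def triples(self) -> list[tuple[float, float, float]]:
        """Grid triples in deterministic tie-break order (C, then gamma,
        then epsilon, each ascending)."""
        return list(
            itertools.product(
                sorted(self.C_grid), sorted(self.gamma_grid), sorted(self.epsilon_grid)
            )
        )


@dataclass
class PredictionResult:
    """LOOCV predictions at the selected hyperparameters, plus diagnostics."""

    y_true: np.ndarray  # original scale
    y_pred: np.ndarray  # original scale
    r: float
    p: float
    mse_normalized: float
    mse_original: float
    best_C: float
    best_gamma: float
    best_epsilon: float
    scaling_mode: str
    n_folds: int
    subject_ids: list[str]
    fold_log: list[dict] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Leave-one-out epsilon-SVR (RBF kernel)",
            "=" * 46,
            f"subjects / folds      : {self.n_folds}",
            f"scaling mode          : {self.scaling_mode}",
            f"best C                : {self.best_C:g}",
            f"best gamma            : {self.best_gamma:g}",
            f"best epsilon          : {self.best_epsilon:g}",
            f"LOOCV Pearson r       : {self.r:.3f}" + (f"  (p = {self.p:.4f})" if np.isfinite(self.p) else ""),
            f"LOOCV MSE (normalized): {self.mse_normalized:.3f}",
            f"LOOCV MSE (original)  : {self.mse_original:.4f}",
        ]
        return "\n".join(lines)

    def scatter_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "actual": self.y_true,
                "predicted": self.y_pred,
            }
        )


def _loocv_predictions(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    epsilon: float,
    scaling_mode: str,
    feature_names: list[str],
    max_iter: int = 20_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (pred_norm, true_norm, pred_original) across the n folds."""
    n = y.size
    pred_norm = np.empty(n)
    true_norm = np.empty(n)
    pred_orig = np.empty(n)
    if scaling_mode == "full-sample":
        xs = MinMaxScale.fit(X, feature_names)
        ys = MinMaxScale.fit(y[:, None])
        Xs, Ys = xs.transform(X), ys.transform(y[:, None]).ravel()
        for i in range(n):
            tr = np.arange(n) != i
            model = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon, max_iter=max_iter)
            model.fit(Xs[tr], Ys[tr])
            pn = float(model.predict(Xs[i : i + 1])[0])
            pred_norm[i] = pn
            true_norm[i] = Ys[i]
            pred_orig[i] = float(ys.inverse(np.array([[pn]]))[0, 0])
    else:  # leakage-safe: scalers fitted on the training fold only
        for i in range(n):
            tr = np.arange(n) != i
            xs = MinMaxScale.fit(X[tr], feature_names)
            ys = MinMaxScale.fit(y[tr][:, None])
            model = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon, max_iter=max_iter)
            model.fit(xs.transform(X[tr]), ys.transform(y[tr][:, None]).ravel())
            pn = float(model.predict(xs.transform(X[i : i + 1]))[0])
            pred_norm[i] = pn
            true_norm[i] = float(ys.transform(np.array([[y[i]]]))[0, 0])
            pred_orig[i] = float(ys.inverse(np.array([[pn]]))[0, 0])
    return pred_norm, true_norm, pred_orig


def loocv_svr_grid(
    features: FeatureMatrix,
    config: SVRConfig | None = None,
) -> PredictionResult:
    """Grid-searched epsilon-SVR under leave-one-out cross-validation.

    Every (C, gamma, epsilon) triple is evaluated by full LOOCV (fold i
    trains on the other n-1 subjects and predicts subject i); the triple
    minimizing LOOCV MSE on the normalized scale wins, ties broken toward
    the smallest C, then gamma, then epsilon.  The reported predictions are
    the LOOCV predictions at the winning triple, inverse-scaled to the
    original improvement-rate scale.  The procedure is fully deterministic.
    """
    config = config or SVRConfig()
    X, y = features.X, features.y
    n = y.size
    if n < 3:
        raise ValueError("need >= 3 subjects for LOOCV")
    degenerate_labels = np.ptp(y) == 0
    if degenerate_labels:
        warnings.warn(
            "all labels identical: Pearson r undefined, MSE still reported",
            RuntimeWarning,
            stacklevel=2,
        )
        best = (config.triples()[0], np.full(n, y[0]), np.zeros(n), np.full(n, y[0]))
        (C, gamma, eps), pred_orig, pred_norm, _ = best
        return PredictionResult(
            y_true=y.copy(), y_pred=pred_orig, r=float("nan"), p=float("nan"),
            mse_normalized=0.0, mse_original=0.0, best_C=C, best_gamma=gamma,
            best_epsilon=eps, scaling_mode=config.scaling_mode, n_folds=n,
            subject_ids=list(features.subject_ids),
        )
    best_mse = np.inf
    best_triple: tuple[float, float, float] | None = None
    best_out: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        for triple in config.triples():
            pn, tn, po = _loocv_predictions(
                X, y, *triple, config.scaling_mode, features.feature_names,
                config.max_iter,
            )
            mse = float(np.mean((pn - tn) ** 2))
            if mse < best_mse:  # strict: first (smallest C, gamma, epsilon) wins ties
                best_mse, best_triple, best_out = mse, triple, (pn, tn, po)
    assert best_triple is not None and best_out is not None
    pn, tn, po = best_out
    r, _, p = pearson_test(po, y)
    fold_log = [
        {"fold": i, "held_out": features.subject_ids[i], "n_train": n - 1}
        for i in range(n)
    ]
    return PredictionResult(
        y_true=y.copy(),
        y_pred=po,
        r=r,
        p=p,
        mse_normalized=best_mse,
        mse_original=float(np.mean((po - y) ** 2)),
        best_C=best_triple[0],
        best_gamma=best_triple[1],
        best_epsilon=best_triple[2],
        scaling_mode=config.scaling_mode,
        n_folds=n,
        subject_ids=list(features.subject_ids),
        fold_log=fold_log,
    )


def evaluate_predictions(result: PredictionResult) -> dict:
    """Summary metrics: Pearson r with two-tailed p, MSE on both scales."""
    if result.y_true.size < 3:
        raise ValueError("need >= 3 prediction pairs")
    return {
        "r": result.r,
        "p": result.p,
        "mse_normalized": result.mse_normalized,
        "mse_original": result.mse_original,
        "n": int(result.y_true.size),
        "best_params": {
            "C": result.best_C,
            "gamma": result.best_gamma,
            "epsilon": result.best_epsilon,
        },
        "scaling_mode": result.scaling_mode,
    }
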