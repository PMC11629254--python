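"""Fisher linear classification functions with backward stepwise selection.

Follows the SPSS convention for Fisher's classification functions: for each
class k with mean vector mu_k and pooled within-class covariance S_w,

    coefficients_k = S_w^{-1} mu_k
    constant_k     = -1/2 mu_k' S_w^{-1} mu_k + log(prior_k)

and a sample is assigned to the class with the larger score Y_k.  Class
priors default to equal.  Backward stepwise selection repeatedly removes
the feature with the smallest partial F-to-remove (Wilks' lambda ratio
statistic) while that F falls below the removal threshold (SPSS default
2.71); the final model is the smallest one along the trace whose
leave-one-out cross-validation accuracy is within a tolerance of the best.

:data:`REFERENCE_MODEL` carries the published four-carnitine discriminant
functions for Yanchi lamb authentication as a fixed worked example for
:func:`classify`; its coefficients are *not* refit by this package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import FeatureTable

__all__ = [
    "FisherModel",
    "StepwiseStep",
    "StepwiseTrace",
    "fit_fisher",
    "classify",
    "stepwise_backward",
    "loocv_accuracy",
    "resubstitution_accuracy",
    "REFERENCE_MODEL",
]

logger = logging.getLogger(__name__)

#: SPSS default probability-of-F-to-remove threshold expressed as an F value.
DEFAULT_F_REMOVE = 2.71


@dataclass
class FisherModel:
    classes: tuple[str, ...]
    features: list[str]
    coefficients: np.ndarray  # classes × features
    constants: np.ndarray  # per class
    canonical_correlation: float | None = None

    def scores(self, x: np.ndarray) -> np.ndarray:
        return self.coefficients @ np.asarray(x, dtype=float) + self.constants


def _xy(table, labels, features):
    if isinstance(table, FeatureTable):
        sub = table.subset(biological_only=True)
        cols = features if features is not None else sub.lipid_ids
        X = sub.abundances[cols].to_numpy(dtype=float)
        y = np.asarray(labels if labels is not None else sub.nx_labels())
    else:
        X = np.asarray(table, dtype=float)
        if features is not None:
            X = X[:, : len(features)]
        y = np.asarray(labels)
    return X, y


def _class_stats(X: np.ndarray, y: np.ndarray):
    classes = list(dict.fromkeys(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    means, counts = [], []
    n, p = X.shape
    Sw = np.zeros((p, p))
    for c in classes:
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        mu = Xc.mean(axis=0)
        dev = Xc - mu
        Sw += dev.T @ dev
        means.append(mu)
        counts.append(Xc.shape[0])
    Sw /= n - len(classes)
    return classes, np.asarray(means), np.asarray(counts), Sw


def _solve_within(Sw: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve Sw X = B, ridge-regularizing a singular pooled covariance."""
    p = Sw.shape[0]
    cond = np.linalg.cond(Sw)
    if not np.isfinite(cond) or cond > 1e12:
        ridge = 1e-8 * np.trace(Sw) / p
        ridge = ridge if ridge > 0 else 1e-12
        warnings.warn(f"singular pooled covariance; adding ridge {ridge:.3e}")
        Sw = Sw + ridge * np.eye(p)
    return np.linalg.solve(Sw, B)


def _wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Wilks' lambda |W| / |T| on the given feature matrix."""
    classes = list(dict.fromkeys(y.tolist()))
    grand = X.mean(axis=0)
    W = np.zeros((X.shape[1], X.shape[1]))
    for c in classes:
        Xc = X[y == c]
        dev = Xc - Xc.mean(axis=0)
        W += dev.T @ dev
    devT = X - grand
    T = devT.T @ devT
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


def fit_fisher(
    table: FeatureTable | np.ndarray,
    labels=None,
    features: list[str] | None = None,
    priors: dict[str, float] | None = None,
) -> FisherModel:
    """Fit Fisher classification functions on the selected feature subset."""
    if isinstance(table, FeatureTable) and features is None:
        features = table.lipid_ids
    X, y = _xy(table, labels, features)
    if features is None:
        features = [f"x{j}" for j in range(X.shape[1])]
    classes, means, counts, Sw = _class_stats(X, y)
    coef = _solve_within(Sw, means.T).T  # classes × features
    if priors is None:
        pri = np.full(len(classes), 1.0 / len(classes))
    else:
        pri = np.array([priors[c] for c in classes], dtype=float)
        pri /= pri.sum()
    const = -0.5 * np.einsum("ij,ij->i", coef, means) + np.log(pri)
    lam = _wilks_lambda(X, y)
    cancorr = float(np.sqrt(max(0.0, 1.0 - lam))) if len(classes) == 2 else None
    return FisherModel(
        classes=tuple(classes),
        features=list(features),
        coefficients=coef,
        constants=const,
        canonical_correlation=cancorr,
    )


def classify(model: FisherModel, x) -> tuple[str, dict[str, float]]:
    """Assign the class with the larger Fisher score.

    ``x`` may be a mapping lipid_id → abundance or an array ordered like
    ``model.features``.  Exact ties break deterministically to the first
    class and are logged.
    """
    if isinstance(x, dict):
        try:
            vec = np.array([x[f] for f in model.features], dtype=float)
        except KeyError as exc:
            raise ValueError(f"missing feature {exc.args[0]!r}") from exc
    else:
        vec = np.asarray(x, dtype=float)
        if vec.shape[0] != len(model.features):
            raise ValueError(
                f"expected {len(model.features)} feature values, got {vec.shape[0]}"
            )
    scores = model.scores(vec)
    best = int(np.argmax(scores))
    if np.sum(scores == scores[best]) > 1:
        logger.info("tied Fisher scores; assigning first class %s", model.classes[0])
        best = int(np.flatnonzero(scores == scores[best])[0])
    return model.classes[best], {c: float(s) for c, s in zip(model.classes, scores)}


def _predict_matrix(model: FisherModel, X: np.ndarray) -> np.ndarray:
    scores = X @ model.coefficients.T + model.constants
    return np.asarray([model.classes[i] for i in np.argmax(scores, axis=1)])


def resubstitution_accuracy(table, labels=None, features=None, model: FisherModel | None = None) -> float:
    """Fraction of the (training) samples the model classifies correctly."""
    if model is None:
        model = fit_fisher(table, labels, features)
    X, y = _xy(table, labels, model.features)
    return float(np.mean(_predict_matrix(model, X) == y))


def loocv_accuracy(table, labels=None, features: list[str] | None = None) -> float:
    """Leave-one-out cross-validation accuracy of the Fisher model on the
    given feature subset; folds whose training split loses a class are
    skipped with a warning."""
    X, y = _xy(table, labels, features)
    if features is None:
        features = [f"x{j}" for j in range(X.shape[1])]
    n = X.shape[0]
    correct, used = 0, 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if len(set(y_train.tolist())) < 2 or min(np.bincount(pd.factorize(y_train)[0])) < 2:
            warnings.warn(f"fold {i}: training split degenerate; skipped")
            continue
        model = fit_fisher(X[mask], y_train, features)
        pred, _ = classify(model, X[i])
        correct += pred == y[i]
        used += 1
    if used == 0:
        raise ValueError("no usable LOOCV folds")
    return correct / used


def _f_to_remove(X: np.ndarray, y: np.ndarray, features: list[str]) -> pd.Series:
    """Partial F-to-remove per feature from the Wilks' lambda ratio."""
    n = X.shape[0]
    g = len(set(y.tolist()))
    p = len(features)
    lam_full = _wilks_lambda(X, y)
    out = {}
    scale = (n - g - p + 1) / (g - 1)
    for j, f in enumerate(features):
        keep = [k for k in range(p) if k != j]
        lam_red = _wilks_lambda(X[:, keep], y) if keep else 1.0
        if lam_full <= 0:
            out[f] = np.inf
        else:
            out[f] = max(0.0, scale * (lam_red / lam_full - 1.0))
    return pd.Series(out)


@dataclass
class StepwiseStep:
    step: int
    features: list[str]
    f_to_remove: dict[str, float]
    canonical_correlation: float
    resubstitution_accuracy: float
    cv_accuracy: float
    removed: str | None = None


@dataclass
class StepwiseTrace:
    steps: list[StepwiseStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [s.step for s in self.steps],
                "n_factors": [len(s.features) for s in self.steps],
                "factors": [",".join(s.features) for s in self.steps],
                "canonical_correlation": [s.canonical_correlation for s in self.steps],
                "prediction_accuracy": [s.resubstitution_accuracy for s in self.steps],
                "cross_validation_accuracy": [s.cv_accuracy for s in self.steps],
                "removed_next": [s.removed for s in self.steps],
            }
        )


def stepwise_backward(
    table,
    labels=None,
    features: list[str] | None = None,
    f_remove: float = DEFAULT_F_REMOVE,
    cv_tolerance: float = 0.0,
    min_features: int = 1,
) -> tuple[StepwiseTrace, FisherModel]:
    """Backward stepwise Fisher discriminant analysis.

    Starting from the full panel, the feature with the smallest partial
    F-to-remove is dropped while that F is below ``f_remove`` (use
    ``f_remove=np.inf`` to trace all the way down to ``min_features``).
    Among the traced models, the final choice is the smallest one whose
    LOOCV accuracy is within ``cv_tolerance`` of the best — fewer factors
    at equal discriminative accuracy.
    """
    if isinstance(table, FeatureTable):
        if features is None:
            features = table.lipid_ids
        sub = table.subset(biological_only=True)
        X_all = sub.abundances[features].to_numpy(dtype=float)
        y = np.asarray(labels if labels is not None else sub.nx_labels())
    else:
        X_all = np.asarray(table, dtype=float)
        y = np.asarray(labels)
        if features is None:
            features = [f"x{j}" for j in range(X_all.shape[1])]
    if len(features) < 2:
        raise ValueError("stepwise selection needs a panel of at least 2 features")

    col = {f: j for j, f in enumerate(features)}
    current = list(features)
    trace = StepwiseTrace()
    step = 0
    while True:
        X = X_all[:, [col[f] for f in current]]
        model = fit_fisher(X, y, current)
        fvals = _f_to_remove(X, y, current)
        entry = StepwiseStep(
            step=step,
            features=list(current),
            f_to_remove=fvals.to_dict(),
            canonical_correlation=model.canonical_correlation or 0.0,
            resubstitution_accuracy=float(np.mean(_predict_matrix(model, X) == y)),
            cv_accuracy=loocv_accuracy(X, y, current),
        )
        trace.steps.append(entry)
        if len(current) <= min_features:
            break
        worst = str(fvals.idxmin())
        if fvals[worst] >= f_remove:
            break
        entry.removed = worst
        current.remove(worst)
        step += 1

    best_cv = max(s.cv_accuracy for s in trace.steps)
    candidates = [s for s in trace.steps if s.cv_accuracy >= best_cv - cv_tolerance]
    chosen = min(candidates, key=lambda s: (len(s.features), -s.step))
    X = X_all[:, [col[f] for f in chosen.features]]
    final = fit_fisher(X, y, chosen.features)
    return trace, final


#: Published four-carnitine Fisher functions (NX vs non-NX) used as a fixed
#: worked example; coefficients are in peak-area^-1 units for CAR1, CAR2,
#: CAR3, CAR5 in that order.
REFERENCE_MODEL = FisherModel(
    classes=("NX", "nonNX"),
    features=["CAR1", "CAR2", "CAR3", "CAR5"],
    coefficients=np.array(
        [
            [4.41e-6, 2.98e-5, 3.54e-5, -1.14e-5],
            [-3.93e-6, 2.86e-5, 1.58e-5, -7.33e-6],
        ]
    ),
    constants=np.array([-11.501, -1.407]),
    canonical_correlation=0.826,
)
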