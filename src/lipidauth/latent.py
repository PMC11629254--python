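"""Latent-variable models for group separation and marker importance.

Implements, from first principles, the three projection methods the
screening pipeline relies on:

* **PCA** via singular value decomposition of the centred matrix;
* **PLS-DA** via NIPALS on a one-hot (centred) class response, supporting
  binary and multi-class labels;
* **OPLS-DA** in the Trygg–Wold style for a binary contrast: class-orthogonal
  variation is deflated from X before the single predictive component is
  extracted, so the predictive scores carry all class-correlated variation.

VIP (variable importance in projection) scores are computed from the
predictive components only,

    VIP_j = sqrt( p * sum_a SSY_a * w_aj^2 / sum_a SSY_a ),

with unit-norm component weights w_a and SSY_a the Y sum of squares
explained by component a; the mean of the squared VIPs is identically 1.

Sign convention for reproducibility: each component is flipped so that its
largest-|weight| (PCA: largest-|loading|) coordinate is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import FeatureTable

__all__ = ["LatentModel", "VipScores", "fit_pca", "fit_plsda", "fit_oplsda", "vip_scores"]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


@dataclass
class LatentModel:
    kind: str  # {"PCA", "PLSDA", "OPLSDA"}
    n_components: int
    scores: np.ndarray  # samples × components (predictive, for OPLS)
    loadings: np.ndarray  # lipids × components
    weights: np.ndarray | None  # lipids × components, unit norm (PLS/OPLS)
    explained_x_variance: np.ndarray  # fraction per component
    ssy: np.ndarray | None = None  # Y sum of squares explained per predictive comp
    y_loadings: np.ndarray | None = None
    orthogonal_scores: np.ndarray | None = None
    orthogonal_loadings: np.ndarray | None = None
    orthogonal_weights: np.ndarray | None = None
    lipid_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    class_order: list[str] = field(default_factory=list)


@dataclass
class VipScores:
    vip: pd.Series

    def __getitem__(self, lipid_id: str) -> float:
        return float(self.vip[lipid_id])


def _fix_sign(vectors: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Return ±1 per column so the largest-|reference| entry is positive."""
    signs = np.ones(reference.shape[1])
    for a in range(reference.shape[1]):
        ref = reference[:, a]
        if ref.any():
            signs[a] = np.sign(ref[np.argmax(np.abs(ref))]) or 1.0
    return signs


def _as_matrix(table: FeatureTable | np.ndarray) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(table, FeatureTable):
        return table.values(), table.lipid_ids, table.sample_ids
    X = np.asarray(table, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])], [f"s{i}" for i in range(X.shape[0])]


def _one_hot(labels) -> tuple[np.ndarray, list[str]]:
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels.tolist()))  # stable order of appearance
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    Y = np.stack([(labels == c).astype(float) for c in classes], axis=1)
    return Y, classes


def fit_pca(table: FeatureTable | np.ndarray, n_components: int = 2) -> LatentModel:
    """Principal component analysis of the (column-centred) table."""
    X, lipid_ids, sample_ids = _as_matrix(table)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating", stacklevel=2
        )
        n_components = rank
    comps = slice(0, n_components)
    loadings = Vt[comps].T  # p × A, orthonormal
    signs = _fix_sign(loadings, loadings)
    loadings = loadings * signs
    scores = (U[:, comps] * s[comps]) * signs
    total = float(np.sum(s**2)) or 1.0
    explained = s[comps] ** 2 / total
    return LatentModel(
        kind="PCA",
        n_components=n_components,
        scores=scores,
        loadings=loadings,
        weights=None,
        explained_x_variance=explained,
        lipid_ids=lipid_ids,
        sample_ids=sample_ids,
    )


def _nipals_component(E: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One NIPALS PLS2 component on residual matrices E (X) and F (Y)."""
    # start from the Y column with the largest sum of squares (ties: first)
    u = F[:, int(np.argmax((F**2).sum(axis=0)))].copy()
    t_old = None
    for _ in range(_NIPALS_MAX_ITER):
        w = E.T @ u
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("degenerate component: X residual uncorrelated with Y")
        w /= norm
        t = E @ w
        c = F.T @ t / (t @ t)
        u = F @ c / (c @ c)
        if t_old is not None and np.linalg.norm(t - t_old) <= _NIPALS_TOL * np.linalg.norm(t):
            break
        t_old = t
    p = E.T @ t / (t @ t)
    return w, t, p, c


def fit_plsda(
    table: FeatureTable | np.ndarray,
    labels,
    n_components: int = 2,
) -> LatentModel:
    """NIPALS PLS-DA on a one-hot class response.

    The input is expected to be scaled (autoscaling upstream); the class
    indicator matrix is centred internally.  Deterministic for fixed input.
    """
    X, lipid_ids, sample_ids = _as_matrix(table)
    Y, classes = _one_hot(labels)
    E = X - X.mean(axis=0)
    F = Y - Y.mean(axis=0)
    ssx_total = float((E**2).sum()) or 1.0

    W, T, P, C, ssy, xvar = [], [], [], [], [], []
    for _ in range(n_components):
        w, t, p, c = _nipals_component(E, F)
        E = E - np.outer(t, p)
        Fhat = np.outer(t, c)
        F = F - Fhat
        W.append(w)
        T.append(t)
        P.append(p)
        C.append(c)
        ssy.append(float((Fhat**2).sum()))
        xvar.append(float((t @ t) * (p @ p)) / ssx_total)

    W = np.stack(W, axis=1)
    T = np.stack(T, axis=1)
    P = np.stack(P, axis=1)
    C = np.stack(C, axis=1)
    signs = _fix_sign(W, W)
    return LatentModel(
        kind="PLSDA",
        n_components=n_components,
        scores=T * signs,
        loadings=P * signs,
        weights=W * signs,
        explained_x_variance=np.asarray(xvar),
        ssy=np.asarray(ssy),
        y_loadings=C * signs,
        lipid_ids=lipid_ids,
        sample_ids=sample_ids,
        class_order=classes,
    )


def fit_oplsda(
    table: FeatureTable | np.ndarray,
    labels,
    n_orthogonal: int = 1,
) -> LatentModel:
    """OPLS-DA for a binary contrast: one predictive component plus
    ``n_orthogonal`` Y-orthogonal components removed from X beforehand."""
    X, lipid_ids, sample_ids = _as_matrix(table)
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels.tolist()))
    if len(classes) != 2:
        raise ValueError("OPLS-DA requires exactly two classes")
    y = (labels == classes[0]).astype(float)
    y = y - y.mean()

    E = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(E)
    if n_orthogonal >= rank:
        raise ValueError(f"n_orthogonal={n_orthogonal} must be below the data rank {rank}")
    ssx_total = float((E**2).sum()) or 1.0

    w = E.T @ y
    w /= np.linalg.norm(w)

    To, Po, Wo = [], [], []
    for _ in range(n_orthogonal):
        t = E @ w
        p = E.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no orthogonal structure left
        w_o /= norm
        t_o = E @ w_o
        p_o = E.T @ t_o / (t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        To.append(t_o)
        Po.append(p_o)
        Wo.append(w_o)

    t = E @ w
    p = E.T @ t / (t @ t)
    c = float(y @ t / (t @ t))
    ssy = np.array([(t @ t) * c**2])
    sign = _fix_sign(w[:, None], w[:, None])[0]

    return LatentModel(
        kind="OPLSDA",
        n_components=1,
        scores=(t * sign)[:, None],
        loadings=(p * sign)[:, None],
        weights=(w * sign)[:, None],
        explained_x_variance=np.array([(t @ t) * (p @ p) / ssx_total]),
        ssy=ssy,
        y_loadings=np.array([[c * sign]]),
        orthogonal_scores=np.stack(To, axis=1) if To else np.empty((X.shape[0], 0)),
        orthogonal_loadings=np.stack(Po, axis=1) if Po else np.empty((X.shape[1], 0)),
        orthogonal_weights=np.stack(Wo, axis=1) if Wo else np.empty((X.shape[1], 0)),
        lipid_ids=lipid_ids,
        sample_ids=sample_ids,
        class_order=classes,
    )


def vip_scores(model: LatentModel) -> VipScores:
    """VIP over the predictive components; mean squared VIP equals 1."""
    if model.kind not in ("PLSDA", "OPLSDA"):
        raise ValueError("VIP is defined for PLS-DA / OPLS-DA models")
    if model.ssy is None or model.weights is None:
        raise ValueError("model lacks SSY per component")
    ssy_total = float(np.sum(model.ssy))
    if ssy_total <= 0:
        raise ValueError("zero explained Y sum of squares")
    p = model.weights.shape[0]
    wnorm = model.weights / np.linalg.norm(model.weights, axis=0, keepdims=True)
    vip = np.sqrt(p * (wnorm**2 @ model.ssy) / ssy_total)
    ids = model.lipid_ids or [f"x{j}" for j in range(p)]
    return VipScores(pd.Series(vip, index=ids, name="vip"))
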