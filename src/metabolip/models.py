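"""PLS-DA and SIMCA classifiers with leave-one-out component selection.

PLS-DA: NIPALS PLS2 regression of the autoscaled feature matrix on a
column-centered one-hot class matrix; samples are assigned to the class
with the largest predicted indicator value.  The per-component explained-Y
sum of squares SS_a is stored for VIP computation.

SIMCA: one autoscaled PCA submodel per class, fit only on that class's
training rows.  Membership of a new sample in class c is judged by its
Hotelling T² within the submodel and its squared orthogonal residual Q
against critical limits at level alpha (T² via the F distribution, Q via a
moment-matched scaled chi-square of the residual eigenvalues).  The
combined reduced distance

    d_c = sqrt[(T²/T²_crit)² + (Q/Q_crit)²]

accepts class c when d_c <= sqrt(2) (class-modelling mode) or assigns the
argmin class (discriminant mode).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# PLS-DA

@dataclass
class PLSDAModel:
    classes: list
    weights: np.ndarray        # W: p x A
    x_loadings: np.ndarray     # P: p x A
    y_loadings: np.ndarray     # Q: g x A
    x_scores: np.ndarray       # T: n x A
    coef: np.ndarray           # B: p x g (for centered X, centered Y)
    y_mean: np.ndarray
    n_lv: int
    ss_y: np.ndarray           # explained Y sum of squares per component
    x_center: np.ndarray | None = None
    x_scale: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]


def _one_hot(labels: Sequence, classes: Sequence | None = None
             ) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels, dtype=object)
    if classes is None:
        classes = sorted(pd.unique(labels))
    Y = np.array([[1.0 if l == c else 0.0 for c in classes] for l in labels])
    return Y, list(classes)


def _coef_for(W: np.ndarray, P: np.ndarray, Q: np.ndarray, k: int) -> np.ndarray:
    Wk, Pk, Qk = W[:, :k], P[:, :k], Q[:, :k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, Qk.T)


def fit_plsda(X: np.ndarray, labels: Sequence, n_lv: int,
              x_center: np.ndarray | None = None,
              x_scale: np.ndarray | None = None,
              max_iter: int = 500, tol: float = 1e-10) -> PLSDAModel:
    """NIPALS PLS2 on an autoscaled X against centered one-hot labels.

    Components whose X scores collapse to numerical zero (rank exhausted)
    end the extraction early with a warning.
    """
    X = np.asarray(X, dtype=float)
    Y, classes = _one_hot(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    n, p = X.shape
    y_mean = Y.mean(axis=0)
    E, F = X.copy(), Y - y_mean
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((Y.shape[1], n_lv))
    T = np.zeros((n, n_lv))
    ss_y = np.zeros(n_lv)
    x_norm0 = np.linalg.norm(X)
    a_done = 0
    for a in range(n_lv):
        u = F[:, int(np.argmax(F.var(axis=0)))]
        if np.allclose(F, 0) or np.linalg.norm(E) <= 1e-12 * max(1.0, x_norm0):
            warnings.warn(f"rank exhausted after {a} components", stacklevel=2)
            break
        t_old = None
        for _ in range(max_iter):
            w = E.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = E @ w
            q = F.T @ t / (t @ t)
            u = F @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                break
            t_old = t
        tt = t @ t
        if tt <= 1e-12:
            warnings.warn(f"degenerate component {a + 1}; stopping", stacklevel=2)
            break
        p_a = E.T @ t / tt
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_a, q, t
        ss_y[a] = tt * (q @ q)          # ||t q'||_F^2
        E = E - np.outer(t, p_a)
        F = F - np.outer(t, q)
        a_done = a + 1
    if a_done == 0:
        raise ValueError("no PLS component could be extracted")
    W, P, Q, T, ss_y = (M[..., :a_done] for M in (W, P, Q, T, ss_y))
    B = _coef_for(W, P, Q, a_done)
    return PLSDAModel(classes=classes, weights=W, x_loadings=P, y_loadings=Q,
                      x_scores=T, coef=B, y_mean=y_mean, n_lv=a_done,
                      ss_y=ss_y, x_center=x_center, x_scale=x_scale)


def predict_plsda(model: PLSDAModel, X_new: np.ndarray,
                  n_lv: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Labels and continuous per-class scores for new samples.

    ``X_new`` must carry the training feature columns; the stored
    center/scale vectors are applied when present.  Assignment is argmax
    over predicted indicator columns; exact ties go to the lowest class
    index.  ``n_lv`` predicts from a truncated component sequence.
    """
    Z = np.asarray(X_new, dtype=float)
    if Z.ndim == 1:
        Z = Z[None, :]
    if Z.shape[1] != model.n_features:
        raise ValueError(f"X_new has {Z.shape[1]} features, "
                         f"model expects {model.n_features}")
    if model.x_center is not None:
        Z = Z - model.x_center
    if model.x_scale is not None:
        Z = Z / model.x_scale
    B = model.coef if n_lv is None or n_lv >= model.n_lv else \
        _coef_for(model.weights, model.x_loadings, model.y_loadings, n_lv)
    scores = Z @ B + model.y_mean
    # argmax with deterministic lowest-index tie-break (np.argmax's rule)
    labels = np.array([model.classes[i] for i in np.argmax(scores, axis=1)],
                      dtype=object)
    return labels, scores


# ---------------------------------------------------------------------------
# SIMCA

@dataclass
class SIMCASubmodel:
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray       # p x k
    eigenvalues: np.ndarray    # the k retained
    residual_eigenvalues: np.ndarray
    n_pcs: int
    n_train: int
    t2_crit: float
    q_crit: float

    def distances(self, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Z = (np.atleast_2d(np.asarray(X_new, float)) - self.center) / self.scale
        T = Z @ self.loadings
        t2 = ((T ** 2) / self.eigenvalues).sum(axis=1)
        R = Z - T @ self.loadings.T
        q = (R ** 2).sum(axis=1)
        return t2, q


@dataclass
class SIMCAModel:
    classes: list
    submodels: Mapping[str, SIMCASubmodel]
    alpha: float

    def reduced_distances(self, X_new: np.ndarray) -> np.ndarray:
        """samples x classes matrix of combined reduced distances d_c."""
        cols = []
        for c in self.classes:
            sm = self.submodels[c]
            t2, q = sm.distances(X_new)
            cols.append(np.sqrt((t2 / sm.t2_crit) ** 2 + (q / sm.q_crit) ** 2))
        return np.column_stack(cols)


def _q_crit_box(residual_eigenvalues: np.ndarray, alpha: float) -> float:
    """Moment-matched (Box) scaled chi-square upper quantile for Q."""
    lam = residual_eigenvalues[residual_eigenvalues > 1e-12]
    if lam.size == 0:
        return np.inf  # perfect-fit model: any residual is an excess
    th1, th2 = lam.sum(), (lam ** 2).sum()
    g, h = th2 / th1, th1 ** 2 / th2
    return float(g * stats.chi2.ppf(1 - alpha, h))


def fit_simca(X: np.ndarray, labels: Sequence,
              n_pcs: Mapping[str, int] | int, alpha: float = 0.05
              ) -> SIMCAModel:
    """Per-class autoscaled PCA submodels with T² and Q critical limits."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    classes = sorted(pd.unique(labels))
    if isinstance(n_pcs, int):
        n_pcs = {c: n_pcs for c in classes}
    submodels = {}
    for c in classes:
        Xc = X[labels == c]
        n_c = Xc.shape[0]
        k = int(n_pcs[c])
        if n_c <= k + 1:
            raise ValueError(f"class {c!r} has {n_c} training samples; "
                             f"needs more than {k + 1} for {k} PCs")
        center = Xc.mean(axis=0)
        scale = Xc.std(axis=0, ddof=1)
        scale = np.where(scale > 0, scale, 1.0)  # constant-in-class columns
        Z = (Xc - center) / scale
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        eig = S ** 2 / (n_c - 1)
        t2_crit = k * (n_c - 1) / (n_c - k) * stats.f.ppf(1 - alpha, k, n_c - k)
        q_crit = _q_crit_box(eig[k:], alpha)
        submodels[c] = SIMCASubmodel(
            center=center, scale=scale, loadings=Vt[:k].T,
            eigenvalues=eig[:k], residual_eigenvalues=eig[k:],
            n_pcs=k, n_train=n_c, t2_crit=float(t2_crit), q_crit=q_crit)
    return SIMCAModel(classes=classes, submodels=submodels, alpha=alpha)


def predict_simca(model: SIMCAModel, X_new: np.ndarray,
                  mode: Literal["class_modelling", "discriminant"]
                  = "discriminant") -> np.ndarray:
    """Discriminant mode: argmin_c d_c labels (ties -> lowest class index).
    Class-modelling mode: samples x classes boolean accepts (d_c <= sqrt 2);
    a sample far from every class is rejected by all."""
    D = model.reduced_distances(X_new)
    if mode == "class_modelling":
        return D <= math.sqrt(2)
    if mode == "discriminant":
        return np.array([model.classes[i] for i in np.argmin(D, axis=1)],
                        dtype=object)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# component selection and metrics

def _loo_misclassifications_plsda(X: np.ndarray, labels: np.ndarray,
                                  max_components: int) -> np.ndarray:
    """LOO misclassification count for k = 1..max_components, from a single
    NIPALS run per left-out sample (coefficients truncated per k)."""
    n = X.shape[0]
    errors = np.zeros(max_components, dtype=int)
    for i in range(n):
        keep = np.arange(n) != i
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_plsda(X[keep], labels[keep], max_components)
        for k in range(1, max_components + 1):
            pred, _ = predict_plsda(m, X[i], n_lv=min(k, m.n_lv))
            errors[k - 1] += pred[0] != labels[i]
    return errors


def _loo_misclassifications_simca(X: np.ndarray, labels: np.ndarray,
                                  max_components: int, alpha: float
                                  ) -> np.ndarray:
    n = X.shape[0]
    errors = np.zeros(max_components, dtype=int)
    min_class = min(np.sum(labels == c) for c in pd.unique(labels))
    for k in range(1, max_components + 1):
        if min_class - 1 <= k + 1:   # leave-one-out shrinks a class by 1
            errors[k - 1] = n + 1    # infeasible: never selected
            continue
        for i in range(n):
            keep = np.arange(n) != i
            m = fit_simca(X[keep], labels[keep], k, alpha)
            pred = predict_simca(m, X[i], "discriminant")
            errors[k - 1] += pred[0] != labels[i]
    return errors


def select_components_loo(X: np.ndarray, labels: Sequence,
                          fitter: Literal["plsda", "simca"] = "plsda",
                          max_components: int = 10, alpha: float = 0.05
                          ) -> tuple[int, np.ndarray]:
    """Smallest component count minimising LOO misclassifications.

    Returns ``(chosen_k, errors_per_k)``; ties break toward parsimony.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    max_components = min(max_components, X.shape[0] - 2, X.shape[1])
    if fitter == "plsda":
        errors = _loo_misclassifications_plsda(X, labels, max_components)
    elif fitter == "simca":
        errors = _loo_misclassifications_simca(X, labels, max_components, alpha)
    else:
        raise ValueError(f"unknown fitter {fitter!r}")
    return int(np.argmin(errors)) + 1, errors


@dataclass
class ClassMetrics:
    """Per-class one-vs-rest counts with derived rates (percent)."""

    classes: list
    confusion: pd.DataFrame          # true class x predicted class
    per_class: pd.DataFrame          # TP FP TN FN sensitivity specificity
    accuracy: float                  # 100 * trace / total
    unseen_predictions: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        out = self.per_class.copy()
        for col in ("sensitivity", "specificity"):
            out[col] = out[col].round(2)
        return out


def evaluate(labels_true: Sequence, labels_pred: Sequence) -> ClassMetrics:
    """One-vs-rest confusion counts and sensitivity/specificity/accuracy."""
    yt = np.asarray(labels_true, dtype=object)
    yp = np.asarray(labels_pred, dtype=object)
    if yt.shape != yp.shape:
        raise ValueError("label vectors differ in length")
    classes = sorted(pd.unique(yt))
    unseen = sorted(set(yp) - set(classes))
    all_labels = classes + unseen
    conf = pd.DataFrame(0, index=pd.Index(classes, name="true"),
                        columns=pd.Index(all_labels, name="predicted"))
    for t, p in zip(yt, yp):
        conf.loc[t, p] += 1
    n = len(yt)
    rows = {}
    for c in classes:
        tp = int(conf.loc[c, c])
        fn = int(conf.loc[c].sum() - tp)
        fp = int(conf[c].sum() - tp)
        tn = n - tp - fn - fp
        sens = 100.0 * tp / (tp + fn) if tp + fn else np.nan
        spec = 100.0 * tn / (tn + fp) if tn + fp else np.nan
        rows[c] = dict(TP=tp, FP=fp, TN=tn, FN=fn,
                       sensitivity=sens, specificity=spec)
    per_class = pd.DataFrame(rows).T
    accuracy = 100.0 * np.trace(conf.loc[classes, classes].to_numpy()) / n
    return ClassMetrics(classes=classes, confusion=conf, per_class=per_class,
                        accuracy=accuracy, unseen_predictions=unseen)
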