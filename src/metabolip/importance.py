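"""Variable importance, variable reduction, ROC, and univariate audits.

VIP (variable importance in projection) for a PLS2 model with A components:

    VIP_j = sqrt( p * sum_a [ SS_a * (w_aj / ||w_a||)^2 ] / sum_a SS_a )

where SS_a is the Y sum of squares explained by component a and w_a the
a-th X-weight vector.  The squared VIPs average to 1, so VIP > 1 marks a
feature contributing more than an exchangeable share.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import PLSDAModel, fit_plsda, predict_plsda, evaluate, ClassMetrics


@dataclass
class VIPResult:
    scores: pd.Series               # per-feature VIP, input order
    ranking: pd.Index               # feature ids, descending VIP

    @property
    def above_one(self) -> pd.Index:
        return self.ranking[self.scores.loc[self.ranking] > 1.0]

    def top(self, k: int) -> pd.Index:
        return self.ranking[:k]


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float
    positive_class: object


def vip_scores(model: PLSDAModel,
               feature_ids: Sequence[str] | None = None) -> VIPResult:
    """VIP scores of a fitted PLS-DA model (multi-response SS_a weighting)."""
    W, ss = model.weights, model.ss_y
    p, A = W.shape
    total = ss.sum()
    if total <= 0:
        raise ValueError("zero explained Y sum of squares")
    wnorm2 = (W ** 2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    vip = np.sqrt(p * ((W ** 2) / wnorm2 @ ss) / total)
    ids = pd.Index(feature_ids) if feature_ids is not None \
        else pd.RangeIndex(p).astype(str)
    s = pd.Series(vip, index=ids, name="VIP")
    # stable descending sort; ties resolved by feature id
    order = s.to_frame().assign(_id=s.index).sort_values(
        ["VIP", "_id"], ascending=[False, True]).index
    return VIPResult(scores=s, ranking=pd.Index(order))


def roc_curve(scores: Sequence[float], labels: Sequence, positive
              ) -> ROCResult:
    """Threshold sweep over the unique scores with trapezoidal AUROC.

    Tied scores move along the curve together, which makes the trapezoidal
    area equal to the rank (Mann-Whitney) statistic with midrank ties:
    AUROC = U / (n_pos * n_neg).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=object) == positive
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # cumulative counts at each distinct threshold (descending)
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auroc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr,
                     auroc=auroc, positive_class=positive)


def univariate_anova(X: pd.DataFrame | np.ndarray, groups: Sequence
                     ) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per feature column.

    Degenerate features (zero within-group variance and equal means) get
    F = 0, p = 1 by convention.  Returns a DataFrame with columns F, p.
    """
    Xd = pd.DataFrame(X)
    g = np.asarray(groups, dtype=object)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    for lev in levels:
        if (g == lev).sum() < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 samples")
    samples = [Xd.loc[np.asarray(g == lev)].to_numpy() for lev in levels]
    with np.errstate(divide="ignore", invalid="ignore"):
        F, p = stats.f_oneway(*samples, axis=0)
    F = np.asarray(F, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(F)
    F[bad], p[bad] = 0.0, 1.0
    return pd.DataFrame({"F": F, "p": p}, index=Xd.columns)


def age_correlation(values: Sequence[float], ages: Sequence[float]
                    ) -> tuple[float, float]:
    """Pearson correlation of a feature with age and its two-sided p-value."""
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 samples")
    if np.std(v) == 0 or np.std(a) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(v, a)
    return float(r), float(p)


def over_representation(selected: Sequence[str],
                        annotation_sets: dict[str, Sequence[str]],
                        universe: Sequence[str]) -> pd.DataFrame:
    """Generic hypergeometric over-representation analysis.

    For each named set: overlap = |selected ∩ set|, expected =
    |selected|*|set|/|universe|, enrichment ratio = overlap/expected, p =
    upper-tail hypergeometric probability of an overlap at least as large.
    Sets are intersected with the universe first.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sel = set(selected)
    if not sel <= uni:
        raise ValueError("selected features must be a subset of the universe")
    N, n = len(uni), len(sel)
    rows = {}
    for name, members in annotation_sets.items():
        K = len(set(members) & uni)
        k = len(set(members) & sel)
        expected = n * K / N
        ratio = k / expected if expected > 0 else np.nan
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows[name] = dict(set_size=K, overlap=k, expected=expected,
                          enrichment_ratio=ratio, p=p)
    return pd.DataFrame(rows).T


def read_gmt(path) -> dict[str, list[str]]:
    """GMT-style set file: one set per line, tab-separated
    ``name<TAB>description<TAB>member1<TAB>member2...``."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = [m for m in parts[2:] if m]
    return sets


def refit_reduced(X_train: pd.DataFrame, labels_train: Sequence,
                  X_test: pd.DataFrame, labels_test: Sequence,
                  subset: Sequence[str], n_lv: int,
                  positive_class="HCC"
                  ) -> tuple[PLSDAModel, ClassMetrics, ROCResult]:
    """Refit the pipeline from autoscaling onward on a feature subset.

    ``X_train``/``X_test`` are unscaled (log10) feature frames; autoscaling
    parameters are learned on the training rows of the subset, a PLS-DA is
    fit, and test metrics plus a positive-class-vs-rest ROC are returned.
    """
    from .preprocess import autoscale_fit

    subset = pd.Index(subset)
    if len(subset) == 0:
        raise ValueError("empty feature subset")
    missing = subset.difference(X_train.columns)
    if len(missing):
        raise KeyError(f"subset features not in X: {list(missing)[:5]}")
    scaler = autoscale_fit(X_train[subset])
    if not len(scaler.mean):
        raise ValueError("all subset features are constant on training data")
    Ztr = scaler.transform(X_train[subset])
    model = fit_plsda(Ztr.to_numpy(), labels_train,
                      n_lv=min(n_lv, len(scaler.mean)),
                      x_center=None, x_scale=None)
    Zte = scaler.transform(X_test[subset])
    pred, cont = predict_plsda(model, Zte.to_numpy())
    metrics = evaluate(labels_test, pred)
    pos_col = model.classes.index(positive_class)
    roc = roc_curve(cont[:, pos_col],
                    np.asarray(labels_test, dtype=object) == positive_class,
                    positive=True)
    return model, metrics, roc
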