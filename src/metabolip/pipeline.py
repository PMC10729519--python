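"""End-to-end workflow: preprocess -> fuse -> KS split -> PLS-DA -> VIP.

``run_workflow`` chains the whole analysis on a pair of feature tables
(typically from :func:`metabolip.cohort.generate_cohort`):

1. per-block preprocessing (missingness filter, QC CV filter, TIS or
   internal-standard normalization, min/5 imputation, log10);
2. one shared per-class Kennard-Stone split on SUM-PCA super scores;
3. autoscaling learned on the training partition, block weighting, fusion;
4. PLS-DA with leave-one-out latent-variable selection, test metrics;
5. VIP scores, top-20 and VIP>1 reduced refits with HCC-vs-rest ROC;
6. the AFP 20 ng/mL rule on the same split, and the AFP-negative HCC
   evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import FeatureTable, METABOLOMICS, LIPIDOMICS
from .preprocess import preprocess_block, autoscale_fit, PreprocessReport, Scaler
from .multiblock import block_weight
from .split import SplitAssignment, split_per_class
from .models import (fit_plsda, predict_plsda, select_components_loo,
                     evaluate, ClassMetrics, PLSDAModel)
from .importance import vip_scores, roc_curve, refit_reduced, VIPResult, ROCResult
from .benchmark import afp_benchmark, compare_methods, AFPBenchmark, afp_classify


@dataclass
class ReducedModelResult:
    subset: pd.Index
    n_lv: int
    metrics: ClassMetrics
    roc: ROCResult


@dataclass
class WorkflowResult:
    processed: dict
    reports: dict
    split: SplitAssignment
    scalers: dict
    weights: dict
    n_lv: int
    loo_errors: np.ndarray
    model: PLSDAModel
    train_metrics: ClassMetrics
    cv_metrics: ClassMetrics
    test_metrics: ClassMetrics
    test_roc: ROCResult
    vip: VIPResult
    reduced: dict = field(default_factory=dict)
    afp: AFPBenchmark | None = None
    comparison: pd.DataFrame | None = None
    afp_negative: ReducedModelResult | None = None


def _fused_frame(processed: Mapping[str, FeatureTable], ids: pd.Index,
                 scalers: Mapping[str, Scaler],
                 weights: Mapping[str, float]) -> pd.DataFrame:
    parts = []
    for name, table in processed.items():
        Z = scalers[name].transform(table.abundances.loc[ids]) * weights[name]
        parts.append(Z)
    return pd.concat(parts, axis=1)


def _loo_cv_metrics(X: np.ndarray, labels: np.ndarray, n_lv: int
                    ) -> ClassMetrics:
    import warnings
    preds = []
    n = len(labels)
    for i in range(n):
        keep = np.arange(n) != i
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_plsda(X[keep], labels[keep], n_lv)
        p, _ = predict_plsda(m, X[i])
        preds.append(p[0])
    return evaluate(labels, np.asarray(preds, dtype=object))


def run_workflow(tables: Mapping[str, FeatureTable],
                 norm_modes: Mapping[str, str] | None = None,
                 fused_components: int = 3, fraction: float = 0.7,
                 max_lv: int = 8, cv_max: float = 30.0,
                 afp_threshold: float = 20.0,
                 positive_class: str = "HCC",
                 scaling: Literal["train", "global"] = "train",
                 reduced_subsets: Sequence[str] = ("top20_vip", "all_vip"),
                 ) -> WorkflowResult:
    """Run the full fused-block classification workflow.

    ``tables`` maps block names to raw FeatureTables.  ``scaling`` chooses
    whether autoscaling parameters are learned on the training partition
    (default, leakage-free) or on all study samples (workflow-faithful
    global mode).  Returns a :class:`WorkflowResult` bundle.
    """
    if norm_modes is None:
        norm_modes = {METABOLOMICS: "total_ion_sum",
                      LIPIDOMICS: "internal_standard"}
    processed: dict[str, FeatureTable] = {}
    reports: dict[str, PreprocessReport] = {}
    for name, table in tables.items():
        mode = norm_modes.get(name, "total_ion_sum")
        processed[name], reports[name] = preprocess_block(
            table, norm_mode=mode, cv_max=cv_max)

    split = split_per_class(processed, fused_components=fused_components,
                            fraction=fraction)
    train_ids, test_ids = split.train_ids, split.test_ids
    meta = next(iter(processed.values())).sample_meta
    y_train = meta.loc[train_ids, "group"].to_numpy(dtype=object)
    y_test = meta.loc[test_ids, "group"].to_numpy(dtype=object)

    scalers, weights = {}, {}
    for name, table in processed.items():
        fit_ids = train_ids if scaling == "train" else \
            table.abundances.index[table.study_mask]
        scalers[name] = autoscale_fit(table.abundances.loc[fit_ids])
        Ztr = scalers[name].transform(table.abundances.loc[train_ids])
        weights[name] = block_weight(Ztr.to_numpy(), "sqrt_p")

    Xtr = _fused_frame(processed, train_ids, scalers, weights)
    Xte = _fused_frame(processed, test_ids, scalers, weights)

    n_lv, loo_errors = select_components_loo(
        Xtr.to_numpy(), y_train, "plsda", max_components=max_lv)
    model = fit_plsda(Xtr.to_numpy(), y_train, n_lv)

    pred_tr, _ = predict_plsda(model, Xtr.to_numpy())
    train_metrics = evaluate(y_train, pred_tr)
    cv_metrics = _loo_cv_metrics(Xtr.to_numpy(), y_train, n_lv)
    pred_te, cont_te = predict_plsda(model, Xte.to_numpy())
    test_metrics = evaluate(y_test, pred_te)
    pos_col = model.classes.index(positive_class)
    test_roc = roc_curve(cont_te[:, pos_col], y_test == positive_class,
                         positive=True)

    vip = vip_scores(model, feature_ids=Xtr.columns)

    # reduced models refit from (unscaled) log10 data on the subset
    log10_train = pd.concat([t.abundances.loc[train_ids]
                             for t in processed.values()], axis=1)
    log10_test = pd.concat([t.abundances.loc[test_ids]
                            for t in processed.values()], axis=1)
    reduced: dict[str, ReducedModelResult] = {}
    for mode in reduced_subsets:
        subset = vip.top(20) if mode == "top20_vip" else vip.above_one
        if len(subset) == 0:
            continue
        rmodel, rmetrics, rroc = refit_reduced(
            log10_train, y_train, log10_test, y_test, subset,
            n_lv=n_lv, positive_class=positive_class)
        reduced[mode] = ReducedModelResult(subset=pd.Index(subset),
                                           n_lv=rmodel.n_lv,
                                           metrics=rmetrics, roc=rroc)

    afp = afp_benchmark(meta, split, threshold=afp_threshold)
    hcc_acc = {
        "plsda_fused": {
            "train": float(train_metrics.per_class.loc["HCC", "sensitivity"]),
            "cv": float(cv_metrics.per_class.loc["HCC", "sensitivity"]),
            "test": float(test_metrics.per_class.loc["HCC", "sensitivity"]),
        }
    }
    comparison = compare_methods(split, hcc_acc, afp)

    afp_negative = afp_negative_eval(
        processed, split, subset_mode="top20_vip", vip=vip, n_lv=n_lv,
        afp_threshold=afp_threshold, positive_class=positive_class)

    return WorkflowResult(processed=processed, reports=reports, split=split,
                          scalers=scalers, weights=weights, n_lv=n_lv,
                          loo_errors=loo_errors, model=model,
                          train_metrics=train_metrics, cv_metrics=cv_metrics,
                          test_metrics=test_metrics, test_roc=test_roc,
                          vip=vip, reduced=reduced, afp=afp,
                          comparison=comparison, afp_negative=afp_negative)


def afp_negative_eval(processed: Mapping[str, FeatureTable],
                      split: SplitAssignment,
                      subset_mode: Literal["all_vip", "top20_vip"] = "top20_vip",
                      vip: VIPResult | None = None, n_lv: int = 2,
                      afp_threshold: float = 20.0,
                      positive_class: str = "HCC") -> ReducedModelResult:
    """Classify AFP-negative HCC test patients against HCV and MC.

    The test partition keeps every non-HCC sample but restricts HCC to
    samples with AFP at or below the threshold; the PLS-DA is refit on the
    full training partition using the requested VIP subset.
    """
    meta = next(iter(processed.values())).sample_meta
    train_ids, test_ids = split.train_ids, split.test_ids
    y_train = meta.loc[train_ids, "group"].to_numpy(dtype=object)

    test_meta = meta.loc[test_ids]
    afp = test_meta["afp"].to_numpy(dtype=float)
    positive, determined = afp_classify(afp, afp_threshold)
    is_hcc = (test_meta["group"] == "HCC").to_numpy()
    keep = ~is_hcc | (determined & ~positive)
    if not (is_hcc & keep).any():
        raise ValueError("no AFP-negative HCC sample in the test partition")
    eval_ids = test_ids[keep]
    y_eval = meta.loc[eval_ids, "group"].to_numpy(dtype=object)

    log10_train = pd.concat([t.abundances.loc[train_ids]
                             for t in processed.values()], axis=1)
    log10_eval = pd.concat([t.abundances.loc[eval_ids]
                            for t in processed.values()], axis=1)
    if vip is None:
        raise ValueError("a fitted VIPResult is required")
    subset = vip.top(20) if subset_mode == "top20_vip" else vip.above_one
    model, metrics, roc = refit_reduced(
        log10_train, y_train, log10_eval, y_eval, subset, n_lv=n_lv,
        positive_class=positive_class)
    return ReducedModelResult(subset=pd.Index(subset), n_lv=model.n_lv,
                              metrics=metrics, roc=roc)
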