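"""Quality filtering, normalization, imputation, transformation, scaling.

The preprocessing chain applied to each omics block, in order:

1. missingness filter — drop features missing in more than 75% of study
   samples or more than 50% of QC pools (strict inequalities, OR-removal);
2. QC CV filter — drop features whose coefficient of variation across QC
   pools exceeds 30% (computed on raw intensities by default);
3. normalization — total-ion-sum for the metabolite block, class-specific
   internal standards for the lipid block;
4. imputation — missing/zero cells replaced by one fifth of the feature's
   minimum observed positive value;
5. log10 transform;
6. autoscaling (per-column mean 0, sample SD 1, n-1 denominator).

QC pools take part in the filters and are re-measured for the report, but
are excluded from classifier fitting downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .cohort import FeatureTable

NormMode = Literal["total_ion_sum", "internal_standard", "none"]


@dataclass
class PreprocessReport:
    """Bookkeeping for one preprocessing step (or a whole chain)."""

    n_features_in: int = 0
    n_removed_missing: int = 0
    n_removed_cv: int = 0
    n_imputed_cells: int = 0
    n_imputed_zeros: int = 0
    normalization_mode: str = "none"
    qc_cv_percent: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    removed_features: list = field(default_factory=list)
    constant_columns_removed: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    @property
    def n_features_out(self) -> int:
        return self.n_features_in - self.n_removed_missing - self.n_removed_cv

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        """Fold a later step's report into this one (additive counts)."""
        self.n_removed_missing += other.n_removed_missing
        self.n_removed_cv += other.n_removed_cv
        self.n_imputed_cells += other.n_imputed_cells
        self.n_imputed_zeros += other.n_imputed_zeros
        if other.normalization_mode != "none":
            self.normalization_mode = other.normalization_mode
        if len(other.qc_cv_percent):
            self.qc_cv_percent = other.qc_cv_percent
        self.removed_features += other.removed_features
        self.constant_columns_removed += other.constant_columns_removed
        self.notes += other.notes
        return self


def qc_cv_percent(table: FeatureTable) -> pd.Series:
    """Per-feature CV% (100 * sd/mean, ddof=1) over observed QC values."""
    qc = table.abundances.loc[table.qc_mask]
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    return cv


def filter_missing(table: FeatureTable, real_threshold: float = 0.75,
                   qc_threshold: float = 0.50
                   ) -> tuple[FeatureTable, PreprocessReport]:
    """Drop features missing in more than ``real_threshold`` of study samples
    OR more than ``qc_threshold`` of QC samples (strictly greater-than)."""
    for name, v in (("real_threshold", real_threshold),
                    ("qc_threshold", qc_threshold)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    study = table.abundances.loc[table.study_mask]
    qc = table.abundances.loc[table.qc_mask]
    if len(study) == 0 or len(qc) == 0:
        raise ValueError("need at least one study and one QC sample")
    frac_study = study.isna().mean(axis=0)
    frac_qc = qc.isna().mean(axis=0)
    drop = (frac_study > real_threshold) | (frac_qc > qc_threshold)
    keep = table.abundances.columns[~drop]
    report = PreprocessReport(
        n_features_in=table.abundances.shape[1],
        n_removed_missing=int(drop.sum()),
        removed_features=list(table.abundances.columns[drop]),
    )
    return table.subset_features(keep), report


def filter_cv(table: FeatureTable, cv_max: float = 30.0
              ) -> tuple[FeatureTable, PreprocessReport]:
    """Drop features with QC CV% above ``cv_max``, with fewer than two
    observed QC values, or with an undefined CV (QC mean 0)."""
    qc = table.abundances.loc[table.qc_mask]
    n_obs = qc.notna().sum(axis=0)
    cv = qc_cv_percent(table)
    undefined = (n_obs < 2) | ~np.isfinite(cv)
    drop = undefined | (cv > cv_max)
    keep = table.abundances.columns[~drop]
    report = PreprocessReport(
        n_features_in=table.abundances.shape[1],
        n_removed_cv=int(drop.sum()),
        qc_cv_percent=cv[keep],
        removed_features=list(table.abundances.columns[drop]),
    )
    if undefined.any():
        report.notes.append(
            f"{int(undefined.sum())} feature(s) removed with undefined QC CV")
    return table.subset_features(keep), report


def normalize(table: FeatureTable, mode: NormMode) -> FeatureTable:
    """Row-wise abundance normalization.

    ``total_ion_sum`` divides every sample row by its sum over retained
    features (row sums become 1).  ``internal_standard`` divides each
    feature sample-wise by its mapped internal-standard feature and then
    drops the IS features.  Missing entries stay missing.
    """
    if mode == "none":
        return table.copy()
    X = table.abundances.copy()
    if mode == "total_ion_sum":
        sums = X.sum(axis=1, skipna=True)
        zero = sums <= 0
        if zero.any():
            raise ValueError(f"zero row sum in sample(s) {list(X.index[zero])}")
        return FeatureTable(X.div(sums, axis=0), table.sample_meta.copy(),
                            table.feature_meta.copy())
    if mode == "internal_standard":
        fmeta = table.feature_meta
        is_map = fmeta["is_id"]
        targets = fmeta.index[fmeta["tag"] != "IS"]
        unmapped = [f for f in targets if pd.isna(is_map.loc[f])]
        if unmapped:
            raise ValueError(f"features without internal-standard mapping: "
                             f"{unmapped[:5]}")
        missing_is = set(is_map.dropna()) - set(X.columns)
        if missing_is:
            raise ValueError(f"internal standards absent from table: "
                             f"{sorted(missing_is)}")
        out = pd.DataFrame(index=X.index, columns=targets, dtype=float)
        for f in targets:
            is_col = X[is_map.loc[f]]
            bad = (is_col <= 0) | is_col.isna()
            if bad.any():
                raise ValueError(
                    f"nonpositive or missing internal-standard value for "
                    f"{is_map.loc[f]!r} in sample(s) {list(X.index[bad])[:5]}")
            out[f] = X[f] / is_col
        return FeatureTable(out, table.sample_meta.copy(),
                            fmeta.loc[targets].copy())
    raise ValueError(f"unknown normalization mode {mode!r}")


def impute_min_fraction(table: FeatureTable, fraction: float = 1 / 5
                        ) -> tuple[FeatureTable, PreprocessReport]:
    """Replace missing and zero cells of each feature with ``fraction`` times
    the feature's minimum observed positive value.  Zeros are treated as
    missing (required before log transform) but counted separately."""
    X = table.abundances.copy()
    report = PreprocessReport(n_features_in=X.shape[1])
    pos = X.where(X > 0)
    col_min = pos.min(axis=0)
    dead = col_min.isna()
    if dead.any():
        raise ValueError(
            f"feature(s) with no observed positive value (should have been "
            f"filtered): {list(X.columns[dead])[:5]}")
    fill = col_min * fraction
    is_na = X.isna()
    is_zero = X.eq(0) & ~is_na
    report.n_imputed_cells = int((is_na | is_zero).to_numpy().sum())
    report.n_imputed_zeros = int(is_zero.to_numpy().sum())
    X = X.mask(is_na | is_zero, fill, axis=1)
    return FeatureTable(X, table.sample_meta.copy(),
                        table.feature_meta.copy()), report


def log10_transform(table: FeatureTable) -> FeatureTable:
    """Elementwise base-10 logarithm; every value must be strictly positive."""
    X = table.abundances
    bad = ~(X > 0)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(f"nonpositive value at sample {X.index[r]!r}, "
                         f"feature {X.columns[c]!r}")
    return FeatureTable(np.log10(X), table.sample_meta.copy(),
                        table.feature_meta.copy())


@dataclass
class Scaler:
    """Per-column centering/scaling parameters learned from a matrix."""

    mean: pd.Series
    sd: pd.Series
    dropped: list

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = self.mean.index
        missing = cols.difference(X.columns)
        if len(missing):
            raise KeyError(f"columns absent at transform: {list(missing)[:5]}")
        return (X[cols] - self.mean) / self.sd


def autoscale_fit(X: pd.DataFrame) -> Scaler:
    """Learn mean/SD (ddof=1) per column; constant columns are dropped."""
    if len(X) < 2:
        raise ValueError("autoscaling needs at least 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd <= 0
    dropped = list(X.columns[constant])
    return Scaler(mean[~constant], sd[~constant], dropped)


def autoscale(X: pd.DataFrame | np.ndarray
              ) -> tuple[pd.DataFrame | np.ndarray, np.ndarray, np.ndarray]:
    """Center each column to mean 0 and scale to sample SD 1 (ddof=1).

    Returns ``(scaled, means, sds)``.  Constant columns are removed (a
    shrunk matrix is returned).  Accepts a DataFrame or a bare array.
    """
    as_array = not isinstance(X, pd.DataFrame)
    Xd = pd.DataFrame(X) if as_array else X
    scaler = autoscale_fit(Xd)
    out = scaler.transform(Xd)
    if as_array:
        return out.to_numpy(), scaler.mean.to_numpy(), scaler.sd.to_numpy()
    return out, scaler.mean, scaler.sd


def preprocess_block(table: FeatureTable, norm_mode: NormMode,
                     real_threshold: float = 0.75, qc_threshold: float = 0.50,
                     cv_max: float = 30.0, impute_fraction: float = 1 / 5
                     ) -> tuple[FeatureTable, PreprocessReport]:
    """Full chain up to (and including) log10; autoscaling is left to the
    modelling stage so it can be fit on training samples only.  The report's
    QC CVs are recomputed after normalization."""
    t, report = filter_missing(table, real_threshold, qc_threshold)
    t, r2 = filter_cv(t, cv_max)
    report.merge(r2)
    t = normalize(t, norm_mode)
    report.normalization_mode = norm_mode
    report.qc_cv_percent = qc_cv_percent(t)
    t, r3 = impute_min_fraction(t, impute_fraction)
    report.merge(r3)
    t = log10_transform(t)
    return t, report
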