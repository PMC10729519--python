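"""AFP-rule benchmark and cohort contingency statistics.

The clinical comparator is the serum AFP rule: a sample is called HCC when
AFP exceeds 20 ng/mL (the standard reference upper limit; a value exactly
at 20 is negative).  AFP accuracy is computed over HCC samples only, on the
same Kennard-Stone train/test partition the omics classifiers use, so the
comparison rows line up sample-for-sample.

Cohort characteristics tables (categorical rows such as gender, age bin, or
marker positivity by class) are compared with a Pearson chi-square test for
r x c tables and a two-sided Fisher exact test for 2 x 2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .split import SplitAssignment


@dataclass
class ContingencyResult:
    observed: np.ndarray
    test: str                      # "chi_square" | "fisher_exact"
    p_value: float
    statistic: float | None = None
    df: int | None = None


@dataclass
class AFPBenchmark:
    threshold: float
    accuracy_train: float          # percent, over HCC samples
    accuracy_test: float
    n_train: int
    n_test: int
    n_excluded: int                # samples without a determined AFP


def chi_square_rxc(table: Sequence[Sequence[float]]) -> ContingencyResult:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("negative cell count")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return ContingencyResult(observed=obs, test="chi_square",
                             p_value=float(p), statistic=float(stat),
                             df=int(df))


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> ContingencyResult:
    """Two-sided Fisher exact test: p is the total probability of all tables
    with the observed margins no more probable than the observed one."""
    obs = np.asarray(table, dtype=int)
    if obs.shape != (2, 2):
        raise ValueError("need a 2 x 2 table")
    if (obs < 0).any():
        raise ValueError("negative cell count")
    _, p = stats.fisher_exact(obs, alternative="two-sided")
    return ContingencyResult(observed=obs.astype(float), test="fisher_exact",
                             p_value=float(p))


def fisher_exact_2x2_enumerated(table: Sequence[Sequence[int]]) -> float:
    """Independent enumeration of the two-sided Fisher p-value over every
    table compatible with the observed margins (oracle-grade, margins
    should stay modest)."""
    obs = np.asarray(table, dtype=int)
    r1, r2 = obs.sum(axis=1)
    c1, _ = obs.sum(axis=0)
    n = obs.sum()

    def log_p(a: int) -> float:
        b, c, d = r1 - a, c1 - a, r2 - (c1 - a)
        return (lgamma(r1 + 1) + lgamma(r2 + 1) + lgamma(c1 + 1)
                + lgamma(n - c1 + 1) - lgamma(n + 1) - lgamma(a + 1)
                - lgamma(b + 1) - lgamma(c + 1) - lgamma(d + 1))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    lp_obs = log_p(int(obs[0, 0]))
    total = 0.0
    for a in range(lo, hi + 1):
        lp = log_p(a)
        if lp <= lp_obs + 1e-9:       # tolerance for float ties
            total += np.exp(lp)
    return min(1.0, total)


def afp_classify(afp: Sequence[float], threshold: float = 20.0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """HCC-positive flags from AFP values.

    Returns ``(positive, determined)``: positive iff AFP > threshold (a
    value exactly at the threshold is negative); samples with missing AFP
    are excluded via the ``determined`` mask.
    """
    a = np.asarray(afp, dtype=float)
    determined = np.isfinite(a)
    positive = determined & (a > threshold)
    return positive, determined


def afp_benchmark(sample_meta: pd.DataFrame, split: SplitAssignment,
                  threshold: float = 20.0) -> AFPBenchmark:
    """AFP-rule accuracy over HCC samples of each split partition."""
    assign = split.assignment
    acc, counts = {}, {}
    excluded = 0
    for part in ("train", "test"):
        ids = assign.index[(assign["split"] == part)
                           & (assign["class"] == "HCC")]
        afp = sample_meta.loc[ids, "afp"]
        positive, determined = afp_classify(afp.to_numpy(), threshold)
        excluded += int((~determined).sum())
        n = int(determined.sum())
        acc[part] = 100.0 * positive.sum() / n if n else np.nan
        counts[part] = n
    return AFPBenchmark(threshold=threshold, accuracy_train=acc["train"],
                        accuracy_test=acc["test"], n_train=counts["train"],
                        n_test=counts["test"], n_excluded=excluded)


def compare_methods(split: SplitAssignment,
                    omics_hcc_accuracy: Mapping[str, Mapping[str, float]],
                    afp: AFPBenchmark) -> pd.DataFrame:
    """HCC-classification accuracy rows, one per method, on the shared split.

    ``omics_hcc_accuracy`` maps a method name (e.g. ``plsda_metabolomics``)
    to ``{"train": %, "cv": %, "test": %}`` computed on the same
    SplitAssignment.  Raises when sample counts disagree with the split.
    """
    class_counts = split.class_counts()
    n_hcc = {p: int(class_counts.loc["HCC", p]) for p in ("train", "test")}
    if afp.n_train + afp.n_test + afp.n_excluded != n_hcc["train"] + n_hcc["test"]:
        raise ValueError("AFP benchmark computed on a different split")
    rows = []
    for method, accs in omics_hcc_accuracy.items():
        rows.append({"method": method,
                     "accuracy_train": accs.get("train", np.nan),
                     "accuracy_cv": accs.get("cv", np.nan),
                     "accuracy_test": accs.get("test", np.nan),
                     "n_train": n_hcc["train"], "n_test": n_hcc["test"]})
    rows.append({"method": "AFP", "accuracy_train": afp.accuracy_train,
                 "accuracy_cv": np.nan, "accuracy_test": afp.accuracy_test,
                 "n_train": afp.n_train, "n_test": afp.n_test})
    return pd.DataFrame(rows).set_index("method")


# ---------------------------------------------------------------------------
# reference cohort characteristics (printed class-by-category counts of the
# 102-patient HCV-positive population the synthetic generator emulates);
# rows are category bins, columns HCC / HCV / MC where determined

COHORT_GENDER_TABLE = np.array([[49, 20],   # HCC: male, female
                                [14, 9],    # HCV
                                [5, 5]])    # MC

COHORT_AGE_TABLE = np.array([[17, 52],      # HCC: <=65, >65
                             [20, 3],       # HCV
                             [4, 6]])       # MC

# liver-function 2x2 tables, HCC vs MC (not determined for HCV)
COHORT_ALT_TABLE = np.array([[6, 63],       # HCC: <=33, >33 U/L
                             [4, 6]])       # MC
COHORT_AST_TABLE = np.array([[6, 63],       # HCC: <=32, >32 U/L
                             [2, 8]])       # MC
COHORT_GGT_TABLE = np.array([[17, 52],      # HCC: <=40, >40 U/L
                             [7, 3]])       # MC


def cohort_summary() -> pd.DataFrame:
    """Chi-square / Fisher p-values for the reference cohort tables.

    2 x 3-class tables use Pearson chi-square; 2 x 2 tables use the
    two-sided Fisher exact test.
    """
    rows = {}
    for name, tbl in (("gender", COHORT_GENDER_TABLE),
                      ("age_over_65", COHORT_AGE_TABLE)):
        res = chi_square_rxc(tbl)
        rows[name] = dict(test=res.test, statistic=res.statistic,
                          df=res.df, p_value=res.p_value)
    for name, tbl in (("ALT_over_33", COHORT_ALT_TABLE),
                      ("AST_over_32", COHORT_AST_TABLE),
                      ("GGT_over_40", COHORT_GGT_TABLE)):
        res = fisher_exact_2x2(tbl)
        rows[name] = dict(test=res.test, statistic=np.nan, df=np.nan,
                          p_value=res.p_value)
    return pd.DataFrame(rows).T
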