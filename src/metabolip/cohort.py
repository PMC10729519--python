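"""Synthetic plasma metabo-lipidomics cohort generator.

Emulates a three-class HCV-positive study population — hepatocellular
carcinoma (HCC), chronic HCV infection, and mixed cryoglobulinemia (MC) —
profiled on two LC-MS blocks: a polar-metabolite block (~160 annotated
features) and a lipid block (~120 features plus class-specific internal
standards).  The generator reproduces the statistical structure the
downstream chemometric pipeline assumes:

* log-normal feature abundances with per-feature baselines and additive
  class offsets on the log10 scale, organised by feature-group tags
  (short/medium/long-chain acylcarnitines, polar marker metabolites,
  lysophosphatidylcholines, phosphatidylcholines, ...);
* pooled quality-control (QC) samples built as the mean of all study
  samples with multiplicative replicate noise of a configurable CV;
* left-censored missingness concentrated at low abundance, mimicking MS
  detection limits;
* serum AFP (alpha-fetoprotein, ng/mL) drawn from a two-component
  log-normal mixture calibrated so the expected fraction above the
  20 ng/mL clinical threshold matches each class's configured rate
  (AFP is not determined for MC patients and is recorded as missing);
* age and gender matching the marginal proportions of the emulated cohort
  (e.g. 75% of HCC patients older than 65).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("HCC", "HCV", "MC")

METABOLOMICS = "metabolomics"
LIPIDOMICS = "lipidomics"


@dataclass(frozen=True)
class EffectTemplate:
    """A group of features sharing per-class abundance offsets (log10 units)."""

    tag: str
    block: str
    n_features: int
    offsets: Mapping[str, float] = field(default_factory=dict)
    #: lipid class used for internal-standard mapping (lipidomics only)
    lipid_class: str | None = None

    def offset(self, group: str) -> float:
        return float(self.offsets.get(group, 0.0))

    @property
    def has_effect(self) -> bool:
        return any(abs(v) > 0 for v in self.offsets.values())


def default_effect_templates(scale: float = 1.0) -> list[EffectTemplate]:
    """Feature-group templates mirroring the differential trends the pipeline
    is meant to recover: short- and long-chain acylcarnitines elevated in HCC,
    medium-chain acylcarnitines elevated in HCV, polar marker metabolites
    highest in HCC, LPCs strongly reduced in HCC, PCs elevated in both HCC and
    HCV relative to MC.  ``scale=0`` yields a null cohort (no class effects).

    With the default within-class SD of 0.2 log10 units, ``scale=1`` places
    the main offsets at 3 baseline SDs.  Exactly 20 feature columns carry a
    class effect (12 metabolites + 8 lipids); the rest are pure noise.
    """
    s = scale

    def t(tag, block, n, lipid_class=None, **offsets):
        return EffectTemplate(tag, block, n, {k: v * s for k, v in offsets.items()},
                              lipid_class=lipid_class)

    return [
        # metabolomics: 12 signal + 148 null = 160
        t("CAR-short", METABOLOMICS, 3, HCC=0.6),
        t("CAR-medium", METABOLOMICS, 3, HCV=0.6),
        t("CAR-long", METABOLOMICS, 3, HCC=0.6),
        t("polar-marker", METABOLOMICS, 3, HCC=0.6, HCV=0.3),
        t("metabolite", METABOLOMICS, 148),
        # lipidomics: 8 signal + 112 null = 120
        t("LPC", LIPIDOMICS, 5, lipid_class="LPC", HCC=-0.6, HCV=-0.2),
        t("PC", LIPIDOMICS, 3, lipid_class="PC", HCC=0.5, HCV=0.6),
        t("TG", LIPIDOMICS, 40, lipid_class="TG"),
        t("SM", LIPIDOMICS, 40, lipid_class="SM"),
        t("PE", LIPIDOMICS, 32, lipid_class="PE"),
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the emulated study: class sizes 69/23/10, AFP
    positivity (>20 ng/mL) in 35/69 HCC, 1/23 HCV and 0/10 MC patients,
    pooled-QC replicate CV of 10%, and left-censored missingness.
    """

    n_hcc: int = 69
    n_hcv: int = 23
    n_mc: int = 10
    n_qc: int = 8
    n_metabolites: int = 160
    n_lipids: int = 120
    effect_templates: Sequence[EffectTemplate] = field(
        default_factory=default_effect_templates)
    base_log10_mean: float = 5.0
    base_log10_sd: float = 0.2
    baseline_spread: float = 1.5
    qc_noise_cv: float = 0.10
    missing_rate_low_abundance: float = 0.3
    low_abundance_quantile: float = 0.05
    afp_positive_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"HCC": 35 / 69, "HCV": 1 / 23, "MC": 0.0})
    age_over65_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"HCC": 52 / 69, "HCV": 3 / 23, "MC": 6 / 10})
    male_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"HCC": 49 / 69, "HCV": 14 / 23, "MC": 5 / 10})
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hcc", "n_hcv", "n_mc", "n_qc", "n_metabolites", "n_lipids"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("qc_noise_cv", "missing_rate_low_abundance",
                     "low_abundance_quantile"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for frac_map in (self.afp_positive_fraction, self.age_over65_fraction,
                         self.male_fraction):
            for g, v in frac_map.items():
                if not 0 <= v <= 1:
                    raise ValueError(f"fraction for {g} must be in [0, 1]")
        counts = dict(zip(GROUPS, (self.n_hcc, self.n_hcv, self.n_mc)))
        for tmpl in self.effect_templates:
            for g in tmpl.offsets:
                if g not in GROUPS:
                    raise ValueError(f"effect template {tmpl.tag!r} references "
                                     f"unknown group {g!r}")
                if abs(tmpl.offsets[g]) > 0 and counts[g] == 0:
                    raise ValueError(
                        f"effect template {tmpl.tag!r} references group {g!r} "
                        "which has zero samples")
            if tmpl.block not in (METABOLOMICS, LIPIDOMICS):
                raise ValueError(f"unknown block {tmpl.block!r}")

    @property
    def class_sizes(self) -> dict[str, int]:
        return {"HCC": self.n_hcc, "HCV": self.n_hcv, "MC": self.n_mc}

    def signal_feature_tags(self) -> list[str]:
        return [t.tag for t in self.effect_templates if t.has_effect]

    def null(self) -> "CohortConfig":
        """Copy of this config with every class offset set to zero."""
        templates = [EffectTemplate(t.tag, t.block, t.n_features, {},
                                    lipid_class=t.lipid_class)
                     for t in self.effect_templates]
        d = asdict(self)
        d["effect_templates"] = templates
        return CohortConfig(**d)


@dataclass
class FeatureTable:
    """Samples x features abundance matrix with sample and feature metadata.

    ``abundances``: DataFrame indexed by sample id, columns = feature ids,
    NaN marks a missing (undetected) entry.  ``sample_meta`` is indexed by
    sample id with columns ``group`` (HCC/HCV/MC, NaN for QC pools),
    ``sample_type`` (study/QC), ``afp`` (ng/mL, NaN if not determined),
    ``age`` and ``gender``.  ``feature_meta`` is indexed by feature id with
    columns ``block``, ``tag`` (feature-group tag) and ``is_id``
    (internal-standard feature id, NaN outside lipidomics).
    """

    abundances: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.abundances.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.abundances.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        if not self.abundances.index.equals(self.sample_meta.index):
            raise ValueError("abundances / sample_meta index mismatch")
        if not self.abundances.columns.equals(self.feature_meta.index):
            raise ValueError("abundances / feature_meta index mismatch")

    # -- masks ---------------------------------------------------------------
    @property
    def study_mask(self) -> pd.Series:
        return self.sample_meta["sample_type"] == "study"

    @property
    def qc_mask(self) -> pd.Series:
        return self.sample_meta["sample_type"] == "QC"

    @property
    def groups(self) -> pd.Series:
        """Class labels of study samples, in table order."""
        return self.sample_meta.loc[self.study_mask, "group"]

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        cols = pd.Index(feature_ids)
        missing = cols.difference(self.abundances.columns)
        if len(missing):
            raise KeyError(f"unknown feature ids: {list(missing)[:5]}")
        return FeatureTable(self.abundances[cols].copy(),
                            self.sample_meta.copy(),
                            self.feature_meta.loc[cols].copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        rows = pd.Index(sample_ids)
        return FeatureTable(self.abundances.loc[rows].copy(),
                            self.sample_meta.loc[rows].copy(),
                            self.feature_meta.copy())

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.abundances.copy(), self.sample_meta.copy(),
                            self.feature_meta.copy())


# ---------------------------------------------------------------------------
# generation

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, lower: float = -np.inf,
                      upper: float = np.inf) -> np.ndarray:
    a, b = (lower - mean) / sd, (upper - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=size)
    return mean + sd * stats.norm.ppf(u)


def generate_afp(groups: Sequence[str], fractions: Mapping[str, float],
                 seed: int, measured: Mapping[str, bool] | None = None,
                 threshold: float = 20.0) -> np.ndarray:
    """Draw per-sample AFP (ng/mL) from a two-component log-normal mixture.

    For each sample, membership in the AFP-positive component is Bernoulli
    with the class's configured fraction; positive values are truncated above
    ``threshold`` and negative values truncated at or below it, so the
    expected exceedance per class equals the configured fraction exactly.
    Classes flagged unmeasured (by default MC, where AFP is not determined)
    receive NaN.
    """
    groups = np.asarray(groups, dtype=object)
    for g, f in fractions.items():
        if not 0 <= f <= 1:
            raise ValueError(f"fraction for {g!r} must be in [0, 1]")
    if measured is None:
        measured = {"MC": False}
    rng = np.random.default_rng(seed)
    n = len(groups)
    afp = np.full(n, np.nan)
    log_thr = np.log10(threshold)
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        if not measured.get(g, True):
            continue
        f = float(fractions.get(g, 0.0))
        pos = rng.random(len(idx)) < f
        vals = np.empty(len(idx))
        n_pos = int(pos.sum())
        if n_pos:
            vals[pos] = 10 ** _truncated_normal(
                rng, 2.2, 0.5, n_pos, lower=log_thr + 1e-9)
        if len(idx) - n_pos:
            vals[~pos] = 10 ** _truncated_normal(
                rng, 0.9, 0.35, len(idx) - n_pos, upper=log_thr)
        afp[idx] = vals
    return afp


def _sample_meta(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    labels = (["HCC"] * config.n_hcc + ["HCV"] * config.n_hcv
              + ["MC"] * config.n_mc)
    sample_ids = [f"S{i + 1:03d}" for i in range(len(labels))]
    groups = np.asarray(labels, dtype=object)

    over65 = np.empty(len(labels), dtype=bool)
    male = np.empty(len(labels), dtype=bool)
    for g in GROUPS:
        idx = np.flatnonzero(groups == g)
        over65[idx] = rng.random(len(idx)) < config.age_over65_fraction.get(g, 0.5)
        male[idx] = rng.random(len(idx)) < config.male_fraction.get(g, 0.5)
    age = np.where(over65,
                   rng.integers(66, 86, size=len(labels)),
                   rng.integers(40, 66, size=len(labels)))
    afp = generate_afp(groups, config.afp_positive_fraction,
                       seed=int(rng.integers(2 ** 31)))
    meta = pd.DataFrame({
        "group": groups, "sample_type": "study", "afp": afp,
        "age": age, "gender": np.where(male, "M", "F"),
    }, index=pd.Index(sample_ids, name="sample_id"))

    qc_ids = [f"QC{i + 1:02d}" for i in range(config.n_qc)]
    qc = pd.DataFrame({
        "group": np.nan, "sample_type": "QC", "afp": np.nan,
        "age": np.nan, "gender": np.nan,
    }, index=pd.Index(qc_ids, name="sample_id"))
    return pd.concat([meta, qc])


def _expand_templates(config: CohortConfig, block: str
                      ) -> tuple[list[str], list[str], list[str | None]]:
    """Feature ids, tags, lipid classes for one block; pads/truncates the
    final (null) template so the block hits its configured feature count."""
    templates = [t for t in config.effect_templates if t.block == block]
    target = config.n_metabolites if block == METABOLOMICS else config.n_lipids
    declared = sum(t.n_features for t in templates)
    counts = [t.n_features for t in templates]
    if templates and declared != target:
        counts[-1] = max(0, counts[-1] + target - declared)
    ids, tags, classes = [], [], []
    prefix = "M" if block == METABOLOMICS else "L"
    k = 0
    for t, c in zip(templates, counts):
        for j in range(c):
            k += 1
            ids.append(f"{prefix}{k:03d}_{t.tag}")
            tags.append(t.tag)
            classes.append(t.lipid_class)
    return ids, tags, classes


def _generate_block(config: CohortConfig, block: str, meta: pd.DataFrame,
                    rng: np.random.Generator) -> FeatureTable:
    ids, tags, classes = _expand_templates(config, block)
    templates = {t.tag: t for t in config.effect_templates if t.block == block}
    study = meta.index[meta["sample_type"] == "study"]
    qc = meta.index[meta["sample_type"] == "QC"]
    groups = meta.loc[study, "group"].to_numpy()

    p = len(ids)
    baseline = rng.uniform(config.base_log10_mean - config.baseline_spread,
                           config.base_log10_mean + config.baseline_spread,
                           size=p)
    offsets = np.zeros((len(study), p))
    for j, tag in enumerate(tags):
        tmpl = templates[tag]
        for g in GROUPS:
            offsets[groups == g, j] = tmpl.offset(g)
    log_vals = (baseline + offsets
                + rng.normal(0.0, config.base_log10_sd, size=(len(study), p)))
    X_study = 10.0 ** log_vals

    # QC pools: mean of all study samples + multiplicative log-normal noise
    pool = X_study.mean(axis=0)
    sigma = np.sqrt(np.log1p(config.qc_noise_cv ** 2))
    noise = np.exp(rng.normal(-sigma ** 2 / 2, sigma, size=(len(qc), p)))
    X_qc = pool[None, :] * noise

    X = np.vstack([X_study, X_qc])

    # left-censoring: low-abundance cells go missing at the configured rate
    if config.missing_rate_low_abundance > 0 and X.size:
        thr = np.quantile(X_study, config.low_abundance_quantile)
        censor = (X < thr) & (rng.random(X.shape)
                              < config.missing_rate_low_abundance)
        X = np.where(censor, np.nan, X)

    abund = pd.DataFrame(X, index=study.append(qc), columns=ids)
    fmeta = pd.DataFrame({"block": block, "tag": tags,
                          "is_id": [np.nan] * p},
                         index=pd.Index(ids, name="feature_id"))

    if block == LIPIDOMICS:
        # one constant-spike internal standard per lipid class, QC-level
        # noise only, never missing, never class-affected
        lipid_classes = sorted({c for c in classes if c is not None})
        for lc in lipid_classes:
            is_id = f"IS_{lc}"
            spike = 1.0e6
            vals = spike * np.exp(rng.normal(-sigma ** 2 / 2, sigma,
                                             size=len(abund)))
            abund[is_id] = vals
            fmeta.loc[is_id] = {"block": block, "tag": "IS", "is_id": np.nan}
        class_of = dict(zip(ids, classes))
        fmeta["is_id"] = [
            f"IS_{class_of[f]}" if f in class_of and class_of[f] else
            np.nan for f in fmeta.index]

    abund = abund[fmeta.index]
    return FeatureTable(abund, meta.copy(), fmeta)


def generate_cohort(config: CohortConfig) -> tuple[FeatureTable, FeatureTable]:
    """Generate the metabolomics and lipidomics blocks of one synthetic cohort.

    Returns ``(metabolomics, lipidomics)`` FeatureTables sharing identical
    sample metadata.  Identical config (including seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    meta = _sample_meta(config, rng)
    metab = _generate_block(config, METABOLOMICS, meta, rng)
    lipid = _generate_block(config, LIPIDOMICS, meta, rng)
    return metab, lipid


# ---------------------------------------------------------------------------
# I/O

def write_cohort(tables: Mapping[str, FeatureTable], outdir: str | Path,
                 config: CohortConfig | None = None) -> None:
    """Write one wide-format and one long-format CSV per block, plus a JSON
    sidecar with the generating config.  Missing entries are empty fields."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.abundances.to_csv(outdir / f"{name}_wide.csv")
        long = (table.abundances.stack(future_stack=True)
                .rename("abundance").reset_index())
        long.columns = ["sample_id", "feature_id", "abundance"]
        long.to_csv(outdir / f"{name}_long.csv", index=False)
        table.sample_meta.to_csv(outdir / f"{name}_samples.csv")
        table.feature_meta.to_csv(outdir / f"{name}_features.csv")
    if config is not None:
        sidecar = asdict(config)
        sidecar["effect_templates"] = [asdict(t) for t in config.effect_templates]
        with open(outdir / "config.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=float)


def read_feature_table(wide_csv: str | Path, samples_csv: str | Path,
                       features_csv: str | Path) -> FeatureTable:
    abund = pd.read_csv(wide_csv, index_col=0)
    smeta = pd.read_csv(samples_csv, index_col=0)
    fmeta = pd.read_csv(features_csv, index_col=0)
    return FeatureTable(abund, smeta, fmeta)
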