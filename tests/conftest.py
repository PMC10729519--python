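import numpy as np
import pandas as pd
import pytest

from metabolip import (CohortConfig, FeatureTable, generate_cohort,
                       METABOLOMICS)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (69/23/10 + 8 QC pools), fixed seed."""
    cfg = CohortConfig(seed=1)
    metab, lipid = generate_cohort(cfg)
    return cfg, metab, lipid


def make_table(values, sample_types=None, groups=None, block=METABOLOMICS,
               feature_ids=None, is_ids=None, tags=None):
    """Small hand-built FeatureTable for unit tests."""
    X = np.asarray(values, dtype=float)
    n, p = X.shape
    sample_ids = [f"S{i}" for i in range(n)]
    if sample_types is None:
        sample_types = ["study"] * n
    if groups is None:
        groups = [("HCC" if t == "study" else np.nan) for t in sample_types]
    if feature_ids is None:
        feature_ids = [f"F{j}" for j in range(p)]
    meta = pd.DataFrame({"group": groups, "sample_type": sample_types,
                         "afp": np.nan, "age": 60, "gender": "M"},
                        index=pd.Index(sample_ids, name="sample_id"))
    fmeta = pd.DataFrame({"block": block,
                          "tag": tags if tags is not None else "feat",
                          "is_id": is_ids if is_ids is not None else np.nan},
                         index=pd.Index(feature_ids, name="feature_id"))
    abund = pd.DataFrame(X, index=meta.index, columns=fmeta.index)
    return FeatureTable(abund, meta, fmeta)
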