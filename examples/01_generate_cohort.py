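"""Generate one synthetic metabo-lipidomics cohort and inspect its structure.

Builds the default three-class cohort (69 HCC / 23 HCV / 10 MC study
samples plus 8 pooled QC injections) with a polar-metabolite block and a
lipid block, then prints the block shapes, the QC replicate precision, and
the AFP positivity per class.
"""

import metabolip as ml

cfg = ml.CohortConfig(seed=1)
metab, lipid = ml.generate_cohort(cfg)

print("block shapes (samples x features):")
print("  metabolomics:", metab.abundances.shape)
print("  lipidomics:  ", lipid.abundances.shape,
      f"({(lipid.feature_meta['tag'] == 'IS').sum()} internal standards)")

cv = ml.qc_cv_percent(metab).dropna()
print(f"\nQC precision (metabolomics): median CV% = {cv.median():.1f}, "
      f"{100 * (cv < 20).mean():.1f}% of features below 20%")
print("-> pooled QC injections scatter ~10% around the cohort mean, the",
      "platform-stability level the CV filter assumes")

afp = metab.sample_meta.groupby("group")["afp"]
print("\nAFP > 20 ng/mL per class (NaN = not determined):")
print(afp.apply(lambda s: f"{(s > 20).sum()}/{s.notna().sum()}").to_string())
print("-> only about half of HCC patients are AFP-positive, the gap the",
      "omics classifier is meant to close")
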