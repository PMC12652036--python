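"""Classify month-24 site states and compare responder rates between arms.

A 400-tree random forest learns baseline site states from clinical indices,
cytokines, MMPs and virulence factors (features with permutation importance
below 2 percentage points are dropped).  Month-24 measurements are re-stated
by the model; improvement (P->G/H, G->H) or staying healthy counts as a
response, and the arm-by-call table is tested with a Yates-corrected
chi-square.
"""

from periomics import CohortConfig, generate_cohort
from periomics.pipeline import condition_features
from periomics.responders import responder_analysis, train_state_model

cohort = generate_cohort(CohortConfig(seed=7))
analytes = list(cohort.config.analytes)
base = condition_features(cohort.biomarkers, 0, analytes)
m24 = condition_features(cohort.biomarkers, 24, analytes)
shared = base.index.intersection(m24.index)
base, m24 = base.loc[shared], m24.loc[shared]
labels = [ix[1] for ix in base.index]
feats = [c for c in base.columns if c != "arm"]

model = train_state_model(base[feats], labels, n_trees=400, seed=12345)
print("per-class baseline accuracy (out-of-bag):")
for cls, acc in sorted(model.per_class_accuracy.items()):
    print(f"  {cls}: {acc:.1%}")
print(f"features kept by the importance filter: {', '.join(model.features)}")
# Absence of bleeding makes healthy sites nearly trivially recognisable,
# which is why the healthy class scores highest.

table = responder_analysis(model, labels, m24[feats], m24["arm"])
print("\narm x call counts:")
print(table.counts.to_string())
for arm, prop in table.proportions.items():
    print(f"  {arm}: {prop:.0%} responders")
print(f"chi-square = {table.statistic:.2f}, p = {table.p_value:.3g}")
# With the default calibration the regimen arm lands near 70% responders
# against roughly 47% for usual care.
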