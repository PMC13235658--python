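"""Synthetic oversampling with fraction-parameterized k, and a threshold sweep.

SMOTE/ADASYN/SMOTE+ENN resolve their neighbor parameter as a fraction of
the case count, so the same setting transfers across cohort sizes.  The
threshold sweep shows the sensitivity/specificity trade-off across
plausible deployment incidences (1-5%).
"""

from pcuste import (
    GeneratorConfig,
    ResamplerParams,
    SklearnRiskModel,
    apply_standardization,
    correct_prior,
    fit_standardization,
    fraction_to_k,
    generate_cohort,
    smote_enn,
    smote_oversample,
    split_cohort,
    threshold_sweep,
)
from pcuste.modeling import PriorCorrectionParams

cohort = generate_cohort(GeneratorConfig.from_reference(seed=31, exact_case_count=True))
split = split_cohort(cohort, 0.7, seed=31)
params = fit_standardization(split.train)
train, test = apply_standardization(split.train, params), apply_standardization(split.test, params)

print("k resolution as a fraction of", train.n_cases, "training cases:")
for pct in (2, 5, 10, 30, 50, 80):
    print(f"  {pct:2d}% -> k = {fraction_to_k(pct / 100, train.n_cases)}")

for fn, label in ((smote_oversample, "SMOTE"), (smote_enn, "SMOTE+ENN")):
    out = fn(train, ResamplerParams(label.replace("+", "_"), k_fraction=0.05, seed=2))
    print(f"{label}: {train.n} -> {out.data.n} rows, case prior "
          f"{train.prior:.3f} -> {out.resampled_prior:.3f}")
print("-> SMOTE balances exactly; ENN cleaning can push cases into the majority")

model = SklearnRiskModel().fit(
    smote_oversample(train, ResamplerParams("SMOTE", k_fraction=0.05, seed=2)).data
)
scores = correct_prior(model.predict_proba(test), PriorCorrectionParams(0.5, train.prior))
sweep = threshold_sweep(test.y, scores, [0.01, 0.02, 0.03, 0.04, 0.05])
print("\nthreshold sweep on the corrected test scores:")
print(sweep[["threshold", "sensitivity", "specificity", "mcc"]].round(3).to_string(index=False))
print("-> raising the cutoff trades sensitivity for specificity monotonically")
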