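"""The clinico-radiological logistic baseline on the published cohort counts.

Reproduces the univariate odds ratios from the embedded 239-patient
reference counts, screens at p < 0.1, and fits the multivariate model on
the survivors.
"""

from lvifusion.baselines import (
    build_reference_table,
    fit_multivariate_logistic,
    fit_univariate_logistic,
    score_clinical,
    screen_univariate,
)
from lvifusion.cohort import CohortSpec, calibrate_intercept, sample_clinical_features, sample_labels
from lvifusion.evaluation import compute_roc_auc

table, y = build_reference_table()
print(f"reference cohort: n={len(y)}, LVI-positive={y.sum()}")
print(f"{'variable':36s} {'OR':>6s} {'95% CI':>16s} {'p':>8s}")
for name in table.columns:
    fit = fit_univariate_logistic(table[name], y, name)
    print(f"{name:36s} {fit.odds_ratio:6.2f} ({fit.ci_low:5.2f}, {fit.ci_high:5.2f}) {fit.p_value:8.3f}")

selected, _ = screen_univariate(table, y, alpha=0.1)
print(f"\nscreened at p < 0.1: {selected}")
# Peritumoral edema (OR ~7.5) and the DWI rim sign (OR ~4.3) dominate; the
# screen admits exactly the four variables with univariate p below 0.1.

# The counts above are per-variable marginals, so the joint (multivariate)
# model is fit on a synthetic cohort with known planted effects instead.
spec = CohortSpec(n_cases=500, seed=1)
features = sample_clinical_features(spec.n_cases, spec)
labels = sample_labels(features, calibrate_intercept(spec, features),
                       spec.effect_log_odds, [spec.seed, 1])
screened, _ = screen_univariate(features, labels, alpha=0.1)
model = fit_multivariate_logistic(features[screened], labels)
print(f"\nmultivariate fit on a synthetic cohort (n={spec.n_cases}), "
      f"screened covariates {screened}:")
for res in model.results:
    print(f"  adjusted {res.name}: OR {res.odds_ratio:.2f} "
          f"({res.ci_low:.2f}, {res.ci_high:.2f}), p {res.p_value:.3f}")
auc = compute_roc_auc(score_clinical(model, features), labels).auc
print(f"clinical-model training AUC: {auc:.3f}")
# Adjusted ORs track the planted values (7.5, 4.3, 2.1) because the
# generator draws features independently.
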