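"""Full workflow on a synthetic cohort: simulate, estimate KM, fit, compare.

Simulates a three-group cohort (103 patients) from the LQRG model, fits
both the classical LQ and the LQRG model to the pooled Kaplan-Meier
samples by MAE minimization, and prints a model-quality comparison
(log-likelihood, AIC; lower AIC is better).
"""

from lqrg import fit_model, simulate_cohort
from lqrg.pipeline import PIPELINE_FREE, build_group_data
from lqrg.synthetic_cohort import default_cohort_spec

SEED = 1

records = simulate_cohort(default_cohort_spec(), seed=SEED)
groups, _curves = build_group_data(records)
m = sum(g.n_samples for g in groups)
print(f"simulated {len(records)} patients "
      f"({sum(r.event for r in records)} loco-regional events), {m} KM samples")

print(f"\n{'model':<7}{'k':>3}{'MAE':>9}{'logL':>9}{'AIC':>10}")
for model in ("lq", "lqrg"):
    fit = fit_model(model, groups, free=PIPELINE_FREE[model], seed=SEED,
                    n_starts=2, max_iter=800, tol=1e-6, patience=30)
    print(f"{model:<7}{fit.k:>3}{fit.cost:>9.4f}"
          f"{fit.log_likelihood:>9.1f}{fit.aic:>10.1f}")

print()
print("The LQRG fit reaches a much smaller mean absolute error and a lower")
print("AIC than classical LQ on LQRG-generated data: the extra shape")
print("parameters (resensitization, delayed regrowth, Gompertz decay) are")
print("needed to track the late part of the survival curve.")
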