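"""Backward-elimination covariate screening before spatial modelling.

For each disease separately, fits a multiple logistic regression and
removes, one at a time, the covariate with the largest Wald p-value above
the 0.1 threshold; age and sex are treated as a-priori covariates that are
never dropped.  A pure-noise column is included to show the screening at
work.  The retained sets feed the spatial model's per-disease design
matrices.
"""

import numpy as np

from jointmap.covariate_selection import backward_eliminate
from jointmap.synthetic_data import simulate_cohort

table, truth, _, _ = simulate_cohort("sage-like", seed=5)
rng = np.random.default_rng(5)
table["noise"] = rng.standard_normal(len(table))

candidates = ("age_c", "female", "urban", "schooling_years", "employed",
              "salt_at_table", "ever_tobacco", "noise")
X = np.column_stack(
    [np.ones(len(table))] + [table[c].to_numpy(float) for c in candidates]
)
names = ("intercept",) + candidates

for outcome, label, beta in (
    ("y_htn", "hypertension", truth.params.beta1),
    ("y_dm", "diabetes", truth.params.beta2),
):
    kept, fit = backward_eliminate(
        X, table[outcome].to_numpy(float), names,
        threshold=0.1, forced={"age_c", "female"},
    )
    print(f"--- {label} (true effects: age_c={beta[0]}, female={beta[1]}, "
          f"urban={beta[2]}, rest 0) ---")
    print("retained:", ", ".join(kept))
    for nm, b, p in zip(fit.names, fit.coef, fit.p_values):
        print(f"  {nm:16s} coef {b:+.3f}  p {p:.3f}")
    print()
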