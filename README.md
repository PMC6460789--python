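# surromix

Risk-score modeling with **partial surrogate outcomes** via mixtures of
linear regressions.

Clinical risk scores are often trained on a surrogate outcome S (readily
measured) rather than the target outcome T (the quantity that matters). A
*partial surrogate* tracks T only inside a latent subpopulation **V** and is
noise in the complement **I** — the motivating example is postoperative serum
creatinine change as a surrogate for 90-day kidney-function decline, which is
informative only in patients whose injury exceeded their renal functional
reserve. Training a single pooled regression on such data averages two
different covariate–outcome relationships; the resulting score can look
excellent against the surrogate while ordering patients poorly on the target.

surromix is for biostatisticians and clinical modelers who suspect this
structure in their data. It provides:

* **`mixture_engine`** — EM fitting of a K-component mixture of linear
  regressions, s | z, k ~ N(α_k + z'β_k, σ_k²), with unconstrained component
  variances, random restarts, a variance-floor degeneracy guard, BIC with
  q = K(p+2)+K−1 parameters, relative classification entropy
  1 − Σ(−τ ln τ)/(n ln K), post-hoc identification of the informative
  component (largest mean |slope|), and modal assignment.
* **`risk_scoring`** — linear predictors as risk scores (the informative
  component's predictor applied to *all* subjects), plus the three
  surrogate-score screening criteria: covariates associated with S (R1) and
  with T (R2), and the concordance criterion
  R3: P(R_i < R_j | T_i < T_j) > ½.
* **`evaluation`** — Mann–Whitney AUC (optionally weighted) with CIs, a
  placement-value test for correlated AUC differences, Spearman's ρ with a
  subject-swap permutation test for dependent correlations, logistic
  observation-propensity weights for missing targets, and a weighted-AUC
  sweep over target cutoffs 5–25.
* **`synthetic_cohort`** — a generator for cohorts with the assumed
  structure (10 covariates, latent V/I membership, scenario-specific
  surrogate models) so everything is testable without any data download.
* **`simulation_study`** — end-to-end replication studies of the two
  canonical scenarios (invalid subpopulation with a random phenotype vs. a
  null phenotype), summarized as mean (0.05, 0.95) quantiles.

See `docs/methods.md` for the model, the numerical choices and the
generator's calibration.

## Worked example

```python
import numpy as np
from surromix import (
    generate_cohort, fit_linear, em_fit, bic,
    identify_informative_component, build_risk_scores,
    discrimination_report,
)

cohort = generate_cohort(4737, scenario="sim2", seed=7)

linear = fit_linear(cohort.Z, cohort.S)
mix = em_fit(cohort.Z, cohort.S, K=2, n_starts=10, seed=7)
k = identify_informative_component(mix)
print(f"BIC linear {bic(linear):.1f} vs mixture {mix.bic:.1f}; "
      f"entropy {mix.relative_entropy:.3f}; informative component {k}")

scores = build_risk_scores(linear, mix, cohort.Z, S=cohort.S)
report = discrimination_report(scores.scores, cohort.T, cutoff=20.0,
                               n_perm=2000, seed=7)
for name, (auc, ci) in report.auc.items():
    print(f"AUC[{name}] = {auc:.3f} ({ci[0]:.3f}, {ci[1]:.3f})")
print("paired AUC p (mixture_V vs linear):",
      round(report.auc_p_values[("linear", "mixture_V")], 4))
```

Output:

```
BIC linear 6766.5 vs mixture 6514.9; entropy 0.617; informative component 1
AUC[raw_surrogate] = 0.582 (0.565, 0.600)
AUC[linear] = 0.953 (0.948, 0.959)
AUC[mixture_V] = 0.963 (0.958, 0.967)
paired AUC p (mixture_V vs linear): 0.0
```

The mixture is preferred by BIC and its moderately separated posteriors
(entropy 0.62) identify an informative component whose prediction
discriminates the target event (a decline beyond 20 units, 0.4 SD) better
than the pooled linear score and far better than the raw surrogate — the
signature of a partial surrogate handled correctly: most subjects' surrogate
is noise, so the raw measurement orders the target barely better than
chance, while the covariate-based scores recover the shared signal. The
paired test of correlated AUCs rejects equality of the mixture and linear
scores at any conventional level (p below the reporting resolution).

The same pipeline is scriptable from the shell:

```bash
surromix simulate-cohort --n 4737 --scenario sim2 --seed 7 --out cohort.csv
surromix fit-mixture --input cohort.csv --k 2 --seed 7 --out model.json
surromix score --input cohort.csv --model model.json --out scored.csv
surromix evaluate --input scored.csv --cutoff 20 --out report.json
surromix sweep --input scored.csv --propensity ipw --out sweep.csv
surromix simstudy --scenario 1 --n 2000 --reps 200 --seed 1 --out-dir study/
```

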