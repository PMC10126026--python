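# relicred

Bayesian single-test reliability analysis as a scriptable library and CLI.

`relicred` estimates five reliability coefficients — McDonald's ω,
Cronbach's α, Guttman's λ₂ and λ₆, and the greatest lower bound (glb) —
from an item-response table, reporting full posterior distributions,
posterior point estimates, highest-posterior-density (HPD) credible
intervals, and prior/posterior probabilities that a coefficient lies in a
user-chosen interval. It also provides:

- **if-item-dropped analysis** with orderings by posterior-mean difference,
  Kullback–Leibler divergence, or Kolmogorov–Smirnov distance, plus
  item-rest correlations;
- **MCMC convergence diagnostics**: Gelman–Rubin R-hat and traceplot data;
- **posterior-predictive checking** of the unidimensional factor model via
  covariance eigenvalue bands;
- **Bayesian fit measures** (BRMSEA, BCFI, BTLI and a likelihood-ratio
  statistic) with posterior tail probabilities;
- **missing-data handling** by listwise deletion or Bayesian imputation
  (data augmentation inside the samplers);
- **synthetic data generators** for unidimensional, arbitrary-covariance,
  and two-factor (misfit) item responses with optional MCAR missingness.

The CTT coefficients (α, λ₂, λ₆, glb) use a conjugate inverse-Wishart
posterior on the item covariance matrix; ω comes from a Gibbs sampler for
the single-factor model (inverse-gamma priors on residual variances, a
zero-centered normal prior on loadings scaled by the residual variances,
and a scalar inverse-Wishart prior on the latent variance).

## Quick start (library)

```python
import relicred as rc

data = rc.load_example()          # bundled 78 x 5 example questionnaire
config = rc.AnalysisConfig(
    coefficients=("omega", "alpha"),
    prob_interval=(0.70, 0.90),
    seed=1,
)
result = rc.run_analysis(data, config)
for row in result.table:
    print(row.coefficient, row.estimate, row.hpd_lower, row.hpd_upper)
rc.write_report(result, "report.json")
```

Deterministic: the same seed reproduces the summary table bit-for-bit.

## Quick start (CLI)

```sh
# full analysis of a CSV (header row; cells "NA" or empty are missing)
relicred run data.csv -c omega -c alpha --prob-interval 0.70 0.90 \
    --if-item-dropped kl --ppc --fit-measures --seed 1 --out report.json

# desk-check a coefficient on a covariance matrix
relicred coef sigma.csv --coefficient glb

# synthetic unidimensional data with a target omega
relicred simulate --n 78 --k 5 --omega 0.8 --seed 1 --out sim.csv
```

`relicred run --config analysis.yaml` reads the same options from YAML;
explicit flags win over the file.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end checks (closed-form
coefficient values, prior calibration, reproduction of the bundled
example, parameter recovery, posterior-predictive calibration, and the
conjugacy oracle). The rest of the suite covers each module with unit and
property tests.

## Package layout

| module | contents |
| --- | --- |
| `relicred.data` | `ItemResponseMatrix`, CSV reader, bundled example |
| `relicred.config` | analysis / MCMC / prior configuration |
| `relicred.estimators` | α, λ₂, λ₆, glb, ω, item-rest correlation |
| `relicred.ctt` | inverse-Wishart covariance posterior + imputation |
| `relicred.factor` | Gibbs sampler for the single-factor model |
| `relicred.summaries` | point estimates, HPD, interval probabilities, KL/KS, densities |
| `relicred.item_dropped` | if-item-dropped analysis |
| `relicred.diagnostics` | R-hat, traceplots, PPC, Bayesian fit measures |
| `relicred.simulate` | synthetic-data generators |
| `relicred.analysis` | orchestration and report writing |
| `relicred.cli` | `relicred` command-line entry point |
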