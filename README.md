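# bladtox

Modelling late genitourinary (bladder) toxicity after prostate radiotherapy
from dose–volume histograms.

Radiation oncologists constrain the dose a bladder receives by limiting
*V_dose* — the fraction of the organ receiving at least a given dose. This
package implements the full modelling chain used to derive such constraints
from a treated cohort:

- **DVH handling** (`bladtox.dvh`): cumulative ↔ differential conversion,
  V_dose interpolation, CSV readers/writers with unit normalization
  (fraction / percent / cm³).
- **Dose-response models** (`bladtox.models`): the generalized equivalent
  uniform dose gEUD = (Σᵢ vᵢ Dᵢᵃ)^{1/a} with bladder exponent a = 1.4, and the
  logistic normal-tissue complication probability
  NTCP(EUD) = 1 / (1 + (TD₅₀/EUD)^{4γ₅₀}), with maximum-likelihood fitting of
  (TD₅₀, γ₅₀) and of univariate logistic risk models P = σ(a + b·X).
- **Threshold search** (`bladtox.scan`): an iterative AIC-minimizing scan over
  candidate doses d, fitting toxicity ~ V_d at each and selecting the dose with
  the lowest AIC among models with Wald p < 0.05 (0.1 Gy refinement pass).
- **Internal validation** (`bladtox.validation`): bootstrap resampling
  (B datasets of the original size, median AUC), Hosmer–Lemeshow calibration
  over risk deciles, calibration-curve data.
- **Clinical risk tables** (`bladtox.risk_table`): inversion of a fitted
  logistic model into "keep V_dose below X% to keep risk below r%" constraints.
- **Synthetic cohorts** (`bladtox.synthetic`): sigmoid-DVH cohorts with a known
  generating logistic truth, so every stage is testable with parameter-recovery
  oracles.
- **Pipeline & CLI** (`bladtox.pipeline`, `bladtox` console script): the whole
  chain, reproducible from config + seed.

## Worked example

Run the pipeline on a 2000-patient synthetic cohort whose toxicity is driven
by the volume fraction at 51.43 Gy through P = σ(−2.5 + 4.3·V):

```python
from bladtox import RunConfig, CohortSpec, run_pipeline

config = RunConfig(cohort_spec=CohortSpec(n=2000, seed=1),
                   bootstrap_B=200, seed=1, outdir="demo_run")
manifest = run_pipeline(config)
print(manifest["selected_dose_gy"], manifest["final_fit"])
```

prints (seed 1):

```
selected_dose_gy: 51.5
final_fit: {'intercept': -2.491, 'slope': 4.381, 'p': 0.0, 'aic': 2309.9636}
validation: {'auc_apparent': 0.7658, 'auc_median': 0.7667, ..., 'hl_p': 0.9451}
```

The scan recovers the generating 51.43 Gy threshold at 51.5 Gy, the logistic
fit recovers the generating coefficients (−2.5, 4.3) within sampling error,
and the Hosmer–Lemeshow p = 0.95 shows no lack of fit for this correctly
specified model. `demo_run/risk_table.txt` renders the fitted model as
dose-volume constraints:

```
V51.5 volume (%)    Risk of toxicity
<6.7%               <10.0%
<25.2%              <20.0%
<56.9%              <50.0%
```

i.e. keeping less than 25.2% of the bladder inside the 51.5 Gy isodose keeps
the predicted toxicity risk below 20%. The same stages are available as CLI
subcommands (`bladtox simulate|scan|fit|validate|risk-table|ntcp|run-all`).

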