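# grsmr

Genetic-risk-score Mendelian randomization of blood pressure on
categorical kidney outcomes.

## The scientific problem

Observational cohorts show strong associations between blood pressure (BP)
and chronic kidney disease (CKD), but reverse causality (early kidney
disease raises BP) and confounding make the causal direction hard to pin
down, and randomized BP-lowering trials have been equivocal for kidney
endpoints.  Mendelian randomization (MR) sidesteps both problems by using
genetic variants — allocated at conception — as instruments for life-long
BP.  A further wrinkle is that the BP–kidney-function relation may be
U-shaped: higher BP may cause both *decreased* filtration (eGFR < 60) and
glomerular *hyperfiltration* (eGFR ≥ 120), so analyses of continuous eGFR
can miss the effect entirely.  This package implements the full analysis
for that question, aimed at genetic epidemiologists who want a tested,
reusable version of the design:

* **phenotype derivation** — measured BP as the mean of two readings with
  the +15/+10 mmHg treatment correction; CKD-EPI eGFR from creatinine and
  cystatin C; clinical eGFR/uACR categories; the CKD composite
  (kidney replacement therapy, eGFR < 60 mL/min/1.73m², or uACR ≥ 3
  mg/mmol);
* **genetic risk scores** — allele harmonization (flips, palindromic
  drops), weighted dosage sums `score_i = Σ_j w_j x_ij`, variance
  explained, Table-1-style quintile summaries;
* **one-sample MR** — logistic and multinomial-logistic GRS models scaled
  to odds ratios per 10 mmHg systolic / 5 mmHg diastolic BP via an internal
  calibration regression, with multivariable (predicted-mediator)
  adjustment, subgroup and residual-characteristic stratification, and SNP
  exclusion reruns;
* **summary-data sensitivity battery** — Wald ratios, IVW, MR-Egger,
  weighted median, modified-Q outlier removal, MR-PRESSO, Steiger
  filtering;
* **conventional comparator** — confounder-adjusted cross-sectional
  estimates corrected for regression dilution using resurvey BP;
* **synthetic biobank generator** — a first-class, tested module producing
  cohorts with instrumented exposures, treated-measurement artefacts,
  confounding, pleiotropy, reverse-pathway variants and a U-shaped
  BP→eGFR structure, plus the ground-truth parameters for recovery tests.

The core estimator is the two-stage ratio: with
`β̂_GY` the log-odds of the outcome per score unit and `β̂_GX` the mmHg of
measured BP per score unit (both covariate-adjusted),

```
log OR per u mmHg = u · β̂_GY / β̂_GX ,   u = 10 (SBP) or 5 (DBP).
```

See `docs/methods.md` for the model, the generator's calibration, and all
numerical choices.

## Worked example

```python
from grsmr import RunConfig, SimConfig, run_pipeline, render_report

cfg = RunConfig(out_dir="demo_run", seed=7,
                sim=SimConfig(n_participants=50_000))
bundle = run_pipeline(cfg)
est = bundle["estimates"]
prim = est[(est.method == "grs_logistic") & (est.outcome == "ckd")]
print(prim[["trait", "or", "ci_low", "ci_high", "p"]].round(3).to_string(index=False))
```

prints (seed 7):

```
trait    or  ci_low  ci_high   p
  sbp 1.320   1.154    1.511 0.0
  dbp 1.252   1.124    1.395 0.0
```

i.e. in this 50,000-participant synthetic cohort each genetically-predicted
10 mmHg higher systolic BP is associated with 1.32-fold odds of CKD
(95% CI 1.15–1.51; the generator's true odds ratio, 1.37, lies inside the
interval), and each 5 mmHg higher diastolic BP with 1.25-fold odds
(truth 1.19).  `render_report("demo_run")` assembles the
quintile table, the forest-style estimate tables, the sensitivity battery
and a truth-vs-estimate appendix into `demo_run/report.txt`.

The same pipeline is scriptable from the shell:

```bash
grsmr simulate --out sim --seed 7
grsmr score --weights sim/weights.tsv --dosages sim/dosages.tsv --trait sbp --out scores.tsv
grsmr run --out demo_run --seed 7
grsmr report --out demo_run
```

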