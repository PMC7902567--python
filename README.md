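# tripletaft

Bayesian treatment-effect-heterogeneity analysis for first-line
chemotherapy in advanced gastric cancer: does adding docetaxel to a
platinum–fluoropyrimidine doublet (DPF vs PF) still help, and for whom?

The package is aimed at biostatisticians and outcomes researchers who
want to run — or stress-test — a registry-style comparative
effectiveness analysis end to end without access to patient-level
registry data: it ships a calibrated synthetic cohort generator with
known ground truth, so every stage of the pipeline is verifiable.

## The model

Survival endpoints (overall survival `OS`, progression-free survival
`PFS`, in months, right-censored) follow a lognormal accelerated
failure time model:

```
log T_i = x_i' β + σ ε_i,    ε_i ~ N(0, 1)
```

A coefficient `β_j` acts multiplicatively on event time: its
exponential is the **time ratio** `TR_j = exp(β_j)`, and `TR = 2` for a
binary covariate means the median time-to-event doubles. Censored
records contribute the lognormal survival function `Φ(−z_i)`.

Inference is Bayesian with three prior classes on the log-TR scale:

* **treatment effect** — an evidence-synthesis prior elicited from a
  meta-analytic hazard ratio via `mean = −ln(HR)`,
  `sd = (ln hi − ln lo)/(2·1.96)`; the packaged defaults are
  `N(0.15, 0.045)` for OS and `N(0.27, 0.07)` for PFS;
* **treatment-by-covariate interactions** — skeptical `N(0, 0.05)`,
  concentrating 99% of prior mass on subgroup deviations under ~13%;
* **nuisance terms** — weakly informative normals on unit-scaled
  covariates.

Continuous covariates (age, calendar year, neutrophil/lymphocyte
ratio) enter through restricted cubic splines (Harrell's
truncated-power basis, 3 knots by default). Missing histology is
screened (columns > 25% missing are dropped) and multiply imputed by
fully conditional specification (20 datasets by default); posteriors
are pooled across imputations as a mixture of draws. Sampling is an
adaptive Metropolis scheme (random-walk with covariance adaptation
mixed with an independence step from a Laplace approximation), checked
by split-chain Gelman–Rubin R̂ < 1.1.

Posterior summaries follow the estimands clinicians ask about:
time ratios with 95% credible intervals, exceedance probabilities
`P(TR > 1.15)` and `P(TR > 1.30)`, mass in the region of practical
equivalence (`|log TR| ≤ ln 1.10`), conditional subgroup effects, and
an individualized calculator giving per-arm predicted median survival.

## Worked example

```python
import tripletaft as ta

cohort = ta.generate_cohort(ta.default_config())      # 1376 synthetic patients
sets = ta.impute_cohort(cohort, m=5, seed=0)          # screen + FCS imputation
model = ta.BayesianAFT(endpoint="os", prior_mode="informative",
                       interactions=("lauren",), n_chains=2,
                       n_warmup=500, n_draws=1000, seed=0).fit_imputed(sets)
print(ta.subgroup_table(model.draws_, model.spec_))
```

prints (posterior over 5 pooled imputations):

```
                        label    tr  cri_lo  cri_hi  p_gt_115  p_gt_130  rope_mass
treatment (reference profile) 1.205   1.127   1.291     0.912     0.016      0.007
               lauren=diffuse 1.205   1.127   1.291     0.912     0.016      0.007
            lauren=intestinal 1.234   1.118   1.356     0.920     0.135      0.010
```

Read: under the evidence-synthesis prior, the docetaxel triplet
multiplies median OS by ~1.21 for a diffuse-subtype reference patient
(91% posterior probability of at least a 15% gain), with a slightly
larger effect in the intestinal subtype — the ordering the generator's
ground truth encodes. The individualized calculator conditions the
same posterior on one patient:

```python
profile = {"age": 58, "ecog": "0", "lauren": "intestinal", "grade": "2",
           "ascites": 0, "stage": "metastatic", "liver_burden": "none",
           "n_organs": 1, "platin": "cisplatin", "nlr": 2.5, "year": 2016}
ta.predict_median_survival(model.draws_, model.spec_, profile, arm="both")
```

```
PF:  median 14.8 months (95% CrI 12.8-17.2)
DPF: median 18.3 months (95% CrI 15.5-21.6)
conditional TR 1.23 (1.12-1.36); P(TR>1.15)=92%; P(TR>1.30)=14%; ROPE=1%
```

The same pipeline is scriptable from a shell:

```bash
tripletaft simulate --out cohort.csv
tripletaft fit --cohort cohort.csv --endpoint os --m 5 --out fit/
tripletaft summarize --fit-dir fit/ --out table.csv
tripletaft predict --fit-dir fit/ --age 58 --lauren intestinal
```

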