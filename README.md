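# sf12impute

Simulation and evaluation of missing-data imputation methods for the
items of the SF-12 health survey.

## The problem

The SF-12 measures health-related quality of life with twelve items —
six physical (PFI2, PFI4, ROLPH2, ROLPH3, PAIN2, GHP1), six mental
(VITAL2, SOC2, ROLEM2, ROLEM3, MHI3, MHI4) — each recoded to a 0–100
score. In clinical settings item nonresponse is common (often 10–20% on
single items) and is *not* missing completely at random: older and less
educated respondents omit items more often. Restricting analyses to
complete cases therefore loses power and biases the sample, and the
practical question is which imputation method best reconstructs what a
respondent would actually have answered.

`sf12impute` implements a benchmarking framework for that question:

1. **Generate** a fully observed SF-12-like cohort (two correlated
   latent health factors, designed item pairs, ordinal items, realistic
   demographics — or read your own complete data).
2. **Amputate**: simulate realistic single-item missingness. For item
   *i* and respondent *j* the missing probability comes from a logistic
   model of the response indicator on age and education,
   `p_ij = 1 − expit(b0 + b_age·age + b_ssc·ssc + b_ueq·ueq)`, and is
   attenuated so its average hits the item's target rate *h_i*:
   `p_ij,adjust = p_ij · h_i / p̄_i`. A Bernoulli indicator (SIV) masks
   the item; the procedure is replicated R times per item.
3. **Impute** the masked cells with seven methods behind one interface:
   item mean (IMV), person mean over the remaining subscale items (PMV),
   stochastic regression with resampled-residual or Student-*t* errors
   (SR_RESID, SR_T), conditional means under an EM-estimated joint
   normal (EM), and two multiple-imputation samplers — joint-normal data
   augmentation (MI_DA) and fully conditional specification (MI_FCS).
4. **Score** each method by the two-way random-effects,
   absolute-agreement, single-measures intraclass correlation between
   fills and ground truth at the masked cells,

   ICC(2,1) = (MSR − MSE) / (MSR + MSE + 2(MSC − MSE)/n),

   averaged over replicates on the Fisher-Z scale. Unlike Pearson's r,
   ICC(2,1) punishes mean and scale disagreement; a constant fill (item
   mean) scores exactly 0.

The imputation engines are scikit-learn-style transformers
(`fit`/`transform`, fitted attributes with trailing underscores), so
they compose with sklearn pipelines; module-level functions
(`impute_em`, `impute_mi_da`, …) wrap them.

## Worked example

```python
from sf12impute import cohort_config, generate_cohort, simulate_replicates, impute
from sf12impute.concordance import evaluate_method
from sf12impute.pipeline import preset_models, preset_rates

base = generate_cohort(cohort_config("clinical", n=2000, seed=0))
datasets = simulate_replicates(base, preset_models(), preset_rates("clinical"),
                               n_replicates=1, seed=0, items=["VITAL2"])
masked = datasets[0]
print(f"masked {masked.n_masked} of {base.n} VITAL2 responses")
for method in ("IMV", "PMV", "SR_RESID", "SR_T", "EM", "MI_DA", "MI_FCS"):
    icc = evaluate_method(impute(masked, method, random_state=1))
    print(f"{method:<9s} ICC(2,1) = {icc:.3f}")
```

prints

```
masked 356 of 2000 VITAL2 responses
IMV       ICC(2,1) = -0.000
PMV       ICC(2,1) = 0.387
SR_RESID  ICC(2,1) = 0.285
SR_T      ICC(2,1) = 0.243
EM        ICC(2,1) = 0.417
MI_DA     ICC(2,1) = 0.252
MI_FCS    ICC(2,1) = 0.249
```

Reading the numbers: 356 of the 2000 simulated respondents had their
VITAL2 answer deleted by the age/education-driven missingness model
(17.8% target rate). The item mean scores 0 by construction — a constant
carries no respondent-specific information. The EM conditional mean
agrees best with the true answers (ICC .42), stochastic regression loses
ground because of its injected noise, and the person mean sits in
between. Replicating the simulation (R=10 per item) and summarising with
`sf12impute.concordance.summarize` reproduces this ranking across
items: EM attains the highest Fisher-mean ICC for 10 of 12 items, and
EM > SR_RESID > IMV for all twelve.

The same study runs from the shell:

```bash
sf12impute run-all --seed 1 --outdir runs/demo          # full default study
sf12impute generate --profile clinical --n 2000 --seed 0 --out cohort.csv
sf12impute simulate --in cohort.csv --reps 10 --seed 0 --outdir runs/sim
sf12impute impute --in runs/sim --method EM --outdir runs/em
sf12impute evaluate --in runs/sim --fills runs/em/fills_EM.csv --out results.csv
```

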