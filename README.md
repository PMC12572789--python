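# mupsurv

Dose–response survival analysis for **markers of ultra-processing (MUPs)**:
from free-text product ingredient lists to marker-specific all-cause
mortality curves.

Ultra-processed foods (NOVA group 4) can be identified objectively: a food
item is ultra-processed if its ingredient list contains at least one MUP —
a cosmetic additive (flavour, colouring agent, sweetener, …) or a
non-culinary industrial ingredient (fructose, modified oil, isolated
protein, …).  `mupsurv` is for epidemiologists who want to move beyond
food-list-based UPF classification and ask which *specific* markers carry
the mortality association.  It provides:

* **`lexicon`** — a 9-category / 57-marker MUP taxonomy with normalized
  search terms (E-numbers, synonyms) and whole-term ingredient-list
  scanning;
* **`exposure`** — the Marker Likelihood Index
  (MLI = fraction of an item's researched commercial products containing
  the marker), portion resolution, and per-participant exposures as a
  percentage of total food intake:
  `%TFI(m) = 100 · grams carrying m / total grams`,
  averaged over up to five 24-h dietary recalls (ratio of means);
* **`cohort`** — the seven exclusion criteria (incl. Oxford-equation
  energy plausibility), follow-up construction and covariate coding;
* **`coxfit`** — Cox proportional-hazards regression with the exposure
  and total energy intake as **penalized cubic splines** (8 basis
  functions, 12 knots, second-order difference penalty tuned to a target
  effective df), linear/non-linear effect decomposition, and Schoenfeld
  diagnostics with Holm-adjusted stratification;
* **`curves`** — hazard-ratio curves rescaled so the **HR-nadir** (the
  lowest HR between 0 and the 99th exposure percentile) equals 1, with
  pointwise 95% CIs;
* **`sensitivity`** — a 17-variant robustness harness (landmark analysis,
  first-recall exposure, truncated MLI, cumulative specific-MUP intake,
  Benjamini–Hochberg FDR by exposure family, …);
* **`simulate`** — a ground-truthed synthetic-data generator for product
  catalogues, recalls, covariates and Weibull proportional-hazards
  survival with configurable true dose–response curves.

The statistical core is the penalized spline Cox model: the log hazard is
`log h(t|x) = log h₀(t) + f(x) + g(energy) + γ'z` with `f`, `g` cubic
P-splines and `z` the categorical covariates; `f` is reported as
`HR(x) = exp(f(x) − f(x_nadir))`.

See `docs/methods.md` for the model, its assumptions and all numerical
choices.

## Worked example

```python
from mupsurv import (GeneratorConfig, EtaTruth, simulate_all, load_lexicon,
                     build_mli_table, build_profiles, apply_exclusions,
                     build_survival_frame, fit_cox_pspline, SplineTermSpec,
                     decompose, curve, hr_at)

cfg = GeneratorConfig(seed=42, n_participants=4000,
                      truth=EtaTruth("linear", beta=0.06),
                      truth_exposure_key="UPF")
sim = simulate_all(cfg)

mli = build_mli_table(sim.products, load_lexicon())
profiles = build_profiles(sim.recalls, mli)

cohort, report = apply_exclusions(sim.participants.join(profiles))
surv = build_survival_frame(cohort)

data = surv.join(cohort[["UPF"]].rename(columns={"UPF": "exposure"}))
fit = fit_cox_pspline(data, spline_terms=[SplineTermSpec("exposure")])
tests, crv = decompose(fit), curve(fit, "exposure")
```

This prints (via the obvious `print` statements):

```
scored 4000 participants; mean UPF intake 18.5 %TFI
analysis cohort n=3560 (440 excluded), 1106 deaths
linear p=7.5e-12, non-linear p=0.59, effective df=4.00
log-HR slope 0.067 per %TFI (truth 0.06)
HR-nadir at 0.0 %TFI
HR at 20 %TFI vs nadir: 1.97 (0.41 to 9.49)
HR at 25 %TFI vs nadir: 2.56 (0.53 to 12.52)
```

Reading: the generated cohort carries a true log-linear hazard increase of
0.06 per %TFI of UPF intake.  The spline fit recovers the slope (0.067),
the linear test is decisive while the non-linear test correctly stays
null, and the curve places the HR-nadir at the bottom of the intake range,
as it must for a monotone risk.  The wide CIs at 20–25 %TFI reflect that
the nadir reference sits below the bulk of the observed intakes.  A
J-shaped truth (`EtaTruth("jshape", nadir=18)`) instead yields a
significant non-linear effect and a nadir estimate near 18 %TFI.

The same pipeline is scriptable from the shell:

```bash
mupsurv simulate --seed 42 --out study/
mupsurv score --products study/products.csv --recalls study/recalls.csv --out study/expo.csv
mupsurv cohort --in study/cohort.csv --exposures study/expo.csv --out study/analysis.csv
mupsurv sensitivity --products study/products.csv --recalls study/recalls.csv \
    --cohort study/cohort.csv --exposures UPF --variants 1,9,15 --out study/matrix.csv
```

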