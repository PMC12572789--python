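# Methods

## The problem

Ultra-processed foods (UPF, NOVA group 4) can be identified objectively by
markers of ultra-processing (MUPs): cosmetic additives (flavour, colouring
agent, sweetener, …) and non-culinary industrial ingredients (fructose,
modified oil, isolated protein, …).  A food item is UPF if its ingredient
list contains at least one MUP.  `mupsurv` implements the full chain from
free-text ingredient lists to marker-specific dose–response mortality
curves: lexicon-based ingredient scanning, Marker Likelihood Index (MLI)
exposure scoring, cohort construction, penalized cubic-spline Cox
regression with nadir-rescaled hazard-ratio curves, and a 17-variant
sensitivity harness — exercised end to end on synthetic cohorts with known
ground truth.

## Exposure model

For each dietary-questionnaire item, up to ten matching commercial
products are researched; each product's ingredient list is normalized
(lower-cased, accent-folded, punctuation collapsed, E-number spellings
unified so "E 620" ≡ "e620") and searched for each marker's terms under
whole-term matching: single-word terms must match a whole token, multi-word
terms a contiguous token run.  The MLI of marker *m* for item *i* is the
fraction of the item's products containing *m*; the item-level UPF
likelihood uses "contains ≥ 1 marker" as the predicate, so
MLI(UPF) ≥ MLI(category) ≥ MLI(member marker) holds per item by
construction.  Items with fewer than ten products use all available
products as denominator; truncated scoring (first 8/6/4 products) is an
exact recount on the truncated catalogue.

Grams of an item carrying marker *m* per consumed portion are
`portion_g × MLI(i, m)` (e.g. 50 g × 0.6 = 30 g).  Millilitre portions are
converted with a configurable specific-gravity table (water = 1.0
default); household measures use a configured per-item fallback standing
in for packaging / standard-portion lookups.  A participant's exposure is

    %TFI(m) = 100 × (mean daily grams carrying m) / (mean daily total grams),

with gram intakes averaged over the participant's 1–5 recalls *before* the
ratio is formed (ratio of means — the stable choice when recall totals
differ; the per-recall-ratio alternative is available as `first_recall` /
mode switches).  Cumulative specific-MUP intake is the plain sum of
specific-marker %TFI values (3 + 2 + 5 = 10), excluding category
aggregates and the UPF key; it may exceed 100.

The shipped lexicon encodes 9 categories and 57 markers.  The glutamate
term set (E620–E625, glutamate, glutamic acids, MSG) is fully attested;
the remaining term sets are field-plausible reconstructions and the whole
file is user-replaceable YAML.  Four markers (flavour, colour,
hydrogenated oil, fibre) are flagged as definitionally identical to their
category.

## Cohort construction

Seven exclusion criteria are applied in fixed order with first-hit
attribution: (1) missing lifestyle factors, (2) implausible
event/censoring data, (3) missing socio-economic factors, (4) missing exam
parameters, (5) malabsorption, (6) diabetes, (7) implausible energy intake
— 0 kcal, < 1.1·BMR − 500, > 2.5·BMR + 500 (strict inequalities; equality
retains), or above the 99.9th percentile of energy intake in the
pre-exclusion recall-completing population.  BMR uses the Oxford (Henry)
weight+height equations, shipped as an editable sex × age-band coefficient
table in MJ/day (× 239.005736 kcal/MJ).  Follow-up runs from the last
dietary assessment to death or censoring (loss to follow-up or the
administrative cut-off 2022-12-19), whichever comes first.  Age, physical
activity, SBP and Townsend index enter the models split at the analysis
cohort's own quintiles; alcohol (<1, 1–<8, 8–<16, ≥16 g/day) and BMI
(<18.5, 18.5–<25, 25–<30, ≥30 kg/m²) use fixed bands.

## Penalized spline Cox model

Each continuous exposure (the marker's %TFI and total energy intake; BMI
and SBP in one sensitivity variant) enters the Cox log-hazard as a cubic
B-spline expansion with 8 basis functions — 12 knots counting the basis
order — over the observed exposure range, with a second-order difference
penalty on adjacent coefficients (P-spline).  Knots are equally spaced and
extend past the data range rather than being stacked at the boundary; with
this layout the Greville abscissae are equally spaced, so the difference
penalty's null space is exactly the functions linear in x and the
infinite-penalty limit is the straight-line Cox fit (verified against an
independent unpenalized Cox implementation to ~1e-6 relative slope error).
The first basis coefficient is fixed at zero: the partial likelihood
cannot identify a constant shift of the linear predictor, and every
reported functional is invariant to that direction.

The penalized partial likelihood (Breslow ties by default; Efron
available) is maximized by Newton–Raphson with step-halving; the penalty
weight λ of each spline term is tuned by root-finding so the term's
effective degrees of freedom, tr[(H + λP)⁻¹H] over the term's block,
matches a target (default 4, the convention of the survival-analysis
ecosystem; the basis size is fixed but the penalty is not prescribed, so
the df target is configurable).  Two covariances are kept:

* **penalized**: (H + λP)⁻¹ — used for curve confidence intervals and the
  penalized Wald statistic (whose null expectation is the effective df);
* **sandwich**: (H + λP)⁻¹ H (H + λP)⁻¹ — the sampling covariance of the
  penalized estimator, used for the linear-effect test.

Each spline term is decomposed into linear and non-linear effects.  The
linear log-HR slope is a precision-weighted (GLS) projection of the
coefficient vector onto the linear trend across the basis centres —
down-weighting the poorly determined exterior basis functions — tested
with a 1-df Wald statistic under the sandwich covariance.  The non-linear
statistic is the total penalized Wald chi-square minus its linear share,
referred to a chi-square with effective df − 1.  In simulation both tests
hold their size (≈ 4–5% rejection at α = 0.05 under a null exposure,
n = 2000, 200+ replicates) and the slope's 95% CI covers a linear truth at
≈ 95%.

Proportional hazards are checked per categorical covariate with a score
test contrasting Schoenfeld residuals against a centred Kaplan–Meier time
transform (rank and identity transforms available), using the V̄ = I/m
risk-set-variance approximation; the test is deliberately conservative.
p-values are Holm-adjusted across covariates, significant violators move
to baseline-hazard strata, and the model is refit once (no re-diagnosis
loop).

## HR-nadir curves

The fitted spline predictor is evaluated on 512 equally spaced points from
0 to the 99th percentile of observed intake.  The HR-nadir is the grid
argmin (ties broken toward the smallest exposure, making results
deterministic); hazard ratios are rescaled so HR(nadir) = 1.  Pointwise
95% CIs use the variance of the contrast η(x) − η(nadir) under the
penalized covariance, so the interval collapses to [1, 1] at the reference
and widens continuously away from it; a flag switches to
reference-held-fixed intervals for comparison.  Off-grid queries
interpolate linearly in log HR (the midpoint of two nodes carries the
geometric mean of their HRs); extrapolation beyond the grid is refused.
Below the smallest observed exposure the basis is evaluated with flat
(clamped) extension.

## Sensitivity harness

Seventeen variants re-run the pipeline with exactly one aspect changed:
landmark exclusion of follow-up < 2 y; exclusion of weight-loss reporters,
atypical-diet reporters, single-recall participants, prior CVD/cancer;
first-recall-only exposure; diet-quality adjustment; waist-to-hip ratio +
height instead of BMI; energy removed; minimal exclusions with pluggable
kNN / random-forest imputation (a registry hook — no imputer is shipped,
and unregistered variants report "delegated"); medication adjustment;
BMI/SBP as splines; assessment-centre adjustment; MLI from the first
8/6/4 products; cumulative specific-MUP exposure; and Benjamini–Hochberg
FDR control applied to the MUP-category and specific-marker families
separately.  A variant whose preconditions fail records a failed cell
rather than aborting the matrix; variant 15 at k = 10 reproduces the main
analysis bit for bit.

## Synthetic data

The generator emulates all four study inputs.  Ingredient lists mix 4–10
filler tokens with one search-term spelling per included marker; markers
are included by a common-shock copula — each marker's marginal probability
is exact while a shared latent uniform (correlation 0.9) makes markers
co-occur within products, as they do in real catalogues.  Marginal
probabilities were chosen once so that category %TFI means in generated
cohorts match the intake pattern of a UK middle-aged cohort (UPF ≈ 18,
flavour ≈ 13, colouring agent ≈ 5, processing aid ≈ 7.5 %TFI); 37 of the
57 markers are realized in the default catalogue.  Planted terms are
restricted to spellings that scan back to exactly their own marker and are
interleaved with filler tokens, so the recorded ground-truth MLIs and
%TFI equal what the scanning pipeline recovers, exactly.

Participants (default 5,000; 238 items with 10 products each) receive 1–5
recalls with configurable consumption probabilities, covariates drawn from
marginals resembling a UK cohort aged 40–75, and survival times from a
Weibull proportional-hazards model (shape 1.3, scale 90 y — roughly 10%
deaths over a 12-year administrative follow-up) whose exposure→log-hazard
curve is configurable: null, linear, or J-shaped
η(x) = a₋·max(x₀−x,0)² + a₊·max(x−x₀,0)² with default nadir x₀ = 18 %TFI
and a = 0.0015 (HR ≈ 2.6 at 43 %TFI versus the nadir — strong enough that
a single 10,000-participant cohort localizes the nadir to a few %TFI,
which a paper-sized effect would need the full-cohort scale to do).
Everything derives from one root seed through per-stage substreams; the
same seed reproduces every output byte for byte.

What the generator does **not** emulate: realistic retailer phrasing
beyond token pools, food-group correlation structure across items,
measurement error in recalls, and confounding between exposure and
covariates (covariates are drawn independently of diet).  Passing tests
therefore demonstrate correctness of the machinery under the stated model,
not robustness to real-data pathologies such as exposure measurement error
or residual confounding.

## Numerical choices and scales

Newton iterations stop when the quadratic model predicts a relative gain
below 1e-9; step-halving tolerates rounding noise of 1e-10·|objective|,
and a trial step that underflows a risk set is rejected outright.  λ is
tuned on log₁₀ scale in [−6, 10] by Brent's method (xtol 1e-3) with warm
starts, two coordinate passes when several spline terms are free.
Degenerate inputs fail loudly: constant exposures, single-level or
constant dummy covariates, < 2 events, zero total food intake, unknown
item ids.  Test-suite problem sizes (hundreds to 2,000 participants for
calibration batteries, 10,000 for nadir recovery, 50–200 replicates) were
chosen as the smallest that make the binomial acceptance bands
informative.

## Known limitations

* The non-linear test's reference distribution uses the effective-df
  heuristic; it is calibrated in our simulations but is not an exact
  finite-sample test.
* The Schoenfeld score test uses the averaged risk-set variance rather
  than the full Grambsch–Therneau matrix correction, making it mildly
  conservative.
* Imputation variants (10–11) only define the interface; no imputer is
  shipped.
* The shipped lexicon's term sets outside glutamate are reconstructions;
  analyses of real catalogues should supply a curated lexicon file.
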