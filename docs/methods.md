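# Methods

This note records the models, default parameters and numerical choices
behind each pipeline stage, what the synthetic data do and do not emulate,
and the design decisions taken where the design was genuinely open.

## Screening rules

Risk-factor flags follow the printed inequalities exactly: waist ≥ 88 cm
(women) / ≥ 102 cm (men); triglycerides ≥ 1.7 mmol/L; HDL < 1.03 (men) /
< 1.29 (women) mmol/L; SBP ≥ 130 **or** DBP ≥ 85 mm Hg; glucose
> 5.6 mmol/L. "At risk" is central obesity plus ≥ 1 secondary factor.
The full-syndrome rule used when selecting the MetS reference group is an
IDF-style definition expressed with this same threshold table — central
obesity plus ≥ 2 secondary factors — rather than the IDF's
ethnicity-specific cut-offs; both minimum counts and all thresholds are
config (`screening:` in `defaults.yaml`). Any missing field needed by a
rule raises: screening requires complete panels, silently skipping a
subject would bias eligibility.

HOMA-IR is computed from fasting glucose and C-peptide with a
configurable multiplicative form, default
`glucose × (C-peptide × 6.0 µU/mL per nmol/L) / 22.5`. The conversion
treats C-peptide as an insulin-equivalent at equimolar secretion; it is
an explicit assumption (C-peptide-based HOMA variants differ), and no
result in this package depends on its constants.

## DHDI scoring

The canonical input is the per-category 1–10 score itself; the FFQ
instrument that produces real scores is out of scope.
`score_component` converts synthetic intake amounts to scores by linear
interpolation between guideline bounds (adequacy components rise with
intake, moderation components mirror). The total is the plain sum over
the eight categories (range 8–80). Carotenoids ride on the diet profile
as an independent biomarker; they are never folded into a category score.

## Health-space score

*Healthy reference selection.* The pool is filtered to BMI ∈ [18, 25] and
zero risk flags, then each of the five biomarkers ranks the pool with the
healthiest extreme first (direction map in config: HDL high; the others
low). Normalized ranks are position/n with ties sharing the mean
position. A subject's ρ is the minimum over k of the Beta(k, m−k+1) CDF
at their k-th smallest rank — the probability that the k-th order
statistic of m uniforms falls that low. The n_top = 10 smallest ρ win;
ties break by subject id for determinism.

*Model.* The outcome is the class code (MetS = 1, healthy = 2) and the
five biomarkers are standardized with pooled training mean/SD (stored in
the model so projection of new individuals is self-contained). Sex enters
as a random effect with intercept *and* slopes (restrictable to intercept
only, or disabled, via `health_space.random_structure`) — with two sex
levels the random effects act as shrunken per-sex coefficient
adjustments; predictions for an unknown sex fall back to the population
coefficients with a warning. The outcome model is linear, not logistic:
the score is a continuous 1–2 scale and observed cohort means sit inside
it, so an unclipped linear prediction is the natural reading; scores are
never clipped. Classification uses score > 1.5 (the midpoint of the
codes); accuracy and Cohen κ come from scikit-learn, and κ is undefined
(error) for single-class truth.

With only two grouping levels the mixed fit can be fragile; a
non-converged or failed fit falls back one structure level with a
warning. The fixed effects — which carry the separation — are stable
under all structures.

## Advice engine

The study's cut-off levels and abnormality→category mapping are
unpublished, so the shipped defaults are explicit assumptions, stored as
data (`advice:` in `defaults.yaml`), and any result depending on them is
config-dependent:

- DHDI sufficiency cut-off: score < 8 per category (8/10 approximates
  guideline adherence);
- carotenoid cut-off 1.0 µmol/L (near, and below, the cohort baseline
  mean), triggering fruit and vegetables;
- flag map: elevated triglycerides → fish, sugar-containing beverages,
  oils and fats; low HDL → fish, nuts, oils and fats; elevated glucose →
  wholegrain, sugar-containing beverages; elevated BP → vegetables,
  dairy; excessive waist → sugar-containing beverages, oils and fats,
  nuts. Each map entry follows the food-category evidence the study
  itself cites per metabolic abnormality.

Plans are composed in the fixed category order, reasons merged per
category, and are pure functions of their logged triggers (auditable:
recomposition regenerates the plan exactly). Strategy selection models
the stage-2 consultation only as a seeded non-empty subset draw; an
empty probabilistic draw keeps the highest-probability advised category.

## Evaluation statistics

- Linear mixed model per outcome: time categorical fixed, subject random
  intercept, ML estimation; the overall time effect is a likelihood-ratio
  test against the intercept-only mixed model (χ², df = timepoints − 1).
  On balanced complete data the estimated per-week means equal raw means
  and contrasts equal paired mean differences (tested).
- Pairwise timepoint contrasts are Wald z-tests from the fixed-effect
  covariance, Benjamini–Hochberg-adjusted **within outcome** (the family
  scope is configurable in code; within-outcome is the default reading).
- Outliers: observations with |residual| > 3×RMSE (strict) are removed
  and the model refitted once — flag, remove, refit, no iteration. Note
  that residual-based trimming is mildly anticonservative: under a clean
  Gaussian null it inflates the empirical size of the time test from
  ≈ 5% to ≈ 7%. Calibration checks therefore assess the mixed-model test
  itself (no trimming); the trimming pass is kept in the pipeline because
  its purpose is robustness to gross errors, not size control.
- Likert outcomes: a cumulative-link (proportional-odds, logit) mixed
  model with subject random intercept, integrated with 15-node
  Gauss–Hermite quadrature; thresholds are parameterized by log-spacings
  for monotonicity, the random-intercept SD on the log scale, and the
  time effect is again an LRT. Response levels with zero observations are
  collapsed with a warning; a constant response raises. With the random
  intercept disabled the fit agrees with the standard proportional-odds
  model (cross-checked against statsmodels OrderedModel).
- Delta correlations are Pearson with two-sided p. The study's
  "visually confirmed in scatterplots" step is replaced by an explicit
  influence diagnostic: drop the single most rho-influential subject and
  flag correlations whose significance vanishes.
- The paired-t sample-size utility documents the study's power
  calculation inputs (δ = 1.85 cm, SD 2.67); the power level behind the
  study's own "n = 16" is unstated, so the utility takes power as an
  argument and asserts nothing about 16.

## Synthetic data generator

The generator's defaults *are* the study conditions, shipped as data
(`defaults.yaml`): the reference-group and cohort baseline moments, the
per-week outcome means (weeks 0/8/16; Likert items 0/16), week-0 SDs,
and the per-category strategy-inclusion frequencies.

*Cross-sectional pools.* Each feature is truncated normal inside
physiological bounds, coupled through a Gaussian copula. Because hard
truncation biases the realized mean toward the far bound, the location
parameter is calibrated (Brent root-finding) so the truncated
distribution's mean equals the specified mean. Right-skewed biomarkers
can switch to a moment-matched log-normal per config; the default stays
truncated normal. The only nonzero default correlation is HDL vs
triglycerides, r = −0.3 — the published tables give no covariances, so
this is a stated assumption chosen to keep classifier checks realistic,
and it is overridable.

*Longitudinal cohort.* Per outcome with single-visit SD σ and
within-subject correlation ρ (default 0.7, an assumption — the study
reports none): subject intercept b_i ~ N(0, ρσ²) plus visit noise
e ~ N(0, (1−ρ)σ²), means following the configured trajectory. Food-
category scores shift only for participants whose fixed strategy includes
the category, mirroring the study's subset-conditional category means;
cohort-level outcomes (total DHDI, biomarkers, Likert) shift for
everyone. Likert items are a latent normal rounded and clipped to 1–7.
Dropout removes all post-baseline rows of k subjects (default 0).

The additive model keeps the moment-convergence guarantees exact but can
produce physically impossible single values (a negative C-peptide about
5% of the time at the published moments). These are repaired at the
analysis boundary, not in the generator: `harmonize_panel` floors
concentrations at a 0.01 detection limit and caps DBP just below SBP,
the way assay floors and measurement conventions would in real data.

*What passing tests show.* The generator reproduces first and second
moments, one chosen cross-sectional correlation, the within-subject
correlation, strategy frequencies and the mean trajectories. It does not
emulate the covariance structure of a real survey population, skewness beyond the optional
log-normal switch, assay error, seasonal intake variation, or informative
dropout — so passing tests certify the *pipeline's* statistical behavior
under the stated data-generating process, not its performance on real
cohorts.

## Problem sizes and tolerances

Test batteries use: 1000 random rank vectors (m ≤ 6) for the RRA oracle;
all 2⁵ flag states for screening; 100 replicates of n = 200/group
reference pools for health-space recovery (accuracy ≥ 0.85 at
threshold 1.5; fitted coefficient signs tracking the group-difference
direction in ≥ 99% of sign checks — the LDL coefficient is the weakest,
its group separation being ≈ 2 SE at this n, and flips in ~2% of
replicates); 1000-replicate null and effect simulations at the study's
n = 34 for test size ([0.03, 0.07] band) and 95%-CI coverage
([0.93, 0.97] band). The acceptance script uses n = 5000 for effect
recovery (the size at which the generator's mean-convergence guarantee is
±0.1 on the DHDI total) and 400 null replicates. Numerical tolerances on
oracle equalities are 1e-9 or tighter; stochastic checks state their
bands explicitly.

## Known limitations

- The health-space coefficients are not comparable to the study's
  (unpublished) standardized contributions; only directions and
  separation behavior are validated.
- The advice engine's cut-offs and flag map are assumptions; advised-
  category frequencies produced by the pipeline are config-dependent and
  intentionally not matched to the study's reported frequencies (those
  enter only as strategy-inclusion probabilities in the generator).
- The ordinal mixed model uses a single random intercept and adaptive
  quadrature is not implemented; with ≤ 2 timepoints and moderate
  variance this is adequate (checked by simulation) but extreme
  random-effect variances would need more nodes.
- Real-participant p-values and correlations are not reproducible by
  construction; the pipeline's statistics are validated by calibration
  and recovery simulations instead.
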