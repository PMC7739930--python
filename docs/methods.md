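# Methods

## The problem

Species-targeted conservation funding can be summarized as a
per-species count of funded projects plus the budget allocated to the
species. The analytical questions are (i) how unevenly that attention
is distributed across taxa relative to known species richness, and
(ii) what species-level traits — online popularity (a proxy for
charisma), body size, extinction-risk category — predict it. The
package implements the measurement pipeline and the statistical model,
plus a generative simulator so every step is testable against ground
truth.

## Budget allocation and bias metrics

A project targeting k species contributes `budget / k` to each target
and one unit to each target's project count. This equal-split rule
makes total allocated budget identically equal to total project budget
(a conservation identity enforced by property tests). Budgets are
nominal EUR; no inflation adjustment is applied when summing across
years, matching how multi-decade portfolio totals are usually
reported. Projects with zero recorded budget are allowed and
contribute only to counts. Duplicate targets within one project are
rejected at parse time.

Group summaries compute shares of funded species and of budget within
the universe spanned by the allocation table. Richness-relative
metrics divide a group's funded-species count and total budget by its
known species richness; the headline bias statistics are
vertebrate/invertebrate quotients of these. Reported percentages are
rounded half-away-from-zero at the printed precision only in the
report layer; all internal values are unrounded.

## Popularity calibration by anchor chaining

Relative search volumes are reported per query batch: each batch is
scaled so its maximum (over all species and months) is 100, then
rounded to integers. Values from different batches are therefore in
incompatible units, and small species in a batch with a dominant one
can be quantized to zero.

Calibration chains batches together through shared anchor species:

* **Planning.** Batches hold up to B = 5 species (the comparison limit
  of the Trends interface; configurable). The first batch has no
  anchor; each later batch re-queries one anchor plus up to B − 1 new
  species, giving `1 + ceil((n − B)/(B − 1))` batches. The anchor is
  the last species of the previous batch so that, when species are
  queried in decreasing order of expected popularity, consecutive
  batches stay close in magnitude and the anchor reports near the top
  of its new batch — away from the rounding floor.
* **Scaling factor.** The factor converting new-batch units into
  calibrated units is the through-origin least-squares slope
  `Σ(ref·new) / Σ(new²)` regressing the anchor's calibrated values on
  its new-batch values. The regression is intercept-free because both
  series share a true zero by construction (a month with no searches
  reports zero in any unit); R² is the uncentered `1 − SSR/Σref²`
  consistent with that model. Anchor candidates are ranked by the
  number of months in which both series are positive, and the first
  candidate with R² above the gate (default 0.95) is used; if none
  passes, the best-R² candidate is used and flagged, so a weak link is
  visible rather than fatal.
* **Chaining.** The first batch defines the common unit; factors
  accumulate multiplicatively down the chain. A species reported in
  several batches keeps its earliest calibration. If an anchor reports
  all zeros (no information), the batch is re-queried with a different
  species from the previous batch before failing.

A species' popularity is the arithmetic mean of its 120 calibrated
monthly values. With a noiseless, rounding-free simulator the chain
recovers latent ratios exactly (machine precision, any depth); with
integer rounding and a latent spread of about two orders of magnitude
the log–log correlation with the truth stays above 0.95, and the
median relative error grows with chain depth — both verified as seeded
properties. The overall scale of the calibrated values is a gauge
freedom: multiplying all outputs by one positive constant shifts only
the count model's intercept, which the test suite verifies by refitting.

## Trait assembly and exploration

IUCN categories are matched by binomial name after whitespace
collapsing and casefolding; unmatched species become DD with an
explicit missing flag (DD is retained as a model category). Continuous
variables are log₁₀-transformed when their sample skewness exceeds 1.0
— a concrete, configurable stand-in for visual homogeneity checks;
the threshold and the decision are emitted in the exploration report
so the rule is auditable. Popularity gets a +1 offset before logging
(zeros mean "never searched"); body size must be strictly positive and
is logged without offset. Collinearity is screened with pairwise
Pearson correlations at a strict |r| > 0.7; flagged pairs are resolved
by a configurable keep-priority whose default keeps average popularity
over its relative variant and the project count over budget.
Zero-variance columns are excluded and reported. All operations return
new tables; inputs are never mutated.

## The mixed count model

Counts of projects per species are modelled as

    y_i ~ Poisson(mu_i)  or  NB2(mu_i, theta),   Var = mu + mu^2/theta
    log mu_i = x_i' beta + b_class(i) + b_order(i) + b_family(i)

with independent Gaussian intercepts per taxonomic level, keyed by the
full nesting path (class, class:order, class:order:family), each level
with its own SD. This absorbs taxonomic non-independence: related
species share intercepts at three depths.

**Estimation.** The marginal likelihood integrates the random effects
out with a Laplace approximation. For fixed (β, σ, θ) the joint
log-density is maximized over b by damped Newton iterations (the
penalized-likelihood Hessian `Z'WZ + D` is positive definite for both
families), and the approximation adds `−½ log det(Z'WZ + D)` at the
mode. The outer parameters (β, log σ per level, log θ) are maximized
by L-BFGS-B with 3-point finite-difference gradients (absolute step
10⁻⁶) from a deterministic start — fixed effects from the
no-random-effect GLM (statsmodels), log σ at −0.5, log θ at 0 — so
fits are reproducible without seeds. Inner modes are warm-started
between outer evaluations. Bounds keep log σ in [−8, 5] so a variance
component can collapse to effectively zero without numerical failure.
For large θ the NB log-likelihood is evaluated through the telescoped
gamma ratio `Σ_{k<y} log(θ+k)` and `log1p(μ/θ)`, avoiding the
catastrophic cancellation of direct `gammaln` differences; this makes
the θ → ∞ limit reproduce the Poisson fit to ~10⁻⁶ in the fixed
effects.

**Uncertainty.** Standard errors come from the inverse of the
numerical observed information (central differences) of the Laplace
log-likelihood at the optimum; Wald z = β/se with two-sided normal
p-values and no multiplicity correction. A categorical level whose
observations are all zero is quasi-separated: its coefficient
diverges (clamped by the linear-predictor bound of ±30) and its SE is
reported as NaN, with a diagnostic note — never silently dropped.

**Accuracy of the Laplace step.** The approximation error per group
scales inversely with the group's effective information (for NB,
per-observation information saturates at θ, so small θ — strong
overdispersion — is the hard regime). The quadrature-oracle tests
therefore use fixtures with moderate-to-large counts, where agreement
with adaptive integration is well inside 10⁻³ in total log-likelihood;
at few counts per group the Laplace log-likelihood can deviate by
~10⁻² like any first-order Laplace implementation.

**Workflow.** `select_family` fits Poisson, computes Pearson
χ² = Σ(y−μ̂)²/μ̂ with residual df = n − p_fixed (random effects not
counted — simple and conservative, stated in output), and refits with
NB2 when the upper-tail χ² p-value is below 0.05. On equidispersed
simulations the conditional dispersion ratio sits slightly below 1
(the fitted random intercepts absorb some variation while the df
correction ignores them), typically 0.82–0.90 at 500 species — inside
the 0.8–1.2 null band used by the tests.

## The synthetic generator

The generator is the study's ground-truth counterpart, not a neutral
fuzzer. Defaults describe one realistic study condition:

| parameter | default | rationale |
|---|---|---|
| n_species | 488 | size of the funded-species pool (410 vertebrates + 78 invertebrates) |
| taxonomy | 4 × 3 × 3 | classes × orders/class × families/order; ~36 families for ~500 species |
| intercept | −0.5 | mean of roughly one project per species at central predictor values |
| popularity slope | 0.19 | per log₁₀ unit of popularity; matches the effect size the model is designed to detect |
| body-size slope, IUCN offsets | 0 | these predictors are generated as non-drivers of attention |
| σ_class, σ_order, σ_family | 0.5, 0.3, 0.3 | moderate taxonomic clustering on the log scale |
| θ (NB2) | 1.0 | visible overdispersion, the regime that forces the family switch |
| budget meanlog, sdlog | 13.9, 0.8 | log-EUR; median ≈ €1.1M, matching a ~€1.1B / 835-project portfolio |
| pop meanlog, sdlog | 2.5, 1.5 (natural log) | latent interest spanning several orders of magnitude across species |
| ρ(log pop, log size) | 0.6 | popularity and body size strongly correlated, as observed in charisma data |
| months | 120 | ten years of monthly series |
| month sdlog | 0.25 | within-species monthly variation of interest |
| multi-species fraction | 0.3 | share of projects targeting 2–5 species, co-targets drawn popularity-weighted |

Latent monthly interest is log-normal around each species' mean; the
API simulator optionally adds per-(species, month) multiplicative
log-normal noise (default off — real sampling noise is not publicly
characterized), then max-normalizes the batch to 0–100 and rounds half
to even (`np.rint`), matching integer reporting. IUCN categories are
drawn independently of popularity by default, as extinction risk is
generated as a non-driver.

Because co-targeting in multi-species projects is popularity-weighted,
end-to-end pipeline runs show a *stronger* popularity effect than the
count-model slope alone — attention couples to popularity through two
channels. Parameter-recovery studies therefore run with the
multi-species fraction at 0, where counts follow the NB mixed model
exactly.

What the simulator does **not** emulate: Google's query-to-query
resampling variability, topic-vs-search-term ambiguity, name synonymy,
real taxonomic imbalance (families here are near-equal in size), and
temporal trends or seasonality in interest. Passing tests show the
pipeline's arithmetic and inference are correct under the generative
assumptions, not that real search data are this well behaved.

## Validation experiments and problem sizes

The `experiments` module fixes the study conditions used by the test
suite and the reproduction script: chain calibration at 100 species
(26 batches) with ~2 orders of magnitude latent spread; dispersion
null and family switch at 500 species; fixed-effect recovery at 500
species × 20 replicates (each true fixed effect should fall within ±2
SE of its estimate in ≥ 90% of replicates; with 20 replicates the
observed minimum coverage across terms fluctuates between 85% and
100%). These sizes keep a full validation run in the tens of seconds
while leaving the statistical checks meaningful.

## Known limitations

* Wald inference only; no profile or bootstrap intervals for variance
  components, and σ estimates on 4 classes are necessarily crude.
* The Laplace approximation is first-order; for severely overdispersed
  sparse counts its likelihood values carry ~10⁻² error (estimates are
  far less sensitive).
* The dispersion df convention ignores the effective parameters of the
  random effects, biasing the null ratio slightly below 1.
* Quasi-separated categorical levels are flagged, not regularized; a
  Firth-type correction is out of scope.
* The batch planner assumes the caller can order species roughly by
  expected popularity (in the synthetic pipeline the true latent order
  is used); a badly shuffled order degrades anchor precision through
  the rounding floor.
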