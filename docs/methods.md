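# Methods

`robustchange` estimates how questionnaire-measured symptom severity,
psychosocial stress, and everyday behaviors change between two assessments
(a retrospective pre-pandemic baseline T0 and a during-outbreak measurement
T1) in a cohort stratified into eleven diagnostic groups — ten self-identified
mental-disorder groups (generalized anxiety, panic/agoraphobia, illness
anxiety, social anxiety, depression, OCD, body dysmorphic, eating,
schizophrenia-spectrum, other) and healthy controls. This note documents the
models, the defaults and why they were chosen, the synthetic-data conventions,
and the limitations of what the test suite can show.

## The change model

Every analysis operates on per-participant difference scores `d = T1 − T0`
in raw score units. Difference scores are modelled with Student-t noise:

```
d_i ~ t(nu, mu, sigma)
```

The normality parameter `nu` receives an exponential prior with rate 1/30
(mean 30). Small `nu` lets the model absorb outliers; large `nu` recovers
the normal model. Because the prior mass near `nu -> 0` can make the fit
*over*-compensate for outliers — `nu`, `mu`, and `sigma` all collapse toward
zero together — `nu` can be floored from below (`nu_floor`, typically 1 or
2). The floor is not applied by default; it is the remediation step of the
convergence gate (below).

Model kinds:

* **single group** — normal prior on `mu`, uniform prior on `sigma`.
* **two group** (Bayesian analog to a t-test) — per-group `mu`/`sigma`,
  shared `nu`.
* **multi group** (ANOVA-like) — cell means `mu_g = beta0 + beta_g` with
  sum-to-zero deflections over the diagnostic groups; per-group scales
  `sigma_g` under a common gamma prior whose mode and spread are themselves
  estimated (broad uniform hyperpriors), giving partial pooling of group
  spreads; shared `nu`.
* **regression** — linear model for the stress change on sociodemographic
  covariates, with the same t noise and normal coefficient priors.

"Non-committal" priors are resolved from the data at fit time: the `mu`
prior is centered at the sample mean with scale 100x the sample SD; the
uniform `sigma` prior spans (SD/1000, SD*1000); deflection/coefficient
priors have scale 10x the pooled SD; the gamma-hyperprior bounds span the
same broad interval. These are the textbook-default magnitudes for robust
Bayesian estimation and are configurable in `ModelSpec`.

Two genuinely open design points, resolved as follows: the exponential
`nu` prior is placed on `nu` itself (no +1 shift; the shifted variant is
available by setting `nu_floor=1`), and the multi-group `nu` is shared
across groups rather than estimated per group.

### Identification of the deflections

The sampler parameterizes the multi-group model by its cell means and
derives `beta0 = mean_g(mu_g)` and `beta_g = mu_g − beta0` by a sum-to-zero
sweep at every draw. Cell means — the quantities all downstream reporting
uses — are invariant to this choice.

## Sampling

No gradient-based PPL is used; the posterior is explored by a hybrid
Gibbs/Metropolis kernel built on the scale-mixture representation of the t
distribution (`d_i | w_i ~ N(mu, sigma^2/w_i)`, `w_i ~ Gamma(nu/2, nu/2)`):

1. latent weights `w_i` are drawn exactly from their gamma conditional;
2. locations (and regression coefficients) are drawn from their exact
   normal conditional given the weights;
3. scales, gamma hyperparameters, and `nu` are updated by random-walk
   Metropolis on the log scale against the *marginal* t likelihood
   (weights integrated out), with `mh_reps` (default 3) sub-iterations per
   sweep.

The marginal updates matter: the pure data-augmentation Gibbs sampler has a
well-known pathology where `sigma` and `nu` crawl through the latent
weights (observed ESS efficiency ~1–10%); updating them against the
marginal likelihood raises efficiency to roughly 20–35% per retained draw.
Step sizes adapt toward 44% acceptance during warmup only, so the
post-warmup kernel is fixed and valid. Chains are seeded from independent
`SeedSequence` spawns of one spec seed; identical data + spec + seed
reproduce draws bit for bit.

Defaults: 4 chains x 12,500 retained draws after 1,000 warmup iterations.
At the measured efficiencies this reliably clears the effective-sample-size
gate of 10,000 on location and scale parameters. Tests and the acceptance
script run reduced chains (stated per test) because their assertions need
posterior-summary accuracy, not the full ESS target.

## Decision layer

Effect sizes are standardized per draw: `delta = mu/sigma` for one group,
`delta = (mu2 − mu1)/sqrt((sigma1^2 + sigma2^2)/2)` for two. Summaries are
the median of per-draw ratios (not the ratio of medians): per-draw
propagation is the coherent Bayesian choice, and on point-mass inputs the
two coincide.

The 95% highest-density interval is the narrowest contiguous window over
the sorted draws containing `ceil(0.95 N)` of them. The region of practical
equivalence (ROPE) defaults to `−0.2 < delta < 0.2` on the effect-size
scale only; raw-score equivalence bounds are deliberately not defined.
The three-way rule: accept the null if the HDI lies entirely inside the
ROPE, accept the alternative if it lies entirely outside, otherwise
inconclusive. Containment is evaluated on the **closed** interval, so an
HDI endpoint exactly on a ROPE bound still counts as inside — this matches
the boundary-touching contrast case in the published tables this package's
report format follows. Alongside the verdict, the report carries the
posterior mass above zero and below/inside/above the ROPE so that trends
remain readable when the verdict is inconclusive.

The pooled-disorder vs healthy-control contrast averages the ten disorder
cell means per draw (unweighted by default; per-group `n` weights are an
option — the source analyses do not state which was used) and uses the
root-mean of disorder-group variances as the pooled scale.

## Convergence gate and remediation

ESS follows `N / (1 + 2 sum rho_k)` with Geyer's initial-positive-sequence
truncation, combined across chains through the between/within variance
estimate; the Gelman-Rubin PSRF uses split chains (each chain halved), so
within-chain drift is also flagged. "Visual inspection" of chain densities
is mechanized as a pairwise histogram-overlap statistic, reported but not
gating. A fit passes when all location/scale/coefficient parameters reach
ESS >= 10,000 (configurable) and PSRF <= 1.05; `nu` is inspected but not
gated. Failing fits are refit up the `nu` floor ladder (none -> 1 -> 2),
one refit per step; exhaustion is a hard, structured failure. The gate is
idempotent on passing fits.

## Questionnaire layer

Instruments are defined by item count, response range, dichotomy flag, and
optional subscales; scores are plain sums after optional per-item reversal.
The default registry ships the study's instrument shapes (e.g. worry scale
16 items 1–5; depression subscale 7 items 0–3; illness-worry scale 14
yes/no items; panic module 15 yes/no items with an 11-item physical-symptom
severity sum). No default definition applies reverse keying — the published
scoring description never mentions it, although the worry questionnaire's
published form contains reverse-keyed items; the per-item flag exists for
users who want it. Subscale item indices are positional blocks because item
wordings are out of scope; the eating-disorder questionnaire's four
subscales share one item (5/5/5/8 items over a 22-item instrument).

Reliability: Cronbach's alpha via the variance formula with the sample
(`n−1`) convention throughout; KR-20 via the `p*q` form with the matching
`n/(n−1)` correction, so KR-20 equals alpha exactly on binary data. Missing
responses are rejected with coordinates, never imputed or prorated.

Percentages in descriptive tables are rounded half-up to two decimals, and
denominators are explicit parameters — published frequency tables switch
denominators silently (total sample vs currently-affected subsample, etc.),
which is the main descriptive-layer trap. One known source inconsistency is
deliberately left as-is: the running text says "approximately 63%" reported
an increased need for therapeutic support while the corresponding table
prints Yes = 36.80% / No = 63.20%; the implementation follows the table.

## Synthetic cohorts

The generator emulates what the analysis assumes, with explicit ground
truth: group sizes default to the study's (135/83/30/86/586/47/16/62/6/156/
1026, total 2,233); T0 is a truncated normal on the score range (the
baseline's shape is low-stakes — inference consumes only differences, and
no per-group baseline descriptives exist to match); individual change is
location-scale t with configurable `(mu_true, sigma_true, nu_true)` per
(group, variable), so `delta_true = mu_true/sigma_true` is known; T1 = T0 +
change, clamped to the score range and rounded to the integer grid
(questionnaire sums are integers). A flag disables clamping/rounding for
calibration studies, because clamping biases effect-size recovery near the
range edges. Covariates: age ~ normal(33.2, 12.7) truncated at 18, gender
and relationship as Bernoulli draws with the study's marginal proportions —
enough to exercise the regression stage. The default stress ground truth
uses the study's per-group posterior medians for (mu, sigma) as generating
values, e.g. (1.55, 3.10) for the depression group, a standardized change
of 0.50.

Per-(group, variable) substreams are derived from one seed via CRC-keyed
`SeedSequence` spawns, so adding a variable never perturbs existing draws.

What the generator does **not** emulate: item-level response processes
(scores are drawn directly at the sum-score level, so reliability analyses
need separately simulated item matrices), missing data, recall bias in the
retrospective baseline, or correlation between variables within
participant. Passing recovery tests therefore demonstrate that the
estimation machinery is calibrated for data satisfying its own assumptions
— they cannot validate the retrospective-measurement design itself, and
real-data effect estimates inherit whatever bias the retrospective baseline
carries.

## Numerical choices and edge cases

* `nu` has a hard support floor of 0.02 regardless of configuration; the
  t likelihood is numerically degenerate below.
* Zero-variance data are rejected (`DegenerateDataError`) naming the
  variable; a robust scale fit is undefined there.
* Constant chains get ESS 0 and a degenerate-chain note rather than NaN.
* The HDI of a point mass is a zero-width interval; `mass=1` returns
  `[min, max]`.
* Rank-deficient regression designs are rejected naming the collinear
  columns (leave-one-out rank test).
* Report values are rounded half-up to 2 decimals at render time only;
  verdicts and fractions are always computed on unrounded draws.
* Exclusion filters apply in a fixed order (incomplete, ambiguous health,
  under-age, after-cutoff); a row violating several rules is counted under
  the first. Filtering is idempotent.

## Problem sizes used in validation

The test suite fits reduced chains (2–4 chains, 300–2,500 retained draws)
chosen so that posterior-median and HDI assertions have comfortable
Monte-Carlo margins; the multi-group recovery study runs 20 seeded
replicates at the full study group sizes (n = 2,233 per replicate) with
4 x 1,200 draws. The conjugate-limit check pins `sigma` to (0.999, 1.001)
and floors `nu` at 500, where the t model is indistinguishable from the
normal closed form at the available Monte-Carlo precision. The acceptance
script uses one 4 x 2,000-draw multi-group fit and one 4 x 1,500-draw
regression fit.

## Known limitations

* The sampler is serial Python/NumPy; a full default-budget run over many
  variables takes minutes, not seconds.
* Rank-normalized R-hat and modern ESS variants are not implemented; the
  split-chain PSRF and initial-positive-sequence ESS are the classical
  forms.
* No multiplicity control across variables (each questionnaire is analyzed
  independently, by design — mirror of the source analysis).
* Bayes factors, model comparison, and multivariate outcome models are out
  of scope.
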