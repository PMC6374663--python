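# Methods

## The model

`fruitprod` models individual-level fruit production of tropical canopy and
subcanopy trees as a function of tree size, soil nutrient availability, and
neighborhood crowding, in a hierarchical Bayesian framework.

For tree *i* of species *j* the linear predictor is

    eta_ij = x_i' beta_j + beta_j,crowd * NCI_i(alpha_j, nu_j) / s + eps_i

where `x_i` holds an intercept plus globally z-scored covariates (DBH and,
depending on the covariate set, the three soil variables NMin, P, SBC),
`eps_i ~ Normal(0, precision tau)` is an individual random effect, and the
neighborhood crowding index is

    NCI_i = sum_k DBH_k^alpha_j * g(d_k; nu_j)

summed over all mapped neighbors within 10 m of tree *i* (conspecific and
heterospecific; neighborhoods are truncated at plot edges with no
correction, and never cross plots). The asymmetric variant ANCI restricts
the sum to neighbors with strictly greater DBH than the focal tree,
capturing size-asymmetric (light) competition. `s` is a fixed conditioning
constant (default 100) that the crowding slope absorbs.

Two distance kernels are provided. `"as_printed"` (the default) is
`g = exp(-nu/d)`, which *increases* toward 1 with distance — the opposite
of a conventional competition kernel, but a form this index has been
printed with, kept as the reference behavior rather than silently
corrected. `"decay"` is the conventional `g = exp(-nu*d)`. Results
can be produced under both.

Three analyses share this predictor:

* **Binomial** — reproductive status `R_i ~ Bernoulli(logit^-1(eta))`,
  where a tree is reproductive if any observation period recorded fruit.
* **All-individual ordinal (K = 4)** — a cumulative-logit
  (proportional-odds) model for the four ordered fruit-count categories
  (0; 1–100; 101–1,000; >1,000): `logit Q_k = gamma_k - eta`,
  `pi_k = Q_k - Q_{k-1}`, with cut points identified by
  `gamma_1 = 0 < gamma_2 < gamma_3`. The default per-tree response is the
  maximum category across the three observation periods.
* **Reproductive-only ordinal (K = 3)** — the same model on reproductive
  trees only, with the zero-fruit category dropped and codes relabeled
  1..3, isolating the drivers of fruit quantity after maturity.

Hierarchy and priors: `beta_j ~ MVNormal(mu, Sigma)` pools species;
`mu` elements get Normal(0, SD 100), `Sigma` an inverse-Wishart(identity,
dim + 2), `tau` a Gamma(0.001, 0.001) (precision parameterization), the
crowding shapes `alpha_j, nu_j` independent Gamma(1, 1), and the free cut
points a flat prior subject to ordering. Plot-level random effects are not included; plots enter only as spatial
containers for neighborhoods and soil interpolation. Species with fewer than two
reproductive individuals are excluded from fitting and logged.

## Inference

Models are fit by a blocked adaptive random-walk Metropolis-within-Gibbs
sampler (`inference.run_mcmc`):

* one block per species holding `beta_j` — and `(log alpha_j, log nu_j)`
  when the crowding shapes are estimated — with a Haario-style adaptive
  proposal covariance and Robbins–Monro global scaling (burn-in only).
  The joint block matters: `beta_crowd` and `log alpha` share an
  exponential posterior ridge (see *Identifiability* below);
* all `eps_i` updated in one vectorized pass of independent single-site
  proposals (valid because the likelihood factorizes over trees);
* an interweaving rescale move `(eps, tau) -> (c*eps, tau/c^2)` whose
  acceptance ratio reduces to the likelihood ratio plus O(0.001) prior
  terms; without it the weakly identified scale of the random effects (and
  hence pD and DIC) mixes far too slowly;
* a joint random-walk update of the free cut points, rejecting unordered
  proposals;
* conjugate Gibbs draws for `mu` (normal), `Sigma` (inverse-Wishart) and
  `tau` (gamma).

Convergence is monitored with the classic Gelman–Rubin potential scale
reduction factor (threshold 1.1); posterior summaries report both SD-based
intervals (mean ± 2 SD for 95%, ± 1.5 SD for 87% — the convention used for
effect classification) and central quantile intervals, plus effective
sample sizes.

Chain protocols: `TEST_SCALE` (3 chains × 5,000 iterations, burn-in 1,000)
for desk-scale work, and the field protocols `FIELD_SCALE_BINOMIAL`
(3 × 50,000 retained after ≥10,000 burn-in) and `FIELD_SCALE_MULTINOMIAL`
(3 × 100,000, thinned to every 10th). Every run is reproducible from a
single integer seed; chains use independently spawned generators.

## Model comparison and effect classification

DIC is computed in conditional form (random effects in focus, matching
what a WinBUGS fit reports): `Dbar` is the mean recorded deviance,
`D(theta-bar)` the deviance at the posterior mean of *all* sampled
quantities (cut points averaged then re-sorted), `pD = Dbar -
D(theta-bar)`, `DIC = Dbar + pD`. Ties within numerical precision go to
the less complex covariate set and are flagged. Comparisons refuse to mix
fits whose data fingerprints differ.

Proper scoring rules supplement DIC: Brier and logarithmic scores for the
binomial analysis and the ranked probability score for the ordinal
analyses, each evaluated at the posterior-mean predictive distribution
(systematic effects per draw, individual effects at their posterior
means — a conditional predictive; the scoring is a package choice, since
no scoring appendix was available to follow).

Effects are classified per species and covariate: *strong* if the 95%
interval (mean ± 2 SD) excludes zero, *moderate* if the 87% interval
(± 1.5 SD) does, otherwise *weak*, with the sign from the posterior mean.

## Post-processing

The reproductive threshold `D_thres` of a species is the DBH at which the
binomial model's reproduction probability is 0.5. Per posterior draw the
crossing `eta = 0` is solved in closed form on the standardized scale and
back-transformed; draws with a non-positive DBH coefficient leave the
threshold undefined and are excluded, with the excluded fraction reported
(a bisection solver cross-checks the closed form). Reference covariates
sit at standardized zero (sample means), `eps = 0` (the population-median
curve); with a crowding term, the crowding covariate sits at its per-draw
species-mean index value, the analog of a sample mean for a covariate that
cannot be pre-standardized.

The interspecific scaling hypothesis `D_thres = 1/2 D_max` is evaluated on
the log scale: OLS of `ln D_thres` on `ln D_max`, plus `1 - SSR/SST` for
the constrained line `ln D_thres = ln D_max - ln 2`. Seed-mass regressions
relate posterior-derived responses (thresholds, average category
probabilities over each species' observed DBH range) to dry seed mass,
with and without a configurable exclusion list. Prediction curves sweep
DBH (or the raw crowding-index value directly) and report posterior mean
category probabilities with central interval bands.

## Synthetic data

The generator (`synthetic_data`) emulates the study conditions: five
41 × 240 m mapped plots; 17 species with ≥ 50 stems each (abundances
echoing the census's spread); truncated-lognormal DBH ≥ 5 cm, skewed
toward small stems; a soil design of 200 one-meter transect composites
down the plot center plus a 10-m lattice (325 samples per 41 × 240 plot);
nutrient surfaces built from two rotated sinusoidal trends (length scale
60 m, amplitude 35% of the mean) plus 10% white noise, clipped at zero —
enough spatial autocorrelation to exercise interpolation without modeling
real pedogenesis; and three observation periods whose categories are
independent draws from the cumulative-logit model given each tree's
`eps_i`. Default truth: hyper-means (intercept, DBH, crowding) =
(−1, 1.5, −1) on the standardized scale, species SDs 0.3–0.5, `tau = 4`
(eps SD 0.5), cut points (0, 1.5, 3), `alpha = nu = 1` — a moderately
size-driven, crowding-suppressed community in which roughly 20–40% of
stems fruit. Optional log-uniform latent counts inside the drawn category
(top category capped at 10,000) support the count-vs-category validation
utilities. Stems are uniform within plots by default; a Thomas cluster
process is available per species.

What the generator does *not* emulate: phenology and masting time series,
dioecy, observation error in the ordinal assessments, and real soil
chemistry. Passing recovery tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness to
the field realities the archived data contain.

Synthetic periods are exchangeable draws, so recovery experiments fit the
ordinal model at the observation level (all periods, sharing each tree's
random effect), which is exactly specified; the max-category reduction —
kept as the default pipeline path for fidelity to the field protocol, where
periods target different phenologies — is *not* an ordinal-logit model of
any single draw (the maximum of three iid draws has cumulative probability
`Q_k^3`), so fitting it to exchangeable synthetic periods would bias
recovery checks.

## Identifiability of the crowding shapes

From a single mapped stem map, `alpha` is close to unidentified: every
focal neighborhood shares nearly the same size composition (the mean log
neighbor DBH varies only a few percent across trees), so raising `DBH` to
`alpha` mostly rescales the whole index by `exp(alpha * mean log DBH)` —
a change the crowding slope absorbs exactly. The Gamma(1, 1) prior (an
exponential, with mode at zero) then pulls `alpha` low, and `beta_crowd`
inflates along the ridge. Two consequences:

* the *sign* of the crowding effect and its CI-versus-zero classification
  are invariant along the ridge — the quantities the analysis interprets
  are robust;
* the crowding slope has no consistent point estimate when the shapes are
  free. Parameter-recovery experiments therefore condition on the known
  generative `(alpha_j, nu_j)` via the `crowding_shapes` model option;
  the unconditional model remains the default everywhere else.

## Numerical choices

* Closed 10-m neighborhood ball (ties included); distances clamped at
  0.1 m for coincident multi-stem mapping artifacts; NCI exponents capped
  at 700 so extreme sampler proposals are rejected on likelihood grounds
  rather than overflowing.
* Inverse-distance soil interpolation uses the 5 nearest samples at power
  1 (configurable); a coincident sample is returned exactly; plots with
  fewer than 5 samples use all available with a warning.
* Ordinal likelihood cells are evaluated on the log scale with
  `expm1`/`logaddexp` identities; probabilities sum to one within 1e-12
  over the tested range.
* Initialization: intercepts at empirical species logits, other
  coefficients zero, chain-specific jitter for overdispersed starts; cut
  points from pooled empirical cumulative logits; up to five
  re-initializations if the posterior is non-finite at the start.
* The Gelman–Rubin statistic is floored at 1.0 (values below are
  finite-sample artifacts).

## Problem sizes used in the shipped experiments

The test-suite and acceptance-script experiments run at desk scale, chosen
so each stage still has sufficient power: recovery uses 4 species × 200
trees × 3 periods with chains 3 × 5,000 over 20 replicates; model-selection
recovery uses 2 species × 150 trees over 12 replicates (ordinal
three-period fits, whose repeated observations keep conditional pD
stable); threshold recovery uses 180 trees over 20 replicates; the
acceptance script runs the full pipeline on a 5-plot, 17-species community
(~2,200 stems). The field-scale chain protocols are shipped as named
configurations and exercised through the same interfaces.

## Known limitations

* Conditional DIC with individual random effects on *binary single
  observations* is unstable at small n (the overfit region of `(eps, tau)`
  is only weakly penalized by the vague prior); the ordinal repeated-
  observation analyses do not share this problem. Marginal DIC is out of
  scope.
* The `"as_printed"` kernel rewards, rather than penalizes, distance;
  conclusions that depend on the kernel's direction should be checked
  under `"decay"`.
* `eps` draws are summarized (pooled means/SDs) rather than stored, so
  per-tree posterior intervals for random effects are not available from
  saved samples.
* Prediction curves and thresholds fix `eps = 0` (population-median
  curves) rather than marginalizing over the random-effect distribution.
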