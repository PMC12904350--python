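# Methods

## Response model

Items are dichotomous and follow the Birnbaum 3-parameter logistic model:
P(θ) = c + (1 − c)·logistic(a(θ − b)), with discrimination a > 0 (logit
units per trait SD), difficulty b on the θ scale, and lower asymptote
0 ≤ c < 1 capturing guessing on multiple-choice items. Fisher information is
I(θ) = a²(Q/P)((P − c)/(1 − c))², Q = 1 − P, which reduces to a²PQ at c = 0.
Probabilities are computed through `scipy.special.expit`, so extreme logits
saturate cleanly instead of overflowing. Polytomous models and item
parameter estimation are out of scope: the engine consumes an
already-calibrated bank.

## Scoring

Scoring is expected a posteriori (EAP) on a quadrature grid. The latent
trait is discretised on `n_grid_points` equally spaced points over
[`theta_min`, `theta_max`] (default 49 points on [−4, 4] — the conventional
CAT-simulation default; configurable). Prior weights are the Normal(0, 1)
density at the points multiplied by composite-trapezoid quadrature
coefficients (half weight at the two endpoints) and renormalised. Each
response multiplies the weights by its Bernoulli likelihood, followed by
renormalisation; the update is commutative up to rounding, so full-length
scores do not depend on administration order. The point estimate is the
posterior mean; the standard error is the posterior SD. Interim and
full-length estimates use the identical machinery.

Numerical notes:

* The trapezoid endpoint coefficients matter. With raw density weights
  (rectangle rule) the worst-case deviation of the posterior SD from a
  10,001-point dense-quadrature reference is ≈5×10⁻³ over random 8-item
  response patterns, dominated by posteriors that pile mass near a grid
  boundary; with trapezoid coefficients it is ≈5×10⁻⁴. The test suite
  asserts 10⁻³ agreement with the dense oracle.
* Truncating and renormalising the prior on [−4, 4] leaves the on-grid
  prior SD slightly below 1.0 (≈0.9994); this is inherent to quadrature
  EAP and is documented rather than corrected.
* Posterior mass cannot vanish for valid items (c > 0 or finite logistic),
  but a zero-mass update raises `NumericalError` rather than producing NaN.

## Item selection

The next item maximises posterior weighted information: Σₖ I_item(xₖ)·wₖ
over grid points xₖ with posterior weights wₖ. Ties break to the lowest bank
index, making every session fully deterministic. While the posterior is
still the bare prior, the first item is chosen by maximum Fisher information
at θ = 0.0 (default) or by MPWI under the prior; with a symmetric prior the
two rules almost always coincide, and both are exposed because descriptions
of the first-item setting in the CAT literature conflate "first item at the
prior mean" with "selection weighted by the prior". No exposure control or
content balancing is applied — this mirrors a prototype adaptive instrument
whose bank is too small for content constraints.

## Stopping rules

Two rules are evaluated after each response is absorbed (never before the
first item): the primary rule stops when SE ≤ `se_threshold`; the secondary
rule stops when `max_items` have been administered. When both fire on the
same item the recorded reason is the SE rule, so the two termination classes
partition the cohort deterministically. `min_items` defaults to 1 — with a
prior SD near 1.0 every realistic threshold admits the first item anyway,
and the floor only guards degenerate configurations. A consequence of
evaluating stopping only after responses is that observed minimum lengths
are data-driven, not configured.

## Simulation modes and the synthetic generator

Post-hoc mode replays a complete recorded 0/1 matrix through the adaptive
logic; it involves no random number generator, so repeated runs are
byte-identical. Generative mode draws responses Bernoulli(P(θᵢ)) from known
true θ and is intended for recovery experiments.

The synthetic generator emulates a calibration study of n = 1000 respondents
on a 22-item, four-option multiple-choice bank:

* θ ~ Normal(0, 1) — the standardized trait metric;
* a ~ LogNormal(log 1.2, 0.35), truncated to [0.5, 3.0] — a realistic
  positive discrimination range for screened items;
* b ~ Normal(0, 1), truncated to [−3, 3] — difficulties covering the bulk
  of the trait distribution;
* c ~ Beta(5, 20) (mean 0.2) — empirical 3PL calibrations of four-option
  items typically land somewhat below the nominal 0.25 chance rate.

All parameters live in `SyntheticSpec`; the single seed drives three
independent child streams (bank, thetas, responses), so a cohort is
reproducible from one integer. What the generator does **not** emulate:
local dependence between items, differential item functioning across
subgroups, missing responses, and the empirical clustering of difficulties
that screened real banks show. Passing tests on synthetic cohorts therefore
demonstrate the engine's correctness and the qualitative behaviour of the
stopping rules, not the quantitative test-length distribution of any
particular real instrument: banks drawn from these defaults are, on
average, less informative than a well-screened operational bank, so median
adaptive lengths at an SE 0.50 threshold typically fall in the 10–15 range
and vary noticeably from seed to seed.

## Evaluation conventions

Fixed so that outputs are bit-reproducible:

* Pearson correlations; population (n-denominator) SDs in summaries;
  linear-interpolation percentiles for medians and IQRs.
* Correlation-by-length curves use carry-forward: a respondent who stopped
  before step k contributes their final θ at step k, matching how a
  deployed CAT capped at k items would score them. (Restricting to
  still-active respondents is possible by filtering results, but
  carry-forward is the default because it reflects operational use.)
* The SE-reduction analysis reports, per step k, the share of respondents
  who took item k+1 whose SE dropped by more than δ = 0.01 (configurable);
  steps nobody reached are omitted rather than reported as zero.
* RMSE is computed against full-length EAP θ from the same response matrix,
  the natural in-sample reference for post-hoc designs.
* Static short forms for comparison are scored by the same EAP machinery on
  a fixed item subset; `top_information_subset` picks the k items with
  maximal Fisher information at θ = 0, a standard way to assemble a strong
  fixed form when no published subset exists.

## Problem sizes

The bundled tests and the acceptance script use cohorts of up to 1000
respondents × 22 items and dense-grid oracles of 10,001 points; a full 2×3
stopping-rule design over such a cohort runs in a few seconds on one core,
so the package is comfortably interactive at realistic calibration-study
scale.

## Known limitations

* No content balancing, exposure control, or randomesque selection.
* Dichotomous items only; no polytomous or multidimensional models.
* EAP/posterior-SD only (no ML/MAP/weighted-likelihood scoring).
* Post-hoc simulation requires a complete response matrix; missing data
  must be handled upstream.
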