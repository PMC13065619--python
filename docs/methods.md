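# Methods

## The model

QFASA (quantitative fatty acid signature analysis) reconstructs a
consumer's diet from the fatty-acid (FA) composition of its stored
triglycerides.  A *signature* is the vector of FA concentrations in µg of
fatty acid per mg of sample.  The model makes three assumptions: no
discrimination between absorbed and excreted FAs during digestion, no
interconversion of FAs after consumption, and no discrimination between
storage and oxidation after absorption.  Under those assumptions a
consumer's stored fat is a convex mixture of its food sources' signatures:

    stored_i ≈ cc_i · Σ_k p_k · m_{k,i}

where `m_{k,i}` is the mean concentration of FA *i* in food *k*, `p` is
the diet-proportion vector on the simplex (`p_k ≥ 0`, `Σ p_k = 1`), and
`cc_i` is a per-FA *calibration coefficient* absorbing whatever
discrimination and interconversion the three assumptions ignore
(`cc = 1` everywhere means the assumptions hold exactly).

The diet estimate is the simplex point minimizing the summed absolute
deviation between predicted and observed signatures; evaluated at the
optimum this is the *best model deviation* (BMD, µg/mg).  The squared
Pearson correlation between the best-fit prediction and the observation
is reported alongside as a scale-free fit measure.

## The search

`fit_diet` enumerates every grid point of the simplex at resolution
`step` (default 0.01, i.e. 1%, consistent with integer-percent diet
tables) and returns the global grid minimum.  The enumeration is
exhaustive — no pruning or descent heuristics — with the last three
composition coordinates vectorised and any leading coordinates looped, so
memory stays bounded at any grid resolution.  Ties are broken toward the
lexicographically smallest proportion vector in sorted source order, and
the number of tying grid optima is reported (`n_ties`); ties arise in
practice only from duplicated or exactly collinear sources.

Absolute deviation was preferred by the source analysis over squared
deviation; it is also what makes the exact cross-check tractable: on the
common-total scaling (below) the objective is piecewise linear in `p`, so
the continuous optimum is a linear program.  The test suite solves that LP
(scipy/HiGHS) as an independent oracle and verifies the grid minimum lands
within one grid step's worth of deviation of it.

## Scaling convention

Published food-source signatures have subset totals that differ by ~20%
across foods, while deviations are reported in µg/mg.  By default every
signature — food means, predictions, and the observation — is restricted
to the selected FA subset and linearly rescaled to a common subset total
(the observed fat's subset total), so deviations compare compositions on a
like-for-like µg/mg scale.  `rescale=False` fits in raw units instead.
Two consequences:

- Calibration vectors are identifiable only up to a common positive
  factor, because predictions are re-closed after applying them.  Derived
  vectors are stored unnormalised; comparisons should be made modulo a
  common factor (e.g. after centering log coefficients).
- A consumer constructed as an exact mixture over the *full* FA set is no
  longer an exact on-grid mixture after restriction to a subset: the
  representation weights get tilted by the sources' subset totals.  On the
  default scenario this leaves a residual BMD below ~1% of the subset
  total at zero noise; diet recovery is still exact to one grid step.

## Fatty-acid selection

`select_shared_fas` keeps FAs whose unweighted mean across the supplied
per-species mean signatures strictly exceeds a floor (default 5.0 µg/mg).
Applied to the packaged consumer table (plateau pika and laboratory
mouse), it reproduces the ten abundant storage FAs: 12:0, 14:0, 15:0,
16:0, 16:1, 17:0, 18:0, 18:1, 18:2, 18:3n3.

## Calibration coefficients as outputs

Feeding trials to measure `cc` directly are often infeasible.  Instead,
the calibration stage treats coefficients as outputs: fit a small set of
*index animals* (one per site, drawn uniformly with a required seed) with
`cc = 1`; compute `cc_i = observed_i / predicted_i` per FA, which by
construction makes each index fit perfect; average the unlogged
coefficients arithmetically across index animals (geometric averaging is
available but not the default); and refit the whole cohort with the
averaged vector.  Reported logs follow the convention that a positive
`ln cc_i` means storage of FA *i* is enriched relative to the consumed
mixture, negative means depleted.

**Identifiability caveat.**  Derived coefficients are faithful only insofar
as the unity-stage fit recovers the true diet.  A distortion direction that
between-food signature differences can mimic is partially absorbed into the
diet estimate instead of the coefficients: in simulations, a mild distortion
collinear with food contrasts was recovered with log-scale errors up to
~0.17, while an equally seeded distortion orthogonal to the food span (a
3× enrichment of 16:1, which no food mixture can produce) was recovered to
within 0.03 log units.  The recovery tests therefore use the orthogonal
construction; on real data the derived coefficients should be read as the
component of diet–storage discrimination not confounded with diet.

## Solution uniqueness

For each source, the uniqueness profile records the minimal deviation over
all grid diets holding that source's proportion fixed at each grid value.
A source is flagged *multimodal* when a proportion with deviation within a
tolerance (default 1%) of the global minimum lies farther than
max(2 grid steps, 5% of the axis) from the optimum.  A shallow single
basin therefore does not flag; a flat exchange direction between
(near-)identical sources, or a genuinely separate basin, does.  On
study-like synthetic cohorts no flags fire, matching the qualitative
uniqueness the source analysis reported.

## Negative control

Because any signature can be "fitted" by some mixture, fit quality needs a
floor: consumers known not to eat the candidate foods.  The packaged
control profile is laboratory-mouse subcutaneous fat — rich in 18:1
(459.8 µg/mg vs 104.8 in the pika) and essentially lacking 18:3n3 (1.0 vs
266.6) — which no mixture of grass, roots and yak feces approximates.  The
per-site comparison is a two-sample t-test on BMDs, Welch's by default
(conservative at n = 5–8 per group); Student's pooled test is available.
On the packaged reference means, the pika profile fits the low-site foods
with BMD ≈ 401 µg/mg versus ≈ 726 for the mouse, reproducing the direction
and rough magnitude of the published ~350 vs ~750 contrast.

## Synthetic scenarios

The generator emulates the study's sampling design so every stage is
testable without the archived per-animal data:

- **Food libraries** — per site and source, 8 replicates per FA drawn from
  a normal with the packaged printed mean and a coefficient of variation
  drawn uniformly from 2–5%, truncated at zero.  Structural zeros (FAs
  genuinely absent from a source, e.g. 13:0 outside feces) never receive
  noise.  Gaussian noise proportional to the mean was chosen because
  printed replicate sds scale roughly with means.
- **Consumers** — 20 animals split 8/7/5 across the low/medium/high sites,
  each an exact mixture of its site's empirical food means, optionally
  distorted by a known `true_cc` and multiplicative noise
  (`consumer_noise_cv`, default 0.02; no published within-animal variance
  exists, so this is an assumption).  The default diets are bimodal in the
  feces fraction — six animals below 5%, fourteen between 10 and 49%,
  site means 12.8/20.4/26.2% — mirroring the published refined cohort
  summary.
- **Controls** — five mouse-like consumers drawn around the packaged mouse
  profile.

What the generator does *not* emulate: physiological FA interconversion
dynamics (only the static `cc` abstraction), within-site spatial structure,
and the long-tailed replicate variation some printed sds show (e.g. a
replicate sd of 43 on a mean of 106 for feces 18:1).  Passing recovery
tests therefore demonstrate correctness of the estimator under the model's
own assumptions, not robustness to violations of them.

## Numerical choices

- Grid step 0.01 default; the step must divide 1 exactly.  Problem sizes
  in tests: 1%-grid fits for all cohort work (5 151 grid points for three
  sources), 0.1%-grid fits for the oracle comparison (up to ~1.7 × 10⁸
  points for four sources, evaluated in vectorised blocks).
- Deviations are accumulated in float64; grid ties are detected by exact
  float equality, which is reproducible because the enumeration order is
  deterministic.
- `r²` is reported as `nan` when a correlation is undefined (fewer than
  three FAs or a constant vector), rather than failing the fit.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; index-animal selection requires a seed by design.

## Known limitations

- Diet estimates carry no sampling uncertainty (no bootstrap over food
  replicates); the uniqueness profile is the only spread diagnostic.
- Calibration derived from three index animals is an average over
  individuals whose own diets are estimated, not known — see the
  identifiability caveat above.
- The >5.0 µg/mg selection rule is a fixed screen, not optimised for
  source discrimination.
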