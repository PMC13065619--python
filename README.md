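# qfasa

Quantitative fatty acid signature analysis (QFASA): estimating what an
animal has been eating from the fatty-acid composition of its stored body
fat.

Food sources differ in their fatty-acid (FA) signatures, and animals tend
to deposit dietary fat with limited conversion, so a consumer's adipose
signature is approximately a convex mixture of its foods' signatures.
This package implements the full analysis for that idea as applied to a
terrestrial case — the plateau pika (*Ochotona curzoniae*) overwintering
on the Qinghai–Tibetan plateau, where grass, plant roots and yak feces are
the candidate winter foods:

- **Mixture fitting** — exhaustive search of the diet-proportion simplex
  at a fixed grid resolution for the mixture minimizing the summed
  absolute deviation (the *best model deviation*, BMD, in µg/mg) between
  predicted and observed signatures, with per-source
  deviation-vs-proportion profiles as a solution-uniqueness diagnostic.
- **Calibration coefficients as outputs** — per-FA multipliers `cc_i`
  capturing diet→storage discrimination, derived as `observed/predicted`
  ratios from seeded index animals fitted with `cc = 1`, averaged
  unlogged, and fed back into a cohort-wide refit.
- **Cohort reporting** — per-site diet tables, sample-size-weighted pooled
  means, a Welch t-test against a negative-control species (laboratory
  mice, which demonstrably ate none of the candidate foods), and
  classification of consumers against a coprophagy threshold.
- **Synthetic scenarios** — seeded generators for food libraries
  (8 replicates/source/site, 2–5% CVs) and consumer cohorts built as known
  mixtures with known distortion and noise, so every stage is testable
  end to end.  Published food-source and consumer mean signatures ship as
  packaged CSV fixtures.

The model: per fatty acid *i*,

    predicted_i = cc_i · Σ_k p_k · m_{k,i}

with `p` on the simplex and signatures compared on a shared abundant-FA
subset after rescaling to a common subset total; the estimate is

    p̂ = argmin_p Σ_i | predicted_i − observed_i |

found by exhaustive grid enumeration (default step 1%).

## Worked example

```python
from qfasa import Signature, fit_diet

foods = {
    "food1": Signature({"16:0": 100.0, "18:0": 0.0}),
    "food2": Signature({"16:0": 0.0, "18:0": 100.0}),
}
observed = Signature({"16:0": 38.0, "18:0": 62.0})
fit = fit_diet(observed, foods, step=0.01)
print(fit.diet.proportions, fit.bmd)
```

prints

```
{'food1': 0.38, 'food2': 0.62} 0.0
```

— a fat store holding 38% of FA1 and 62% of FA2 is explained exactly
(zero deviation) by drawing 38% of its fatty acids from food 1.  With
foods (80, 20) and (60, 40) instead, no mixture can reproduce the
observation (both foods are richer in FA1 than the fat is) and the fit
returns 100% food 2 with BMD 44 — the least-deviant corner.

A full two-pass pipeline (simulate a pika-like cohort, fit with `cc = 1`,
derive calibration coefficients from three index animals, refit, compare
against mouse controls) runs from a YAML config:

```
qfasa run --config scenario.yaml
```

```yaml
# scenario.yaml
scenario:
  seed: 11
  consumer_noise_cv: 0.02
  n_controls: 5
out_dir: demo_run
index_seed: 7
step: 0.01
```

The run writes `fits_unity.csv`, `cc.csv`, `fits_calibrated.csv`,
`report.json` and a reproducibility manifest.  On this scenario the
report shows the cohort structure the generator encodes being recovered
from the signatures alone: 14 of 20 animals above the 10% feces
threshold (`"count_above": 14, "fraction": 0.7`), a bimodal histogram
(`[6, 0, 14, 0]` across the 0–5 / 5–10 / 10–50 / 50–100% bins), pooled
feces contribution 18.7%, and mouse controls fitting the food library an
order of magnitude worse than the pika-like consumers
(`mean_control_bmd ≈ 919` vs `mean_target_bmd ≈ 12` µg/mg,
p ≈ 2.6 × 10⁻⁵).

Subcommands `qfasa simulate | fit | calibrate | report` expose the stages
individually; all tables are plain CSV (long or wide signature dialects).

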