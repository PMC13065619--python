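"""Seeded generators for food libraries and consumer cohorts.

The generator emulates the statistical structure the diet-reconstruction
pipeline assumes: per-site food sources measured in replicate with small
coefficients of variation (2–5% by default, 8 replicates per source and
site), and consumers whose stored fat is a known convex mixture of the
site's food means, distorted per fatty acid by a known calibration vector
and multiplicative noise.  Every draw is seeded, so scenarios are
bit-reproducible.

Default mean signatures are published field values for three food sources
(grass, roots, yak feces) at three elevation sites on the Qinghai–Tibetan
plateau, and the mean stored-fat profiles of the plateau pika (the study
consumer) and of laboratory mice fed an unrelated diet (the negative
control).  They ship as packaged CSV fixtures.  Structural zeros — fatty
acids genuinely absent from a source, like 13:0 outside feces — never
receive noise.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .calibration import derive_calibration
from .cohort import fit_cohort
from .core import CalibrationVector, DietProportions
from .signatures import (
    ConsumerSample,
    Signature,
    SourceLibrary,
    SourceSampleSet,
    ValidationError,
    canonical_fa_order,
    select_shared_fas,
    species_mean_signatures,
)

__all__ = [
    "ScenarioConfig",
    "reference_food_library_means",
    "reference_consumer_means",
    "reference_cc",
    "default_consumer_diets",
    "gen_source_library",
    "gen_consumer",
    "gen_cohort",
    "gen_negative_controls",
    "recovery_experiment",
]

_SITES = ("low", "medium", "high")


def _data_frame(name: str) -> pd.DataFrame:
    with resources.files("qfasa.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def reference_food_library_means() -> dict[tuple[str, str], tuple[Signature, dict[str, float]]]:
    """Published per-site food means and sds: {(source, site): (mean, sd)}."""
    df = _data_frame("food_sources.csv")
    out: dict[tuple[str, str], tuple[Signature, dict[str, float]]] = {}
    for (source, site), grp in df.groupby(["source", "site"], sort=False):
        mean = Signature(dict(zip(grp["fa_label"], grp["mean_ug_per_mg"])))
        sd = dict(zip(grp["fa_label"], grp["sd_ug_per_mg"]))
        out[(source, site)] = (mean, sd)
    return out


def reference_consumer_means() -> dict[str, Signature]:
    """Published mean stored-fat signatures per species (pika, mouse)."""
    df = _data_frame("consumer_fat.csv")
    return {
        species: Signature(dict(zip(grp["fa_label"], grp["mean_ug_per_mg"])))
        for species, grp in df.groupby("species", sort=False)
    }


def reference_cc(labels: Sequence[str] | None = None) -> CalibrationVector:
    """A published-style calibration vector over the 10 abundant storage FAs.

    Strong enrichment of 16:1 and 18:3n3 in storage, strong depletion of
    12:0 and 18:0, mild factors elsewhere.  Useful as a realistic non-unit
    distortion in simulations.
    """
    base = {
        "12:0": 0.176, "14:0": 1.2, "15:0": 0.9, "16:0": 1.1, "16:1": 5.658,
        "17:0": 0.8, "18:0": 0.537, "18:1": 1.0, "18:2": 1.3, "18:3n3": 2.37,
    }
    if labels is None:
        return CalibrationVector(base)
    return CalibrationVector({lab: base.get(lab, 1.0) for lab in labels})


def default_consumer_diets() -> list[tuple[str, DietProportions]]:
    """Twenty (site, diet) pairs mirroring the study cohort's structure.

    Sample sizes 8/7/5 across the low/medium/high sites; feces fractions
    bimodal (six animals below 5%, fourteen between 10 and 49%, fourteen
    above 10%) with site means near 12.8/20.4/26.2%; roots substantial at
    the low site and near zero at the high site.
    """
    feces = {
        "low": [0, 2, 3, 4, 15, 20, 26, 32],
        "medium": [3, 12, 18, 22, 28, 29, 31],
        "high": [4, 18, 26, 35, 48],
    }
    roots = {
        "low": [38, 36, 34, 34, 30, 28, 28, 28],
        "medium": [30, 26, 22, 16, 14, 10, 6],
        "high": [1, 0, 0, 0, 0],
    }
    out: list[tuple[str, DietProportions]] = []
    for site in _SITES:
        for f, r in zip(feces[site], roots[site]):
            g = 100 - f - r
            out.append(
                (site, DietProportions({"grass": g / 100, "roots": r / 100,
                                        "feces": f / 100}))
            )
    return out


@dataclass
class ScenarioConfig:
    """Everything needed to generate one synthetic study.

    ``sources_per_site`` maps (source, site) to a mean signature; the
    default is the packaged published table.  ``food_cv`` is the range the
    per-FA replicate coefficient of variation is drawn from (uniformly);
    ``consumer_noise_cv`` is the multiplicative noise applied to consumer
    fat (the within-animal measurement scatter, for which no published
    value exists — 2% is an assumption).  ``true_cc`` defaults to no
    distortion.  The seed is required.
    """

    seed: int
    sources_per_site: Mapping[tuple[str, str], Signature] | None = None
    replicates_per_source: int = 8
    food_cv: tuple[float, float] = (0.02, 0.05)
    true_cc: CalibrationVector | None = None
    consumer_diets: list[tuple[str, DietProportions]] = field(
        default_factory=default_consumer_diets
    )
    consumer_noise_cv: float = 0.02
    n_controls: int = 5

    def __post_init__(self) -> None:
        lo, hi = self.food_cv
        if not (0 <= lo <= hi < 1):
            raise ValidationError(f"food_cv bounds must satisfy 0 ≤ lo ≤ hi < 1: {self.food_cv}")
        if self.replicates_per_source < 1:
            raise ValidationError("need at least 1 replicate per source")
        if not (0 <= self.consumer_noise_cv < 1):
            raise ValidationError("consumer_noise_cv must lie in [0, 1)")
        if self.sources_per_site is None:
            self.sources_per_site = {
                key: mean for key, (mean, _) in reference_food_library_means().items()
            }

    @property
    def sites(self) -> list[str]:
        out: dict[str, None] = {}
        for _, site in self.sources_per_site:
            out.setdefault(site, None)
        return list(out)


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Multiplicative-style Gaussian draw clipped at zero; exact zeros in the
    mean stay exactly zero (structural zeros)."""
    draw = rng.normal(mean, sd)
    draw = np.clip(draw, 0.0, None)
    return np.where(mean == 0, 0.0, draw)


def gen_source_library(config: ScenarioConfig) -> SourceLibrary:
    """Replicate food signatures per site and source.

    Each FA's replicate values are drawn from a normal with the configured
    mean and a cv drawn uniformly from ``food_cv``, truncated at zero.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.food_cv
    sets: list[SourceSampleSet] = []
    for (source, site), mean_sig in sorted(config.sources_per_site.items()):
        labs = list(mean_sig.labels)
        mean = mean_sig.aligned(labs)
        cvs = rng.uniform(lo, hi, size=len(labs))
        sds = mean * cvs
        reps = [
            Signature.from_arrays(labs, _truncated_normal(rng, mean, sds))
            for _ in range(config.replicates_per_source)
        ]
        sets.append(SourceSampleSet(source_name=source, site=site, replicates=reps))
    return SourceLibrary(sets)


def gen_consumer(
    diet: DietProportions,
    library_site_means: Mapping[str, Signature],
    true_cc: CalibrationVector | None,
    noise_cv: float,
    seed: int | np.random.Generator,
    *,
    animal_id: str = "synthetic",
    species: str = "pika",
    site: str = "synthetic",
) -> ConsumerSample:
    """A consumer whose fat is the cc-distorted diet mixture plus noise.

    fat_i = cc_i × Σ_k p_k mean_{k,i}, re-closed to the mixture total, then
    perturbed per FA by multiplicative Gaussian noise of the given cv,
    truncated at zero.  Structural zeros stay zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sources = sorted(library_site_means)
    unknown = set(diet.sources) - set(sources)
    if unknown:
        raise ValidationError(f"diet references unknown source(s): {sorted(unknown)}")
    labs = canonical_fa_order(
        [lab for s in sources for lab in library_site_means[s].labels]
    )
    M = np.vstack([library_site_means[s].aligned(labs) for s in sources])
    p = diet.as_array(sources)
    mix = p @ M
    total = mix.sum()
    if true_cc is not None:
        pred = mix * true_cc.expanded(labs)
        pred = pred * (total / pred.sum())
    else:
        pred = mix
    fat = _truncated_normal(rng, pred, pred * noise_cv)
    return ConsumerSample(
        animal_id=animal_id, species=species, site=site,
        fat=Signature.from_arrays(labs, fat),
    )


def gen_cohort(config: ScenarioConfig) -> tuple[SourceLibrary, list[ConsumerSample]]:
    """A full scenario: the food library plus one consumer per configured diet."""
    library = gen_source_library(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    consumers: list[ConsumerSample] = []
    for i, (site, diet) in enumerate(config.consumer_diets, start=1):
        means = library.site_means(site)
        consumers.append(
            gen_consumer(
                diet, means, config.true_cc, config.consumer_noise_cv, rng,
                animal_id=f"P{i:02d}", species="pika", site=site,
            )
        )
    return library, consumers


def gen_negative_controls(
    config: ScenarioConfig,
    *,
    control_mean: Signature | None = None,
) -> list[ConsumerSample]:
    """Mouse-like control consumers drawn around an unrelated fat signature.

    The default control mean is the packaged laboratory-mouse profile
    (18:1-rich, essentially no 18:3n3) — a consumer that demonstrably did
    not eat any of the library foods.  Controls are spread over the sites
    round-robin so site-matched fitting works.
    """
    mean = control_mean if control_mean is not None else reference_consumer_means()["mouse"]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    labs = list(mean.labels)
    mu = mean.aligned(labs)
    sites = config.sites or list(_SITES)
    out = []
    for i in range(config.n_controls):
        fat = _truncated_normal(rng, mu, mu * config.consumer_noise_cv)
        out.append(
            ConsumerSample(
                animal_id=f"M{i + 1:02d}", species="mouse",
                site=sites[i % len(sites)],
                fat=Signature.from_arrays(labs, fat),
            )
        )
    return out


def recovery_experiment(
    config: ScenarioConfig,
    step: float = 0.01,
    *,
    fa_threshold: float = 5.0,
    include_calibration: bool = False,
    calibration_seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """True-vs-estimated diets for one scenario, with error summaries.

    Generates the scenario, restricts to the abundant-FA subset chosen from
    the consumers themselves, fits every consumer, and reports per-source
    absolute errors.  With ``include_calibration`` the calibration stage
    runs (index animals from the cohort, seeded) and the cohort is refitted
    with the averaged coefficients; the returned summary then includes the
    mean absolute log-ratio between averaged and true coefficients.
    """
    library, consumers = gen_cohort(config)
    subset = select_shared_fas(
        list(species_mean_signatures(consumers).values()), threshold=fa_threshold
    )
    cc = None
    summary: dict[str, float] = {}
    if include_calibration:
        seed = config.seed if calibration_seed is None else calibration_seed
        cc, _ = derive_calibration(
            consumers, library, seed=seed, step=step, fa_subset=subset
        )
        if config.true_cc is not None:
            labs = [lab for lab in subset if lab in config.true_cc.labels]
            est = cc.as_array(labs)
            true = config.true_cc.as_array(labs)
            # compare up to the unidentifiable common factor
            log_ratio = np.log(est / true)
            log_ratio -= log_ratio.mean()
            summary["cc_mean_abs_log_error"] = float(np.abs(log_ratio).mean())

    report = fit_cohort(consumers, library, cc=cc, step=step, fa_subset=subset)

    rows = []
    errs = []
    for (site, true_diet), animal in zip(config.consumer_diets, consumers):
        fit = report.fits[animal.animal_id]
        for s in sorted(true_diet.sources):
            true_p = true_diet[s]
            est_p = fit.diet[s]
            errs.append(abs(est_p - true_p))
            rows.append(
                dict(animal_id=animal.animal_id, site=site, source=s,
                     true_proportion=true_p, estimated_proportion=est_p,
                     abs_error=abs(est_p - true_p), bmd=fit.bmd)
            )
    table = pd.DataFrame(rows)
    summary["mean_abs_error"] = float(np.mean(errs))
    summary["max_abs_error"] = float(np.max(errs))
    summary["rmse"] = float(np.sqrt(np.mean(np.square(errs))))
    summary["mean_bmd"] = float(report.per_animal["bmd"].mean())
    return table, summary
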