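"""Cohort-level orchestration: per-site fit tables, negative-control
comparison, pooled summaries and consumer classification.

A cohort report collects one mixture fit per animal, aggregates the fitted
source percentages and best model deviations (BMD) by site, and pools the
site means weighted by sample size.  A negative control — animals known not
to eat any of the candidate foods — bounds the credibility of the target
cohort's reconstructions: if the control animals fit the food library about
as well as the target animals do, the diet estimates carry little weight.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import CalibrationVector, FitResult, fit_diet
from .signatures import (
    ConsumerSample,
    Signature,
    SourceLibrary,
    ValidationError,
)

__all__ = [
    "CohortReport",
    "fit_cohort",
    "negative_control_compare",
    "pooled_weighted_mean",
    "classify_consumers",
    "TTestResult",
    "ClassificationResult",
]


@dataclass
class CohortReport:
    """Per-animal fits plus site-level and pooled aggregation.

    ``per_animal`` has one row per consumer: animal_id, site, one
    ``<source>_pct`` column per food source (percent of stored fatty acids
    attributed to that source), bmd (µg/mg) and r_squared.  ``per_site``
    holds arithmetic means and sds of those rows by site; ``pooled`` holds
    sample-size-weighted means across sites.
    """

    sources: list[str]
    per_animal: pd.DataFrame
    per_site: pd.DataFrame
    pooled: dict[str, float]
    fits: dict[str, FitResult] = field(default_factory=dict)

    def bmds(self) -> list[float]:
        return self.per_animal["bmd"].tolist()


class TTestResult(NamedTuple):
    t: float
    p: float
    mean_target: float
    mean_control: float


class ClassificationResult(NamedTuple):
    count_above: int
    total: int
    fraction: float
    bin_edges: tuple[float, ...]
    bin_counts: tuple[int, ...]


def fit_cohort(
    consumers: Sequence[ConsumerSample],
    library: SourceLibrary,
    cc: CalibrationVector | None = None,
    step: float = 0.01,
    *,
    fa_subset: Sequence[str] | None = None,
    site_matched: bool = True,
    rescale: bool = True,
) -> CohortReport:
    """Fit every consumer against its site's food means and aggregate.

    In site-matched mode (default) each animal is fitted against the mean
    signatures of the foods sampled at its own site; pooled mode uses means
    across all sites.  ``fa_subset`` restricts every signature to a shared
    FA list before fitting (zero-filling absent FAs).
    """
    if not consumers:
        raise ValidationError("no consumers to fit")
    sources = sorted(library.sources)
    pooled_means = None if site_matched else library.pooled_means()

    rows = []
    fits: dict[str, FitResult] = {}
    for animal in consumers:
        means = library.site_means(animal.site) if site_matched else pooled_means
        observed = animal.fat
        if fa_subset is not None:
            observed = Signature.from_arrays(
                list(fa_subset), observed.aligned(list(fa_subset))
            )
        fit = fit_diet(observed, means, cc=cc, step=step, rescale=rescale)
        fits[animal.animal_id] = fit
        row = {"animal_id": animal.animal_id, "site": animal.site}
        for s in sources:
            row[f"{s}_pct"] = 100.0 * fit.diet[s]
        row["bmd"] = fit.bmd
        row["r_squared"] = fit.r_squared
        rows.append(row)

    per_animal = pd.DataFrame(rows)
    pct_cols = [f"{s}_pct" for s in sources]

    site_rows = []
    for site, grp in per_animal.groupby("site", sort=False):
        rec: dict[str, object] = {"site": site, "n": len(grp)}
        for col in pct_cols + ["bmd"]:
            rec[f"{col}_mean"] = grp[col].mean()
            rec[f"{col}_sd"] = grp[col].std(ddof=1) if len(grp) > 1 else 0.0
        site_rows.append(rec)
    per_site = pd.DataFrame(site_rows)

    pooled: dict[str, float] = {}
    for col in pct_cols + ["bmd"]:
        pairs = list(zip(per_site[f"{col}_mean"], per_site["n"]))
        key = col.removesuffix("_pct") if col != "bmd" else "bmd"
        pooled[key] = pooled_weighted_mean(pairs)

    return CohortReport(
        sources=sources,
        per_animal=per_animal,
        per_site=per_site,
        pooled=pooled,
        fits=fits,
    )


def negative_control_compare(
    bmd_target: Sequence[float],
    bmd_control: Sequence[float],
    *,
    welch: bool = True,
) -> TTestResult:
    """Two-sample t-test of best model deviations, target vs control.

    Welch's unequal-variance test is the default (conservative at the small
    per-site sample sizes typical here); ``welch=False`` gives the pooled
    Student's test.  Returns the t statistic, two-sided p value and the two
    group means.
    """
    a = np.asarray(bmd_target, dtype=float)
    b = np.asarray(bmd_control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 BMD values")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(t=float(t), p=float(p),
                       mean_target=float(a.mean()), mean_control=float(b.mean()))


def pooled_weighted_mean(site_means: Sequence[tuple[float, int]]) -> float:
    """Sample-size-weighted mean of site means: ``Σ n_s m_s / Σ n_s``.

    Recovers the across-animal mean from per-site summaries.
    """
    if not site_means:
        raise ValidationError("no site means supplied")
    means = np.array([m for m, _ in site_means], dtype=float)
    ns = np.array([n for _, n in site_means], dtype=float)
    if np.any(ns < 1):
        raise ValidationError("every site needs n ≥ 1")
    return float((means * ns).sum() / ns.sum())


_DEFAULT_BINS = (0.0, 5.0, 10.0, 50.0, 100.0)


def classify_consumers(
    report: CohortReport,
    source: str,
    threshold: float = 10.0,
    *,
    bin_edges: Sequence[float] = _DEFAULT_BINS,
) -> ClassificationResult:
    """Count animals whose fitted percentage for ``source`` strictly exceeds
    ``threshold``, plus a histogram over ``bin_edges`` (percent scale).

    The default bins (0–5, 5–10, 10–50, 50–100 %) expose the bimodal
    low-consumer / substantial-consumer split that motivates the threshold.
    """
    col = f"{source}_pct"
    if col not in report.per_animal.columns:
        raise ValidationError(f"unknown source {source!r}")
    pcts = report.per_animal[col].to_numpy(dtype=float)
    count = int((pcts > threshold).sum())
    total = int(len(pcts))
    counts, _ = np.histogram(pcts, bins=np.asarray(bin_edges, dtype=float))
    return ClassificationResult(
        count_above=count,
        total=total,
        fraction=count / total,
        bin_edges=tuple(float(e) for e in bin_edges),
        bin_counts=tuple(int(c) for c in counts),
    )
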