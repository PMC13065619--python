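"""Calibration coefficients derived as outputs from index animals.

Stored fat is not a faithful copy of the consumed-fat mixture: uptake,
interconversion and selective deposition distort each fatty acid by some
factor.  Feeding trials to measure those factors directly are often
infeasible, so this module derives them from the data instead: fit a few
*index animals* (one per site, chosen at random with a required seed) with
all coefficients at 1, compute per-FA ratios observed/predicted that would
make each index fit perfect, and average the unlogged ratios across index
animals.  The averaged vector is then fed back into the optimiser to refit
the whole cohort.

Because predictions are re-closed to a common subset total, calibration
vectors are identifiable only up to a common factor; the derived vectors are
stored unnormalised.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .core import CalibrationVector, FitResult, fit_diet
from .signatures import (
    ConsumerSample,
    Signature,
    SourceLibrary,
    ValidationError,
)

__all__ = [
    "IndexFit",
    "derive_perfect_fit_cc",
    "average_cc",
    "log_cc_report",
    "select_index_animals",
    "derive_calibration",
]


@dataclass
class IndexFit:
    """One index animal: its all-ones-coefficient fit and the coefficient
    vector that would make that fit exact."""

    animal_id: str
    site: str
    unity_fit: FitResult
    derived_cc: CalibrationVector


def derive_perfect_fit_cc(observed: Signature, unity_fit: FitResult) -> CalibrationVector:
    """Per-FA coefficients ``observed_i / predicted_i`` making the fit exact.

    ``unity_fit`` must have been computed with all coefficients at 1.  FAs
    at zero in both the observed and predicted signature get coefficient 1
    (no information); a predicted zero against a positive observation has
    no finite coefficient and is an error.
    """
    pred = unity_fit.predicted
    if set(pred.labels) != set(observed.labels):
        raise ValidationError("fit and observation use different FA subsets")
    coefs: dict[str, float] = {}
    for lab in pred.labels:
        o, p = observed[lab], pred[lab]
        if p > 0:
            coefs[lab] = o / p
        elif o == 0:
            coefs[lab] = 1.0
        else:
            raise ValidationError(
                f"coefficient undefined for {lab!r}: predicted 0 but observed {o}"
            )
    # observed/predicted can be 0 where the observation is 0; a calibration
    # coefficient must stay positive, so clamp exact zeros to a tiny floor.
    coefs = {lab: (c if c > 0 else 1e-12) for lab, c in coefs.items()}
    return CalibrationVector(coefs)


def average_cc(
    ccs: Sequence[CalibrationVector], *, geometric: bool = False
) -> CalibrationVector:
    """Average calibration vectors per FA on the unlogged scale.

    The arithmetic mean of the raw (unlogged) coefficients is the default;
    ``geometric=True`` averages on the log scale instead.
    """
    if not ccs:
        raise ValidationError("no calibration vectors to average")
    labels = ccs[0].labels
    for cc in ccs[1:]:
        if set(cc.labels) != set(labels):
            raise ValidationError("calibration vectors use different FA subsets")
    mat = np.vstack([cc.as_array(labels) for cc in ccs])
    if geometric:
        avg = np.exp(np.log(mat).mean(axis=0))
    else:
        avg = mat.mean(axis=0)
    return CalibrationVector(dict(zip(labels, avg)))


def log_cc_report(cc: CalibrationVector) -> dict[str, float]:
    """Natural-log coefficients per FA.

    A positive logged value means the consumer discriminates in favour of
    storing that fatty acid relative to the consumed mixture (the observed
    level exceeds the mixture prediction); a negative value means storage
    of that FA is depleted; 0 means no discrimination.
    """
    return {lab: math.log(cc[lab]) for lab in cc.labels}


def select_index_animals(
    consumers: Sequence[ConsumerSample], seed: int, n_per_site: int = 1
) -> list[ConsumerSample]:
    """Seeded uniform choice of ``n_per_site`` index animals per site.

    The seed is required: index-animal choice changes the derived
    coefficients, so it must be reproducible.
    """
    if not consumers:
        raise ValidationError("no consumers to select from")
    rng = np.random.default_rng(seed)
    by_site: dict[str, list[ConsumerSample]] = {}
    for c in consumers:
        by_site.setdefault(c.site, []).append(c)
    chosen: list[ConsumerSample] = []
    for site in sorted(by_site):
        group = by_site[site]
        if len(group) < n_per_site:
            raise ValidationError(
                f"site {site!r} has {len(group)} animals, need {n_per_site}"
            )
        idx = rng.choice(len(group), size=n_per_site, replace=False)
        chosen.extend(group[i] for i in sorted(idx))
    return chosen


def derive_calibration(
    consumers: Sequence[ConsumerSample],
    library: SourceLibrary,
    *,
    seed: int,
    step: float = 0.01,
    fa_subset: Sequence[str] | None = None,
    rescale: bool = True,
    site_matched: bool = True,
    geometric: bool = False,
) -> tuple[CalibrationVector, list[IndexFit]]:
    """Full calibration stage: pick index animals, fit at unity, derive and
    average the perfect-fit coefficients.

    Returns the averaged vector and the per-index-animal details.  Consumer
    signatures are restricted to ``fa_subset`` (default: all FAs of each
    consumer) before fitting, exactly as in the main cohort fit.
    """
    index_animals = select_index_animals(consumers, seed=seed)
    fits: list[IndexFit] = []
    for animal in index_animals:
        means = library.site_means(animal.site) if site_matched else library.pooled_means()
        observed = animal.fat
        if fa_subset is not None:
            observed = Signature.from_arrays(
                list(fa_subset), observed.aligned(list(fa_subset))
            )
        unity = fit_diet(observed, means, cc=None, step=step, rescale=rescale)
        derived = derive_perfect_fit_cc(observed, unity)
        fits.append(
            IndexFit(animal_id=animal.animal_id, site=animal.site,
                     unity_fit=unity, derived_cc=derived)
        )
    averaged = average_cc([f.derived_cc for f in fits], geometric=geometric)
    return averaged, fits
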