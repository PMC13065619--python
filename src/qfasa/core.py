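"""Diet-proportion estimation by exhaustive least-absolute-deviation search.

The estimator assumes consumed fatty acids pass into storage without
discrimination or interconversion, so the stored-fat signature of a consumer
is (approximately) a convex mixture of its food-source signatures, optionally
distorted per fatty acid by a calibration coefficient.  The diet is estimated
by enumerating every grid point of the diet-proportion simplex at a fixed
resolution (default 1%) and returning the mixture whose predicted signature
has the smallest summed absolute deviation (the *best model deviation*, BMD,
in µg/mg) from the observed stored fat.

Signatures are compared on a shared fatty-acid subset after rescaling every
signature — food means and predictions alike — to a common subset total
(by default the observed fat's subset total), so that deviations are in
µg/mg on a like-for-like scale.  Raw-unit fitting without rescaling is
available via ``rescale=False``.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .signatures import (
    Signature,
    ValidationError,
    canonical_fa_order,
    restrict_and_rescale,
)

__all__ = [
    "DietProportions",
    "CalibrationVector",
    "SourceProfile",
    "FitResult",
    "predict_fat_signature",
    "summed_abs_deviation",
    "pearson_r_squared",
    "fit_diet",
    "uniqueness_profile",
]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class DietProportions:
    """A point on the simplex over food sources: fraction of stored fatty
    acids attributed to each source."""

    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        props = {str(k): float(v) for k, v in self.proportions.items()}
        if not props:
            raise ValidationError("diet has no sources")
        for name, p in props.items():
            if not np.isfinite(p) or p < -_SIMPLEX_TOL or p > 1 + _SIMPLEX_TOL:
                raise ValidationError(f"proportion for {name!r} outside [0, 1]: {p}")
        if abs(sum(props.values()) - 1.0) > 1e-6:
            raise ValidationError(
                f"diet proportions sum to {sum(props.values())}, not 1"
            )
        object.__setattr__(self, "proportions", props)

    def __getitem__(self, source: str) -> float:
        return self.proportions[source]

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(self.proportions)

    def as_array(self, sources: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.proportions[s] for s in sources], dtype=float)
        except KeyError as e:
            raise ValidationError(f"diet references unknown source {e.args[0]!r}") from None

    def as_percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.proportions.items()}


@dataclass(frozen=True)
class CalibrationVector:
    """Per-FA positive multipliers translating consumed-fat composition into
    stored-fat composition (diet→storage discrimination factors)."""

    coefficients: Mapping[str, float]

    def __post_init__(self) -> None:
        coefs = {str(k): float(v) for k, v in self.coefficients.items()}
        if not coefs:
            raise ValidationError("calibration vector is empty")
        for lab, c in coefs.items():
            if not np.isfinite(c) or c <= 0:
                raise ValidationError(
                    f"calibration coefficient for {lab!r} must be positive and "
                    f"finite, got {c}"
                )
        object.__setattr__(self, "coefficients", coefs)

    def __getitem__(self, label: str) -> float:
        return self.coefficients[label]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def as_array(self, labels: Sequence[str]) -> np.ndarray:
        missing = [lab for lab in labels if lab not in self.coefficients]
        if missing:
            raise ValidationError(f"calibration vector missing FAs: {missing}")
        return np.array([self.coefficients[lab] for lab in labels], dtype=float)

    def expanded(self, labels: Sequence[str], fill: float = 1.0) -> np.ndarray:
        """Coefficient vector over ``labels``, filling uncovered FAs with
        ``fill`` (no distortion).  Used by the simulator, where a vector
        defined on the abundant-FA subset acts on a full signature."""
        return np.array(
            [self.coefficients.get(lab, fill) for lab in labels], dtype=float
        )

    @classmethod
    def ones(cls, labels: Sequence[str]) -> "CalibrationVector":
        return cls({lab: 1.0 for lab in labels})


@dataclass
class SourceProfile:
    """Uniqueness diagnostic for one source: the minimal deviation achievable
    at each fixed value of that source's proportion."""

    source: str
    grid: np.ndarray          # proportion values, shape (n_steps + 1,)
    min_deviation: np.ndarray  # minimal BMD at each fixed proportion
    multimodal: bool = False


@dataclass
class FitResult:
    """Outcome of the exhaustive simplex search for one consumer."""

    diet: DietProportions
    bmd: float
    r_squared: float
    predicted: Signature
    profiles: dict[str, SourceProfile] = field(default_factory=dict)
    step: float = 0.01
    n_ties: int = 1

    @property
    def multimodal(self) -> bool:
        return any(p.multimodal for p in self.profiles.values())


def _aligned_inputs(
    observed: Signature,
    source_means: Mapping[str, Signature],
    cc: CalibrationVector | None,
    rescale: bool,
    target_total: float | None,
):
    """Common preparation: canonical label/source order, aligned matrices."""
    if len(source_means) < 2:
        raise ValidationError("need at least 2 sources to fit a diet")
    labels = canonical_fa_order(observed.labels)
    sources = sorted(source_means)
    target = float(target_total) if target_total is not None else observed.total(labels)
    if target <= 0:
        raise ValidationError("non-positive target total")
    obs = observed.aligned(labels)
    if rescale:
        obs = obs * (target / obs.sum())
        rows = [
            restrict_and_rescale(source_means[s], labels, target).aligned(labels)
            for s in sources
        ]
    else:
        rows = [source_means[s].aligned(labels) for s in sources]
    M = np.vstack(rows)
    cc_vec = cc.as_array(labels) if cc is not None else np.ones(len(labels))
    return labels, sources, obs, M, cc_vec, target


def _apply_cc(mix: np.ndarray, cc_vec: np.ndarray, rescale: bool, target: float) -> np.ndarray:
    """Apply calibration coefficients to mixture rows, then re-close to the
    common subset total (calibration is identifiable only up to composition)."""
    pred = mix * cc_vec
    if rescale:
        sums = pred.sum(axis=-1, keepdims=True)
        if np.any(sums <= 0):
            raise ValidationError("predicted signature has zero total")
        pred = pred * (target / sums)
    return pred


def predict_fat_signature(
    diet: DietProportions,
    source_means: Mapping[str, Signature],
    cc: CalibrationVector | None = None,
    *,
    rescale: bool = True,
    target_total: float | None = None,
) -> Signature:
    """Predicted stored-fat signature for a given diet.

    Per FA *i* the prediction is ``cc_i × Σ_k p_k × source_mean_{k,i}``,
    re-closed to the common subset total when ``rescale`` is on.  The default
    target total is the total of the uncalibrated mixture, so with all
    coefficients at 1 the prediction is the plain mixture.
    """
    sources = sorted(source_means)
    unknown = set(diet.sources) - set(sources)
    if unknown:
        raise ValidationError(f"diet references unknown source(s): {sorted(unknown)}")
    labels = canonical_fa_order(
        [lab for s in sources for lab in source_means[s].labels]
    )
    p = diet.as_array(sources)
    M = np.vstack([source_means[s].aligned(labels) for s in sources])
    mix = p @ M
    if target_total is None:
        target = float(mix.sum())
    else:
        target = float(target_total)
        if rescale:
            mix = mix * (target / mix.sum())
    cc_vec = cc.as_array(labels) if cc is not None else np.ones(len(labels))
    pred = _apply_cc(mix, cc_vec, rescale, target)
    return Signature.from_arrays(labels, pred)


def summed_abs_deviation(predicted: Signature, observed: Signature) -> float:
    """Σ_i |predicted_i − observed_i| over the shared FA subset (µg/mg).

    This is the model deviation; evaluated at the best-fit diet it is the
    best model deviation (BMD).  The two signatures must be defined on the
    same FA label set.
    """
    if set(predicted.labels) != set(observed.labels):
        raise ValidationError("signatures are defined on different FA subsets")
    labs = predicted.labels
    return float(np.abs(predicted.aligned(labs) - observed.aligned(labs)).sum())


def pearson_r_squared(predicted: Signature, observed: Signature) -> float:
    """Squared Pearson correlation between two signatures across FAs."""
    if set(predicted.labels) != set(observed.labels):
        raise ValidationError("signatures are defined on different FA subsets")
    labs = predicted.labels
    if len(labs) < 3:
        raise ValidationError("need at least 3 shared FAs for a correlation")
    x = predicted.aligned(labs)
    y = observed.aligned(labs)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# Simplex grid enumeration
# ---------------------------------------------------------------------------

def _compositions_tail(m: int, k: int) -> np.ndarray:
    """All compositions of the integer ``m`` into ``k`` non-negative parts,
    fully vectorised, for k ≤ 3.

    Returned as float64 (all values are small integers, hence exact) so the
    downstream BLAS matmul needs no conversion pass.
    """
    if k == 1:
        return np.array([[m]], dtype=np.float64)
    if k == 2:
        a = np.arange(m + 1, dtype=np.float64)
        return np.column_stack([a, m - a])
    if k == 3:
        counts = np.arange(m, -1, -1, dtype=np.int64) + 1
        a = np.repeat(np.arange(m + 1, dtype=np.float64), counts)
        offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
        b = (np.arange(counts.sum(), dtype=np.int64)
             - np.repeat(offsets, counts)).astype(np.float64)
        return np.column_stack([a, b, m - a - b])
    raise ValueError("tail enumeration only supports k ≤ 3")


def _composition_chunks(n: int, k: int) -> Iterator[tuple[tuple[int, ...], np.ndarray]]:
    """Yield the compositions of ``n`` into ``k`` parts as
    ``(head, tail_block)`` pairs: a fixed integer prefix plus a fully
    vectorised block of compositions over the remaining (≤ 3) parts.

    For k ≤ 3 there is a single pair with an empty head; for larger k the
    leading coordinates are looped over in ascending order, which bounds
    memory while keeping the enumeration exhaustive.
    """
    if k < 2:
        raise ValidationError("need at least 2 sources")
    if k <= 3:
        yield (), _compositions_tail(n, k)
        return

    def rec(prefix: tuple[int, ...], remaining: int, parts_left: int):
        if parts_left == 3:
            yield prefix, _compositions_tail(remaining, 3)
            return
        for a in range(remaining + 1):
            yield from rec(prefix + (a,), remaining - a, parts_left - 1)

    yield from rec((), n, k)


def _steps_from_fraction(step: float) -> int:
    if not (0 < step <= 1):
        raise ValidationError(f"step must lie in (0, 1], got {step}")
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9:
        raise ValidationError(f"step {step} does not divide 1 exactly")
    return n


def fit_diet(
    observed: Signature,
    source_means: Mapping[str, Signature],
    cc: CalibrationVector | None = None,
    step: float = 0.01,
    *,
    rescale: bool = True,
    target_total: float | None = None,
    profile_tol: float = 0.01,
    compute_profiles: bool = True,
) -> FitResult:
    """Exhaustive simplex-grid search for the least-absolute-deviation diet.

    Every diet with proportions that are multiples of ``step`` is evaluated;
    the global grid minimum of the summed absolute deviation is returned.
    Ties are broken deterministically in favour of the lexicographically
    smallest proportion vector in canonical (sorted) source order, and the
    number of grid optima is reported in ``n_ties``.

    ``r_squared`` is ``nan`` when a Pearson correlation is undefined
    (fewer than 3 FAs, or a constant vector).  ``compute_profiles=False``
    skips the per-source deviation profiles, which speeds up very fine
    grids considerably.
    """
    n = _steps_from_fraction(step)
    labels, sources, obs, M, cc_vec, target = _aligned_inputs(
        observed, source_means, cc, rescale, target_total
    )
    k = len(sources)

    best_bmd = np.inf
    best_row: tuple[int, ...] | None = None
    n_ties = 0
    profiles = {s: np.full(n + 1, np.inf) for s in sources}
    Mn = M / n  # per-grid-unit contribution of each source
    cc_is_unity = bool(np.all(cc_vec == 1.0))

    ones_f = np.ones(M.shape[1])
    for head, tail in _composition_chunks(n, k):
        h = len(head)
        mix = tail @ Mn[h:]
        if h:
            mix += np.array(head, dtype=float) @ Mn[:h]
        if cc_is_unity and rescale:
            pred = mix  # source rows already share the target total
        else:
            pred = _apply_cc(mix, cc_vec, rescale, target)
        d = pred - obs
        np.abs(d, out=d)
        dev = d @ ones_f
        m = dev.min()
        if compute_profiles:
            for j in range(h):
                s = sources[j]
                if m < profiles[s][head[j]]:
                    profiles[s][head[j]] = m
            for j in range(tail.shape[1]):
                np.minimum.at(profiles[sources[h + j]], tail[:, j].astype(np.int64), dev)
        if m > best_bmd:
            continue
        cand = tail[dev == m].astype(np.int64)
        cand_best = head + tuple(int(v) for v in cand[np.lexsort(cand.T[::-1])[0]])
        if m < best_bmd:
            best_bmd = m
            best_row = cand_best
            n_ties = int(cand.shape[0])
        else:  # equal minimum in a later chunk
            n_ties += int(cand.shape[0])
            if cand_best < best_row:
                best_row = cand_best

    assert best_row is not None
    p_best = np.array(best_row, dtype=float) / n
    diet = DietProportions(dict(zip(sources, p_best)))
    pred_best = _apply_cc(p_best @ M, cc_vec, rescale, target)
    predicted = Signature.from_arrays(labels, np.maximum(pred_best, 0.0))
    try:
        r2 = pearson_r_squared(predicted, Signature.from_arrays(labels, obs))
    except ValidationError:
        r2 = float("nan")

    grid = np.arange(n + 1, dtype=float) / n
    prof = {}
    if compute_profiles:
        prof = {
            s: _flag_profile(SourceProfile(s, grid, profiles[s]), float(best_bmd), profile_tol)
            for s in sources
        }
    return FitResult(
        diet=diet,
        bmd=float(best_bmd),
        r_squared=r2,
        predicted=predicted,
        profiles=prof,
        step=step,
        n_ties=n_ties,
    )


def _flag_profile(profile: SourceProfile, bmd: float, tol: float) -> SourceProfile:
    """Mark a profile multimodal when a near-optimal proportion lies far
    from the global minimum.

    "Near-optimal" means deviation within ``tol`` (relative, plus a tiny
    absolute floor) of the global minimum; "far" means more than
    max(2 grid steps, 5% of the proportion axis) away.  A shallow single
    basin therefore does not flag, while a flat exchange direction between
    (near-)collinear sources, or a second distant basin, does.
    """
    d = profile.min_deviation
    g = int(np.argmin(d))
    cutoff = bmd * (1.0 + tol) + 1e-12
    step = float(profile.grid[1] - profile.grid[0]) if len(profile.grid) > 1 else 1.0
    far = max(2.0 * step, 0.05)
    near_optimal = np.flatnonzero(d <= cutoff)
    if np.any(np.abs(profile.grid[near_optimal] - profile.grid[g]) > far):
        profile.multimodal = True
    return profile


def uniqueness_profile(
    observed: Signature,
    source_means: Mapping[str, Signature],
    cc: CalibrationVector | None = None,
    step: float = 0.01,
    *,
    rescale: bool = True,
    target_total: float | None = None,
    tol: float = 0.01,
) -> dict[str, SourceProfile]:
    """Deviation-vs-proportion curves used to check solution uniqueness.

    For each source and each grid proportion value, reports the minimum
    deviation over all grid diets holding that source fixed at that value.
    A source is flagged multimodal when a non-adjacent local minimum lies
    within ``tol`` of the global minimum — e.g. when two sources have
    (near-)identical signatures and trade off freely.
    """
    fit = fit_diet(
        observed, source_means, cc, step,
        rescale=rescale, target_total=target_total, profile_tol=tol,
    )
    return fit.profiles
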