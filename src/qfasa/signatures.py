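"""Fatty-acid signature containers, table I/O, subset selection and rescaling.

A *signature* is the vector of fatty-acid (FA) concentrations, in µg fatty
acid per mg sample, that characterises a food source or an adipose-tissue
sample.  All downstream diet reconstruction operates on these signatures:
food sources carry replicate signatures grouped by sampling site, consumers
carry a single stored-fat signature each.

Fatty acids are named in carbon:double-bond nomenclature (``16:0``,
``18:1``, ``18:3n3``).  Within any one signature the labels are unique and
kept in canonical order (ascending chain length, then double bonds, then
n-series).  Fatty acids absent from a sample are treated as concentration
zero, so signatures over different label sets can always be aligned.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "parse_fa_label",
    "fa_sort_key",
    "canonical_fa_order",
    "Signature",
    "SourceSampleSet",
    "ConsumerSample",
    "SourceLibrary",
    "mean_signature",
    "cv_profile",
    "select_shared_fas",
    "restrict_and_rescale",
    "read_signature_table",
    "write_signature_table",
    "species_mean_signatures",
]


class ValidationError(ValueError):
    """Raised when an input table or domain object violates its invariants."""


_FA_RE = re.compile(r"^(\d{1,2}):(\d{1,2})(?:n-?(\d))?$")


def parse_fa_label(label: str) -> tuple[int, int, int | None]:
    """Parse ``'18:3n3'`` into ``(carbon, double_bonds, n_series)``.

    The n-series suffix is optional; ``'n-3'`` and ``'n3'`` are equivalent.
    Raises :class:`ValidationError` for anything that is not
    ``<int>:<int>[n<int>]``.
    """
    m = _FA_RE.match(str(label).strip())
    if m is None:
        raise ValidationError(f"unparseable fatty-acid label: {label!r}")
    carbon, dbonds, series = m.groups()
    return int(carbon), int(dbonds), (int(series) if series is not None else None)


def fa_sort_key(label: str) -> tuple[int, int, int]:
    """Canonical ordering key: chain length, double bonds, n-series.

    Unsuffixed labels sort before n-suffixed ones at the same
    carbon/double-bond count, and the n-series descends (ω-6 before ω-3),
    matching the row order of published FA tables.
    """
    carbon, dbonds, series = parse_fa_label(label)
    return carbon, dbonds, -100 if series is None else -series


def canonical_fa_order(labels: Iterable[str]) -> list[str]:
    """Sort FA labels into canonical chain-length order, dropping duplicates."""
    seen: dict[str, None] = {}
    for lab in labels:
        seen.setdefault(str(lab).strip(), None)
    return sorted(seen, key=fa_sort_key)


class Signature(Mapping):
    """Immutable map from fatty-acid label to concentration (µg/mg).

    All concentrations must be finite and non-negative, and at least one
    must be positive.  Iteration order is canonical FA order.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        items: dict[str, float] = {}
        for lab in canonical_fa_order(values.keys()):
            v = float(values[lab])
            if not np.isfinite(v):
                raise ValidationError(f"non-finite concentration for {lab!r}: {v}")
            if v < 0:
                raise ValidationError(f"negative concentration for {lab!r}: {v}")
            items[lab] = v
        if len(items) != len(values):
            raise ValidationError("duplicate fatty-acid labels after normalisation")
        if not items:
            raise ValidationError("signature has no fatty acids")
        if not any(v > 0 for v in items.values()):
            raise ValidationError("signature is identically zero")
        object.__setattr__(self, "_values", items)

    def __getitem__(self, label: str) -> float:
        return self._values[label]

    def __iter__(self):
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        head = ", ".join(f"{k}={v:g}" for k, v in list(self._values.items())[:4])
        more = "" if len(self) <= 4 else f", … ({len(self)} FAs)"
        return f"Signature({head}{more})"

    def __eq__(self, other) -> bool:
        if isinstance(other, Signature):
            return self._values == other._values
        return NotImplemented

    def __hash__(self):
        return hash(tuple(self._values.items()))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._values)

    def aligned(self, labels: Sequence[str]) -> np.ndarray:
        """Concentration vector over ``labels``, zero-filling absent FAs."""
        return np.array([self._values.get(lab, 0.0) for lab in labels], dtype=float)

    def total(self, subset: Sequence[str] | None = None) -> float:
        """Summed concentration, optionally over a subset of FAs."""
        if subset is None:
            return float(sum(self._values.values()))
        return float(self.aligned(subset).sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self._values, name="ug_per_mg")

    @classmethod
    def from_arrays(cls, labels: Sequence[str], values: Sequence[float]) -> "Signature":
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate fatty-acid labels")
        return cls(dict(zip(labels, values)))


@dataclass
class SourceSampleSet:
    """Replicate signatures of one food source at one site."""

    source_name: str
    site: str
    replicates: list[Signature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValidationError(
                f"source {self.source_name!r} at site {self.site!r} has no replicates"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        """Union of FA labels across replicates, canonical order."""
        labs: list[str] = []
        for rep in self.replicates:
            labs.extend(rep.labels)
        return tuple(canonical_fa_order(labs))

    def matrix(self) -> np.ndarray:
        labs = self.labels
        return np.vstack([rep.aligned(labs) for rep in self.replicates])


@dataclass
class ConsumerSample:
    """One consumer animal: identity, species, site and stored-fat signature."""

    animal_id: str
    species: str
    site: str
    fat: Signature


@dataclass
class SourceLibrary:
    """Named food sources with per-site replicate signatures.

    Provides the per-site mean signatures the mixture fit runs against,
    and pooled-across-site means as an alternative.
    """

    sample_sets: list[SourceSampleSet]

    def __post_init__(self) -> None:
        if not self.sample_sets:
            raise ValidationError("source library is empty")
        seen = set()
        for ss in self.sample_sets:
            key = (ss.source_name, ss.site)
            if key in seen:
                raise ValidationError(f"duplicate source/site pair: {key}")
            seen.add(key)

    @property
    def sources(self) -> list[str]:
        out: dict[str, None] = {}
        for ss in self.sample_sets:
            out.setdefault(ss.source_name, None)
        return list(out)

    @property
    def sites(self) -> list[str]:
        out: dict[str, None] = {}
        for ss in self.sample_sets:
            out.setdefault(ss.site, None)
        return list(out)

    def sample_set(self, source: str, site: str) -> SourceSampleSet:
        for ss in self.sample_sets:
            if ss.source_name == source and ss.site == site:
                return ss
        raise ValidationError(f"no samples for source {source!r} at site {site!r}")

    def site_means(self, site: str) -> dict[str, Signature]:
        """Mean signature of every source at one site."""
        out = {
            ss.source_name: mean_signature(ss)
            for ss in self.sample_sets
            if ss.site == site
        }
        if not out:
            raise ValidationError(f"site {site!r} not present in source library")
        return out

    def pooled_means(self) -> dict[str, Signature]:
        """Mean signature of every source pooling replicates across sites."""
        out: dict[str, Signature] = {}
        for source in self.sources:
            reps: list[Signature] = []
            for ss in self.sample_sets:
                if ss.source_name == source:
                    reps.extend(ss.replicates)
            out[source] = mean_signature(
                SourceSampleSet(source_name=source, site="pooled", replicates=reps)
            )
        return out


def mean_signature(samples: SourceSampleSet) -> Signature:
    """Per-FA arithmetic mean across a sample set's replicates."""
    labs = samples.labels
    return Signature.from_arrays(labs, samples.matrix().mean(axis=0))


def cv_profile(samples: SourceSampleSet) -> dict[str, float]:
    """Per-FA coefficient of variation (sample sd / mean) across replicates.

    FAs whose replicate mean is zero have an undefined cv and are reported
    as ``nan``.  Requires at least two replicates.
    """
    if len(samples.replicates) < 2:
        raise ValidationError("cv undefined for fewer than 2 replicates")
    labs = samples.labels
    mat = samples.matrix()
    means = mat.mean(axis=0)
    sds = mat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means > 0, sds / means, np.nan)
    return dict(zip(labs, cvs.tolist()))


def select_shared_fas(
    consumer_means: Sequence[Signature], threshold: float = 5.0
) -> list[str]:
    """FAs whose mean across consumer mean-signatures strictly exceeds a floor.

    The screen mirrors how abundant storage FAs are chosen for diet fitting:
    average each FA's concentration across the supplied per-species mean
    signatures (unweighted) and keep those above ``threshold`` µg/mg.
    Returned in canonical chain-length order.
    """
    if not consumer_means:
        raise ValidationError("no consumer mean signatures supplied")
    if threshold < 0:
        raise ValidationError("threshold must be non-negative")
    labs: list[str] = []
    for sig in consumer_means:
        labs.extend(sig.labels)
    labs = canonical_fa_order(labs)
    mat = np.vstack([sig.aligned(labs) for sig in consumer_means])
    means = mat.mean(axis=0)
    kept = [lab for lab, m in zip(labs, means) if m > threshold]
    if not kept:
        raise ValidationError(f"no FAs pass threshold {threshold} µg/mg")
    return kept


def restrict_and_rescale(
    sig: Signature, subset: Sequence[str], target_total: float
) -> Signature:
    """Restrict a signature to ``subset`` and rescale its sum to ``target_total``.

    Relative composition within the subset is preserved; absent FAs enter
    as zero.  Errors if the signature has no mass on the subset.
    """
    subset = list(subset)
    if not subset:
        raise ValidationError("empty FA subset")
    vals = sig.aligned(subset)
    tot = vals.sum()
    if tot <= 0:
        raise ValidationError("signature has zero total over the requested subset")
    return Signature.from_arrays(subset, vals * (target_total / tot))


def species_mean_signatures(consumers: Sequence[ConsumerSample]) -> dict[str, Signature]:
    """Per-species mean stored-fat signature across a consumer cohort."""
    if not consumers:
        raise ValidationError("no consumers supplied")
    by_species: dict[str, list[Signature]] = {}
    for c in consumers:
        by_species.setdefault(c.species, []).append(c.fat)
    out: dict[str, Signature] = {}
    for species, sigs in by_species.items():
        labs: list[str] = []
        for s in sigs:
            labs.extend(s.labels)
        labs = canonical_fa_order(labs)
        mat = np.vstack([s.aligned(labs) for s in sigs])
        out[species] = Signature.from_arrays(labs, mat.mean(axis=0))
    return out


# ---------------------------------------------------------------------------
# Table I/O
#
# Two plain-CSV dialects are accepted.  Long format has one row per
# (sample, fatty acid):
#
#   sample_id,group,site,fa_label,ug_per_mg
#
# where ``group`` is the source name for food tables and the species for
# consumer tables.  Wide format has one row per sample with metadata columns
# followed by one column per FA label.
# ---------------------------------------------------------------------------

_LONG_COLS = ["sample_id", "group", "site", "fa_label", "ug_per_mg"]
_META_COLS = ("sample_id", "group", "site")


def _validate_cell(value: float, sample: str, label: str) -> float:
    v = float(value)
    if not np.isfinite(v):
        raise ValidationError(
            f"non-finite concentration for sample {sample!r}, FA {label!r}"
        )
    if v < 0:
        raise ValidationError(
            f"negative concentration {v} for sample {sample!r}, FA {label!r}"
        )
    return v


def _frame_to_long(df: pd.DataFrame, path: str) -> pd.DataFrame:
    cols = [str(c).strip() for c in df.columns]
    df = df.set_axis(cols, axis=1)
    if "fa_label" in cols:
        missing = [c for c in _LONG_COLS if c not in cols]
        if missing:
            raise ValidationError(f"{path}: long-format table missing columns {missing}")
        return df[_LONG_COLS].copy()
    # wide format: metadata columns then FA columns
    missing = [c for c in _META_COLS if c not in cols]
    if missing:
        raise ValidationError(f"{path}: wide-format table missing columns {missing}")
    fa_cols = [c for c in cols if c not in _META_COLS]
    if not fa_cols:
        raise ValidationError(f"{path}: no fatty-acid columns")
    for c in fa_cols:
        parse_fa_label(c)  # raises with the offending column name
    long = df.melt(
        id_vars=list(_META_COLS),
        value_vars=fa_cols,
        var_name="fa_label",
        value_name="ug_per_mg",
    )
    return long.dropna(subset=["ug_per_mg"])


def read_signature_table(
    path: str | Path, kind: str
) -> list[SourceSampleSet] | list[ConsumerSample]:
    """Read a food-source or consumer signature table from CSV.

    ``kind`` is ``"source"`` (returns :class:`SourceSampleSet` grouped by
    source and site) or ``"consumer"`` (returns :class:`ConsumerSample`,
    one per sample_id, with ``group`` interpreted as species).
    """
    if kind not in ("source", "consumer"):
        raise ValidationError(f"kind must be 'source' or 'consumer', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "group": str, "site": str})
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no samples (empty file)") from None
    if df.empty:
        raise ValidationError(f"{path}: no samples")
    long = _frame_to_long(df, str(path))
    if long.empty:
        raise ValidationError(f"{path}: no samples")

    sigs: dict[tuple[str, str, str], dict[str, float]] = {}
    order: list[tuple[str, str, str]] = []
    for row in long.itertuples(index=False):
        label = str(row.fa_label).strip()
        parse_fa_label(label)
        value = _validate_cell(row.ug_per_mg, str(row.sample_id), label)
        key = (str(row.sample_id), str(row.group), str(row.site))
        if key not in sigs:
            sigs[key] = {}
            order.append(key)
        if label in sigs[key]:
            raise ValidationError(
                f"{path}: duplicate FA {label!r} for sample {key[0]!r}"
            )
        sigs[key][label] = value

    if kind == "consumer":
        return [
            ConsumerSample(animal_id=sid, species=grp, site=site, fat=Signature(vals))
            for (sid, grp, site), vals in ((k, sigs[k]) for k in order)
        ]

    grouped: dict[tuple[str, str], list[Signature]] = {}
    g_order: list[tuple[str, str]] = []
    for sid, grp, site in order:
        key = (grp, site)
        if key not in grouped:
            grouped[key] = []
            g_order.append(key)
        grouped[key].append(Signature(sigs[(sid, grp, site)]))
    return [
        SourceSampleSet(source_name=grp, site=site, replicates=grouped[(grp, site)])
        for grp, site in g_order
    ]


def write_signature_table(
    records: Sequence[SourceSampleSet] | Sequence[ConsumerSample],
    path: str | Path,
) -> None:
    """Write sample sets or consumers back to the long CSV dialect."""
    rows: list[dict] = []
    for rec in records:
        if isinstance(rec, SourceSampleSet):
            for i, rep in enumerate(rec.replicates, start=1):
                sid = f"{rec.source_name}_{rec.site}_{i}"
                for lab, v in rep.items():
                    rows.append(
                        dict(sample_id=sid, group=rec.source_name, site=rec.site,
                             fa_label=lab, ug_per_mg=v)
                    )
        elif isinstance(rec, ConsumerSample):
            for lab, v in rec.fat.items():
                rows.append(
                    dict(sample_id=rec.animal_id, group=rec.species, site=rec.site,
                         fa_label=lab, ug_per_mg=v)
                )
        else:
            raise ValidationError(f"cannot write record of type {type(rec).__name__}")
    if not rows:
        raise ValidationError("nothing to write")
    pd.DataFrame(rows, columns=_LONG_COLS).to_csv(path, index=False)
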