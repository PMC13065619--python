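"""Shared fixtures: toy two-food signatures and the packaged reference
tables (published food-source and consumer-fat means)."""

from __future__ import annotations

import numpy as np
import pytest

from qfasa import Signature
from qfasa.synthetic import (
    reference_consumer_means,
    reference_food_library_means,
)


@pytest.fixture(scope="session")
def ref_foods():
    """{(source, site): (mean Signature, {fa: sd})} from the packaged table."""
    return reference_food_library_means()


@pytest.fixture(scope="session")
def ref_consumers():
    """{'pika': Signature, 'mouse': Signature} mean stored-fat profiles."""
    return reference_consumer_means()


@pytest.fixture
def vertex_foods():
    """Two foods concentrated on opposite fatty acids: (100,0) and (0,100)."""
    return {
        "food1": Signature({"16:0": 100.0, "18:0": 0.0}),
        "food2": Signature({"16:0": 0.0, "18:0": 100.0}),
    }


@pytest.fixture
def skewed_foods():
    """Two foods both richer in the first FA: (80,20) and (60,40)."""
    return {
        "food1": Signature({"16:0": 80.0, "18:0": 20.0}),
        "food2": Signature({"16:0": 60.0, "18:0": 40.0}),
    }


@pytest.fixture
def observed_38_62():
    """An observed fat signature of 38% FA1 / 62% FA2."""
    return Signature({"16:0": 38.0, "18:0": 62.0})


def random_instance(rng: np.random.Generator, n_sources: int, n_fas: int):
    """A random fitting instance: positive source signatures scaled to a
    common total of 100, plus an observed signature with the same total."""
    labels = [f"{c}:0" for c in range(10, 10 + n_fas)]
    sources = {}
    for i in range(n_sources):
        v = rng.uniform(0.5, 10.0, size=n_fas)
        sources[f"s{i}"] = Signature.from_arrays(labels, 100.0 * v / v.sum())
    w = rng.uniform(0.5, 10.0, size=n_fas)
    observed = Signature.from_arrays(labels, 100.0 * w / w.sum())
    return labels, sources, observed
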