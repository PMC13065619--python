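"""The exhaustive least-absolute-deviation simplex search and its statistics."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qfasa import (
    CalibrationVector,
    DietProportions,
    Signature,
    ValidationError,
    fit_diet,
    pearson_r_squared,
    predict_fat_signature,
    summed_abs_deviation,
    uniqueness_profile,
)

from .conftest import random_instance
from .lad_oracle import lad_simplex_optimum


class TestPredict:
    def test_mixture_of_vertex_foods(self, vertex_foods):
        diet = DietProportions({"food1": 0.38, "food2": 0.62})
        pred = predict_fat_signature(diet, vertex_foods)
        assert pred["16:0"] == pytest.approx(38.0)
        assert pred["18:0"] == pytest.approx(62.0)

    def test_pure_diet_returns_the_food_signature(self, skewed_foods):
        diet = DietProportions({"food1": 1.0, "food2": 0.0})
        pred = predict_fat_signature(diet, skewed_foods)
        assert pred == skewed_foods["food1"]

    def test_doubling_one_cc_raises_its_share_and_lowers_others(self):
        foods = {
            "a": Signature({"12:0": 30.0, "14:0": 30.0, "16:0": 40.0}),
            "b": Signature({"12:0": 20.0, "14:0": 50.0, "16:0": 30.0}),
        }
        diet = DietProportions({"a": 0.5, "b": 0.5})
        base = predict_fat_signature(diet, foods)
        cc = CalibrationVector({"12:0": 2.0, "14:0": 1.0, "16:0": 1.0})
        boosted = predict_fat_signature(diet, foods, cc, target_total=base.total())
        assert boosted["12:0"] > base["12:0"]
        assert boosted["14:0"] < base["14:0"]
        assert boosted["16:0"] < base["16:0"]

    def test_unknown_source_in_diet_is_an_error(self, vertex_foods):
        diet = DietProportions({"food1": 0.5, "weeds": 0.5})
        with pytest.raises(ValidationError, match="unknown source"):
            predict_fat_signature(diet, vertex_foods)

    def test_missing_cc_label_is_an_error(self, vertex_foods):
        diet = DietProportions({"food1": 1.0, "food2": 0.0})
        with pytest.raises(ValidationError, match="missing"):
            predict_fat_signature(diet, vertex_foods, CalibrationVector({"16:0": 1.0}))


class TestDeviationAndCorrelation:
    def test_worked_example_deviation_is_44(self, observed_38_62):
        pred = Signature({"16:0": 60.0, "18:0": 40.0})
        assert summed_abs_deviation(pred, observed_38_62) == pytest.approx(44.0)

    def test_zero_for_identical_and_symmetric(self, observed_38_62):
        assert summed_abs_deviation(observed_38_62, observed_38_62) == 0.0
        pred = Signature({"16:0": 60.0, "18:0": 40.0})
        assert summed_abs_deviation(pred, observed_38_62) == summed_abs_deviation(
            observed_38_62, pred
        )

    def test_mismatched_subsets_rejected(self):
        with pytest.raises(ValidationError):
            summed_abs_deviation(Signature({"16:0": 1.0}), Signature({"18:0": 1.0}))

    def test_perfect_linear_relation_gives_r2_one(self):
        obs = Signature({"12:0": 1.0, "14:0": 2.0, "16:0": 3.0})
        pred = Signature({"12:0": 2.0, "14:0": 4.0, "16:0": 6.0})
        assert pearson_r_squared(pred, obs) == pytest.approx(1.0)

    def test_zero_covariance_gives_r2_zero(self):
        # x = (1,2,3) against y with Σ(x-x̄)(y-ȳ) = 0
        obs = Signature({"12:0": 1.0, "14:0": 2.0, "16:0": 3.0})
        pred = Signature({"12:0": 1.0, "14:0": 3.0, "16:0": 1.0})
        assert pearson_r_squared(pred, obs) == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_covariance_formula(self):
        rng = np.random.default_rng(3)
        labels = [f"{c}:0" for c in range(10, 18)]
        x = rng.uniform(1, 50, 8)
        y = rng.uniform(1, 50, 8)
        # independent implementation from the definition
        sx, sy = x - x.mean(), y - y.mean()
        r = (sx * sy).sum() / math.sqrt((sx**2).sum() * (sy**2).sum())
        got = pearson_r_squared(
            Signature.from_arrays(labels, x), Signature.from_arrays(labels, y)
        )
        assert got == pytest.approx(r * r, rel=1e-12)
        assert 0.0 <= got <= 1.0

    def test_constant_vector_is_an_error(self):
        obs = Signature({"12:0": 1.0, "14:0": 2.0, "16:0": 3.0})
        flat = Signature({"12:0": 2.0, "14:0": 2.0, "16:0": 2.0})
        with pytest.raises(ValidationError, match="constant"):
            pearson_r_squared(flat, obs)


class TestFitDiet:
    def test_vertex_foods_give_exact_38_62_split(self, vertex_foods, observed_38_62):
        fit = fit_diet(observed_38_62, vertex_foods, step=0.01)
        assert fit.diet.proportions == {"food1": 0.38, "food2": 0.62}
        assert fit.bmd == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_direction_pushes_to_pure_food2(
        self, skewed_foods, observed_38_62
    ):
        fit = fit_diet(observed_38_62, skewed_foods, step=0.01)
        assert fit.diet.proportions == {"food1": 0.0, "food2": 1.0}
        assert fit.bmd == pytest.approx(44.0)

    def test_vertex_recovery(self, skewed_foods):
        fit = fit_diet(skewed_foods["food1"], skewed_foods, step=0.01)
        assert fit.diet["food1"] == 1.0
        assert fit.bmd == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("step", [0.0, -0.1, 1.5, 0.03])
    def test_invalid_step_rejected(self, vertex_foods, observed_38_62, step):
        with pytest.raises(ValidationError, match="step"):
            fit_diet(observed_38_62, vertex_foods, step=step)

    def test_needs_two_sources(self, vertex_foods, observed_38_62):
        with pytest.raises(ValidationError):
            fit_diet(observed_38_62, {"food1": vertex_foods["food1"]})

    def test_grid_optimality_by_exhaustive_rescan(self):
        # independent re-enumeration with itertools at a coarse step
        rng = np.random.default_rng(11)
        labels, sources, observed = random_instance(rng, 3, 6)
        step = 0.1
        fit = fit_diet(observed, sources, step=step)
        names = sorted(sources)
        M = np.vstack([sources[s].aligned(labels) for s in names])
        obs = observed.aligned(labels)
        best = min(
            np.abs((np.array([a, b, 10 - a - b]) / 10) @ M - obs).sum()
            for a, b in itertools.product(range(11), repeat=2)
            if a + b <= 10
        )
        assert fit.bmd == pytest.approx(best, abs=1e-9)

    def test_halving_the_step_never_increases_bmd(self):
        rng = np.random.default_rng(5)
        _, sources, observed = random_instance(rng, 3, 8)
        bmds = [fit_diet(observed, sources, step=s).bmd for s in (0.1, 0.05, 0.025)]
        assert bmds[0] >= bmds[1] >= bmds[2]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20), grid=st.integers(0, 20))
    def test_exact_mixture_is_recovered(self, seed, grid):
        # observed constructed exactly on the grid must be recovered exactly
        rng = np.random.default_rng(seed)
        _, sources, _ = random_instance(rng, 3, 5)
        a = grid
        b = rng.integers(0, 21 - a)
        p_true = {"s0": a / 20, "s1": int(b) / 20, "s2": (20 - a - int(b)) / 20}
        observed = predict_fat_signature(DietProportions(p_true), sources)
        fit = fit_diet(observed, sources, step=0.05)
        assert fit.bmd <= 1e-9
        for s, p in p_true.items():
            assert abs(fit.diet[s] - p) <= 0.025 + 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(13)
        labels, sources, observed = random_instance(rng, 3, 6)
        fit = fit_diet(observed, sources, step=0.05)
        renamed = {"zz_" + k: v for k, v in sources.items()}
        fit2 = fit_diet(observed, renamed, step=0.05)
        for k in sources:
            assert fit2.diet["zz_" + k] == pytest.approx(fit.diet[k], abs=1e-12)

    def test_duplicate_sources_tie_break_is_lexicographic_and_counted(
        self, vertex_foods, observed_38_62
    ):
        foods = {
            "a": vertex_foods["food1"],
            "b": vertex_foods["food1"],
            "c": vertex_foods["food2"],
        }
        fit = fit_diet(observed_38_62, foods, step=0.01)
        # all mass on the duplicate pair goes to the later source: the
        # lexicographically smallest proportion vector puts 0 first
        assert fit.diet["a"] == 0.0
        assert fit.diet["b"] == pytest.approx(0.38)
        assert fit.n_ties == 39  # any split of 0.38 across a and b ties

    def test_bmd_recomputes_from_diet_and_predicted(self, skewed_foods, observed_38_62):
        fit = fit_diet(observed_38_62, skewed_foods, step=0.01)
        assert fit.bmd == pytest.approx(
            summed_abs_deviation(fit.predicted, observed_38_62), abs=1e-9
        )

    def test_matches_lp_oracle_on_small_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            k = int(rng.integers(2, 4))
            labels, sources, observed = random_instance(rng, k, 6)
            names = sorted(sources)
            M = np.vstack([sources[s].aligned(labels) for s in names])
            obs = observed.aligned(labels)
            _, lp_opt = lad_simplex_optimum(M, obs)
            fit = fit_diet(observed, sources, step=0.01, compute_profiles=False)
            slack = 0.01 * k * 100.0  # one grid step × worst-case sensitivity
            assert lp_opt - 1e-9 <= fit.bmd <= lp_opt + slack


class TestUniquenessProfile:
    def test_v_shaped_profile_with_unique_minimum(self, vertex_foods, observed_38_62):
        profs = uniqueness_profile(observed_38_62, vertex_foods, step=0.01)
        p1 = profs["food1"]
        i = int(np.argmin(p1.min_deviation))
        assert p1.grid[i] == pytest.approx(0.38)
        assert not p1.multimodal
        # strictly decreasing then increasing around the minimum
        assert np.all(np.diff(p1.min_deviation[:i]) < 0)
        assert np.all(np.diff(p1.min_deviation[i:]) > 0)

    def test_identical_sources_are_flagged_non_unique(
        self, vertex_foods, observed_38_62
    ):
        foods = {
            "a": vertex_foods["food1"],
            "b": vertex_foods["food1"],
            "c": vertex_foods["food2"],
        }
        profs = uniqueness_profile(observed_38_62, foods, step=0.02)
        assert profs["a"].multimodal or profs["b"].multimodal
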