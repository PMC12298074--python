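import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prillopt import desirability_ga as dga
from prillopt.dataset_io import DESIGN_BOUNDS
from prillopt.errors import DomainError

UP_SPEC = dga.DesirabilitySpec("prilling_score", 10, "UP", 0, 1.5, 1.6, 2)
TENT_SPEC = dga.DesirabilitySpec("feret_mm", 5, "TENT", 1.107, 2, 2.5, 3.022)


class TestDesirability:
    def test_up_at_min(self):
        assert dga.desirability(UP_SPEC, 0.0) == 0.0

    def test_up_ramp_midpoint(self):
        assert dga.desirability(UP_SPEC, 0.75) == pytest.approx(0.5)

    def test_up_plateau(self):
        assert dga.desirability(UP_SPEC, 1.5) == 1.0
        assert dga.desirability(UP_SPEC, 2.0) == 1.0

    def test_up_beyond_max_scores_one_with_warning(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            with pytest.warns(UserWarning, match="out of the calibrated range"):
                assert dga.desirability(UP_SPEC, 2.5) == 1.0

    def test_up_alternative_ramp_convention(self):
        spec = dga.DesirabilitySpec("core_score", 9, "UP", 0, 4, 4.1, 5)
        assert dga.desirability(spec, 4.0, up_ramp="to_mid1") == 1.0
        assert dga.desirability(spec, 4.0, up_ramp="to_mid2") == 0.0

    def test_tent_plateau(self):
        assert dga.desirability(TENT_SPEC, 2.10) == 1.0

    def test_tent_at_max_and_min(self):
        assert dga.desirability(TENT_SPEC, 3.022) == 0.0
        assert dga.desirability(TENT_SPEC, 1.107) == 0.0

    def test_tent_ramps(self):
        mid_up = (1.107 + 2) / 2
        assert dga.desirability(TENT_SPEC, mid_up) == pytest.approx(0.5)
        mid_down = (2.5 + 3.022) / 2
        assert dga.desirability(TENT_SPEC, mid_down) == pytest.approx(0.5)

    def test_invalid_breakpoints(self):
        with pytest.raises(DomainError):
            dga.DesirabilitySpec("x", 1, "UP", 2, 1, 3, 4)

    @given(x=st.floats(-10, 10))
    @settings(max_examples=80, deadline=None)
    def test_bounded_unit_interval(self, x):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for spec in (UP_SPEC, TENT_SPEC):
                assert 0.0 <= dga.desirability(spec, x) <= 1.0

    @given(a=st.floats(0, 2), b=st.floats(0, 2))
    @settings(max_examples=60, deadline=None)
    def test_up_non_decreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert dga.desirability(UP_SPEC, lo) <= dga.desirability(UP_SPEC, hi) + 1e-12


class TestOverallDesirability:
    def test_reference_optimum_scores_100(self, reference_specs):
        values = {
            "prilling_score": 2, "feret_mm": 2.10, "circularity": 0.86,
            "core_score": 4, "coating_mm": 0.28,
        }
        assert dga.overall_desirability(reference_specs, values) == pytest.approx(100.0)

    def test_all_zero(self, reference_specs):
        values = {
            "prilling_score": 0, "feret_mm": 1.107, "circularity": 0.642,
            "core_score": 0, "coating_mm": 0.074,
        }
        assert dga.overall_desirability(reference_specs, values) == pytest.approx(0.0)

    def test_equal_weight_half(self):
        specs = [
            dga.DesirabilitySpec("a", 1, "UP", 0, 1, 1, 2),
            dga.DesirabilitySpec("b", 1, "UP", 0, 1, 1, 2),
        ]
        assert dga.overall_desirability(specs, {"a": 1.5, "b": 0.0}) == pytest.approx(50.0)

    def test_missing_property_named(self, reference_specs):
        with pytest.raises(DomainError, match="feret_mm"):
            dga.overall_desirability(reference_specs, {"prilling_score": 2})

    def test_geometric_mode(self):
        specs = [
            dga.DesirabilitySpec("a", 1, "UP", 0, 1, 1, 2),
            dga.DesirabilitySpec("b", 1, "UP", 0, 1, 1, 2),
        ]
        assert dga.overall_desirability(
            specs, {"a": 1.5, "b": 0.0}, aggregation="geometric"
        ) == 0.0


class TestLoadSpecs:
    def test_reference_table(self, reference_specs):
        assert len(reference_specs) == 5
        by_name = {s.property_name: s for s in reference_specs}
        assert by_name["prilling_score"].weight == 10
        assert by_name["feret_mm"].shape == "TENT"
        assert by_name["coating_mm"].mid1 == pytest.approx(0.2345)

    def test_missing_column(self):
        with pytest.raises(DomainError):
            dga.load_desirability_csv("property,weight\nx,1\n")


def _bowl_predictor(frame: pd.DataFrame) -> dict:
    u = np.column_stack([
        (frame[v].to_numpy() - DESIGN_BOUNDS[v][0])
        / (DESIGN_BOUNDS[v][1] - DESIGN_BOUNDS[v][0])
        for v in dga.CONTINUOUS_VARS
    ])
    return {"y": 1.0 - ((u - 0.3) ** 2).sum(axis=1)}


BOWL_SPECS = [dga.DesirabilitySpec("y", 1.0, "UP", 0.0, 1.0, 1.0, 1.0)]


class TestGaOptimize:
    def test_matches_grid_oracle_on_bowl(self):
        res = dga.ga_optimize(_bowl_predictor, BOWL_SPECS, config=dga.GaConfig(seed=3))
        # grid oracle: max of the bowl over 50 points/dimension, chunked over
        # the first axis to keep memory flat
        grid = np.linspace(0, 1, 50)
        mesh4 = np.meshgrid(*[grid] * 4, indexing="ij")
        u4 = np.column_stack([m.ravel() for m in mesh4])
        tail_sq = ((u4 - 0.3) ** 2).sum(axis=1)
        oracle = max(
            (1.0 - ((x - 0.3) ** 2 + tail_sq)).max() for x in grid
        ) * 100
        assert res.overall_desirability >= oracle * 0.98

    def test_deterministic_under_seed(self):
        r1 = dga.ga_optimize(_bowl_predictor, BOWL_SPECS, config=dga.GaConfig(seed=9))
        r2 = dga.ga_optimize(_bowl_predictor, BOWL_SPECS, config=dga.GaConfig(seed=9))
        assert r1.best_settings == r2.best_settings
        assert r1.trace == r2.trace

    def test_reachable_plateau_hits_100(self):
        specs = [dga.DesirabilitySpec("y", 1.0, "UP", 0.0, 0.5, 0.5, 1.0)]
        res = dga.ga_optimize(_bowl_predictor, specs, config=dga.GaConfig(seed=1))
        assert res.overall_desirability == pytest.approx(100.0)

    def test_trace_non_decreasing(self):
        res = dga.ga_optimize(_bowl_predictor, BOWL_SPECS, config=dga.GaConfig(seed=5))
        assert all(b >= a for a, b in zip(res.trace, res.trace[1:]))
        assert len(res.trace) == 101

    def test_zero_mutation_no_crossover_collapses_to_elites(self):
        cfg = dga.GaConfig(seed=2, mutation_sd=0.0, crossover=False, iterations=30)
        res = dga.ga_optimize(_bowl_predictor, BOWL_SPECS, config=cfg)
        # degenerate operators cannot explore; result equals best elite found early
        assert res.trace[-1] == pytest.approx(max(res.trace[:5]), abs=1e-9)

    def test_predictor_failure_attaches_settings(self):
        def broken(frame):
            raise ValueError("boom")

        with pytest.raises(DomainError, match="predictor failed"):
            dga.ga_optimize(broken, BOWL_SPECS, config=dga.GaConfig(seed=1, iterations=1))

    def test_invalid_space(self):
        with pytest.raises(DomainError):
            dga.DesignSpace(bounds={"kgm_conc": (0.7, 0.6)})

    def test_result_within_bounds(self):
        res = dga.ga_optimize(_bowl_predictor, BOWL_SPECS, config=dga.GaConfig(seed=4))
        s = res.best_settings
        for name in dga.CONTINUOUS_VARS:
            lo, hi = DESIGN_BOUNDS[name]
            assert lo <= getattr(s, name) <= hi
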