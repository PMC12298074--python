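import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prillopt import dataset_io as dio
from prillopt import neurofuzzy as nfl
from prillopt.errors import DegenerateInputError, DomainError
from prillopt.synthetic_rig import RigConfig, random_design, sample_batch


class TestFuzzyPartition:
    @given(
        x=st.floats(-5.0, 15.0),
        nodes=st.lists(st.floats(0.0, 10.0), min_size=2, max_size=6, unique=True),
    )
    @settings(max_examples=100, deadline=None)
    def test_partition_of_unity(self, x, nodes):
        part = nfl.FuzzyPartition("v", nodes=tuple(sorted(nodes)))
        m = part.memberships(np.array([x]))
        assert m.min() >= 0
        assert m.sum() == pytest.approx(1.0, abs=1e-9)

    def test_triangular_shape(self):
        part = nfl.FuzzyPartition("v", nodes=(0.0, 1.0, 2.0))
        m = part.memberships(np.array([0.0, 0.5, 1.0, 1.5, 2.0]))
        assert m[:, 1] == pytest.approx([0.0, 0.5, 1.0, 0.5, 0.0])

    def test_categorical_one_hot(self):
        part = nfl.FuzzyPartition("nc", levels=("A", "B", "C"))
        m = part.memberships(np.array(["B", "A"], dtype=object))
        assert m.tolist() == [[0, 1, 0], [1, 0, 0]]

    def test_unknown_level_rejected(self):
        part = nfl.FuzzyPartition("nc", levels=("A", "B"))
        with pytest.raises(DomainError):
            part.memberships(np.array(["Z"], dtype=object))

    def test_nodes_must_increase(self):
        with pytest.raises(DomainError):
            nfl.FuzzyPartition("v", nodes=(1.0, 1.0, 2.0))

    def test_labels(self):
        assert nfl.set_labels(2) == ["LOW", "HIGH"]
        assert nfl.set_labels(3) == ["LOW", "MID", "HIGH"]


class TestSrmScore:
    def test_zero_mse(self):
        assert nfl.srm_score(0.0, 3, 20) == 0.0

    def test_monotone_in_p(self):
        scores = [nfl.srm_score(1.0, p, 30) for p in range(1, 10)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_hand_evaluation(self):
        # p=2, n=20, mse=1, c1=0.75
        h = 0.75 * (2 / 20) * (1 + math.log(10)) + math.log(20) / 40
        expected = 1.0 / (1.0 - math.sqrt(h))
        assert nfl.srm_score(1.0, 2, 20, c1=0.75) == pytest.approx(expected)

    def test_inadmissible_returns_inf(self):
        assert nfl.srm_score(1.0, 25, 20) == math.inf

    def test_bad_args(self):
        with pytest.raises(DomainError):
            nfl.srm_score(1.0, 2, 0)
        with pytest.raises(DomainError):
            nfl.srm_score(-1.0, 2, 20)


class TestFixedStructureFit:
    def test_reference_structures_strong_fit(self, reference_dataset):
        ds23 = dio.score_failed_blockage(reference_dataset)
        for resp, struct in nfl.REFERENCE_STRUCTURES.items():
            data = ds23 if resp == "prilling_score" else reference_dataset
            m = nfl.fit_fixed_structure(data, resp, struct, densities="max")
            assert m.training_r2_percent >= 73.0, resp

    def test_noiseless_linear_interpolated(self):
        g = np.linspace(0, 1, 12)
        df = pd.DataFrame({"x1": g, "y": g})
        m = nfl.fit_fixed_structure(df, "y", [("x1",)], densities=3)
        assert m.training_r2_percent > 99.9

    def test_constant_response_degenerate(self):
        df = pd.DataFrame({"x1": np.linspace(0, 1, 10), "y": np.zeros(10)})
        m = nfl.fit_fixed_structure(df, "y", [("x1",)], densities=2)
        assert np.allclose(m.submodels[0].coefficients, 0.0, atol=1e-6)
        with pytest.raises(DegenerateInputError):
            _ = m.training_r2

    def test_unknown_input_rejected(self, reference_dataset):
        with pytest.raises(DomainError):
            nfl.fit_fixed_structure(reference_dataset, "feret_mm", [("bogus",)])

    def test_ill_posed_flagged(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x1": rng.random(4), "x2": rng.random(4)})
        df["y"] = rng.random(4)
        m = nfl.fit_fixed_structure(df, "y", [("x1", "x2")], densities=3)
        assert m.ill_posed

    def test_additivity_against_basis_expansion_oracle(self, reference_dataset):
        m = nfl.fit_fixed_structure(
            reference_dataset, "circularity",
            nfl.REFERENCE_STRUCTURES["circularity"], densities="max",
        )
        frame = dio.usable_records(reference_dataset, "circularity").to_frame()
        # brute-force: assemble the full basis matrix and apply coefficients
        expected = np.full(len(frame), m.intercept)
        for s in m.submodels:
            mats = [p.memberships(frame[p.input_name].to_numpy()) for p in s.partitions]
            if len(mats) == 2:
                basis = np.einsum("ni,nj->nij", mats[0], mats[1]).reshape(len(frame), -1)
            else:
                basis = mats[0]
            expected += basis @ s.coefficients
        assert m.predict(frame) == pytest.approx(expected, abs=1e-10)

    def test_ridge_converges_to_ols(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x1": np.linspace(0, 1, 30)})
        df["y"] = 2.0 * df["x1"] + rng.normal(0, 0.1, 30)
        m_tiny = nfl.fit_fixed_structure(df, "y", [("x1",)], densities=2, ridge_factor=1e-12)
        # OLS oracle on the same basis
        part = m_tiny.submodels[0].partitions[0]
        X = np.hstack([np.ones((30, 1)), part.memberships(df["x1"].to_numpy())])
        w_ols, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
        pred_ols = X @ w_ols
        assert m_tiny.predict(df) == pytest.approx(pred_ols, abs=1e-5)

    def test_yaml_round_trip(self, reference_dataset, tmp_path):
        m = nfl.fit_fixed_structure(
            reference_dataset, "core_score", nfl.REFERENCE_STRUCTURES["core_score"]
        )
        path = tmp_path / "model.yaml"
        m.to_yaml(path)
        again = nfl.NflModel.from_yaml(path)
        frame = dio.usable_records(reference_dataset, "core_score").to_frame()
        assert again.predict(frame) == pytest.approx(m.predict(frame), abs=1e-12)


class TestAsmod:
    def test_recovers_additive_structure(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            n = 80
            df = pd.DataFrame({f"x{i}": rng.random(n) for i in range(1, 8)})
            df["y"] = np.sin(3 * df["x1"]) + 2 * df["x2"] ** 2 + rng.normal(0, 0.05, n)
            m = nfl.fit_asmod(df, "y", inputs=[f"x{i}" for i in range(1, 8)])
            selected = {name for s in m.submodels for name in s.inputs}
            hits += selected == {"x1", "x2"}
        assert hits >= 18

    def test_pure_noise_gives_intercept_only(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            df = pd.DataFrame({f"x{i}": rng.random(100) for i in range(1, 4)})
            df["y"] = rng.normal(0, 1, 100)
            m = nfl.fit_asmod(df, "y", inputs=["x1", "x2", "x3"])
            hits += len(m.submodels) == 0
        assert hits >= 19

    def test_single_input_monotone_response(self):
        df = pd.DataFrame({"x1": np.linspace(0, 1, 40), "x2": np.zeros(40) + 0.5})
        df["y"] = 3.0 * df["x1"]
        m = nfl.fit_asmod(df, "y", inputs=["x1", "x2"])
        assert len(m.submodels) == 1
        assert m.submodels[0].inputs == ("x1",)

    def test_never_worse_than_intercept_only(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x1": rng.random(50), "x2": rng.random(50)})
        df["y"] = df["x1"] + rng.normal(0, 0.2, 50)
        m = nfl.fit_asmod(df, "y", inputs=["x1", "x2"])
        y = df["y"].to_numpy()
        intercept_score = nfl.srm_score(float(np.mean((y - y.mean()) ** 2)), 1, len(y))
        assert m.srm_score <= intercept_score

    def test_recovers_rig_interaction(self):
        rig0 = RigConfig(noise_sd={k: 0.0 for k in dio.RESPONSE_COLUMNS})
        hits = 0
        for rep in range(20):
            data = sample_batch(rig0, random_design(60, seed=300 + rep), seed=300 + rep)
            m = nfl.fit_asmod(data, "feret_mm")
            hits += {"nc", "p_outer"} in [set(s.inputs) for s in m.submodels]
        assert hits >= 18

    def test_too_few_records_rejected(self):
        df = pd.DataFrame({"x1": [0.0, 1.0, 2.0], "y": [0.0, 1.0, 2.0]})
        with pytest.raises(DomainError):
            nfl.fit_asmod(df, "y", inputs=["x1"])


class TestRules:
    def test_univariate_density2_two_rules(self):
        df = pd.DataFrame({"x1": np.linspace(0, 1, 20)})
        df["y"] = df["x1"]
        m = nfl.fit_fixed_structure(df, "y", [("x1",)], densities=2)
        rules = nfl.extract_rules(m)
        assert len(rules) == 2
        assert {r.antecedent[0][1] for r in rules} == {"LOW", "HIGH"}

    def test_tensor_rule_count(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x1": rng.random(40), "x2": rng.random(40)})
        df["y"] = df["x1"] * df["x2"]
        m = nfl.fit_fixed_structure(
            df, "y", [("x1", "x2")], densities={"x1": 2, "x2": 3}
        )
        rules = nfl.extract_rules(m)
        assert len(rules) == 6

    def test_monotone_effect_orders_consequents(self):
        df = pd.DataFrame({"x1": np.linspace(0, 1, 25)})
        df["y"] = 2.0 * df["x1"]
        m = nfl.fit_fixed_structure(df, "y", [("x1",)], densities=2)
        rules = {r.antecedent[0][1]: r for r in nfl.extract_rules(m)}
        assert rules["HIGH"].confidence > rules["LOW"].confidence
        assert all(0.0 <= r.confidence <= 1.0 for r in rules.values())

    def test_render_mentions_labels(self):
        df = pd.DataFrame({"x1": np.linspace(0, 1, 20)})
        df["y"] = df["x1"]
        m = nfl.fit_fixed_structure(df, "y", [("x1",)], densities=2)
        text = nfl.extract_rules(m)[0].render("y")
        assert text.startswith("IF x1 IS ")
        assert "THEN y IS" in text
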