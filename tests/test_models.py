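"""Response transforms, AICc selection, and partial R²."""

import numpy as np
import pandas as pd
import pytest

import phylotank as pt
from phylotank.models import ROLE_TERMS, _apply_box_cox


class TestStandardize:
    def test_hand_example(self):
        assert pt.standardize(np.array([1.0, 2.0, 3.0])).tolist() == \
            pytest.approx([-1.0, 0.0, 1.0])

    def test_moments(self, rng):
        y = pt.standardize(rng.normal(3, 7, 100))
        assert abs(y.mean()) < 1e-12
        assert y.std(ddof=1) == pytest.approx(1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pt.standardize(np.full(5, 2.0))


class TestAICc:
    def test_correction_closed_form(self):
        # n = 20, k = 3: AICc - AIC = 2*3*4/16 = 1.5
        llf = -12.3
        assert pt.aicc(llf, 3, 20) - (-2 * llf + 6) == pytest.approx(1.5)

    def test_correction_vanishes_for_large_n(self):
        assert pt.aicc(0.0, 3, 10000) - 6.0 < 0.01

    def test_infinite_when_unidentifiable(self):
        assert np.isinf(pt.aicc(0.0, 10, 11))


class TestCandidateFamily:
    def test_marginality_respected(self):
        cands = pt.candidate_terms(ROLE_TERMS["colonization"])
        for combo in cands:
            cs = set(combo)
            if "size2" in cs:
                assert "size" in cs
            if "size_x_predator" in cs:
                assert {"size", "predator"} <= cs
        assert () in cands  # null model present
        assert len(cands) == 8

    def test_survey_family_includes_detritus(self):
        cands = pt.candidate_terms(ROLE_TERMS["survey"])
        assert len(cands) == 16


class TestSelectionRule:
    def test_two_delta_fewest_variables_tie_break(self):
        """Candidates 1.2 AICc apart with 2 vs 3 terms: the 2-term model
        wins under the within-2-delta parsimony rule."""
        cand = pd.DataFrame({
            "terms": [("size", "predator", "size_x_predator"), ("size", "predator")],
            "n_terms": [3, 2],
            "aicc": [100.0, 101.2],
        })
        assert pt.select_by_aicc(cand) == ("size", "predator")

    def test_outside_two_delta_minimum_wins(self):
        cand = pd.DataFrame({
            "terms": [("size",), ()],
            "n_terms": [1, 0],
            "aicc": [100.0, 102.5],
        })
        assert pt.select_by_aicc(cand) == ("size",)

    def test_fit_candidates_consistent_with_rule(self, rng):
        """The model chosen by fit_candidates always satisfies the
        documented rule given its own candidate table."""
        for _ in range(20):
            n = 20
            meta = pt.BromeliadMeta(pd.DataFrame({
                "capacity_ml": np.exp(rng.uniform(3, 7, n)),
                "predator_present": rng.random(n) < 0.5,
            }, index=[f"b{i}" for i in range(n)]))
            design = pt.build_design(meta, "colonization")
            y = rng.normal(size=n) + rng.normal() * design["size"].to_numpy()
            res = pt.fit_candidates(design, y, role="colonization")
            assert res.chosen_terms == pt.select_by_aicc(res.candidates)

    def test_selection_consistency_under_strong_signal(self):
        """y = 2*size + small noise: 'size' beats null and size+size² in
        nearly every replicate."""
        hits = 0
        reps = 200
        rng = np.random.default_rng(0)
        for _ in range(reps):
            n = 20
            size = rng.uniform(-1, 1, n)
            y = 2 * size + rng.normal(0, 0.3, n)
            design = pd.DataFrame({"size": size, "size2": size**2})
            res = pt.fit_candidates(design, y, terms=("size", "size2"))
            hits += res.chosen_terms == ("size",)
        assert hits >= 0.9 * reps

    def test_pure_noise_selects_null_most_often(self):
        rng = np.random.default_rng(1)
        nulls = 0
        reps = 100
        for _ in range(reps):
            n = 20
            design = pd.DataFrame({"size": rng.uniform(-1, 1, n)})
            y = rng.normal(size=n)
            res = pt.fit_candidates(design, y, terms=("size",))
            nulls += res.chosen_terms == ()
        assert nulls > reps / 2

    def test_missing_responses_dropped(self, rng):
        design = pd.DataFrame({"size": rng.uniform(-1, 1, 20)})
        y = rng.normal(size=20)
        y[3] = np.nan
        res = pt.fit_candidates(design, y, terms=("size",))
        assert res.n == 19


class TestPartialR2:
    def test_three_point_hand_computation(self):
        """y = (1, 2, 4) on x = (0, 1, 2): SSE_full = 1/6,
        SSE_intercept = 14/3, partial R² = 27/28."""
        design = pd.DataFrame({"size": [0.0, 1.0, 2.0]})
        y = np.array([1.0, 2.0, 4.0])
        pr2 = pt.partial_r2(design, y, ("size",))
        assert pr2["size"] == pytest.approx(27 / 28)

    def test_perfect_predictor_gives_one(self):
        design = pd.DataFrame({"size": np.arange(10.0)})
        y = 3.0 * design["size"].to_numpy() + 1.0
        assert pt.partial_r2(design, y, ("size",))["size"] == pytest.approx(1.0)

    def test_null_predictor_near_zero(self, rng):
        n = 2000
        design = pd.DataFrame({"size": rng.uniform(-1, 1, n),
                               "predator": rng.integers(0, 2, n).astype(float)})
        y = design["size"].to_numpy() + rng.normal(0, 0.1, n)
        pr2 = pt.partial_r2(design, y, ("size", "predator"))
        assert pr2["predator"] < 0.01

    def test_dropping_main_drops_dependents(self, rng):
        n = 50
        size = rng.uniform(-1, 1, n)
        pred = (rng.random(n) < 0.5).astype(float)
        design = pd.DataFrame({"size": size, "predator": pred,
                               "size_x_predator": size * pred})
        y = size + 0.5 * size * pred + rng.normal(0, 0.2, n)
        chosen = ("size", "predator", "size_x_predator")
        pr2 = pt.partial_r2(design, y, chosen)
        # the 'size' partial compares against a model without size AND
        # without the interaction, so it captures both contributions
        assert pr2["size"] > pr2["size_x_predator"]


class TestTransforms:
    def test_box_cox_limits(self):
        y = np.array([1.0, 2.0, 5.0])
        assert _apply_box_cox(y, 0.0) == pytest.approx(np.log(y))
        assert _apply_box_cox(y, 1.0) == pytest.approx(y - 1.0)

    def test_box_cox_requires_positive(self):
        with pytest.raises(ValueError, match="positive"):
            pt.transform_response(np.array([-1.0, 1.0, 2.0]), method="box_cox")

    def test_yeo_johnson_on_normal_data_lambda_near_one(self, rng):
        y = rng.normal(0, 1, 200)
        res = pt.transform_response(y, method="yeo_johnson")
        assert res.method == "yeo_johnson"
        assert abs(res.lam - 1.0) < 0.25

    def test_auto_mode_skips_transform_when_diagnostics_pass(self, rng):
        n = 100
        design = pd.DataFrame({"size": rng.uniform(-1, 1, n)})
        y = design["size"].to_numpy() + rng.normal(0, 1, n)
        res = pt.transform_response(y, design, method="auto")
        assert res.method == "none"
        assert res.diagnostics["pass"]

    def test_auto_mode_transforms_skewed_response(self, rng):
        n = 100
        design = pd.DataFrame({"size": rng.uniform(-1, 1, n)})
        y = np.exp(3 + design["size"].to_numpy() + rng.normal(0, 1, n))
        res = pt.transform_response(y, design, method="auto")
        assert res.method in ("box_cox", "yeo_johnson")
        assert not res.diagnostics["pass"]
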