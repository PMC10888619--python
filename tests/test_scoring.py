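"""Sullivan point system: derivation, look-up table, patient scoring."""

import numpy as np
import pytest
from scipy.special import logit

import rbcscore as rs
from rbcscore.scoring import round_half_away

from conftest import make_cohort

PATIENT_1 = {"surgery_type": "lumbar", "vbr": "yes", "stages": "0", "hb": 9.1}
PATIENT_2 = {"surgery_type": "combination", "vbr": "no", "stages": "gt3", "hb": 11.7}

PUBLISHED_POINTS = {
    "surgery_type": {"cervical": 0, "thoracic": 0, "lumbar": 1, "combination": 2},
    "vbr": {"no": 0, "yes": 1},
    "stages": {"0": 0, "1": 1, "2": 2, "3": 3, "gt3": 3},
}
PUBLISHED_HB_POINTS = {"<8": 7, "[8,12)": 5, "[12,16]": 2, ">16": 0}


@pytest.fixture
def derived_system():
    return rs.derive_points(rs.published_coefficients(), "vbr",
                            [rs.default_hb_bands()])


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.5, 1), (1.5, 2), (2.5, 3), (-0.5, -1), (0.49, 0), (-1.49, -1), (0.0, 0)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestDerivePoints:
    def test_published_coefficients_reproduce_published_points(self, derived_system):
        assert derived_system.categorical_points == PUBLISHED_POINTS
        assert derived_system.banded_points["hb"] == PUBLISHED_HB_POINTS
        assert derived_system.b == pytest.approx(0.841)
        assert derived_system.max_score == 13

    def test_b_source_must_be_binary(self):
        with pytest.raises(rs.ScoringError, match="binary"):
            rs.derive_points(rs.published_coefficients(), "stages",
                             [rs.default_hb_bands()])

    def test_negative_categorical_coefficient_demands_reorientation(self):
        fit = rs.FitResult(intercept=0.0,
                           coefficients={"vbr[yes]": 0.8, "fracture[yes]": -0.4},
                           converged=True, n_used=100)
        with pytest.raises(rs.ScoringError, match="reorient"):
            rs.derive_points(fit, "vbr")

    def test_missing_band_spec_is_an_error(self):
        with pytest.raises(rs.ScoringError, match="band"):
            rs.derive_points(rs.published_coefficients(), "vbr", [])


class TestReorient:
    def _fit_two_ways(self):
        cfg = rs.default_config(n=4000, seed=13)
        cfg.missingness = {}
        cohort = rs.generate(cfg)
        model = rs.CandidateModel(("surgery_type", "vbr", "stages", "hb"))
        # reference the HIGHEST-risk stage so reorientation has work to do
        spec = rs.DEFAULT_DESIGN.with_reference("stages", "3")
        return cohort, model, rs.fit_model(cohort, model, spec), spec

    def test_already_lowest_risk_references_unchanged(self):
        fit = rs.published_coefficients()
        out, spec = rs.reorient_to_lowest_risk(fit)
        assert out.coefficients == fit.coefficients
        assert spec.references == rs.DEFAULT_DESIGN.references

    def test_reorientation_makes_all_categorical_coefficients_nonnegative(self):
        _, _, fit, spec = self._fit_two_ways()
        assert any(v < 0 for k, v in fit.coefficients.items() if "stages[" in k)
        out, new_spec = rs.reorient_to_lowest_risk(fit, spec)
        assert all(v >= 0 for k, v in out.coefficients.items() if "[" in k)
        assert new_spec.reference("stages") == "0"

    def test_reorientation_preserves_predictions_for_every_record(self):
        cohort, model, fit, spec = self._fit_two_ways()
        out, new_spec = rs.reorient_to_lowest_risk(fit, spec)
        d_old = rs.encode_design(cohort, model, spec)
        d_new = rs.encode_design(cohort, model, new_spec)
        p_old = rs.predict_prob(fit, d_old)
        p_new = rs.predict_prob(out, d_new)
        np.testing.assert_allclose(p_old, p_new, atol=1e-12)


class TestLookup:
    def _fitted_system(self):
        cfg = rs.default_config(n=6000, seed=19)
        cfg.missingness = {}
        cohort = rs.generate(cfg)
        fit = rs.fit_model(cohort, rs.CandidateModel(("surgery_type", "vbr", "stages", "hb")))
        fit, spec = rs.reorient_to_lowest_risk(fit)
        system = rs.derive_points(fit, "vbr", [rs.default_hb_bands()], spec)
        return fit, system

    def test_lookup_probabilities_strictly_increase(self):
        fit, system = self._fitted_system()
        lookup = rs.build_lookup(fit, system)
        probs = [lookup[s] for s in range(system.max_score + 1)]
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_logit_increment_per_point_equals_b(self):
        fit, system = self._fitted_system()
        lookup = rs.build_lookup(fit, system)
        incr = np.diff([logit(lookup[s]) for s in range(system.max_score + 1)])
        np.testing.assert_allclose(incr, system.b, atol=1e-9)

    def test_missing_intercept_is_an_error(self):
        system, _ = rs.published_score_fixture()
        with pytest.raises(rs.ScoringError, match="intercept"):
            rs.build_lookup(rs.published_coefficients(), system)


class TestPublishedFixture:
    def test_lookup_endpoints(self):
        _, lookup = rs.published_score_fixture()
        assert lookup[0] == pytest.approx(0.0013)
        assert lookup[13] == pytest.approx(0.9859)

    def test_max_score_is_sum_of_per_term_maxima(self):
        system, lookup = rs.published_score_fixture()
        assert system.max_score == 2 + 1 + 3 + 7 == 13
        assert lookup.max_score == 13

    def test_fixture_logit_increments_consistent_with_b(self):
        _, lookup = rs.published_score_fixture()
        incr = np.diff([logit(lookup[s]) for s in range(14)])
        assert ((incr >= 0.80) & (incr <= 0.88)).all()

    def test_fixture_equals_freshly_derived_points(self):
        system, _ = rs.published_score_fixture()
        derived = rs.derive_points(rs.published_coefficients(), "vbr",
                                   [rs.default_hb_bands()])
        assert system.categorical_points == derived.categorical_points
        assert system.banded_points == derived.banded_points


class TestScorePatient:
    def test_worked_example_patient_1(self, derived_system):
        _, lookup = rs.published_score_fixture()
        res = rs.score_patient(PATIENT_1, derived_system, lookup)
        assert res.per_term == {"surgery_type": 1, "vbr": 1, "stages": 0, "hb": 5}
        assert res.total == 7
        assert res.probability == pytest.approx(0.3113)

    def test_worked_example_patient_2(self, derived_system):
        _, lookup = rs.published_score_fixture()
        res = rs.score_patient(PATIENT_2, derived_system, lookup)
        assert res.per_term == {"surgery_type": 2, "vbr": 0, "stages": 3, "hb": 5}
        assert res.total == 10
        assert res.probability == pytest.approx(0.8491)

    def test_all_reference_patient_scores_zero(self, derived_system):
        _, lookup = rs.published_score_fixture()
        res = rs.score_patient(
            {"surgery_type": "cervical", "vbr": "no", "stages": "0", "hb": 17.0},
            derived_system, lookup,
        )
        assert res.total == 0

    @pytest.mark.parametrize(
        "hb, band_points",
        [(7.99, 7), (8.0, 5), (11.99, 5), (12.0, 2), (16.0, 2), (16.01, 0)],
    )
    def test_hb_band_edges(self, derived_system, hb, band_points):
        res = rs.score_patient({**PATIENT_1, "hb": hb}, derived_system)
        assert res.per_term["hb"] == band_points

    def test_missing_term_errors_and_names_the_field(self, derived_system):
        with pytest.raises(rs.ScoringError, match="hb"):
            rs.score_patient({k: v for k, v in PATIENT_1.items() if k != "hb"},
                             derived_system)

    def test_score_cohort_matches_per_record_scoring(self, derived_system):
        cohort = make_cohort([
            PATIENT_1 | {"transfused": "yes"},
            PATIENT_2 | {"transfused": "no"},
            {"vbr": None},
        ])
        scores, dropped = rs.score_cohort(cohort, derived_system)
        assert dropped == 1
        assert scores.iloc[0] == 7 and scores.iloc[1] == 10
        assert np.isnan(scores.iloc[2])
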