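"""Estimator: category probabilities, likelihood, posterior, preservation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ovistage import (
    INTERVALS,
    CategoryProbabilities,
    ObservationSet,
    PreservationMode,
    Status,
    TemperatureProfile,
    VisibilityCategory,
    category_probability,
    estimate_age,
    interval_likelihood,
)

ALL_IDS = None  # filled by fixture use; tests take `table`


def full_observation(table, present_ids, temp=25.0, preservation=PreservationMode.LIVING):
    """Every landmark assessed: PRESENT for the given ids, ABSENT otherwise."""
    return ObservationSet(
        statuses={
            lm: (Status.PRESENT if lm in present_ids else Status.ABSENT)
            for lm in table.landmark_ids
        },
        preservation=preservation,
        nominal_temp_c=temp,
    )


SIGNATURE_90 = {
    "posterior_spiracles": Status.PRESENT,
    "spine_bands": Status.PRESENT,
    "coil_shaped_gut": Status.PRESENT,
    "fully_developed_tracheal_system": Status.ABSENT,
}


class TestCategoryProbability:
    @pytest.mark.parametrize(
        "cat,expected",
        [
            (VisibilityCategory.ABSENT, 0.01),
            (VisibilityCategory.RARE, 0.125),
            (VisibilityCategory.COMMON, 0.5),
            (VisibilityCategory.PREVALENT, 0.875),
        ],
    )
    def test_defaults(self, cat, expected):
        assert category_probability(cat) == expected

    def test_override_must_stay_in_category_range(self):
        CategoryProbabilities(rare=0.2)  # fine: inside (0, 0.25)
        with pytest.raises(ValueError, match="RARE"):
            CategoryProbabilities(rare=0.3)
        with pytest.raises(ValueError, match="PREVALENT"):
            CategoryProbabilities(prevalent=0.5)


class TestIntervalLikelihood:
    def test_bright_ring_signature_peaks_at_20_percent(self, table):
        obs = full_observation(table, {"bright_peripheral_ring"}, temp=25.0)
        loglik = interval_likelihood(obs, table)
        assert int(np.argmax(loglik)) == 2

    def test_no_evidence_gives_flat_likelihood(self, table):
        obs = ObservationSet(
            statuses={lm: Status.NOT_ASSESSED for lm in table.landmark_ids},
            nominal_temp_c=25.0,
        )
        with pytest.warns(UserWarning, match="flat"):
            loglik = interval_likelihood(obs, table)
        assert np.all(loglik == 0.0)

    def test_90_percent_signature_matches_brute_force(self, table):
        """Independent oracle: enumerate the product likelihood over all 11
        intervals straight from the calibration cells."""
        obs = ObservationSet(statuses=dict(SIGNATURE_90), nominal_temp_c=7.3)
        loglik = interval_likelihood(obs, table)

        probs = CategoryProbabilities()
        expected = []
        for iv in INTERVALS:
            value = 0.0
            for lm_id, status in SIGNATURE_90.items():
                q = probs.prob(table.category(lm_id, iv, 7.3))
                value += math.log(q if status is Status.PRESENT else 1.0 - q)
            expected.append(value)
        assert loglik == pytest.approx(expected)
        assert int(np.argmax(loglik)) == 9

    def test_unknown_landmark_rejected(self, table):
        obs = ObservationSet(statuses={"wing_buds": Status.PRESENT})
        with pytest.raises(KeyError, match="wing_buds"):
            interval_likelihood(obs, table)

    def test_noncalibrated_temperature_uses_nearest_cooler_on_tie(self, table):
        sig = {"bright_peripheral_ring": Status.PRESENT}
        mid = (7.3 + 25.0) / 2  # equidistant: tie resolves to 7.3
        ll_mid = interval_likelihood(
            ObservationSet(statuses=dict(sig), nominal_temp_c=mid), table
        )
        ll_cool = interval_likelihood(
            ObservationSet(statuses=dict(sig), nominal_temp_c=7.3), table
        )
        assert np.allclose(ll_mid, ll_cool)


class TestEstimateAge:
    def test_90_percent_signature_full_estimate(self, table):
        obs = ObservationSet(
            statuses=dict(SIGNATURE_90), nominal_temp_c=7.3
        )
        est = estimate_age(obs, table, profile=TemperatureProfile.constant(7.3))
        assert est.map_interval.index == 9
        assert est.proportion_range[0] >= 0.9
        assert 108.0 - 0.01 <= est.age_bounds_h.t_min
        assert est.age_bounds_h.t_max <= 120.0 + 0.01
        assert est.adh_bounds[0] >= 680.4 - 1e-6
        assert est.adh_bounds[1] <= 756.0 + 1e-6

    def test_flat_likelihood_returns_prior(self, table):
        obs = ObservationSet(
            statuses={lm: Status.NOT_ASSESSED for lm in table.landmark_ids},
            nominal_temp_c=25.0,
        )
        prior = np.array([0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.05, 0.03, 0.02])
        est = estimate_age(obs, table, prior=prior)
        assert est.posterior.probabilities == pytest.approx(prior)

    def test_flat_uniform_gives_all_interval_credible_set(self, table):
        obs = ObservationSet(
            statuses={lm: Status.NOT_ASSESSED for lm in table.landmark_ids},
            nominal_temp_c=25.0,
        )
        est = estimate_age(obs, table)
        assert len(est.credible_set) == 11
        assert est.proportion_range == (0.0, 1.0)

    def test_masking_invariance_under_hwk(self, table):
        """Posterior is identical whatever is recorded for the four
        non-HWK-visible landmarks on HWK material."""
        core = {lm: Status.ABSENT for lm in table.hwk_visible_ids}
        core["coil_shaped_gut"] = Status.PRESENT
        posteriors = []
        for fill in (Status.PRESENT, Status.ABSENT, Status.NOT_ASSESSED):
            statuses = dict(core)
            for lm in table.landmark_ids:
                if lm not in statuses:
                    statuses[lm] = fill
            obs = ObservationSet(
                statuses=statuses,
                preservation=PreservationMode.HWK_ETHANOL,
                nominal_temp_c=7.3,
            )
            posteriors.append(estimate_age(obs, table).posterior.probabilities)
        assert np.allclose(posteriors[0], posteriors[1])
        assert np.allclose(posteriors[0], posteriors[2])

    def test_single_landmark_bayes_oracle(self, table):
        """Brute-force two-term normalisation over the 11 intervals for a
        single assessed landmark."""
        probs = CategoryProbabilities()
        for lm_id in ("bright_peripheral_ring", "sack_shaped_gut"):
            for status in (Status.PRESENT, Status.ABSENT):
                obs = ObservationSet(
                    statuses={lm_id: status}, nominal_temp_c=25.0
                )
                est = estimate_age(obs, table)
                lik = np.array(
                    [
                        probs.prob(table.category(lm_id, iv, 25.0))
                        if status is Status.PRESENT
                        else 1.0 - probs.prob(table.category(lm_id, iv, 25.0))
                        for iv in INTERVALS
                    ]
                )
                expected = lik / lik.sum()  # uniform prior cancels
                assert est.posterior.probabilities == pytest.approx(expected)

    def test_map_tie_breaks_toward_earlier_interval(self, table):
        obs = ObservationSet(
            statuses={lm: Status.NOT_ASSESSED for lm in table.landmark_ids},
            nominal_temp_c=25.0,
        )
        est = estimate_age(obs, table)  # uniform posterior: all tied
        assert est.map_interval.index == 0

    def test_credible_set_is_contiguous(self, table):
        obs = full_observation(table, {"bright_peripheral_ring"}, temp=25.0)
        est = estimate_age(obs, table)
        indices = [iv.index for iv in est.credible_set]
        assert indices == list(range(indices[0], indices[-1] + 1))
        assert est.map_interval in est.credible_set

    def test_invalid_prior_rejected(self, table):
        obs = full_observation(table, set(), temp=25.0)
        with pytest.raises(ValueError, match="prior"):
            estimate_age(obs, table, prior=np.full(11, 0.2))
        with pytest.raises(ValueError):
            estimate_age(obs, table, prior=-np.full(11, 1 / 11))

    def test_missing_profile_gives_interval_only_with_warning(self, table):
        obs = ObservationSet(statuses=dict(SIGNATURE_90), nominal_temp_c=7.3)
        est = estimate_age(obs, table, profile=None)
        assert est.age_bounds_h is None
        assert any("thermal history" in w for w in est.warnings)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(data=st.data())
    def test_posterior_always_normalised(self, table, data):
        statuses = {
            lm: data.draw(st.sampled_from(list(Status)), label=lm)
            for lm in table.landmark_ids
        }
        temp = data.draw(st.sampled_from([7.3, 25.0, 15.0]))
        obs = ObservationSet(statuses=statuses, nominal_temp_c=temp)
        est = estimate_age(obs, table)
        assert abs(float(est.posterior.probabilities.sum()) - 1.0) <= 1e-9
        assert np.all(est.posterior.probabilities >= 0)


class TestEthanolDirect:
    def test_with_larval_morphology_censors_to_terminal_window(self, table):
        obs = ObservationSet(
            statuses={},
            preservation=PreservationMode.ETHANOL_DIRECT,
            larval_morphology=Status.PRESENT,
            nominal_temp_c=7.3,
        )
        est = estimate_age(obs, table, profile=TemperatureProfile.constant(7.3))
        assert est.censored
        assert est.proportion_range == (0.9, 1.0)
        assert {iv.index for iv in est.credible_set} == {9, 10}
        assert est.age_bounds_h.t_min == pytest.approx(108.0, abs=0.01)
        assert est.age_bounds_h.t_max == pytest.approx(120.0, abs=0.01)

    def test_without_larval_morphology_fully_censored(self, table):
        obs = ObservationSet(
            statuses={lm: Status.NOT_ASSESSED for lm in table.landmark_ids},
            preservation=PreservationMode.ETHANOL_DIRECT,
            nominal_temp_c=7.3,
        )
        est = estimate_age(obs, table)
        assert est.censored
        assert est.proportion_range == (0.0, 1.0)
        assert len(est.credible_set) == 11
        assert any("decomposition" in w for w in est.warnings)

    def test_interval_likelihood_refuses_direct_ethanol(self, table):
        obs = ObservationSet(
            statuses={}, preservation=PreservationMode.ETHANOL_DIRECT
        )
        with pytest.raises(ValueError, match="direct-ethanol"):
            interval_likelihood(obs, table)
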