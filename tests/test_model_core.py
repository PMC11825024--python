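import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from scipy.stats import binom, norm

from mrocc.model_core import (
    Design,
    LatentState,
    ModelParams,
    PriorSpec,
    complete_loglik,
    full_conditional_omega,
    full_conditional_z,
    linpred_detection,
    linpred_occupancy,
    linpred_richness,
    log_prior,
    site_marginal,
)

from _oracles import enumerate_omega_conditional, enumerate_z_conditional


def _one_region_design(J=1, K=1, X_rich_row=None):
    X = np.zeros((1, 10))
    X[0, 0] = 1.0
    if X_rich_row is not None:
        X[0] = X_rich_row
    return Design(
        X_rich=X,
        X_occ=np.zeros((1, 4)),
        cam=np.zeros((1, J)),
        settl_site=np.zeros((1, J)),
        site_mask=np.ones((1, J), dtype=bool),
        K=np.full((1, J), float(K)),
        region_ids=["R01"],
    )


class TestLinearPredictors:
    def test_zero_coefficients_give_half(self):
        X = np.zeros((3, 10))
        X[:, 0] = 1.0
        np.testing.assert_allclose(linpred_richness(np.zeros(10), X), 0.5)
        np.testing.assert_allclose(
            linpred_occupancy(np.zeros(5), np.zeros((3, 2)), np.zeros((3, 4))), 0.5
        )
        np.testing.assert_allclose(
            linpred_detection(np.zeros(3), np.zeros((3, 2)), np.zeros((3, 4)),
                              np.zeros((3, 4))),
            0.5,
        )

    def test_human_density_slope_evaluation(self):
        # beta_hden = -0.15 at one standardized SD of human density
        X = np.zeros((1, 10))
        X[0, 0] = 1.0
        X[0, 6] = 1.0  # hden column
        beta = np.zeros(10)
        beta[6] = -0.15
        np.testing.assert_allclose(
            linpred_richness(beta, X), expit(-0.15), atol=1e-12
        )
        assert abs(linpred_richness(beta, X).item() - 0.4626) < 1e-3

    def test_saturation_limit(self):
        X = np.zeros((1, 10))
        X[0, 0] = 1.0
        beta = np.zeros(10)
        beta[0] = 500.0
        assert linpred_richness(beta, X).item() == 1.0

    def test_patch_size_slope_evaluation(self):
        theta = np.zeros(5)
        theta[3] = 0.42  # psize column
        X_occ = np.array([[0.0, 0.0, 1.0, 0.0]])
        psi = linpred_occupancy(theta, np.zeros((1, 1)), X_occ)
        assert abs(psi.item() - 0.6035) < 1e-3

    def test_occupancy_effect_cancellation(self):
        theta = np.array([0.3, 0.1, -0.2, 0.4, 0.0])
        X_occ = np.array([[1.0, 0.5, -1.0, 2.0]])
        lin = theta[0] + (X_occ @ theta[1:]).item()
        psi = linpred_occupancy(theta, np.array([[-lin]]), X_occ)
        np.testing.assert_allclose(psi, 0.5, atol=1e-12)

    def test_camera_trigger_shifts_logit_additively(self):
        alpha = np.array([0.0, -0.3, 0.0])
        p = linpred_detection(
            alpha, np.zeros((1, 1)), np.array([[0.0, 1.0]]), np.zeros((1, 2))
        )
        lo = np.log(p / (1 - p))
        assert abs((lo[0, 0, 1] - lo[0, 0, 0]) - (-0.3)) < 1e-12

    def test_detection_intercept(self):
        p = linpred_detection(
            np.array([-2.0, 0.0, 0.0]), np.zeros((1, 1)),
            np.zeros((1, 1)), np.zeros((1, 1)),
        )
        assert abs(p.item() - 0.1192) < 1e-3

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            linpred_richness(np.zeros(9), np.zeros((2, 10)))


class TestSiteMarginal:
    def test_zero_history_value(self):
        val = site_marginal(0, 30, 0.5, 0.1)
        expected = 0.5 * 0.9**30 + 0.5
        np.testing.assert_allclose(val, expected, rtol=1e-12)
        assert abs(val - 0.5212) < 1e-3

    def test_reduces_to_binomial_when_psi_one(self):
        for y in range(6):
            np.testing.assert_allclose(
                site_marginal(y, 5, 1.0, 0.3), binom.pmf(y, 5, 0.3), rtol=1e-10
            )

    def test_detection_without_occupancy_impossible(self):
        assert site_marginal(2, 5, 0.0, 0.3) == 0.0

    def test_y_above_k_rejected(self):
        with pytest.raises(ValueError):
            site_marginal(6, 5, 0.5, 0.3)


class TestFullConditionals:
    def test_z_hand_value(self):
        # psi (1-p)^K / (psi (1-p)^K + 1 - psi) = 0.125/0.625
        np.testing.assert_allclose(
            full_conditional_z(0, 2, 0.5, 0.5, 1), 0.2, rtol=1e-12
        )

    def test_z_forced_by_detection_and_membership(self):
        assert full_conditional_z(3, 5, 0.2, 0.1, 1) == 1.0
        assert full_conditional_z(0, 5, 0.9, 0.1, 0) == 0.0

    def test_omega_hand_value(self):
        # p = 1 makes the all-zero site marginal 1 - psi = 0.5
        val = full_conditional_omega([0], 3, 0.5, [1.0], 0.5)
        np.testing.assert_allclose(val, 1.0 / 3.0, rtol=1e-12)

    def test_omega_certain_cases(self):
        assert full_conditional_omega([0, 0], 5, 0.5, [0.2, 0.3], 1.0) == 1.0
        assert full_conditional_omega([0, 2], 5, 0.5, [0.2, 0.3], 0.4) == 1.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.integers(min_value=0, max_value=3),
        st.floats(min_value=0.05, max_value=0.95),
        st.floats(min_value=0.05, max_value=0.95),
    )
    def test_z_matches_enumeration(self, y, psi, p):
        K = 3
        ours = float(full_conditional_z(y, K, psi, p, 1))
        oracle = enumerate_z_conditional(y, K, psi, p, 1)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=2), min_size=1, max_size=3),
        st.floats(min_value=0.05, max_value=0.95),
        st.floats(min_value=0.05, max_value=0.95),
        st.floats(min_value=0.05, max_value=0.95),
    )
    def test_omega_matches_enumeration(self, y_row, Omega, psi, p):
        K = 2
        y_row = [min(v, K) for v in y_row]
        p_row = [p] * len(y_row)
        ours = float(full_conditional_omega(y_row, K, psi, p_row, Omega))
        oracle = enumerate_omega_conditional(np.array(y_row), K, Omega, psi, p_row)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.floats(min_value=0.05, max_value=0.95),
        st.floats(min_value=0.05, max_value=0.95),
        st.integers(min_value=0, max_value=4),
    )
    def test_marginalization_consistency(self, psi, p, y):
        # summing the two z branches of the complete likelihood recovers the
        # site marginal
        K = 4
        total = 0.0
        for z in (0, 1):
            pz = psi if z else 1 - psi
            total += pz * binom.pmf(y, K, p * z)
        np.testing.assert_allclose(
            site_marginal(y, K, psi, p), total, atol=1e-10
        )


class TestCompleteLoglik:
    def _params(self, beta0=0.0, theta0=0.0, alpha0=0.0, R=1, M=1):
        beta = np.zeros(10)
        beta[0] = beta0
        theta = np.zeros(5)
        theta[0] = theta0
        alpha = np.zeros(3)
        alpha[0] = alpha0
        return ModelParams(
            beta=beta, theta=theta, alpha=alpha,
            sigma_psi=np.ones(R), sigma_p=np.ones(R),
            eps_psi=np.zeros((R, M)), eps_p=np.zeros((R, M)),
        )

    def test_hand_sum_three_bernoullis(self):
        design = _one_region_design(J=1, K=1)
        params = self._params()
        latents = LatentState(omega=np.array([[1]]), z=np.array([[[1]]]))
        y = np.array([[[1]]])
        ll = complete_loglik(params, latents, y, design)
        eps_terms = 2 * norm.logpdf(0.0, 0.0, 1.0)
        np.testing.assert_allclose(ll - eps_terms, 3 * math.log(0.5), atol=1e-10)
        assert abs(3 * math.log(0.5) - (-2.0794)) < 1e-3

    def test_detection_without_occupancy_is_minus_inf(self):
        design = _one_region_design(J=1, K=1)
        latents = LatentState(omega=np.array([[1]]), z=np.array([[[0]]]))
        ll = complete_loglik(self._params(), latents, np.array([[[1]]]), design)
        assert ll == -np.inf

    def test_additivity_over_identical_regions(self):
        design1 = _one_region_design(J=2, K=3)
        params1 = self._params(beta0=0.3, theta0=-0.2, alpha0=-1.0)
        y1 = np.array([[[2, 0]]])
        lat1 = LatentState(omega=np.array([[1]]), z=np.array([[[1, 1]]]))
        ll1 = complete_loglik(params1, lat1, y1, design1)

        X2 = np.tile(design1.X_rich, (2, 1))
        design2 = Design(
            X_rich=X2, X_occ=np.zeros((2, 4)), cam=np.zeros((2, 2)),
            settl_site=np.zeros((2, 2)), site_mask=np.ones((2, 2), bool),
            K=np.full((2, 2), 3.0), region_ids=["R01", "R02"],
        )
        params2 = self._params(beta0=0.3, theta0=-0.2, alpha0=-1.0, R=2)
        y2 = np.tile(y1, (2, 1, 1))
        lat2 = LatentState(omega=np.ones((2, 1)), z=np.tile(lat1.z, (2, 1, 1)))
        ll2 = complete_loglik(params2, lat2, y2, design2)
        np.testing.assert_allclose(ll2, 2 * ll1, rtol=1e-12)

    def test_invariant_to_permuting_empty_augmented_rows(self):
        rng = np.random.default_rng(4)
        M, J = 4, 2
        design = Design(
            X_rich=np.array([[1.0] + [0.0] * 9]), X_occ=np.zeros((1, 4)),
            cam=np.zeros((1, J)), settl_site=np.zeros((1, J)),
            site_mask=np.ones((1, J), bool), K=np.full((1, J), 3.0),
            region_ids=["R01"],
        )
        params = self._params(M=M)
        y = np.zeros((1, M, J))
        y[0, 0] = [2, 1]
        omega = np.array([[1, 0, 0, 0]])
        z = np.zeros((1, M, J))
        z[0, 0] = 1
        ll = complete_loglik(params, LatentState(omega=omega, z=z), y, design)
        perm = [0, 3, 1, 2]  # permutes the empty rows only
        ll_perm = complete_loglik(
            params,
            LatentState(omega=omega[:, perm], z=z[:, perm]),
            y[:, perm],
            design,
        )
        np.testing.assert_allclose(ll, ll_perm, rtol=1e-12)


class TestPriors:
    def test_slope_prior_closed_form_at_zero(self):
        spec = PriorSpec()
        params = ModelParams(
            beta=np.zeros(10), theta=np.zeros(5), alpha=np.zeros(3),
            sigma_psi=np.array([1.0]), sigma_p=np.array([1.0]),
        )
        lp = log_prior(params, spec)
        slope_term = -math.log(1.5 * math.sqrt(2 * math.pi))
        intercept_term = math.log(0.25)  # logistic(0,1) density at 0
        sigma_term = -math.log(5.0)
        expected = 15 * slope_term + 3 * intercept_term + 2 * sigma_term
        np.testing.assert_allclose(lp, expected, rtol=1e-12)

    def test_sigma_outside_support_minus_inf(self):
        params = ModelParams(
            beta=np.zeros(10), theta=np.zeros(5), alpha=np.zeros(3),
            sigma_psi=np.array([6.0]), sigma_p=np.array([1.0]),
        )
        assert log_prior(params) == -np.inf

    def test_symmetric_prior_maximized_at_mean(self):
        spec = PriorSpec()
        at0 = float(spec.logpdf("slopes", 0.0))
        assert at0 > float(spec.logpdf("slopes", 0.7))
        assert at0 > float(spec.logpdf("slopes", -0.7))

    def test_yaml_round_trip(self, tmp_path):
        spec = PriorSpec(slopes=("normal", 0.0, 2.5))
        spec.to_yaml(tmp_path / "priors.yaml")
        back = PriorSpec.from_yaml(tmp_path / "priors.yaml")
        assert back == spec


class TestLatentState:
    def test_z_requires_membership(self):
        lat = LatentState(omega=np.array([[0]]), z=np.array([[[1]]]))
        with pytest.raises(ValueError, match="omega"):
            lat.validate()

    def test_detection_forces_z(self):
        lat = LatentState(omega=np.array([[1]]), z=np.array([[[0]]]))
        with pytest.raises(ValueError, match="y"):
            lat.validate(y=np.array([[[2]]]))
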