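"""Grid posteriors: priors, likelihood, marginalization, median readout."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slantflow.bayes_core import (
    DefLikelihood,
    EstimatorConfig,
    RotationPrior,
    SlantPrior,
    closed_form_retinal_estimate,
    def_likelihood,
    estimate_slant,
    inverse_optics_config,
    joint_posterior,
    marginal_slant_posterior,
    posterior_median,
    retinal_config,
    rotation_prior_density,
    slant_prior_density,
    SlantMarginal,
)


def norm_peak(s):
    return 1.0 / (s * math.sqrt(2 * math.pi))


class TestPriorDensities:
    def test_slant_prior_zero_for_negative(self):
        assert slant_prior_density(-1.0, SlantPrior(1.0)) == 0.0

    def test_slant_prior_peak_is_twice_gaussian(self):
        assert slant_prior_density(0.0, SlantPrior(1.0)) == pytest.approx(
            2 * norm_peak(1.0), rel=1e-9
        )

    def test_slant_prior_normalized(self):
        x = np.linspace(0, 30, 20001)
        assert np.trapezoid(slant_prior_density(x, SlantPrior(2.0)), x) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_stationarity_prior_peak(self):
        p = RotationPrior("stationarity", 0.32, 0.1)
        # far from the zero-truncation boundary the peak is the Gaussian peak
        assert rotation_prior_density(0.32, p) == pytest.approx(norm_peak(0.1), rel=1e-3)

    def test_rotation_priors_normalized_on_support(self):
        w = np.linspace(0, 50, 200001)
        for p in (
            RotationPrior("stationarity", 0.32, 0.1),
            RotationPrior("stationarity", 0.05, 0.2),  # truncation matters here
            RotationPrior("noninformative", None, 2.0),
        ):
            assert np.trapezoid(rotation_prior_density(w, p), w) == pytest.approx(
                1.0, abs=1e-4
            )

    def test_noninformative_zero_for_negative(self):
        assert rotation_prior_density(-0.1, RotationPrior("noninformative", None, 1.0)) == 0.0


class TestDefLikelihood:
    def test_peak_at_mean(self):
        lik = DefLikelihood(cv=None, sigma_def_rad_s=0.1)
        assert def_likelihood(1.883, 5.671, 0.332, lik) == pytest.approx(
            norm_peak(0.1), rel=1e-3
        )

    def test_symmetric_in_residual(self):
        lik = DefLikelihood(cv=None, sigma_def_rad_s=0.2)
        d = 1.0
        assert def_likelihood(d, 1.0, d + 0.3, lik) == pytest.approx(
            def_likelihood(d, 1.0, d - 0.3, lik), rel=1e-12
        )

    def test_cv_mode_scales_spread(self):
        lik = DefLikelihood(cv=0.05)
        assert lik.spread_for(2.0) == pytest.approx(0.1)
        assert lik.spread_for(0.0) == lik.sigma_floor_rad_s

    def test_exactly_one_parameterization(self):
        with pytest.raises(ValueError):
            DefLikelihood(cv=0.05, sigma_def_rad_s=0.1)
        with pytest.raises(ValueError):
            DefLikelihood(cv=None, sigma_def_rad_s=None)


class TestJointPosterior:
    def test_normalization_and_model_flag(self):
        grid = joint_posterior(0.5, retinal_config(k=1.5))
        total = np.trapezoid(
            np.trapezoid(grid.density, grid.omega_axis, axis=1), grid.sigma_axis
        )
        assert total == pytest.approx(1.0, abs=1e-6)
        assert grid.model == "retinal"
        assert joint_posterior(0.5, inverse_optics_config(0.332)).model == "inverse_optics"

    def test_zero_def_concentrates_near_origin_product(self):
        cfg = retinal_config(likelihood=DefLikelihood(cv=None, sigma_def_rad_s=1e-3))
        grid = joint_posterior(0.0, cfg)
        S, W = np.meshgrid(grid.sigma_axis, grid.omega_axis, indexing="ij")
        products = (S * W)[grid.density > grid.density.max() * 1e-3]
        assert np.max(products) < 0.05

    def test_retinal_ridge_follows_hyperbola(self):
        d = 1.0
        cfg = retinal_config(likelihood=DefLikelihood(cv=None, sigma_def_rad_s=0.01))
        grid = joint_posterior(d, cfg)
        # at each omega column with appreciable mass, the densest sigma sits on
        # sigma*omega = def
        for j in range(50, len(grid.omega_axis), 100):
            col = grid.density[:, j]
            if col.max() < grid.density.max() * 1e-2:
                continue
            s_star = grid.sigma_axis[np.argmax(col)]
            assert s_star * grid.omega_axis[j] == pytest.approx(d, rel=0.05)

    def test_small_sigma_omega_collapses_to_1d_posterior(self):
        # oracle: with omega pinned at omega_E the marginal is the 1-D posterior
        # prior(sigma) * N(def; sigma*omega_E, sigma_def)
        omega_e, d_obs, s_def = 0.332, 0.7, 0.02
        cfg = inverse_optics_config(
            omega_e, 1e-4, likelihood=DefLikelihood(cv=None, sigma_def_rad_s=s_def)
        )
        marg = marginal_slant_posterior(joint_posterior(d_obs, cfg))
        x = marg.sigma_axis
        oracle = slant_prior_density(x, cfg.slant_prior) * np.exp(
            -0.5 * ((d_obs - x * omega_e) / s_def) ** 2
        )
        oracle /= np.trapezoid(oracle, x)
        assert posterior_median(marg) == pytest.approx(
            posterior_median(SlantMarginal(x, oracle)), rel=1e-3
        )

    def test_negative_def_rejected(self):
        with pytest.raises(ValueError):
            joint_posterior(-0.1, retinal_config())

    def test_prior_mass_coverage_enforced(self):
        cfg = retinal_config(sigma_Sigma=8.0, slant_max=10.0)  # >1% mass beyond grid
        with pytest.raises(ValueError, match="prior mass"):
            joint_posterior(0.5, cfg)


class TestMarginalAndMedian:
    def test_marginal_integrates_to_one(self):
        marg = marginal_slant_posterior(joint_posterior(1.0, retinal_config()))
        assert np.trapezoid(marg.density, marg.sigma_axis) == pytest.approx(1.0, abs=1e-6)

    def test_unnormalized_grid_rejected(self):
        from slantflow.bayes_core import PosteriorGrid

        g = PosteriorGrid(
            np.linspace(0, 1, 4),
            np.linspace(0, 1, 4),
            np.ones((4, 4)),
            normalized=False,
            model="retinal",
        )
        with pytest.raises(ValueError):
            marginal_slant_posterior(g)

    def test_symmetric_marginal_median_at_center(self):
        x = np.linspace(0, 4, 2001)
        d = np.exp(-0.5 * ((x - 2.0) / 0.3) ** 2)
        d /= np.trapezoid(d, x)
        assert posterior_median(SlantMarginal(x, d)) == pytest.approx(2.0, abs=1e-4)

    def test_degenerate_marginal_rejected(self):
        with pytest.raises(ValueError):
            posterior_median(SlantMarginal(np.linspace(0, 1, 10), np.zeros(10)))

    def test_median_stable_under_grid_refinement(self):
        d = 0.7
        med = {
            n: estimate_slant(d, retinal_config(k=1.88, grid_n=n)) for n in (512, 1024)
        }
        assert med[1024] == pytest.approx(med[512], rel=0.01)


class TestClosedForm:
    @pytest.mark.parametrize(
        "d, k, expected", [(1.0, 1.0, 1.0), (1.883, 1.88, 2.5798), (0.0, 2.0, 0.0)]
    )
    def test_values(self, d, k, expected):
        assert closed_form_retinal_estimate(d, k) == pytest.approx(expected, abs=1e-4)

    def test_negative_def_rejected(self):
        with pytest.raises(ValueError):
            closed_form_retinal_estimate(-0.5, 1.0)

    def test_retinal_median_matches_closed_form(self):
        # full sweep lives in the acceptance suite; spot-check two regimes here
        for k, d in ((1.0, 1.0), (1.88, 1.883)):
            est = estimate_slant(d, retinal_config(k=k))
            assert est == pytest.approx(closed_form_retinal_estimate(d, k), rel=0.01)


class TestModelContrasts:
    def test_veridical_limit_spot_check(self):
        omega_e, tan_true = 0.332, math.tan(math.radians(50))
        cfg = inverse_optics_config(
            omega_e, 1e-3, likelihood=DefLikelihood(cv=None, sigma_def_rad_s=1e-3)
        )
        assert estimate_slant(tan_true * omega_e, cfg) == pytest.approx(tan_true, rel=0.02)

    def test_monotone_bias_in_rotation_uncertainty(self):
        # slant under-estimation grows with rotation-prior uncertainty once
        # sigma_Omega is an appreciable fraction of omega_E (below ~0.3
        # omega_E a small Jensen-driven over-estimation precedes it)
        omega_e = 0.332
        d = math.tan(math.radians(65)) * omega_e
        estimates = [
            estimate_slant(d, inverse_optics_config(omega_e, s))
            for s in (0.1, 0.2, 0.4, 1.0, 3.0)
        ]
        assert all(a >= b - 1e-6 for a, b in zip(estimates, estimates[1:]))

    def test_passive_equivalence_with_broad_prior(self):
        # an inverse-optics observer whose rotation prior is far broader than
        # the head signal behaves like the retinal-only observer
        omega_e, d = 0.332, 1.0
        sigma_w = 100 * omega_e
        inv = inverse_optics_config(omega_e, sigma_w, sigma_Sigma=3.0)
        ret = EstimatorConfig(
            slant_prior=SlantPrior(3.0),
            rotation_prior=RotationPrior("noninformative", None, sigma_w),
        )
        assert estimate_slant(d, inv) == pytest.approx(estimate_slant(d, ret), rel=0.01)


class TestConfig:
    def test_k_property(self):
        cfg = retinal_config(k=1.88, sigma_Sigma=3.0)
        assert cfg.k == pytest.approx(1.88, rel=1e-9)

    def test_round_trip_dict(self):
        cfg = inverse_optics_config(0.332, 0.05, sigma_Sigma=2.5, grid_n=256)
        assert EstimatorConfig.from_dict(cfg.to_dict()) == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="sigmaOmga"):
            EstimatorConfig.from_dict({"sigmaOmga": 1.0})

    @given(
        d=st.floats(0.01, 3.0),
        k=st.floats(0.5, 2.5),
    )
    @settings(max_examples=10)
    def test_estimates_within_grid_bounds(self, d, k):
        cfg = retinal_config(k=k, grid_n=256)
        est = estimate_slant(d, cfg)
        assert 0.0 <= est <= cfg.slant_max
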