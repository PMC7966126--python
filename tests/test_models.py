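"""Conditional log-likelihoods of the CV and BI model families."""

import numpy as np
import pytest
from scipy.stats import norm

import irtlink as il
from irtlink.models import _probit_cuts

LOG_2PI = np.log(2 * np.pi)


def _spec(name, linkset, scale, **kw):
    st = kw.pop("structural", il.StructuralSpec(has_slope=False, iiv=("baseline",)))
    return il.model_spec(name, st, linkset=linkset,
                         n_categories=scale.n_total_categories,
                         ts_min=scale.min_total, **kw)


class TestCVLoglik:
    def test_density_at_the_mean_with_unit_sigma(self, linkset, scale):
        spec = _spec("S-CV", linkset, scale)
        theta = {"theta1": 50.0, "sigma": 1.0}
        eta = {"baseline": np.zeros(1)}
        ll = il.cv_obs_loglik(spec, [50.0], [0.0], None, theta, eta)
        assert np.isclose(ll[0], -0.5 * LOG_2PI)

    def test_icv_matches_hand_computed_normal_density(self, linkset, scale):
        spec = _spec("I-CV", linkset, scale)
        theta = {"theta1": 0.9}
        eta = {"baseline": np.array([0.25])}
        psi = 0.9 + 0.25
        mu = float(linkset.pn1(psi))
        sd = float(linkset.pn2(psi))
        y = mu + 3.0
        expected = norm.logpdf(y, mu, sd)
        got = il.cv_obs_loglik(spec, [y], [0.0], None, theta, eta)
        assert np.isclose(got[0], expected, atol=1e-10)

    def test_integrates_to_one_over_y(self, linkset, scale):
        # quadrature over a wide y grid for the heteroscedastic I-CV density
        spec = _spec("I-CV", linkset, scale)
        theta = {"theta1": 1.2}
        eta = {"baseline": np.zeros(1)}
        y = np.linspace(-50, 200, 4001)
        ll = il.cv_obs_loglik(spec, y, np.zeros_like(y), None, theta, eta)
        assert np.isclose(np.trapezoid(np.exp(ll), y), 1.0, atol=1e-6)

    def test_icv_mean_bounded_by_scale_range(self, linkset, scale):
        spec = _spec("I-CV", linkset, scale)
        from irtlink.models import _mean_and_psi

        for psi in np.linspace(*linkset.domain, 41):
            mu, _ = _mean_and_psi(spec, [0.0], None, {"theta1": psi},
                                  {"baseline": np.zeros(1)})
            assert scale.min_total - 0.5 < float(mu[0]) < scale.max_total + 0.5

    def test_scaled_sd_with_unit_theta_equals_fixed(self, linkset, scale):
        fixed = _spec("I-CV", linkset, scale)
        scaled = _spec("I-CV", linkset, scale, sd_structure="irt_scaled")
        y, t = np.array([40.0, 70.0]), np.zeros(2)
        eta = {"baseline": np.zeros(2)}
        ll_fixed = il.cv_obs_loglik(fixed, y, t, None, {"theta1": 1.0}, eta)
        ll_scaled = il.cv_obs_loglik(scaled, y, t, None,
                                     {"theta1": 1.0, "sd_scale": 1.0}, eta)
        assert np.allclose(ll_fixed, ll_scaled)


class TestBILogPmf:
    @pytest.mark.parametrize("n", [2, 5, 133])
    def test_standard_normal_gives_uniform_law(self, n):
        k = np.arange(1, n + 1)
        p = np.exp(il.bi_log_pmf(k, 0.0, 1.0, n))
        assert np.allclose(p, 1.0 / n, atol=1e-12)

    def test_three_categories_direct_phi_arithmetic(self):
        mu, sd = 0.5, 0.8
        c = norm.ppf([1 / 3, 2 / 3])
        expected = np.array(
            [norm.cdf((c[0] - mu) / sd),
             norm.cdf((c[1] - mu) / sd) - norm.cdf((c[0] - mu) / sd),
             1 - norm.cdf((c[1] - mu) / sd)]
        )
        got = np.exp(il.bi_log_pmf(np.array([1, 2, 3]), mu, sd, 3))
        assert np.allclose(got, expected, atol=1e-12)
        assert np.isclose(got.sum(), 1.0, atol=1e-12)

    @pytest.mark.parametrize("mu,sd", [(0.0, 1.0), (2.5, 0.1), (-4.0, 0.05), (10.0, 0.5)])
    def test_probabilities_sum_to_one_n133(self, mu, sd):
        k = np.arange(1, 134)
        p = np.exp(il.bi_log_pmf(k, mu, sd, 133))
        assert np.isclose(p.sum(), 1.0, atol=1e-10)

    def test_top_category_probability_tends_to_one(self):
        p = np.exp(il.bi_log_pmf(5, 50.0, 1.0, 5))
        assert np.isclose(p, 1.0, atol=1e-12)

    def test_extreme_means_stay_finite_in_log_space(self):
        ll = il.bi_log_pmf(1, 8.0, 0.3, 133)
        assert np.isfinite(ll) and ll < -100

    def test_out_of_range_category_rejected(self):
        with pytest.raises(ValueError):
            il.bi_log_pmf(0, 0.0, 1.0, 5)


class TestBIObsLoglik:
    def test_sbi_with_zero_mean_unit_sd_gives_log_uniform(self, linkset, scale):
        spec = _spec("S-BI", linkset, scale)
        theta = {"theta1": 0.0, "sigma": 1.0}
        eta = {"baseline": np.zeros(3)}
        ll = il.bi_obs_loglik(spec, [0, 66, 132], np.zeros(3), None, theta, eta)
        assert np.allclose(ll, -np.log(scale.n_total_categories), atol=1e-12)

    def test_enumeration_normalized_pmf_toy_five_categories(self, linkset):
        # 5-score scale via a single 5-category item
        sc = il.ScaleDefinition(
            items=(il.ItemParams("q", 1.0, (-1.0, 0.0, 1.0, 2.0), (0, 1, 2, 3, 4)),)
        )
        st = il.StructuralSpec(has_slope=False, iiv=("baseline",))
        spec = il.model_spec("S-BI", st, n_categories=5, ts_min=0)
        theta = {"theta1": 0.4, "sigma": 0.7}
        eta = {"baseline": np.full(5, 0.1)}
        ll = il.bi_obs_loglik(spec, np.arange(5), np.zeros(5), None, theta, eta)
        p = np.exp(ll)
        # oracle: renormalized direct Phi differences
        cuts = _probit_cuts(5)
        direct = norm.cdf((cuts[1:] - 0.5) / 0.7) - norm.cdf((cuts[:-1] - 0.5) / 0.7)
        assert np.isclose(p.sum(), 1.0, atol=1e-12)
        assert np.allclose(p, direct / direct.sum(), atol=1e-12)

    def test_score_outside_range_rejected(self, linkset, scale):
        spec = _spec("S-BI", linkset, scale)
        with pytest.raises(ValueError, match="total score outside"):
            il.bi_obs_loglik(spec, [133], [0.0], None,
                             {"theta1": 0.0, "sigma": 1.0}, {"baseline": np.zeros(1)})

    def test_sdibi_equals_ibi_when_mean_link_is_identity(self):
        # engineered linkset with pn3 = identity on the z scale: the SDI-BI
        # prediction then maps to the same psi, so likelihoods coincide
        from numpy.polynomial import Chebyshev

        lk = il.LinkSet(
            pn1=Chebyshev.interpolate(lambda x: x, 1, domain=[-3, 3]),
            pn2=Chebyshev.interpolate(lambda x: 0 * x + 1.0, 1, domain=[-3, 3]),
            pn3=Chebyshev.interpolate(lambda x: x, 1, domain=[-3, 3]),
            pn4=Chebyshev.interpolate(lambda x: 0.2 + 0.01 * x**2, 2, domain=[-3, 3]),
            domain=(-3.0, 3.0),
        )
        st = il.StructuralSpec(has_slope=False, iiv=("baseline",))
        sdibi = il.model_spec("SDI-BI", st, linkset=lk, n_categories=9, ts_min=0)
        ibi = il.model_spec("I-BI", st, linkset=lk, n_categories=9, ts_min=0)
        y = np.array([2, 4, 7])
        eta = {"baseline": np.array([0.1, -0.2, 0.0])}
        ll_a = il.bi_obs_loglik(sdibi, y, np.zeros(3), None, {"theta1": 0.3}, eta)
        ll_b = il.bi_obs_loglik(ibi, y, np.zeros(3), None, {"theta1": 0.3}, eta)
        assert np.allclose(ll_a, ll_b, atol=1e-6)


class TestStructural:
    def test_truth_arithmetic_one_year(self):
        st = il.StructuralSpec(has_slope=True, has_medication=True,
                               iiv=("baseline",))
        theta = {"theta1": 0.654, "theta2": 0.449, "theta3": 0.0}
        val = il.structural_psi(st, [1.0], [0.0], theta, {"baseline": np.zeros(1)})
        assert np.isclose(val[0], 1.103)

    def test_medication_offset_contract(self):
        st = il.StructuralSpec(has_slope=True, has_medication=True, iiv=("baseline",))
        theta = {"theta1": 1.0, "theta2": 0.2, "theta3": 0.3}
        on = il.structural_psi(st, [2.0], [1.0], theta, {})
        off = il.structural_psi(st, [2.0], [0.0], theta, {})
        assert np.isclose(on[0] - off[0], -0.3)

    def test_additive_baseline_iiv_shift(self):
        st = il.StructuralSpec(has_slope=False, iiv=("baseline",))
        theta = {"theta1": 1.0}
        shifted = il.structural_psi(st, [0.0], None, theta,
                                    {"baseline": np.array([0.2])})
        assert np.isclose(shifted[0], 1.2)

    def test_missing_covariate_named(self):
        st = il.StructuralSpec(has_slope=False, has_medication=True,
                               iiv=("baseline",), covariate="MED")
        with pytest.raises(KeyError, match="MED"):
            il.structural_psi(st, [0.0], None,
                              {"theta1": 0.0, "theta3": 1.0}, {})


class TestModelSpecValidation:
    def test_psi_scale_requires_linkset(self):
        st = il.StructuralSpec(has_slope=False, iiv=("baseline",))
        with pytest.raises(ValueError, match="linkset"):
            il.model_spec("I-CV", st, linkset=None)

    def test_eight_families_constructible(self, linkset, scale):
        st = il.StructuralSpec(has_slope=False, iiv=("baseline",))
        for name in il.MODEL_NAMES:
            spec = il.model_spec(name, st, linkset=linkset,
                                 n_categories=scale.n_total_categories,
                                 ts_min=scale.min_total)
            assert spec.name == name
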