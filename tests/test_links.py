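"""Link functions: analytic moments, Z link, Chebyshev approximation."""

import numpy as np
import pytest

import irtlink as il
from conftest import enumerate_joint


class TestExpectedTS:
    def test_single_binary_item_at_threshold(self):
        sc = il.ScaleDefinition(items=(il.ItemParams("b", 1.0, (0.5,), (0, 1)),))
        assert np.isclose(il.expected_ts(sc, 0.5), 0.5)

    @pytest.mark.parametrize("psi", [-2.0, -0.3, 0.6, 1.9])
    def test_matches_joint_enumeration(self, toy_scale, psi):
        totals, probs = enumerate_joint(toy_scale)
        p = probs(psi)
        assert np.isclose(il.expected_ts(toy_scale, psi), float(p @ totals), atol=1e-10)

    def test_saturates_at_max_total(self, toy_scale):
        assert np.isclose(il.expected_ts(toy_scale, 60.0), toy_scale.max_total, atol=1e-9)
        assert np.isclose(il.expected_ts(toy_scale, -60.0), toy_scale.min_total, atol=1e-9)

    def test_nondecreasing_in_psi(self, scale):
        grid = np.linspace(*scale.psi_domain, 400)
        vals = il.expected_ts(scale, grid)
        assert np.all(np.diff(vals) > 0)


class TestTsSd:
    def test_degenerate_distribution_gives_zero_sd(self, toy_scale):
        assert il.ts_sd(toy_scale, -60.0) < 1e-6

    @pytest.mark.parametrize("psi", [-2.0, -0.3, 0.6, 1.9])
    def test_matches_joint_enumeration(self, toy_scale, psi):
        totals, probs = enumerate_joint(toy_scale)
        p = probs(psi)
        mean = float(p @ totals)
        sd = float(np.sqrt(p @ (totals - mean) ** 2))
        assert np.isclose(il.ts_sd(toy_scale, psi), sd, atol=1e-10)

    def test_single_binary_item_bernoulli_sd(self):
        sc = il.ScaleDefinition(items=(il.ItemParams("b", 2.0, (-0.3,), (0, 1)),))
        assert np.isclose(il.ts_sd(sc, -0.3), 0.5)

    def test_variance_additivity_vs_convolution(self, toy_scale):
        # catches the dimensionally inconsistent per-item-sum-with-total-mean
        # variance form: sd^2 must equal the variance of the exact
        # total-score distribution
        for psi in (-1.5, 0.0, 0.7, 2.5):
            pmf = il.ts_distribution(toy_scale, psi)
            k = np.arange(toy_scale.min_total, toy_scale.max_total + 1)
            mean = pmf @ k
            var = pmf @ (k - mean) ** 2
            assert np.isclose(il.ts_sd(toy_scale, psi) ** 2, var, atol=1e-8)

    def test_variance_additivity_on_larger_scale(self, scale):
        for psi in (-1.0, 1.0, 3.0):
            pmf = il.ts_distribution(scale, psi)
            k = np.arange(scale.min_total, scale.max_total + 1)
            mean = pmf @ k
            var = pmf @ (k - mean) ** 2
            assert np.isclose(il.ts_sd(scale, psi) ** 2, var, rtol=1e-8)


class TestTsDistribution:
    def test_two_fair_binary_items_binomial(self):
        sc = il.ScaleDefinition(
            items=(il.ItemParams("a", 1.0, (0.0,), (0, 1)),
                   il.ItemParams("b", 1.0, (0.0,), (0, 1)))
        )
        assert np.allclose(il.ts_distribution(sc, 0.0), [0.25, 0.5, 0.25])

    def test_matches_enumeration_aggregated_by_sum(self, toy_scale):
        totals, probs = enumerate_joint(toy_scale)
        p = probs(0.4)
        expected = np.bincount(totals, weights=p, minlength=toy_scale.max_total + 1)
        assert np.allclose(il.ts_distribution(toy_scale, 0.4), expected, atol=1e-12)

    def test_sums_to_one(self, scale):
        for psi in (-4.0, 0.654, 8.0):
            assert abs(il.ts_distribution(scale, psi).sum() - 1.0) < 1e-10


class TestZLink:
    def test_uniform_distribution_gives_zero_mean(self):
        # a scale whose TS distribution is uniform is symmetric on the
        # probit grid; checked through the representative-z convention
        from irtlink.links import _representative_z

        n = 7
        z = _representative_z(n)
        assert np.isclose(np.mean(z), 0.0, atol=1e-12)  # uniform weights
        assert np.all(np.diff(z) > 0)

    def test_degenerate_middle_category_of_odd_n(self):
        from irtlink.links import _representative_z

        n = 5
        z = _representative_z(n)
        assert np.isclose(z[n // 2], 0.0, atol=1e-12)

    def test_three_category_hand_enumeration(self):
        # P = (0.2, 0.5, 0.3) on a 3-category grid: cut points probit(1/3),
        # probit(2/3); z_hat = (tail mean, 0, tail mean); direct arithmetic
        from scipy.stats import norm

        from irtlink.links import _representative_z

        p = np.array([0.2, 0.5, 0.3])
        c = norm.ppf([1 / 3, 2 / 3])
        zhat = np.array(
            [-norm.pdf(c[0]) / norm.cdf(c[0]), 0.0,
             norm.pdf(c[1]) / norm.sf(c[1])]
        )
        mean = p @ zhat
        sd = np.sqrt(p @ (zhat - mean) ** 2)
        assert np.allclose(_representative_z(3), zhat)
        # and through the full z_link on a scale engineered to have 3 scores
        sc = il.ScaleDefinition(
            items=(il.ItemParams("t", 1.0, (-0.5, 0.5), (0, 1, 2)),)
        )
        mz, sz = il.z_link(sc, 0.0)
        pmf = il.ts_distribution(sc, 0.0)
        assert np.isclose(mz, pmf @ zhat)
        assert np.isclose(sz, np.sqrt(pmf @ (zhat - pmf @ zhat) ** 2))
        assert sd > 0  # sanity on the hand case

    def test_mean_z_nondecreasing(self, scale):
        vals = [il.z_link(scale, p)[0] for p in np.linspace(-4, 8, 40)]
        assert np.all(np.diff(vals) > -1e-9)


class TestChebyshevFit:
    def test_cubic_recovered_exactly(self):
        fn = lambda x: 0.3 * x**3 - x + 2
        poly, degree = il.fit_link_polynomial(fn, (-2, 2), tol=0.01)
        assert degree <= 3
        g = np.linspace(-2, 2, 100)
        assert np.max(np.abs(poly(g) - fn(g))) < 1e-10

    def test_degree_matches_brute_force_sweep(self):
        # independent oracle: try every degree, find the smallest meeting tol
        from numpy.polynomial import Chebyshev

        fn = np.abs
        tol = 0.05
        grid = np.linspace(-1, 1, 2001)
        oracle_degree = None
        for d in range(1, 61):
            p = Chebyshev.interpolate(fn, d, domain=[-1, 1])
            if np.max(np.abs(p(grid) - fn(grid))) <= tol:
                oracle_degree = d
                break
        _, degree = il.fit_link_polynomial(fn, (-1, 1), tol=tol)
        assert degree == oracle_degree

    def test_unmeetable_tolerance_raises_with_achieved_error(self):
        with pytest.raises(RuntimeError, match="deviation"):
            il.fit_link_polynomial(np.abs, (-1, 1), tol=1e-12, max_degree=5)


class TestLinkSet:
    def test_tolerances_met_on_shifted_grid(self, scale, linkset):
        # re-verify on an independent 2003-point grid at 2x tolerance
        g = np.linspace(*linkset.domain, 2003)
        assert np.max(np.abs(linkset.pn1(g) - il.expected_ts(scale, g))) <= 0.02
        assert np.max(np.abs(linkset.pn2(g) - il.ts_sd(scale, g))) <= 0.02
        mz = np.array([il.z_link(scale, p) for p in g[::7]])
        assert np.max(np.abs(linkset.pn3(g[::7]) - mz[:, 0])) <= 0.02
        assert np.max(np.abs(linkset.pn4(g[::7]) - mz[:, 1])) <= 0.01

    def test_pn1_strictly_increasing_pn3_nondecreasing(self, linkset):
        g = np.linspace(*linkset.domain, 2001)
        assert np.all(np.diff(linkset.pn1(g)) > 0)
        assert np.all(np.diff(linkset.pn3(g)) > -1e-9)

    def test_pn1_s_shaped_and_bounded(self, linkset, scale):
        g = np.linspace(*linkset.domain, 2001)
        v = linkset.pn1(g)
        assert v.min() > scale.min_total - 0.5
        assert v.max() < scale.max_total + 0.5
        # steeper in the middle than at the edges (S shape)
        dv = np.gradient(v, g)
        assert dv[1000] > 5 * min(dv[0], dv[-1])

    def test_sd_curve_has_interior_maximum(self, linkset):
        g = np.linspace(*linkset.domain, 2001)
        v = linkset.pn2(g)
        imax = np.argmax(v)
        assert 100 < imax < 1900
        assert v[imax] > 2 * min(v[0], v[-1])

    def test_sd_floor_clamp(self, linkset):
        # force evaluation below the floor by shifting the polynomial
        from numpy.polynomial import Chebyshev

        neg = Chebyshev([-1.0], domain=list(linkset.domain))
        assert il.eval_link(neg, 0.0, linkset.domain, floor=linkset.sd_floor) == linkset.sd_floor

    def test_out_of_domain_warns_but_evaluates(self, linkset, caplog):
        import logging

        from irtlink.links import _warned_domains

        _warned_domains.clear()  # the warning is once-per-process
        with caplog.at_level(logging.WARNING, logger="irtlink.links"):
            val = il.eval_link(linkset.pn1, linkset.domain[1] + 1.0, linkset.domain)
        assert np.isfinite(val)
        assert any("outside" in r.message for r in caplog.records)

    def test_serialization_round_trip(self, linkset, tmp_path):
        path = tmp_path / "links.txt"
        il.save_linkset(linkset, path)
        back = il.load_linkset(path)
        g = np.linspace(*linkset.domain, 101)
        for name in ("pn1", "pn2", "pn3", "pn4"):
            assert np.allclose(getattr(back, name)(g), getattr(linkset, name)(g), atol=1e-12)
        assert back.degrees == linkset.degrees
        assert back.tolerances == linkset.tolerances
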