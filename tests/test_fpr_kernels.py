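"""Pair-reaction probability kernels and event sampling."""

import math

import numpy as np
import pytest

from prd import fpr_kernels as fk
from prd import rate_theory as rt


class TestPReact3D:
    def test_zero_rate_and_far_separation(self):
        assert fk.p_react_3d(5.0, 0.1, 0.0, 1.0, 10.0) == 0.0
        assert fk.p_react_3d(1e6, 0.1, 100.0, 1.0, 10.0) < 1e-12

    def test_infinite_time_limit_is_ultimate_capture(self):
        p = fk.p_react_3d(1.5, 1e9, 100.0, 1.0, 10.0)
        assert p == pytest.approx(
            float(fk.p_ultimate_3d(1.5, 100.0, 1.0, 10.0)), rel=1e-4)

    def test_monotonicity(self):
        r0 = np.linspace(1.0, 6.0, 40)
        p = fk.p_react_3d(r0, 0.1, 100.0, 1.0, 10.0)
        assert np.all(np.diff(p) <= 0)
        for lo, hi in [(10.0, 50.0), (50.0, 200.0)]:
            assert np.all(fk.p_react_3d(r0, 0.1, hi, 1.0, 10.0)
                          >= fk.p_react_3d(r0, 0.1, lo, 1.0, 10.0))
        assert np.all(fk.p_react_3d(r0, 0.2, 100.0, 1.0, 10.0)
                      >= fk.p_react_3d(r0, 0.1, 100.0, 1.0, 10.0))

    def test_bounded_and_negligible_at_cutoff(self):
        """The cutoff radius is where a pair can no longer react in dt."""
        for sigma, D, dt, ka in [(2.0, 20.0, 0.1, 247.97),
                                 (1.0, 10.0, 0.1, 100.0),
                                 (0.73, 20.0, 0.1, 20.0)]:
            rcut = rt.rcut_for_rule(sigma, 3, D, dt)
            p = fk.p_react_3d(np.linspace(sigma, rcut, 50), dt, ka, sigma, D)
            assert np.all((p >= 0) & (p <= 1))
            assert p[-1] <= 1e-3

    def test_overlap_raises(self):
        with pytest.raises(fk.OverlapError):
            fk.p_react_3d(0.5, 0.1, 100.0, 1.0, 10.0)

    def test_vectorized_pair_diffusion(self):
        r0 = np.array([1.5, 1.5])
        D = np.array([10.0, 20.0])
        p = fk.p_react_3d(r0, 0.1, 100.0, 1.0, D)
        assert p[0] != p[1]
        assert p[0] == pytest.approx(
            float(fk.p_react_3d(1.5, 0.1, 100.0, 1.0, 10.0)))


class TestPReact2D:
    def test_zero_rate(self):
        assert np.all(fk.p_react_2d(np.array([2.0, 3.0]), 0.1, 0.0, 2.0, 4.0)
                      == 0.0)

    def test_monotone_decreasing_in_r0(self):
        r0 = np.linspace(2.0, 6.0, 60)
        p = fk.p_react_2d(r0, 0.1, 0.53, 2.0, 4.0)
        assert np.all(np.diff(p) <= 1e-15)

    def test_negligible_beyond_cutoff(self):
        rcut = rt.rcut_for_rule(2.0, 2, 4.0, 0.1)
        p = float(fk.p_react_2d(rcut, 0.1, 0.53, 2.0, 4.0))
        assert p <= 1e-3
        assert float(fk.p_react_2d(rcut + 5, 0.1, 0.53, 2.0, 4.0, rmax=rcut)) \
            == 0.0

    def test_grid_convergence(self):
        g1 = fk.GreensFunction2D(0.53, 4.0, 2.0, 0.1, rmax=7.0,
                                 n_grid=1200, n_sub=256)
        g2 = fk.GreensFunction2D(0.53, 4.0, 2.0, 0.1, rmax=7.0,
                                 n_grid=2400, n_sub=512)
        r = np.array([2.0, 2.3, 3.0, 4.0])
        assert np.allclose(g1(r), g2(r), rtol=1e-3, atol=1e-9)

    def test_against_brownian_dynamics_oracle(self):
        """Fine-step 2D BD with a local planar radiation boundary agrees
        with the tabulated Green's function within 3 SE."""
        ka2d, sigma, D, dt = 0.53, 2.0, 4.0, 0.1
        rng = np.random.default_rng(12)
        ntraj, sub = 60000, 300
        tau = dt / sub
        kappa = ka2d / (2 * math.pi * sigma)
        from scipy.special import erfc, erfcx
        y = kappa * math.sqrt(tau / D)
        for r0 in (2.05, 2.6):
            pos = np.zeros((ntraj, 2))
            pos[:, 0] = r0
            alive = np.ones(ntraj, bool)
            reacted = 0
            for _ in range(sub):
                idx = np.nonzero(alive)[0]
                r = np.hypot(pos[idx, 0], pos[idx, 1])
                x = np.maximum(r - sigma, 0) / math.sqrt(4 * D * tau)
                p = erfc(x) - erfcx(x + y) * np.exp(-x * x)
                hit = rng.random(idx.size) < p
                reacted += hit.sum()
                alive[idx[hit]] = False
                idx = idx[~hit]
                pos[idx] += rng.normal(0, math.sqrt(2 * D * tau),
                                       (idx.size, 2))
                r = np.hypot(pos[idx, 0], pos[idx, 1])
                inside = r < sigma
                ii = idx[inside]
                pos[ii] *= ((2 * sigma - r[inside]) / r[inside])[:, None]
            est = reacted / ntraj
            se = math.sqrt(est * (1 - est) / ntraj)
            gf = float(fk.p_react_2d(r0, dt, ka2d, sigma, D))
            assert abs(est - gf) < 3 * se + 0.02 * gf


class TestImplicitSurface:
    def test_zero_density_and_far_height(self):
        assert np.all(fk.p_bind_implicit_surface(
            np.array([2.0]), 0.1, 250.0, 1.0, 0.0, 10.0) == 0.0)
        p_far = fk.p_bind_implicit_surface(
            np.array([50.0]), 0.1, 250.0, 1.0, 2.5e-4, 10.0)
        assert float(p_far[0]) < 1e-6

    def test_bounded_and_monotone_in_height(self):
        z = np.linspace(1.0, 12.0, 50)
        p = fk.p_bind_implicit_surface(z, 0.1, 250.0, 1.0, 2.5e-4, 10.0)
        assert np.all((p >= 0) & (p <= 1))
        assert np.all(np.diff(p) <= 1e-15)

    def test_proportional_to_density_at_small_p(self):
        p1 = fk.p_bind_implicit_surface(np.array([3.0]), 0.1, 250.0, 1.0,
                                        1e-6, 10.0)
        p2 = fk.p_bind_implicit_surface(np.array([3.0]), 0.1, 250.0, 1.0,
                                        2e-6, 10.0)
        assert float(p2[0]) == pytest.approx(2 * float(p1[0]), rel=1e-3)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            fk.p_bind_implicit_surface(np.array([2.0]), 0.1, 250.0, 1.0,
                                       -1e-4, 10.0)


class TestEventSampling:
    def test_first_order_trivials(self):
        rng = np.random.default_rng(0)
        assert fk.sample_first_order(100, 0.0, 0.1, rng) == 0
        assert fk.sample_first_order(0, 0.5, 0.1, rng) == 0

    def test_first_order_moments(self):
        """N=10000, k*dt=1e-3: mean event count over 1000 draws is 10."""
        rng = np.random.default_rng(42)
        draws = [fk.sample_first_order(10000, 1e-2, 0.1, rng)
                 for _ in range(1000)]
        mean = np.mean(draws)
        se = np.std(draws, ddof=1) / math.sqrt(len(draws))
        assert abs(mean - 10.0) < 3 * se

    def test_first_order_guards(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            fk.sample_first_order(10, 20.0, 0.1, rng)
        with pytest.warns(UserWarning):
            fk.sample_first_order(10, 2.0, 0.1, rng)

    def test_zeroth_order_moments(self):
        rng = np.random.default_rng(7)
        assert fk.sample_zeroth_order(0.0, 0.1, rng) == 0
        draws = [fk.sample_zeroth_order(50.0, 0.1, rng) for _ in range(1000)]
        mean = np.mean(draws)
        se = np.std(draws, ddof=1) / math.sqrt(len(draws))
        assert abs(mean - 5.0) < 3 * se
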