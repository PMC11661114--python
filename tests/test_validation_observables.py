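"""Reference solutions, estimators, scaling metrics, benchmark builders."""

import numpy as np
import pytest

from prd import validation_observables as vo
from prd.serial_engine import Engine


class TestAnalyticBimolecular:
    def test_initial_condition_and_irreversible_limit(self):
        out = vo.analytic_reversible_bimolecular(2.0, 1.0, 1e-4, 1e-5,
                                                 np.array([0.0]))
        assert out["AB"][0] == 0.0
        out = vo.analytic_reversible_bimolecular(2.0, 1.0, 1e-4, 0.0,
                                                 np.array([1e9]))
        assert out["AB"][-1] == pytest.approx(1.0, rel=1e-6)

    def test_matches_numerical_integration(self):
        from scipy.integrate import solve_ivp
        kon, koff, A0, B0 = 1e-4, 1e-5, 2.0, 1.3
        t = np.linspace(0.0, 30000.0, 25)
        ana = vo.analytic_reversible_bimolecular(A0, B0, kon, koff, t)
        sol = solve_ivp(lambda _t, y: [kon * (A0 - y[0]) * (B0 - y[0])
                                       - koff * y[0]],
                        (0, t[-1]), [0.0], t_eval=t, rtol=1e-10, atol=1e-14)
        np.testing.assert_allclose(ana["AB"], sol.y[0], rtol=1e-7, atol=1e-10)

    def test_equilibrium_deff_printed_value(self):
        """[A]eq DA + [AB]eq Ddimer weighted mean = 7.47 um^2/s for the
        bimolecular benchmark concentrations."""
        deff = vo.equilibrium_deff(0.2076, 0.2076, 100.0, 10.0, 10.0, 5.0)
        assert deff == pytest.approx(7.47, abs=0.005)


class TestAssemblyODE:
    def test_monomer_conservation(self):
        t = np.linspace(0, 0.01, 10)
        out = vo.assembly_ode(3, 10.86, 901.6, 1.2e7, 200.0, t)
        total = sum(k * out[f"C{k}"] for k in (1, 2, 3)) + 3 * out["ring"]
        np.testing.assert_allclose(total, 200.0, rtol=1e-7)

    def test_equilibrium_matches_ring_ladder(self):
        """Cross-method consistency: the ODE steady state equals the
        iterative ring-equilibrium solution."""
        kon, koff, kclose, ctot = 11.16, 926.3, 1.2044e7, 200.0
        t = np.linspace(0, 1.0, 6)
        ode = vo.assembly_ode(6, kon, koff, kclose, ctot, t)
        eq = vo.ring_equilibrium(kon / koff, kclose / koff, 6, ctot)
        for k in eq:
            assert ode[k][-1] == pytest.approx(eq[k], rel=1e-6, abs=1e-12)

    def test_failure_reported(self):
        with pytest.raises(ValueError):
            vo.ring_equilibrium(1.0, 1.0, 6, -1.0)


class TestRingEquilibrium:
    def test_weak_binding_all_monomer(self):
        eq = vo.ring_equilibrium(1e-12, 1e-6, 6, 100.0)
        assert eq["C1"] == pytest.approx(100.0, rel=1e-6)
        assert eq["ring"] < 1e-6

    def test_strong_binding_all_rings(self):
        eq = vo.ring_equilibrium(1e4, 1e9, 6, 100.0)
        assert 6 * eq["ring"] == pytest.approx(100.0, rel=1e-3)

    def test_monomer_conservation(self):
        eq = vo.ring_equilibrium(0.012, 1.3e4, 6, 200.0)
        total = sum(k * eq[f"C{k}"] for k in range(1, 7)) + 6 * eq["ring"]
        assert total == pytest.approx(200.0, rel=1e-10)


class TestMSD:
    def test_recovers_known_diffusion(self):
        rng = np.random.default_rng(3)
        D, dt = 10.0, 1.0
        x = np.cumsum(rng.normal(0, np.sqrt(2 * D * dt), (300, 200)), axis=0)
        out = vo.msd_estimator(x, 0, [1, 2, 4])
        assert abs(out["D"] - D) < 3 * out["se_D"]

    def test_immobile_is_zero(self):
        x = np.ones((50, 10))
        out = vo.msd_estimator(x, 0, [1])
        assert out["msd"][0] == 0.0

    def test_insufficient_samples_error(self):
        with pytest.raises(ValueError):
            vo.msd_estimator(np.zeros((4, 3)), 0, [2])


class TestScalingMetrics:
    def test_linear_scaling(self):
        rep = vo.scaling_metrics(strong={1: 100.0, 2: 50.0, 4: 25.0},
                                 weak={1: 10.0, 4: 10.0})
        assert rep.speedup[4] == pytest.approx(4.0)
        assert rep.e_strong[2] == pytest.approx(1.0)
        assert rep.e_weak[4] == pytest.approx(1.0)

    def test_printed_arithmetic(self):
        rep = vo.scaling_metrics(strong={1: 100.0, 4: 40.0})
        assert rep.speedup[4] == pytest.approx(2.5)
        assert rep.e_strong[4] == pytest.approx(0.625)

    def test_requires_baseline(self):
        with pytest.raises(ValueError):
            vo.scaling_metrics(strong={2: 10.0})


class TestAdsorptionReference:
    def test_equilibrium_matches_mass_action(self):
        """Long-time bound density satisfies ka rho_free c = kb b."""
        out = vo.adsorption_1d(Lz=200.0, Dz=10.0, ka=100.0, kb=1e-4,
                               c0_vol=1e-6, rho_l0=1e-4,
                               t_eval=np.linspace(0, 4e5, 8))
        b = out["bound"][-1]
        c = out["c_mean"][-1]
        lhs = 100.0 * (1e-4 - b) * c
        assert lhs == pytest.approx(1e-4 * b, rel=0.02)


class Test2DKinetics:
    def test_membrane_bimolecular_matches_wellmixed(self):
        """C+D<->C.D on the membrane follows area mass action with the
        steady-state kon2D and the derived koff within 3 SEM (pooled)."""
        from prd import rate_theory as rt
        from prd.validation_observables import \
            analytic_reversible_bimolecular
        box = np.array([3200.0, 500.0, 100.0])
        trajs = []
        for seed in (401, 402, 403):
            m = vo.build_benchmark("bimol2d", scale=0.04, seed=seed, dt=1.0)
            m.config.box = box
            eng = Engine(m)
            trajs.append(eng.run(5000, 500))
        m = vo.build_benchmark("bimol2d", scale=0.04)
        n0 = m.config.copies["C"]
        S = box[0] * box[1]
        rule = m.rules[0]
        b = rt.b_rho_2d(S, n0, rule.sigma)
        kon2d = rt.kon2d_steady_state(rule.ka_intrinsic, rule.D_pair,
                                      rule.sigma, b)
        koff = rule.kb_intrinsic * kon2d / rule.ka_intrinsic
        rho0 = n0 / S
        t_us = np.array([r["time"] for r in trajs[0]])
        ana = analytic_reversible_bimolecular(rho0, rho0, kon2d, koff, t_us)
        cd = np.array([[r["counts"].get("C.D", 0) / S for r in tr]
                       for tr in trajs])
        mean = cd.mean(axis=0)
        sem = cd.std(axis=0, ddof=1) / np.sqrt(3)
        pooled = np.sqrt(np.mean(sem[1:] ** 2))
        z = (mean - ana["AB"]) / max(pooled, 1e-18)
        assert np.abs(z).max() < 3.0


class TestImplicitMembrane:
    def test_implicit_matches_explicit_lipids(self):
        """Binding kinetics to the implicit lipid field match an explicit
        2D-particle membrane with identical rates within 3 SEM."""
        box = np.array([800.0, 400.0, 100.0])

        def run(name, seed):
            m = vo.build_benchmark(name, scale=0.02, seed=seed, dt=0.25)
            m.config.box = box.copy()
            m.config.copies = {k: 200 for k in m.config.copies}
            m.config.implicit_lipid_copies = 200
            eng = Engine(m)
            return eng.run(3000, 300)

        imp = [run("implicit2d", s) for s in (11, 12, 13)]
        exp = [run("bimol3d2d", s) for s in (11, 12, 13)]

        def bound(recs, tag):
            return np.array([[sum(v for k, v in r["counts"].items()
                                  if tag in k) for r in tr]
                             for tr in recs], float) / 200

        bi = bound(imp, "@m")
        be = bound(exp, "E.F")
        mi, me = bi.mean(axis=0), be.mean(axis=0)
        pool = np.sqrt(np.mean((bi.std(axis=0, ddof=1) / np.sqrt(3))[1:] ** 2)
                       + np.mean((be.std(axis=0, ddof=1)
                                  / np.sqrt(3))[1:] ** 2))
        z = (mi - me) / max(pool, 1e-12)
        assert np.abs(z).max() < 3.0
        # lipid bookkeeping: the free pool shrank by the bound count
        assert mi[-1] > 0.1


class TestBenchmarkBuilders:
    @pytest.mark.parametrize("name", vo.BENCHMARKS)
    def test_builds_and_validates(self, name):
        model = vo.build_benchmark(name, scale=0.02 if name != "lattice"
                                   else 0.06)
        eng = Engine(model)
        rep = eng.validate_report()
        assert rep["dt_max_system"] > 0 or not eng.order2

    def test_bimol3d_table_row(self):
        from prd._units import kon3d_to_display, rate1_to_display
        m = vo.build_benchmark("bimol3d")
        assert m.config.copies == {"A": 10000, "B": 10000}
        np.testing.assert_allclose(m.types["A"].Dt, [10, 10, 10])
        r = m.rules[0]
        assert kon3d_to_display(r.kon_macro) == pytest.approx(100.0)
        assert rate1_to_display(r.koff_macro) == pytest.approx(10.0)

    def test_trimer_small_table_row(self):
        from prd._units import kon3d_to_display, rate1_to_display
        m = vo.build_benchmark("trimer-small")
        np.testing.assert_allclose(m.config.box, [5000, 100, 100])
        assert m.config.copies["A"] == 6022
        r = m.rules[0]
        assert kon3d_to_display(r.kon_macro) == pytest.approx(10.86)
        assert rate1_to_display(r.koff_macro) == pytest.approx(901.6)
        assert r.sigma == 0.73

    def test_lattice_rules(self):
        from prd._units import kon3d_to_display, rate1_to_display
        m = vo.build_benchmark("lattice", scale=0.05)
        byname = {r.name: r for r in m.rules}
        r = byname["ap_lipid"]
        assert kon3d_to_display(r.kon_macro) == pytest.approx(3.22)
        assert rate1_to_display(r.koff_macro) == pytest.approx(0.97)
        assert (r.sigma, r.h) == (1.0, 2.0)
        assert byname["tt_coop"].dG_coop == pytest.approx(2.3)
        assert byname["tt_coop"].reactants[0].context == [("ap", "bound")]

    def test_scale_preserves_concentration(self):
        from prd._units import copies_to_uM
        full = vo.build_benchmark("bimol3d", scale=1.0)
        small = vo.build_benchmark("bimol3d", scale=0.05)
        cf = copies_to_uM(full.config.copies["A"], full.config.volume)
        cs = copies_to_uM(small.config.copies["A"], small.config.volume)
        assert cs == pytest.approx(cf, rel=1e-3)

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            vo.build_benchmark("nope")

    def test_ring_state_builder(self):
        model = vo.build_benchmark("hexamer-small", scale=0.05, seed=1)
        st = vo.build_ring_state(model, {("chain", 2): 3, ("ring", 6): 2},
                                 seed=4)
        eng = Engine(model, state=st)
        counts = eng.count_species()
        assert counts.get("A2", 0) == 3
        assert counts.get("A6r", 0) == 2
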