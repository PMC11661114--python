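"""Rigid-body state: complex diffusion, propagation, bond geometry."""

import math

import numpy as np
import pytest

from prd.rigid_body import State, complex_diffusion
from prd.serial_engine import Engine
from tests.conftest import make_ab_model, make_ring_model


class TestComplexDiffusion:
    def test_single_molecule_keeps_own_constants(self):
        Dt, Drot = complex_diffusion(np.array([[10.0, 10.0, 10.0]]),
                                     np.array([0.1]))
        np.testing.assert_allclose(Dt, [10, 10, 10])
        assert Drot == 0.1

    def test_dimer_halves(self):
        """Two identical members diffuse at D/2 (friction additivity)."""
        Dt, Drot = complex_diffusion(np.full((2, 3), 10.0), np.full(2, 0.1))
        np.testing.assert_allclose(Dt, [5, 5, 5])
        assert Drot == pytest.approx(0.05)

    @pytest.mark.parametrize("n", [1, 2, 3, 6, 10])
    def test_n_identical_members_give_D_over_n(self, n):
        Dt, _ = complex_diffusion(np.full((n, 3), 12.0), np.full(n, 0.3))
        np.testing.assert_allclose(Dt, 12.0 / n, rtol=1e-12)

    def test_membrane_member_pins_z(self):
        Dt, _ = complex_diffusion(np.array([[10.0, 10, 10], [2.0, 2, 0]]),
                                  np.array([0.1, 0.1]))
        assert Dt[2] == 0.0
        assert Dt[0] == pytest.approx(1 / (1 / 10 + 1 / 2))

    def test_fully_anchored_member_is_valid(self):
        Dt, Drot = complex_diffusion(np.array([[10.0, 10, 10], [0.0, 0, 0]]),
                                     np.array([0.1, 0.0]))
        np.testing.assert_allclose(Dt, 0.0)
        assert Drot == 0.0


class TestPropagation:
    def test_zero_diffusion_is_identity(self):
        model = make_ab_model()
        for t in model.types.values():
            t.Dt = np.zeros(3)
        eng = Engine(model)
        before = eng.state.com[eng.state.live_rows()].copy()
        eng.run(5, 5)
        np.testing.assert_array_equal(
            eng.state.com[eng.state.live_rows()], before)

    def test_msd_matches_einstein_relation(self):
        """Ensemble x-MSD over one step equals 2 D dt within 3 SE."""
        model = make_ab_model(box=(4000, 4000, 4000), copies=400, dt=1.0,
                              kon=0.0, koff=0.0)
        model.rules = []
        eng = Engine(model)
        xs = [eng.state.com[eng.state.live_rows(), 0].copy()]
        for _ in range(60):
            eng.step()
            xs.append(eng.state.com[eng.state.live_rows(), 0].copy())
        disp = np.diff(np.array(xs), axis=0).ravel()
        msd = (disp ** 2).mean()
        se = (disp ** 2).std(ddof=1) / math.sqrt(disp.size)
        assert abs(msd - 2 * 10.0 * 1.0) < 3 * se

    def test_rigidity_preserved_under_propagation(self):
        """Intra-complex site distances constant to 1e-9 nm over many steps."""
        model = make_ring_model(copies=30, box=(200, 200, 200))
        eng = Engine(model)
        st = eng.state
        sp = st.site_positions().copy()
        eng._execute_association(0, 0, 1, 1, model.rules[0],
                                 __import__("prd.partition", fromlist=["PairCandidates"]).PairCandidates.empty(model.rules),
                                 sp)
        st.invalidate_sites()
        rows = st.complexes[int(st.complex_id[0])].rows
        def dists():
            s = st.site_positions(rows)
            pts = np.concatenate([st.com[rows], s.reshape(-1, 3)])
            return np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d0 = dists()
        for _ in range(50):
            eng.step()
        np.testing.assert_allclose(dists(), d0, atol=1e-9)

    def test_reflection_keeps_molecules_in_box(self):
        model = make_ab_model(box=(50, 50, 50), copies=60, dt=5.0)
        model.rules = []
        eng = Engine(model)
        for _ in range(30):
            eng.step()
            rows = eng.state.live_rows()
            assert np.all(eng.state.com[rows] >= 0)
            assert np.all(eng.state.com[rows] <= eng.state.model.config.box)

    def test_mirror_fold(self):
        """A point stepping to z = -eps reflects to z = +eps."""
        model = make_ab_model()
        eng = Engine(model)
        com = np.array([[10.0, 10.0, 1.0]])
        dx = np.array([[0.0, 0.0, -3.0]])
        out = eng._fold(com, dx)
        assert (com + out)[0, 2] == pytest.approx(2.0)

    def test_2d_species_stay_in_plane(self):
        from prd.validation_observables import build_benchmark
        model = build_benchmark("bimol2d", scale=0.01)
        eng = Engine(model)
        eng.run(20, 20)
        rows = eng.state.live_rows()
        assert np.all(eng.state.com[rows, 2] == 0.0)


class TestAssociationGeometry:
    def _chain(self, model, n):
        st = State(model, n + 2)
        for i in range(n):
            st.add_molecule(0, [10 + 2.8 * i, 10, 10])
        eng = Engine(model, state=st)
        from prd.partition import PairCandidates
        empty = PairCandidates.empty(model.rules)
        sp = st.site_positions().copy()
        for i in range(n - 1):
            assert eng._execute_association(i, 0, i + 1, 1, model.rules[0],
                                            empty, sp)
            st.invalidate_sites()
        return eng, st

    def test_bond_placed_at_sigma(self):
        model = make_ring_model()
        eng, st = self._chain(model, 2)
        sp = st.site_positions(np.array([0, 1]))
        assert np.linalg.norm(sp[0, 0] - sp[1, 1]) == pytest.approx(
            model.rules[0].sigma, abs=1e-9)

    def test_trimer_geometry_closes_equilateral_ring(self):
        """Two 60-degree associations leave the free ends exactly at sigma
        and the centers on an equilateral triangle of side 2*arm + sigma."""
        model = make_ring_model()
        eng, st = self._chain(model, 3)
        sp = st.site_positions(np.array([0, 1, 2]))
        sigma = model.rules[0].sigma
        assert np.linalg.norm(sp[2, 0] - sp[0, 1]) == pytest.approx(
            sigma, abs=1e-9)
        side = 2 * 1.0 + sigma
        coms = st.com[:3]
        for i in range(3):
            assert np.linalg.norm(coms[i] - coms[(i + 1) % 3]) \
                == pytest.approx(side, abs=1e-9)

    def test_loop_closure_candidates(self):
        model = make_ring_model()
        eng, st = self._chain(model, 3)
        cid = int(st.complex_id[0])
        cands = st.loop_closure_candidates(cid, model.rules)
        assert len(cands) == 1
        ra, sa, rb, sb, rule = cands[0]
        st.bind(ra, sa, rb, sb, rule)
        rows = st.complexes[int(st.complex_id[0])].rows
        assert int(np.sum(st.bound_gid[rows] >= 0)) // 2 == 3
        # dimers have no closure candidates
        eng2, st2 = self._chain(make_ring_model(), 2)
        assert st2.loop_closure_candidates(int(st2.complex_id[0]),
                                           model.rules) == []

    def test_hexamer_geometry_closes(self):
        model = make_ring_model(interior_deg=120.0, sigma=1.0)
        eng, st = self._chain(model, 6)
        cid = int(st.complex_id[0])
        cands = st.loop_closure_candidates(cid, model.rules)
        assert len(cands) == 1

    def test_steric_overlap_rejects_association(self):
        """Binding that would place a partner on top of a third reactive
        molecule is rejected and the state reverts."""
        model = make_ab_model(box=(200, 200, 200))
        st = State(model, 4)
        st.add_molecule(0, [50.0, 50, 50])        # A1
        st.add_molecule(1, [56.0, 50, 50])        # B, will be placed at x=52
        st.add_molecule(0, [53.0, 50.0, 50.0])    # A2: reactive partner of B
        eng = Engine(model, state=st)
        rows = st.live_rows()
        eng.grid.assign(st.com[rows], rows)
        from prd import partition
        cands = partition.pair_candidates(st, eng.grid, model.rules,
                                          eng.rcut_sys, rows)
        sp = st.site_positions().copy()
        before = st.com[:3].copy()
        ok = eng._execute_association(0, 0, 1, 0, model.rules[0], cands, sp)
        assert not ok
        np.testing.assert_array_equal(st.com[:3], before)
        assert np.all(st.bound_gid[rows] == -1)


class TestDissociation:
    def test_dimer_splits_and_recovers_monomer_diffusion(self):
        model = make_ring_model()
        st = State(model, 4)
        st.add_molecule(0, [10.0, 10, 10])
        st.add_molecule(0, [12.8, 10, 10])
        eng = Engine(model, state=st)
        from prd.partition import PairCandidates
        sp = st.site_positions().copy()
        eng._execute_association(0, 0, 1, 1, model.rules[0],
                                 PairCandidates.empty(model.rules), sp)
        assert st.mol_comp_Dt[0][0] == pytest.approx(5.0)
        gids = set(st.gid[st.live_rows()])
        st.unbind(0, 0)
        assert st.mol_comp_Dt[0][0] == pytest.approx(10.0)
        assert len(st.complexes) == 2
        # separation slightly beyond sigma, global ids unchanged
        sp = st.site_positions(np.array([0, 1]))
        assert np.linalg.norm(sp[0, 0] - sp[1, 1]) == pytest.approx(
            model.rules[0].sigma + 1e-3, abs=1e-9)
        assert set(st.gid[st.live_rows()]) == gids

    def test_ring_bond_removal_keeps_one_complex(self):
        model = make_ring_model()
        st = State(model, 4)
        for i in range(3):
            st.add_molecule(0, [10 + 2.8 * i, 10, 10])
        eng = Engine(model, state=st)
        from prd.partition import PairCandidates
        empty = PairCandidates.empty(model.rules)
        sp = st.site_positions().copy()
        eng._execute_association(0, 0, 1, 1, model.rules[0], empty, sp)
        st.invalidate_sites()
        eng._execute_association(1, 0, 2, 1, model.rules[0], empty, sp)
        (ra, sa, rb, sb, rule), = st.loop_closure_candidates(
            int(st.complex_id[0]), model.rules)
        st.bind(ra, sa, rb, sb, rule)
        st.unbind(0, 0)
        assert len(st.complexes) == 1
        rows = st.complexes[int(st.complex_id[0])].rows
        assert len(rows) == 3
        assert int(np.sum(st.bound_gid[rows] >= 0)) // 2 == 2
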