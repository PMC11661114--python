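"""Domain decomposition, serialization, transports, consistency."""

import numpy as np
import pytest

from prd import parallel_engine as pe
from prd.serial_engine import Engine
from tests.conftest import make_ab_model, make_ring_model


class TestDecompose:
    def test_single_rank_covers_box(self):
        lay = pe.DomainLayout.decompose([2000, 300, 300], 1, 35.0, 57)
        assert lay.interval(0)[0] == 0.0
        assert lay.interval(0)[1] == pytest.approx(2000.0)

    def test_equal_intervals(self):
        lay = pe.DomainLayout.decompose([2000, 300, 300], 4, 35.0, 56)
        widths = [lay.interval(r)[1] - lay.interval(r)[0] for r in range(4)]
        assert sum(widths) == pytest.approx(2000.0)
        assert max(widths) - min(widths) <= lay.cell_x + 1e-9

    def test_too_many_ranks_rejected(self):
        with pytest.raises(pe.ConfigurationError):
            pe.DomainLayout.decompose([200, 100, 100], 4, 40.0, 5)

    def test_owner_of_x(self):
        lay = pe.DomainLayout.decompose([2000, 300, 300], 4, 35.0, 56)
        x = np.array([10.0, 600.0, 1100.0, 1900.0])
        owners = lay.owner_of_x(x)
        assert list(owners) == [0, 1, 2, 3]


class TestSerialization:
    def _state_with_bonds(self):
        model = make_ring_model(copies=80, box=(300, 100, 100))
        eng = Engine(model)
        eng.run(100, 100)
        return model, eng.state

    def test_round_trip_field_identical(self):
        from prd.rigid_body import State
        model, st = self._state_with_bonds()
        rows = st.live_rows()
        batch = pe.serialize_batch(st, rows)
        st2 = State(model, capacity=len(rows))
        pe.deserialize_batch(st2, batch)
        rows2 = st2.live_rows()
        order = np.argsort(st.gid[rows])
        order2 = np.argsort(st2.gid[rows2])
        np.testing.assert_array_equal(st.gid[rows][order],
                                      st2.gid[rows2][order2])
        # bit-exact coordinate and bond transfer
        np.testing.assert_array_equal(st.com[rows][order],
                                      st2.com[rows2][order2])
        np.testing.assert_array_equal(st.quat[rows][order],
                                      st2.quat[rows2][order2])
        np.testing.assert_array_equal(st.bound_gid[rows][order],
                                      st2.bound_gid[rows2][order2])
        assert set(st2.complexes) == set(st.complexes)
        for cid in st.complexes:
            assert sorted(st.gid[st.complexes[cid].rows]) \
                == sorted(st2.gid[st2.complexes[cid].rows])

    def test_merge_is_idempotent(self):
        from prd.rigid_body import State
        model, st = self._state_with_bonds()
        batch = pe.serialize_batch(st, st.live_rows())
        st2 = State(model, capacity=st.n)
        info1 = pe.deserialize_batch(st2, batch)
        com_after = st2.com[st2.live_rows()].copy()
        info2 = pe.deserialize_batch(st2, batch)
        assert len(info1["inserted"]) == len(st.live_rows())
        assert len(info2["inserted"]) == 0
        np.testing.assert_array_equal(st2.com[st2.live_rows()], com_after)

    def test_empty_batch(self):
        from prd.rigid_body import State
        model, st = self._state_with_bonds()
        batch = pe.serialize_batch(st, np.zeros(0, dtype=np.int64))
        st2 = State(model, capacity=4)
        info = pe.deserialize_batch(st2, batch)
        assert info["inserted"] == [] and info["updated"] == []

    def test_schema_mismatch_rejected(self):
        from prd.rigid_body import State
        model, st = self._state_with_bonds()
        batch = pe.serialize_batch(st, st.live_rows())
        bad = pe.SerializedBatch(b"XXXX" + batch.payload[4:])
        st2 = State(model, capacity=4)
        with pytest.raises(pe.InvariantViolation):
            pe.deserialize_batch(st2, bad)


class TestTransport:
    def test_loopback_contract(self):
        tp = pe.LoopbackTransport()
        b = pe.SerializedBatch(b"payload")
        tp.post_send(0, 1, b)
        h = tp.post_receive(0, 1)
        (got,) = tp.wait([h])
        assert got.payload == b"payload"
        with pytest.raises(pe.InvariantViolation):
            tp.wait([tp.post_receive(1, 0)])

    def test_mpi_transport_requires_mpi4py(self):
        try:
            import mpi4py  # noqa: F401
            pytest.skip("mpi4py available")
        except ImportError:
            with pytest.raises(ImportError):
                pe.MPITransport()


class TestParallelStep:
    def test_zero_rate_zero_D_step_is_identity(self):
        model = make_ab_model(copies=60, box=(2000, 300, 300))
        model.rules = []
        for t in model.types.values():
            t.Dt = np.zeros(3)
        sim = pe.ParallelSimulation(model, 2)
        before = {int(e.rank): e.state.com[e.state.live_rows()].copy()
                  for e in sim.ranks}
        sim.step()
        for e in sim.ranks:
            np.testing.assert_array_equal(
                e.state.com[e.state.live_rows()], before[e.rank])

    def test_rank_invariance_quick(self):
        serial = Engine(make_ab_model(seed=3))
        rs = serial.run(60, 10)
        sim = pe.ParallelSimulation(make_ab_model(seed=3), 2)
        rp = sim.run(60, 10)
        assert rs == rp

    def test_migration_changes_owner(self):
        """A molecule diffusing across the boundary is owned by the right
        rank afterwards and leaves the left owned set."""
        model = make_ab_model(copies=40, box=(2000, 300, 300), dt=1.0)
        model.rules = []
        sim = pe.ParallelSimulation(model, 2)
        lay = sim.layout
        xb = lay.interval(0)[1]
        # plant a molecule just left of the boundary on rank 0
        e0 = sim.ranks[0]
        row = e0.state.live_rows()[0]
        gid = int(e0.state.gid[row])
        for eng in sim.ranks:
            r = eng.state.row_of_gid.get(gid)
            if r is not None:
                eng.state.com[r] = [xb - 0.5, 150.0, 150.0]
                eng.state.invalidate_sites()
        sim._migrate()
        # walk until it crosses
        for _ in range(200):
            sim.step()
            r = sim.ranks[0].state.row_of_gid.get(gid)
            if r is None or sim.ranks[0].state.com[r, 0] >= xb:
                break
        r1 = sim.ranks[1].state.row_of_gid.get(gid)
        assert r1 is not None
        assert sim.ranks[1].owns_gid(gid)
        assert not sim.ranks[0].owns_gid(gid)
        assert not pe.consistency_audit(sim.ranks)

    def test_audit_flags_cloned_gid(self):
        model = make_ab_model(copies=40, box=(2000, 300, 300))
        sim = pe.ParallelSimulation(model, 2)
        sim.run(3, 3)
        assert pe.consistency_audit(sim.ranks) == []
        # clone a foreign gid into rank 1's owned region
        e1 = sim.ranks[1]
        e0 = sim.ranks[0]
        row = e0.owned_rows()[0]
        gid = int(e0.state.gid[row])
        mid = 0.5 * (e1.x_lo + e1.x_hi)
        e1.state.add_molecule(0, [mid, 10.0, 10.0], gid=gid)
        violations = pe.consistency_audit(sim.ranks)
        assert violations
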