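"""Spatial domain decomposition along x with edge/ghost regions.

The box is divided into per-rank x-intervals aligned to sub-volume columns.
Each rank owns the molecules whose center of mass lies in its interval and
additionally holds *ghost* copies: everything within the two boundary
sub-volume columns of each neighbor, complexes duplicated in their
entirety whenever any member enters that window, and a further shell of
reaction partners around duplicated complexes (the visibility a rank needs
to make every reaction decision that can touch an owned molecule).

Because every stochastic decision is counter-keyed by step and global ids
(:mod:`prd._rng`) and every floating-point reduction runs in gid order,
each rank independently computes *identical* updates for the molecules it
shares with its neighbors.  The staggered six-step protocol then reduces to
data motion: (1) zeroth/first-order events over the full region, (2)
pairwise probabilities for owned + ghost molecules, (3) reactions and
left-half diffusion, (4) serialize and send the left edge/ghost records to
the left neighbor and merge the incoming ones, (5) right-half reactions'
remainder and diffusion, (6) send right and merge, followed by migration
cleanup (molecules whose center of mass crossed the boundary change owner;
copies that left the edge/ghost window are removed).  Rank-count
invariance -- bitwise identical time series for any number of ranks on the
loopback transport -- is asserted in the test suite; it is a strictly
stronger property than the statistical serial-vs-parallel equivalence the
method requires.

The transport is an abstract contract; the in-process loopback backend is
deterministic and used by all tests.  A message-passing backend (mpi4py)
can be slotted in where available; it is optional at runtime.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .serial_engine import Engine, InvariantViolation

_MAGIC = b"PRDB"
SCHEMA_VERSION = 1
GHOST_COLS = 2          # ghost width: two sub-volume columns >= 2*Rcut


class ConfigurationError(ValueError):
    pass


# --------------------------------------------------------------------------
# domain layout

@dataclass
class DomainLayout:
    """Per-rank x-intervals aligned to sub-volume column boundaries."""
    p: int
    nx_cols: int
    cell_x: float
    col_edges: np.ndarray       # (p+1,) column index of each boundary

    @classmethod
    def decompose(cls, box, p: int, rcut: float, nx_cols: int,
                  max_complex_extent: float = 0.0) -> "DomainLayout":
        """Equal-width intervals (to column granularity).

        Errors if an interval cannot hold the ghost window twice (the
        half-domain constraint: the largest complex must fit in half a
        rank's region, and the ghost window must fit in each half).
        """
        if p < 1:
            raise ConfigurationError("p must be >= 1")
        cell_x = box[0] / nx_cols
        width = box[0] / p
        if p > 1:
            need = 2 * max(GHOST_COLS * cell_x, rcut, max_complex_extent)
            if width < need:
                pmax = max(int(box[0] // need), 1)
                raise ConfigurationError(
                    f"interval width {width:.3g} nm < required {need:.3g} nm; "
                    f"use at most p={pmax} ranks for this box/cutoff")
            if nx_cols < 2 * GHOST_COLS * p:
                raise ConfigurationError(
                    f"{nx_cols} x-columns cannot host {p} ranks with "
                    f"{GHOST_COLS}-column ghosts")
        edges = np.round(np.linspace(0, nx_cols, p + 1)).astype(np.int64)
        return cls(p, nx_cols, cell_x, edges)

    def interval(self, rank: int) -> tuple:
        return (self.col_edges[rank] * self.cell_x,
                self.col_edges[rank + 1] * self.cell_x)

    def owner_of_x(self, x: np.ndarray) -> np.ndarray:
        col = np.clip((np.asarray(x) / self.cell_x).astype(np.int64),
                      0, self.nx_cols - 1)
        return np.searchsorted(self.col_edges, col, side="right") - 1


# --------------------------------------------------------------------------
# serialization

def _mol_dtype(smax: int) -> np.dtype:
    return np.dtype([
        ("gid", "<i8"), ("type_id", "<i8"), ("com", "<f8", (3,)),
        ("quat", "<f8", (4,)), ("complex_id", "<i8"),
        ("bound_gid", "<i8", (smax,)), ("bound_site", "<i8", (smax,)),
        ("bond_rule", "<i8", (smax,)), ("n_lipid", "<i8"),
        ("lipid_rule", "<i8"),
    ])


@dataclass
class SerializedBatch:
    """Flat octet buffer encoding molecules + complexes by global ID."""
    payload: bytes
    mol_gids: np.ndarray = field(default=None)
    complex_cids: np.ndarray = field(default=None)

    @property
    def nbytes(self) -> int:
        return len(self.payload)


def serialize_batch(state, rows: np.ndarray) -> SerializedBatch:
    """Pack the given molecules and their complexes into one byte buffer.

    All cross-references are global IDs; the float payload is copied
    bit-exactly, so deserialize(serialize(x)) is field-identical.
    """
    rows = np.asarray(sorted(int(r) for r in rows), dtype=np.int64)
    dt = _mol_dtype(state.smax)
    mols = np.zeros(len(rows), dtype=dt)
    mols["gid"] = state.gid[rows]
    mols["type_id"] = state.type_id[rows]
    mols["com"] = state.com[rows]
    mols["quat"] = state.quat[rows]
    mols["complex_id"] = state.complex_id[rows]
    mols["bound_gid"] = state.bound_gid[rows]
    mols["bound_site"] = state.bound_site[rows]
    mols["bond_rule"] = state.bond_rule[rows]
    mols["n_lipid"] = state.n_lipid[rows]
    mols["lipid_rule"] = state.lipid_rule[rows]
    cids = sorted({int(state.complex_id[r]) for r in rows})
    counts, members = [], []
    for cid in cids:
        mem = sorted(int(state.gid[r]) for r in state.complexes[cid].rows) \
            if cid in state.complexes else []
        counts.append(len(mem))
        members.extend(mem)
    head = struct.pack("<4sIIQQQQ", _MAGIC, SCHEMA_VERSION, state.smax,
                       len(mols), len(cids), len(members),
                       int(state.next_gid))
    payload = head + mols.tobytes() \
        + np.asarray(cids, dtype="<i8").tobytes() \
        + np.asarray(counts, dtype="<i8").tobytes() \
        + np.asarray(members, dtype="<i8").tobytes()
    return SerializedBatch(payload, mols["gid"].copy(),
                           np.asarray(cids, dtype=np.int64))


def deserialize_batch(state, batch: SerializedBatch,
                      rebuild: bool = True) -> dict:
    """Merge a batch into local tables: overwrite existing gids (ghost
    refresh), insert new arrivals, rebuild the global-id -> local-index
    mapping and complexes.  Raises on schema mismatch or dangling complex
    references."""
    data = batch.payload
    hsize = struct.calcsize("<4sIIQQQQ")
    magic, ver, smax, n_mol, n_cx, n_mem, next_gid = struct.unpack(
        "<4sIIQQQQ", data[:hsize])
    if magic != _MAGIC or ver != SCHEMA_VERSION:
        raise InvariantViolation(f"batch schema mismatch: {magic} v{ver}")
    if smax != state.smax:
        raise InvariantViolation("batch smax does not match model")
    dt = _mol_dtype(smax)
    off = hsize
    mols = np.frombuffer(data, dtype=dt, count=n_mol, offset=off)
    off += mols.nbytes
    cids = np.frombuffer(data, dtype="<i8", count=n_cx, offset=off)
    off += cids.nbytes
    counts = np.frombuffer(data, dtype="<i8", count=n_cx, offset=off)
    off += counts.nbytes
    members = np.frombuffer(data, dtype="<i8", count=n_mem, offset=off)

    inserted, updated = [], []
    for rec in mols:
        gid = int(rec["gid"])
        row = state.row_of_gid.get(gid)
        if row is None:
            row = state.add_molecule(int(rec["type_id"]), rec["com"],
                                     rec["quat"], gid=gid)
            inserted.append(gid)
        else:
            state.com[row] = rec["com"]
            state.quat[row] = rec["quat"]
            updated.append(gid)
        state.bound_gid[row] = rec["bound_gid"]
        state.bound_site[row] = rec["bound_site"]
        state.bond_rule[row] = rec["bond_rule"]
        state.n_lipid[row] = rec["n_lipid"]
        state.lipid_rule[row] = rec["lipid_rule"]
    state.next_gid = max(state.next_gid, int(next_gid))
    # verify the complex manifest is resolvable
    known = state.row_of_gid
    pos = 0
    for cid, cnt in zip(cids, counts):
        for g in members[pos:pos + cnt]:
            if int(g) not in known:
                raise InvariantViolation(
                    f"dangling complex reference: complex {cid} member {g}")
        pos += cnt
    if rebuild:
        state.invalidate_sites()
        state.rebuild_complexes()
    return {"inserted": inserted, "updated": updated,
            "complexes": [int(c) for c in cids]}


# --------------------------------------------------------------------------
# transport contract

class LoopbackTransport:
    """Deterministic in-process message passing (the test backend)."""

    def __init__(self):
        self._mail: dict = {}

    def post_send(self, src: int, dst: int, batch: SerializedBatch) -> None:
        self._mail.setdefault((src, dst), []).append(batch)

    def post_receive(self, src: int, dst: int):
        return (src, dst)

    def wait(self, handles) -> list:
        out = []
        for (src, dst) in handles:
            queue = self._mail.get((src, dst), [])
            if not queue:
                raise InvariantViolation(
                    f"no message pending from rank {src} to {dst}")
            out.append(queue.pop(0))
        return out


class MPITransport:
    """Message-passing backend (requires mpi4py at runtime)."""

    def __init__(self):
        try:
            from mpi4py import MPI  # noqa: F401
        except ImportError as e:
            raise ImportError(
                "MPITransport requires mpi4py; install it or use the "
                "loopback transport") from e
        from mpi4py import MPI
        self.comm = MPI.COMM_WORLD

    def post_send(self, src, dst, batch):
        return self.comm.isend(batch.payload, dest=dst)

    def post_receive(self, src, dst):
        return self.comm.irecv(source=src)

    def wait(self, handles):
        return [SerializedBatch(h.wait()) for h in handles]


# --------------------------------------------------------------------------
# rank engine

class RankEngine(Engine):
    """Engine owning one x-interval plus ghost/partner shells."""

    def __init__(self, model, state, layout: DomainLayout, rank: int,
                 seed=None):
        super().__init__(model, state=state, seed=seed)
        self.layout = layout
        self.rank = rank
        self.x_lo, self.x_hi = layout.interval(rank)

    def owns_gid(self, gid: int) -> bool:
        row = self.state.row_of_gid.get(int(gid))
        if row is None:
            return False
        x = self.state.com[row, 0]
        return self.x_lo <= x < self.x_hi

    def owned_cell_mask(self, cells: np.ndarray) -> np.ndarray:
        # creations run over the resident window so same-step creations near
        # a boundary are identical on both ranks owning the view
        col = self.grid.x_column(cells)
        lo = max(self.layout.col_edges[self.rank] - GHOST_COLS, 0)
        hi = min(self.layout.col_edges[self.rank + 1] + GHOST_COLS,
                 self.layout.nx_cols)
        return (col >= lo) & (col < hi)

    def owned_rows(self) -> np.ndarray:
        rows = self.state.live_rows()
        x = self.state.com[rows, 0]
        return rows[(x >= self.x_lo) & (x < self.x_hi)]

    def refresh_ghost_flags(self) -> None:
        st = self.state
        rows = st.live_rows()
        x = st.com[rows, 0]
        owned = (x >= self.x_lo) & (x < self.x_hi)
        st.ghost[rows] = ~owned
        st.owner[rows] = self.layout.owner_of_x(x)


# --------------------------------------------------------------------------
# visibility closure

def visibility_rows(state, seed_rows: np.ndarray, rcut_pad: float,
                    shells: int = 2) -> np.ndarray:
    """Rows a rank must hold to decide everything touching ``seed_rows``:
    complete complexes, plus ``shells`` rounds of partners within the padded
    cutoff (each round again complex-completed)."""
    rows_all = state.live_rows()
    if len(rows_all) == 0 or len(seed_rows) == 0:
        return np.asarray(seed_rows, dtype=np.int64)
    tree = cKDTree(state.com[rows_all])
    current = set(int(r) for r in seed_rows)

    def complete(rs: set) -> set:
        cids = {int(state.complex_id[r]) for r in rs}
        out = set(rs)
        for cid in cids:
            c = state.complexes.get(cid)
            if c is not None:
                out.update(int(r) for r in c.rows)
        return out

    current = complete(current)
    for _ in range(shells):
        pts = state.com[sorted(current)]
        hits = tree.query_ball_point(pts, r=rcut_pad)
        add = set()
        for h in hits:
            add.update(int(rows_all[k]) for k in h)
        current = complete(current | add)
    return np.asarray(sorted(current), dtype=np.int64)


# --------------------------------------------------------------------------
# the parallel driver

class ParallelSimulation:
    """Loopback-parallel run: p rank engines stepped in lockstep.

    With the counter-keyed RNG, every rank computes identical updates for
    shared molecules, so the per-step exchanges are pure data motion and
    the species time series is bitwise identical for any p.
    """

    def __init__(self, model, p: int, transport=None, seed: int | None = None):
        self.model = model
        self.p = int(p)
        self.transport = transport or LoopbackTransport()
        template = Engine(model, seed=seed)
        self.layout = DomainLayout.decompose(
            model.config.box, self.p, max(template.rcut_view, 1e-9),
            template.grid.shape[0])
        self.seed = template.seed
        self.ranks: list[RankEngine] = []
        full = template.state
        for r in range(self.p):
            xlo, xhi = self.layout.interval(r)
            rows = full.live_rows()
            x = full.com[rows, 0]
            w = GHOST_COLS * self.layout.cell_x
            seeds = rows[(x >= xlo - w) & (x < xhi + w)]
            resident = visibility_rows(full, seeds, template.rcut_view)
            eng = RankEngine(model, full.extract(resident), self.layout, r,
                             seed=self.seed)
            eng.il_pool = dict(template.il_pool)
            eng.refresh_ghost_flags()
            self.ranks.append(eng)
        self.t = 0.0
        self.istep = 0
        self.records: list = []

    # -- per-step communication -------------------------------------------

    def _send_window_rows(self, eng: RankEngine, direction: int) -> np.ndarray:
        """Owned molecules a neighbor needs: the boundary window plus
        complex/partner completion (computed on the sender's full view)."""
        st = eng.state
        rows = st.live_rows()
        x = st.com[rows, 0]
        w = (GHOST_COLS + 1) * self.layout.cell_x
        if direction < 0:
            seeds = rows[x < eng.x_lo + w]
        else:
            seeds = rows[x >= eng.x_hi - w]
        return visibility_rows(st, seeds, eng.rcut_view)

    def _exchange(self, direction: int) -> None:
        """One staggered exchange: every rank sends its boundary records in
        ``direction`` (-1 = left, +1 = right) and merges the symmetric
        incoming batch.  Empty batches still flow (protocol lockstep)."""
        sends = {}
        for r, eng in enumerate(self.ranks):
            dst = r + direction
            if 0 <= dst < self.p:
                sends[r] = serialize_batch(eng.state,
                                           self._send_window_rows(eng, direction))
                self.transport.post_send(r, dst, sends[r])
        for r, eng in enumerate(self.ranks):
            src = r - direction
            if 0 <= src < self.p:
                handle = self.transport.post_receive(src, r)
                (batch,) = self.transport.wait([handle])
                info = deserialize_batch(eng.state, batch)
                eng.mark_external_change(info["complexes"])

    def _migrate(self) -> None:
        """Ownership cleanup: keep owned + visibility window, drop the rest
        (records sent but not received back are removed)."""
        w = GHOST_COLS * self.layout.cell_x
        for eng in self.ranks:
            st = eng.state
            rows = st.live_rows()
            x = st.com[rows, 0]
            seeds = rows[(x >= eng.x_lo - w) & (x < eng.x_hi + w)]
            resident = visibility_rows(st, seeds, eng.rcut_view)
            if len(resident) != len(rows):   # resident is a subset of rows
                eng.state = st.extract(resident)
                eng._closure_cache = {}
                eng._closure_dirty = set(eng.state.complexes.keys())
            eng.refresh_ghost_flags()

    def step(self) -> None:
        # steps 1-3 + 5 (compute; decisions are keyed, so the left/right
        # halves can be evaluated without an intervening merge)
        for eng in self.ranks:
            eng.step_core(self.istep)
        # step 4: leftward exchange; step 6: rightward exchange
        self._exchange(-1)
        self._exchange(+1)
        self._migrate()
        # implicit-lipid pool reduction (owned deltas only)
        deltas: dict = {}
        for eng in self.ranks:
            for rid, d in eng.il_delta.items():
                deltas[rid] = deltas.get(rid, 0) + d
        for eng in self.ranks:
            for rid, d in deltas.items():
                eng.il_pool[rid] = max(eng.il_pool.get(rid, 0) + d, 0)
            eng.istep += 1
            eng.t += eng.dt
        self.istep += 1
        self.t += self.ranks[0].dt

    def count_species(self) -> dict:
        out: dict = {}
        for eng in self.ranks:
            for k, v in eng.count_species().items():
                out[k] = out.get(k, 0) + v
        return out

    def run(self, n_steps: int, record_every: int = 100) -> list:
        if not self.records:
            self.records.append({"time": self.t,
                                 "counts": self.count_species()})
        for _ in range(n_steps):
            self.step()
            if self.istep % max(record_every, 1) == 0:
                self.records.append({"time": self.t,
                                     "counts": self.count_species()})
        return self.records


# --------------------------------------------------------------------------
# audit

def consistency_audit(ranks) -> list:
    """Cross-rank invariants; returns a list of violation strings."""
    violations = []
    owned_by: dict = {}
    copies: dict = {}
    for eng in ranks:
        st = eng.state
        for r in st.live_rows():
            gid = int(st.gid[r])
            rec = (st.com[r].tobytes(), st.quat[r].tobytes(),
                   st.bound_gid[r].tobytes(), int(st.n_lipid[r]))
            copies.setdefault(gid, []).append((eng.rank, rec))
            if eng.owns_gid(gid):
                if gid in owned_by:
                    violations.append(
                        f"gid {gid} owned by ranks {owned_by[gid]} and {eng.rank}")
                owned_by[gid] = eng.rank
    for gid, recs in copies.items():
        if gid not in owned_by:
            violations.append(f"gid {gid} has copies but no owner")
        uniq = {rec for _, rec in recs}
        if len(uniq) > 1:
            violations.append(f"gid {gid} ghost copies differ across ranks")
    for eng in ranks:
        st = eng.state
        for cid, c in st.complexes.items():
            for r in c.rows:
                for s in range(st.smax):
                    pg = int(st.bound_gid[r, s])
                    if pg >= 0 and pg not in st.row_of_gid:
                        violations.append(
                            f"rank {eng.rank}: complex {cid} bond partner "
                            f"{pg} not resident")
    return violations
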