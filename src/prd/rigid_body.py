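"""Molecules, rigid complexes, Brownian propagation and bond geometry.

A molecule is a rigid body: a center of mass (COM) plus fixed-offset
interface sites, oriented by a unit quaternion.  Bound molecules form a
complex that translates and rotates as one unit; complex diffusion
constants follow friction additivity (1/D sums over members, the
Einstein-Stokes composition that makes a dimer of two identical monomers
diffuse at D/2).

State is stored in flat numpy arrays indexed by *row*; every molecule also
carries a stable ``global id`` (gid) that never changes or gets reused, and
every complex is identified by the minimum gid of its members, which makes
complex identity deterministic and independent of event ordering.

Geometry of association: the two reacting sites are placed at separation
sigma along the bond axis.  By default ("point at each other") the bond
axis is the stationary partner's COM->site direction, the mobile partner is
rotated so its own COM->site direction is anti-parallel to the axis, and
the two molecules' body normals (body-frame +z) are aligned by a final
rotation about the axis.  With site arms subtending the rule's design angle
this produces closed rings / flat lattices without any per-rule angle
tables; explicit five-angle rules override the defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

_EPS_SEP = 1e-3     # extra separation after dissociation, nm
MAX_RETRIES = 50    # overlap-rejection resamples before zeroing a move


# --------------------------------------------------------------------------
# quaternion helpers (w, x, y, z), vectorized over leading axes

def quat_identity(n: int) -> np.ndarray:
    q = np.zeros((n, 4))
    q[:, 0] = 1.0
    return q


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    w2, x2, y2, z2 = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ], axis=-1)


def quat_normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """(..., 4) -> (..., 3, 3) rotation matrices."""
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - z * w)
    m[..., 0, 2] = 2 * (x * z + y * w)
    m[..., 1, 0] = 2 * (x * y + z * w)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - x * w)
    m[..., 2, 0] = 2 * (x * z - y * w)
    m[..., 2, 1] = 2 * (y * z + x * w)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def quat_from_axis_angle(axis: np.ndarray, angle) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    angle = np.asarray(angle, dtype=float)
    n = np.linalg.norm(axis, axis=-1, keepdims=True)
    n = np.where(n == 0, 1.0, n)
    u = axis / n
    half = angle / 2.0
    s = np.sin(half)
    return np.concatenate([np.cos(half)[..., None], u * s[..., None]], axis=-1)


def quat_from_euler_small(angles: np.ndarray) -> np.ndarray:
    """Compose rotations about x, y, z body axes by the given (small) angles.

    (n, 3) -> (n, 4).  Used for Brownian rotational steps; exact composition
    of the three axis rotations (order x, y, z), not a small-angle
    approximation, so rigid geometry is preserved for any step size.
    """
    qx = quat_from_axis_angle(np.array([1.0, 0, 0]), angles[:, 0])
    qy = quat_from_axis_angle(np.array([0, 1.0, 0]), angles[:, 1])
    qz = quat_from_axis_angle(np.array([0, 0, 1.0]), angles[:, 2])
    return quat_normalize(quat_multiply(qz, quat_multiply(qy, qx)))


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation quaternion taking unit vector a to unit vector b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    if c < -1.0 + 1e-12:
        # 180 degrees: any axis perpendicular to a
        ax = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(ax) < 1e-9:
            ax = np.cross(a, [0.0, 1.0, 0.0])
        return quat_from_axis_angle(ax, math.pi)
    axis = np.cross(a, b)
    return quat_normalize(np.array([1.0 + c, axis[0], axis[1], axis[2]]))


# --------------------------------------------------------------------------
# complex diffusion (Einstein-Stokes friction additivity)

def complex_diffusion(Dts: np.ndarray, Drots: np.ndarray) -> tuple:
    """Per-axis translational and rotational D of a rigid assembly.

    ``Dts`` is (n, 3), ``Drots`` (n,).  Friction adds: D = (sum 1/D_i)^-1
    per axis; a zero component in any member pins that axis (membrane-bound
    or anchored members).  n identical members yield D/n, so a dimer
    diffuses at half the monomer rate.
    """
    Dts = np.atleast_2d(np.asarray(Dts, float))
    Drots = np.atleast_1d(np.asarray(Drots, float))
    out_t = np.zeros(3)
    for ax in range(3):
        col = Dts[:, ax]
        if np.any(col == 0.0):
            out_t[ax] = 0.0
        else:
            out_t[ax] = 1.0 / np.sum(1.0 / col)
    if np.any(Drots == 0.0):
        out_r = 0.0
    else:
        out_r = 1.0 / np.sum(1.0 / Drots)
    return out_t, float(out_r)


# --------------------------------------------------------------------------
# state container

@dataclass
class Complex:
    """Rigid assembly bookkeeping: members by row, derived transport."""
    cid: int
    rows: np.ndarray
    Dt: np.ndarray
    Drot: float

    @property
    def n_members(self) -> int:
        return len(self.rows)


class State:
    """Array-backed molecule and complex tables for one region of space.

    Row arrays (length = capacity, first ``n`` in use, ``alive`` masks
    removals): gid, type_id, com, quat, complex id (min member gid),
    per-site bond partner gid / partner site / rule, ghost flag, owner rank,
    implicit-lipid bond count.
    """

    def __init__(self, model, capacity: int = 0):
        self.model = model
        types = model.type_list
        self.n_types = len(types)
        smax = max((t.n_sites for t in types), default=0)
        self.smax = max(smax, 1)
        self.type_Dt = np.array([t.Dt for t in types]).reshape(self.n_types, 3)
        self.type_Drot = np.array([t.Drot for t in types])
        self.type_n_sites = np.array([t.n_sites for t in types], dtype=np.int64)
        self.type_site_offsets = np.zeros((self.n_types, self.smax, 3))
        for t in types:
            if t.n_sites:
                self.type_site_offsets[t.type_id, :t.n_sites] = t.site_offsets
        self.type_is2d = np.array([t.is_2d for t in types], dtype=bool)
        self.type_implicit = np.array([t.is_implicit_surface for t in types],
                                      dtype=bool)
        self.type_names = [t.name for t in types]

        n0 = max(capacity, 16)
        self.n = 0
        self.gid = np.full(n0, -1, dtype=np.int64)
        self.type_id = np.zeros(n0, dtype=np.int64)
        self.com = np.zeros((n0, 3))
        self.quat = quat_identity(n0)
        self.complex_id = np.full(n0, -1, dtype=np.int64)
        self.bound_gid = np.full((n0, self.smax), -1, dtype=np.int64)
        self.bound_site = np.full((n0, self.smax), -1, dtype=np.int64)
        self.bond_rule = np.full((n0, self.smax), -1, dtype=np.int64)
        self.alive = np.zeros(n0, dtype=bool)
        self.ghost = np.zeros(n0, dtype=bool)
        self.owner = np.zeros(n0, dtype=np.int64)
        self.n_lipid = np.zeros(n0, dtype=np.int64)
        self.lipid_rule = np.full(n0, -1, dtype=np.int64)
        # per-row mirror of the owning complex's transport (vectorized reads)
        self.mol_comp_Dt = np.zeros((n0, 3))
        self.mol_comp_Drot = np.zeros(n0)

        self.complexes: dict[int, Complex] = {}
        self.row_of_gid: dict[int, int] = {}
        self.next_gid = 0
        self._site_cache = None

    # -- capacity / row management ----------------------------------------

    def _grow(self, need: int) -> None:
        cap = len(self.gid)
        if self.n + need <= cap:
            return
        new = max(cap * 2, self.n + need)
        for name in ("gid", "type_id", "complex_id", "alive", "ghost",
                     "owner", "n_lipid", "lipid_rule"):
            arr = getattr(self, name)
            ext = np.zeros(new, dtype=arr.dtype)
            if name in ("gid", "complex_id", "lipid_rule"):
                ext[:] = -1
            ext[:cap] = arr
            setattr(self, name, ext)
        for name, fill in (("bound_gid", -1), ("bound_site", -1), ("bond_rule", -1)):
            arr = getattr(self, name)
            ext = np.full((new, self.smax), fill, dtype=arr.dtype)
            ext[:cap] = arr
            setattr(self, name, ext)
        ext = np.zeros((new, 3))
        ext[:cap] = self.com
        self.com = ext
        ext = np.zeros((new, 3))
        ext[:cap] = self.mol_comp_Dt
        self.mol_comp_Dt = ext
        ext = np.zeros(new)
        ext[:cap] = self.mol_comp_Drot
        self.mol_comp_Drot = ext
        ext = quat_identity(new)
        ext[:cap] = self.quat
        self.quat = ext

    def add_molecule(self, type_id: int, com, quat=None, gid: int | None = None) -> int:
        """Insert a molecule; returns its row.  Creates a singleton complex."""
        self._grow(1)
        row = self.n
        self.n += 1
        if gid is None:
            gid = self.next_gid
        self.next_gid = max(self.next_gid, gid + 1)
        self.gid[row] = gid
        self.type_id[row] = type_id
        self.com[row] = com
        self.quat[row] = quat if quat is not None else (1.0, 0.0, 0.0, 0.0)
        self.alive[row] = True
        self.bound_gid[row] = -1
        self.bound_site[row] = -1
        self.bond_rule[row] = -1
        self.n_lipid[row] = 0
        self.lipid_rule[row] = -1
        self.ghost[row] = False
        self.row_of_gid[gid] = row
        self.complex_id[row] = gid
        self.complexes[gid] = Complex(
            gid, np.array([row]), self.type_Dt[type_id].copy(),
            float(self.type_Drot[type_id]))
        self.mol_comp_Dt[row] = self.type_Dt[type_id]
        self.mol_comp_Drot[row] = self.type_Drot[type_id]
        self._site_cache = None
        return row

    def remove_molecule(self, row: int) -> None:
        gid = int(self.gid[row])
        cid = int(self.complex_id[row])
        self.alive[row] = False
        del self.row_of_gid[gid]
        c = self.complexes.get(cid)
        if c is not None:
            rest = c.rows[c.rows != row]
            if len(rest) == 0:
                del self.complexes[cid]
            else:
                self._rebuild_complex_from_rows(rest)
                if cid not in {int(self.complex_id[r]) for r in rest}:
                    self.complexes.pop(cid, None)
        self._site_cache = None

    # -- derived geometry --------------------------------------------------

    def live_rows(self) -> np.ndarray:
        return np.nonzero(self.alive[:self.n])[0]

    def site_positions(self, rows: np.ndarray | None = None) -> np.ndarray:
        """World-frame site positions, shape (len(rows), smax, 3).

        Slots beyond a type's site count hold the molecule COM (harmless
        sentinels; they never match any rule).  Cached per step for the full
        table.
        """
        if rows is None:
            if self._site_cache is not None:
                return self._site_cache
            rows = np.arange(self.n)
            full = True
        else:
            full = False
        R = quat_to_matrix(self.quat[rows])                       # (m,3,3)
        offs = self.type_site_offsets[self.type_id[rows]]         # (m,smax,3)
        pos = self.com[rows, None, :] + np.einsum("mij,msj->msi", R, offs)
        if full:
            self._site_cache = pos
        return pos

    def invalidate_sites(self) -> None:
        self._site_cache = None

    def normals(self, rows: np.ndarray) -> np.ndarray:
        """Body-frame +z in world coordinates (molecule normal)."""
        R = quat_to_matrix(self.quat[rows])
        return R[..., :, 2]

    def complex_com(self, cid: int) -> np.ndarray:
        rows = self.complexes[cid].rows
        return self.com[rows].mean(axis=0)

    def complex_x_extent(self, cid: int) -> tuple:
        rows = self.complexes[cid].rows
        sp = self.site_positions(rows)
        xs = np.concatenate([self.com[rows, 0], sp[..., 0].ravel()])
        return float(xs.min()), float(xs.max())

    # -- complex bookkeeping ----------------------------------------------

    def _complex_transport(self, rows: np.ndarray) -> tuple:
        # sum in gid order so the result is bitwise identical no matter
        # which local rows the members occupy (rank-count invariance)
        rows = np.asarray(rows)
        rows = rows[np.argsort(self.gid[rows], kind="stable")]
        Dt, Drot = complex_diffusion(self.type_Dt[self.type_id[rows]],
                                     self.type_Drot[self.type_id[rows]])
        n_lip = int(self.n_lipid[rows].sum())
        if n_lip > 0:
            lr = int(self.lipid_rule[rows[self.n_lipid[rows] > 0][0]])
            lip_type = self.model.rules[lr].lipid_type_id
            lip_Dt = self.type_Dt[lip_type]
            lip_Drot = self.type_Drot[lip_type]
            all_Dt = np.vstack([self.type_Dt[self.type_id[rows]]]
                               + [lip_Dt[None, :]] * n_lip)
            all_Drot = np.concatenate([self.type_Drot[self.type_id[rows]],
                                       np.full(n_lip, lip_Drot)])
            Dt, Drot = complex_diffusion(all_Dt, all_Drot)
        return Dt, Drot

    def _rebuild_complex_from_rows(self, rows: np.ndarray) -> int:
        rows = np.asarray(rows)
        cid = int(self.gid[rows].min())
        Dt, Drot = self._complex_transport(rows)
        self.complexes[cid] = Complex(cid, np.sort(rows), Dt, Drot)
        self.complex_id[rows] = cid
        self.mol_comp_Dt[rows] = Dt
        self.mol_comp_Drot[rows] = Drot
        return cid

    def refresh_complex(self, cid: int) -> None:
        c = self.complexes[cid]
        c.Dt, c.Drot = self._complex_transport(c.rows)
        self.mol_comp_Dt[c.rows] = c.Dt
        self.mol_comp_Drot[c.rows] = c.Drot

    def connected_components(self, rows: Iterable[int]) -> list:
        """Split rows into bond-connected components (BFS on the bond graph)."""
        rows = list(int(r) for r in rows)
        rowset = set(rows)
        seen: set = set()
        comps = []
        for r0 in rows:
            if r0 in seen:
                continue
            stack = [r0]
            comp = []
            seen.add(r0)
            while stack:
                r = stack.pop()
                comp.append(r)
                for s in range(self.smax):
                    pg = int(self.bound_gid[r, s])
                    if pg < 0:
                        continue
                    pr = self.row_of_gid.get(pg)
                    if pr is None or pr not in rowset or pr in seen:
                        continue
                    seen.add(pr)
                    stack.append(pr)
            comps.append(np.array(sorted(comp)))
        return comps

    # -- bonds -------------------------------------------------------------

    def bond_pairs(self, rows: np.ndarray | None = None) -> list:
        """Unordered bond list [(row_a, site_a, row_b, site_b, rule_id)]."""
        if rows is None:
            rows = self.live_rows()
        out = []
        for r in rows:
            for s in range(int(self.type_n_sites[self.type_id[r]])):
                pg = int(self.bound_gid[r, s])
                if pg < 0:
                    continue
                pr = self.row_of_gid.get(pg)
                if pr is None:
                    continue
                if (self.gid[r], s) < (pg, int(self.bound_site[r, s])):
                    out.append((int(r), s, pr, int(self.bound_site[r, s]),
                                int(self.bond_rule[r, s])))
        return out

    def count_bound_pairs(self, rule_id: int) -> int:
        mask = self.alive[:self.n, None] & (self.bond_rule[:self.n] == rule_id)
        return int(mask.sum()) // 2

    # -- association / dissociation ----------------------------------------

    def _move_complex(self, cid: int, dq: np.ndarray | None, pivot, shift) -> None:
        rows = self.complexes[cid].rows
        if dq is not None:
            R = quat_to_matrix(dq)
            self.com[rows] = (self.com[rows] - pivot) @ R.T + pivot
            self.quat[rows] = quat_normalize(
                quat_multiply(dq[None, :], self.quat[rows]))
        if shift is not None:
            self.com[rows] += shift
        self._site_cache = None

    def place_bond_geometry(self, rowA: int, siteA: int, rowB: int, siteB: int,
                            rule) -> tuple:
        """Compute and apply the post-association placement.

        Returns (saved coordinates) so the caller can revert on steric
        rejection.  The stationary partner is the membrane-bound complex if
        exactly one is membrane-bound, otherwise the slower-diffusing one.
        """
        cidA = int(self.complex_id[rowA])
        cidB = int(self.complex_id[rowB])
        cA, cB = self.complexes[cidA], self.complexes[cidB]
        saved = self._save_coords([cidA, cidB])

        a2d = cA.Dt[2] == 0.0
        b2d = cB.Dt[2] == 0.0
        if a2d and not b2d:
            stat_row, stat_site, mov_row, mov_site = rowA, siteA, rowB, siteB
            mov_cid, stat_cid = cidB, cidA
        elif b2d and not a2d:
            stat_row, stat_site, mov_row, mov_site = rowB, siteB, rowA, siteA
            mov_cid, stat_cid = cidA, cidB
        elif (cA.Dt.mean(), cidA) >= (cB.Dt.mean(), cidB):
            stat_row, stat_site, mov_row, mov_site = rowB, siteB, rowA, siteA
            mov_cid, stat_cid = cidA, cidB
        else:
            stat_row, stat_site, mov_row, mov_site = rowA, siteA, rowB, siteB
            mov_cid, stat_cid = cidB, cidA

        sp_stat = self.site_positions(np.array([stat_row]))[0, stat_site]
        sp_mov = self.site_positions(np.array([mov_row]))[0, mov_site]
        v_stat = self._site_arm(stat_row, stat_site)
        sep = sp_mov - sp_stat
        nsep = np.linalg.norm(sep)
        if v_stat is not None:
            axis = v_stat
        elif nsep > 1e-9:
            axis = sep / nsep
        else:
            axis = np.array([0.0, 0.0, 1.0])
        mov2d = self.complexes[mov_cid].Dt[2] == 0.0
        if mov2d:
            # keep membrane species in-plane: project the axis
            axis = np.array([axis[0], axis[1], 0.0])
            n = np.linalg.norm(axis)
            axis = axis / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])

        v_mov = self._site_arm(mov_row, mov_site)
        if v_mov is not None:
            dq = rotation_between(v_mov, -axis)
            self._move_complex(mov_cid, dq, sp_mov, None)
            # dihedral: align the moving molecule's normal with the static one
            n_stat = self.normals(np.array([stat_row]))[0]
            n_mov = self.normals(np.array([mov_row]))[0]
            dq2 = self._axis_align(axis, n_mov, n_stat)
            if dq2 is not None:
                self._move_complex(mov_cid, dq2,
                                   self.site_positions(np.array([mov_row]))[0, mov_site],
                                   None)
        target = sp_stat + rule.sigma * axis
        sp_mov_now = self.site_positions(np.array([mov_row]))[0, mov_site]
        self._move_complex(mov_cid, None, None, target - sp_mov_now)
        return saved, stat_cid, mov_cid

    def _site_arm(self, row: int, site: int) -> np.ndarray | None:
        off = self.type_site_offsets[self.type_id[row], site]
        n = np.linalg.norm(off)
        if n < 1e-9:
            return None
        R = quat_to_matrix(self.quat[row])
        return (R @ off) / n

    @staticmethod
    def _axis_align(axis: np.ndarray, v_from: np.ndarray,
                    v_to: np.ndarray) -> np.ndarray | None:
        """Rotation about `axis` taking the projection of v_from onto the
        plane perpendicular to axis into that of v_to."""
        pf = v_from - np.dot(v_from, axis) * axis
        pt = v_to - np.dot(v_to, axis) * axis
        nf, nt = np.linalg.norm(pf), np.linalg.norm(pt)
        if nf < 1e-9 or nt < 1e-9:
            return None
        pf /= nf
        pt /= nt
        c = float(np.clip(np.dot(pf, pt), -1.0, 1.0))
        s = float(np.dot(np.cross(pf, pt), axis))
        ang = math.atan2(s, c)
        return quat_from_axis_angle(axis, ang)

    def _save_coords(self, cids: Sequence[int]) -> dict:
        saved = {}
        for cid in cids:
            rows = self.complexes[cid].rows
            saved[cid] = (rows.copy(), self.com[rows].copy(), self.quat[rows].copy())
        return saved

    def restore_coords(self, saved: dict) -> None:
        for rows, com, quat in saved.values():
            self.com[rows] = com
            self.quat[rows] = quat
        self._site_cache = None

    def bind(self, rowA: int, siteA: int, rowB: int, siteB: int, rule) -> None:
        """Record the bond and merge complexes (geometry already placed)."""
        if self.bound_gid[rowA, siteA] >= 0 or self.bound_gid[rowB, siteB] >= 0:
            raise RuntimeError("bind() on an occupied site (bug)")
        self.bound_gid[rowA, siteA] = self.gid[rowB]
        self.bound_site[rowA, siteA] = siteB
        self.bond_rule[rowA, siteA] = rule.rule_id
        self.bound_gid[rowB, siteB] = self.gid[rowA]
        self.bound_site[rowB, siteB] = siteA
        self.bond_rule[rowB, siteB] = rule.rule_id
        cidA = int(self.complex_id[rowA])
        cidB = int(self.complex_id[rowB])
        if cidA != cidB:
            rows = np.concatenate([self.complexes[cidA].rows,
                                   self.complexes[cidB].rows])
            old = {cidA, cidB}
            new = self._rebuild_complex_from_rows(rows)
            for c in old - {new}:
                self.complexes.pop(c, None)

    def bind_surface(self, row: int, site: int, rule) -> None:
        """Bond a site to an implicit-lipid density field (sentinel -2)."""
        if self.bound_gid[row, site] != -1:
            raise RuntimeError("bind_surface() on an occupied site (bug)")
        self.bound_gid[row, site] = -2
        self.bond_rule[row, site] = rule.rule_id
        self.n_lipid[row] += 1
        self.lipid_rule[row] = rule.rule_id
        self.refresh_complex(int(self.complex_id[row]))
        self._site_cache = None

    def unbind_surface(self, row: int, site: int) -> None:
        if self.bound_gid[row, site] != -2:
            raise RuntimeError("unbind_surface() on a non-surface site (bug)")
        self.bound_gid[row, site] = -1
        self.bond_rule[row, site] = -1
        self.n_lipid[row] -= 1
        if self.n_lipid[row] == 0:
            self.lipid_rule[row] = -1
        self.refresh_complex(int(self.complex_id[row]))
        self._site_cache = None

    def unbind(self, rowA: int, siteA: int) -> tuple:
        """Remove the bond at (rowA, siteA).

        Returns (rowB, siteB, split) where split is True if the complex
        fragmented; fragments are displaced to sigma + eps along the former
        bond axis and their transport recomputed.  A ring bond leaves the
        complex connected (no displacement).
        """
        gidB = int(self.bound_gid[rowA, siteA])
        if gidB < 0:
            raise RuntimeError("unbind() on a free site (bug)")
        rowB = self.row_of_gid[gidB]
        siteB = int(self.bound_site[rowA, siteA])
        rule_id = int(self.bond_rule[rowA, siteA])
        spA = self.site_positions(np.array([rowA]))[0, siteA]
        spB = self.site_positions(np.array([rowB]))[0, siteB]
        self.bound_gid[rowA, siteA] = -1
        self.bound_site[rowA, siteA] = -1
        self.bond_rule[rowA, siteA] = -1
        self.bound_gid[rowB, siteB] = -1
        self.bound_site[rowB, siteB] = -1
        self.bond_rule[rowB, siteB] = -1
        cid = int(self.complex_id[rowA])
        rows = self.complexes[cid].rows
        comps = self.connected_components(rows)
        if len(comps) == 1:
            self.refresh_complex(cid)
            self._site_cache = None
            return rowB, siteB, False
        # split: displace along former bond axis
        axis = spB - spA
        n = np.linalg.norm(axis)
        axis = axis / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])
        sigma = self.model.rules[rule_id].sigma if rule_id >= 0 else n
        target = sigma + _EPS_SEP
        extra = max(target - n, 0.0)
        for comp in comps:
            newcid = self._rebuild_complex_from_rows(comp)
            sign = -0.5 if rowA in comp else 0.5
            shift = sign * extra * axis
            if self.complexes[newcid].Dt[2] == 0.0:
                shift = shift.copy()
                shift[2] = 0.0
            self.com[comp] += shift
        new_cids = {int(self.complex_id[c[0]]) for c in comps}
        if cid not in new_cids:
            self.complexes.pop(cid, None)
        self._site_cache = None
        return rowB, siteB, True

    # -- loop closure -------------------------------------------------------

    def loop_closure_candidates(self, cid: int, rules: Sequence,
                                tol_frac: float = 0.2) -> list:
        """Free intra-complex site pairs geometrically positioned to close a
        ring: pattern matches a loop-eligible order-2 rule, the two sites sit
        within ``tol_frac * sigma`` of sigma, and the two molecules are not
        already directly bonded.  Returns [(rowA, siteA, rowB, siteB, rule)].
        """
        c = self.complexes.get(cid)
        if c is None or c.n_members < 3:
            return []
        rows = c.rows
        sp = self.site_positions(rows)
        out = []
        row_pos = {int(r): k for k, r in enumerate(rows)}
        for rule in rules:
            if rule.order != 2 or not rule.is_loop_closure_eligible:
                continue
            for pa, pb in ((rule.reactants[0], rule.reactants[1]),
                           (rule.reactants[1], rule.reactants[0])):
                for ra in rows:
                    for sa in self._match_sites(ra, pa):
                        if self.bound_gid[ra, sa] != -1:
                            continue
                        for rb in rows:
                            if rb <= ra:
                                continue
                            if self._directly_bonded(ra, rb):
                                continue
                            for sb in self._match_sites(rb, pb):
                                if self.bound_gid[rb, sb] != -1:
                                    continue
                                d = np.linalg.norm(sp[row_pos[int(ra)], sa]
                                                   - sp[row_pos[int(rb)], sb])
                                if abs(d - rule.sigma) <= tol_frac * rule.sigma:
                                    out.append((int(ra), int(sa), int(rb),
                                                int(sb), rule))
        dedup = {}
        for ra, sa, rb, sb, rule in out:
            key = (min((ra, sa), (rb, sb)), max((ra, sa), (rb, sb)))
            dedup.setdefault(key, (ra, sa, rb, sb, rule))
        return list(dedup.values())

    def _match_sites(self, row: int, pat) -> list:
        """Site indices on this molecule matching the pattern (with context)."""
        t = self.model.type_list[self.type_id[row]]
        if t.name != pat.mol or not pat.site:
            return []
        for cs, cond in pat.context:
            for ci in t.sites_matching(cs):
                bound = self.bound_gid[row, ci] != -1
                if (cond == "bound") != bound:
                    return []
        return t.sites_matching(pat.site)

    def _directly_bonded(self, ra: int, rb: int) -> bool:
        return np.any(self.bound_gid[ra] == self.gid[rb])

    # -- output helpers -----------------------------------------------------

    def snapshot_records(self) -> tuple:
        rows = self.live_rows()
        rows = rows[~self.ghost[rows]]
        labels, coords = [], []
        sp = self.site_positions(rows)
        for i, r in enumerate(rows):
            t = self.model.type_list[self.type_id[r]]
            labels.append(t.name)
            coords.append(self.com[r])
            for s in range(t.n_sites):
                labels.append(f"{t.name}.{t.site_names[s]}")
                coords.append(sp[i, s])
        return labels, coords

    def to_dict(self) -> dict:
        rows = self.live_rows()
        return {
            "schema": 1,
            "next_gid": int(self.next_gid),
            "gid": self.gid[rows].tolist(),
            "type_id": self.type_id[rows].tolist(),
            "com": self.com[rows].tolist(),
            "quat": self.quat[rows].tolist(),
            "bound_gid": self.bound_gid[rows].tolist(),
            "bound_site": self.bound_site[rows].tolist(),
            "bond_rule": self.bond_rule[rows].tolist(),
            "n_lipid": self.n_lipid[rows].tolist(),
            "lipid_rule": self.lipid_rule[rows].tolist(),
        }

    @classmethod
    def from_dict(cls, model, data: dict) -> "State":
        st = cls(model, capacity=len(data["gid"]))
        for i, g in enumerate(data["gid"]):
            st.add_molecule(int(data["type_id"][i]), data["com"][i],
                            data["quat"][i], gid=int(g))
        rows = st.live_rows()
        st.bound_gid[rows] = np.asarray(data["bound_gid"], dtype=np.int64)
        st.bound_site[rows] = np.asarray(data["bound_site"], dtype=np.int64)
        st.bond_rule[rows] = np.asarray(data["bond_rule"], dtype=np.int64)
        st.n_lipid[rows] = np.asarray(data["n_lipid"], dtype=np.int64)
        st.lipid_rule[rows] = np.asarray(data["lipid_rule"], dtype=np.int64)
        st.next_gid = int(data["next_gid"])
        st.rebuild_complexes()
        return st

    def extract(self, rows: Iterable[int]) -> "State":
        """New State holding copies of the given molecules (bonds preserved;
        complexes rebuilt).  Used for domain distribution and migration."""
        rows = np.asarray(sorted(int(r) for r in rows), dtype=np.int64)
        st = State(self.model, capacity=max(len(rows), 16))
        for r in rows:
            st.add_molecule(int(self.type_id[r]), self.com[r].copy(),
                            self.quat[r].copy(), gid=int(self.gid[r]))
        new_rows = st.live_rows()
        st.bound_gid[new_rows] = self.bound_gid[rows]
        st.bound_site[new_rows] = self.bound_site[rows]
        st.bond_rule[new_rows] = self.bond_rule[rows]
        st.n_lipid[new_rows] = self.n_lipid[rows]
        st.lipid_rule[new_rows] = self.lipid_rule[rows]
        st.next_gid = self.next_gid
        st.rebuild_complexes()
        return st

    def rebuild_complexes(self) -> None:
        """Recompute all complexes from the bond graph (after deserialize)."""
        self.complexes = {}
        rows = self.live_rows()
        for comp in self.connected_components(rows):
            self._rebuild_complex_from_rows(comp)
        self._site_cache = None
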