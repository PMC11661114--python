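"""The single-process timestep loop.

Order of operations per fixed timestep dt (reactions are evaluated before
diffusion; a molecule that reacted does not also diffuse):

a. zeroth-order creations (per sub-volume Poisson counts);
b. first-order events -- bond dissociation, loop closure of geometrically
   eligible intra-complex site pairs, unimolecular decay, implicit-lipid
   unbinding -- each sampled per member with probability k*dt;
c. pair-reaction probabilities over all cutoff-limited candidates (3D, 2D
   and membrane-projected kernels), plus implicit-surface binding
   propensities;
d. acceptance draws, conflict resolution (the canonically first accepted
   event per molecule wins; the rest are voided), and execution honoring
   one reaction per molecule and per site per step;
e. Brownian propagation of all non-reacted complexes, with overlap
   rejection against frozen step-start neighbor positions (bounded
   resampling, then a zero move);
f. sub-volume reassignment and observable accumulation.

Every random decision is drawn from the counter-keyed RNG
(:mod:`prd._rng`), keyed by step number and the stable global ids involved,
never from a sequential stream.  Decisions therefore do not depend on
enumeration order or on how space is split across processors, which is what
lets the domain-decomposed engine reproduce this one bit for bit.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

from . import _rng, fpr_kernels, partition, rate_theory
from .rigid_body import State, quat_from_euler_small, quat_multiply, \
    quat_normalize, quat_to_matrix

_CREATION_CAP = 64          # max creations per cell per step (gid packing)
_STERIC_MARGIN = 1.0 - 1e-6


class InvariantViolation(RuntimeError):
    pass


class Engine:
    """Serial simulation engine; also the per-rank kernel of the parallel one.

    Hooks overridden by the parallel rank engine: :meth:`owns_gid` (is a
    molecule's authoritative copy here) and :meth:`owned_cell_mask`.
    """

    def __init__(self, model, state: State | None = None, seed: int | None = None):
        self.model = model
        self.config = model.config
        self.dt = float(model.config.dt)
        self.box = model.config.box
        self.seed = int(model.config.seed if seed is None else seed)
        self.rules = model.rules
        self.order2 = [r for r in self.rules
                       if r.order == 2 and not r.implicit_surface]
        self.il_rules = [r for r in self.rules
                         if r.order == 2 and r.implicit_surface]
        self.decay_rules = [r for r in self.rules if r.order == 1]
        self.creation_rules = [r for r in self.rules if r.order == 0]

        self.cutoffs = rate_theory.CutoffSpec.from_rules(self.order2, self.dt)
        self.rcut_sys = self.cutoffs.rcut
        lmax = max((t.max_site_extent for t in model.type_list), default=0.0)
        self.rcut_pad = self.rcut_sys + 2.0 * lmax
        self._kb = np.array([
            (r.kb_intrinsic if (r.order == 2 and r.kb_intrinsic) else 0.0)
            for r in self.rules]) if self.rules else np.zeros(0)

        self._il_zcut = {r.rule_id: r.sigma + 3.0 * math.sqrt(
            2.0 * 3 * max(self._binder_Dz(r), 1e-12) * self.dt)
            for r in self.il_rules}
        self.rcut_view = max([self.rcut_pad] + list(self._il_zcut.values()))
        # without any pairwise interactions the cell size is free; keep
        # enough x-columns for domain decomposition and creation buckets
        grid_len = self.rcut_view if self.rcut_view > 0 \
            else float(np.max(self.box)) / 8.0
        self.grid = partition.build_grid(self.box, grid_len)

        self.state = self._place_initial() if state is None else state

        # implicit-lipid pools: rule_id -> free copy count (authoritative)
        self.il_pool = {}
        for r in self.il_rules:
            lip_name = model.type_list[r.lipid_type_id].name
            n = model.config.copies.get(lip_name,
                                        model.config.implicit_lipid_copies)
            self.il_pool[r.rule_id] = int(n)
        self.il_delta: dict = {}

        self.closure_rules = [r for r in self.order2
                              if r.is_loop_closure_eligible]
        self._closure_cache: dict = {}
        self._closure_dirty = set(self.state.complexes.keys())

        self.t = 0.0
        self.istep = 0
        self.records: list = []
        self._rot_type = np.array(
            [t.max_site_extent > 0 for t in model.type_list], dtype=bool) \
            if model.type_list else np.zeros(0, dtype=bool)

    # -- hooks overridden by the parallel rank engine ----------------------

    def owns_gid(self, gid: int) -> bool:
        return True

    def owned_cell_mask(self, cells: np.ndarray) -> np.ndarray:
        return np.ones(len(cells), dtype=bool)

    def mark_external_change(self, cids) -> None:
        """Complexes changed by a merge from another rank: refresh caches."""
        self._closure_dirty.update(int(c) for c in cids)

    # -- setup -------------------------------------------------------------

    def _binder_Dz(self, rule) -> float:
        binder = rule.reactants[rule.binder_index]
        return float(self.model.types[binder.mol].Dt[2])

    def _place_initial(self) -> State:
        rng = np.random.default_rng(self.seed)
        total = sum(self.config.copies.values())
        st = State(self.model, capacity=max(total, 16))
        for t in self.model.type_list:
            if t.is_implicit_surface:
                continue
            n = self.config.copies.get(t.name, 0)
            if n == 0:
                continue
            pos = rng.uniform(0.0, 1.0, size=(n, 3)) * self.box[None, :]
            if t.is_2d:
                pos[:, 2] = 0.0
                ang = rng.uniform(0.0, 2.0 * math.pi, size=n)
                quats = np.stack([np.cos(ang / 2), np.zeros(n), np.zeros(n),
                                  np.sin(ang / 2)], axis=1)
            else:
                quats = rng.normal(size=(n, 4))
                quats /= np.linalg.norm(quats, axis=1, keepdims=True)
            for i in range(n):
                st.add_molecule(t.type_id, pos[i], quats[i])
        return st

    # -- validation report -------------------------------------------------

    def validate_report(self) -> dict:
        """Cutoffs, timestep limits and derived rates (for `prd validate`)."""
        dens = {}
        for r in self.order2:
            n1 = self.config.copies.get(r.reactants[0].mol, 0)
            n2 = self.config.copies.get(r.reactants[1].mol, 0)
            d = r.dimensionality
            Ld = self.config.area if d == 2 else self.config.volume
            rho = max(n1, n2, 1) / Ld
            ta = self.model.types[r.reactants[0].mol]
            tb = self.model.types[r.reactants[1].mol]
            dens[r.name] = (rho, ta.D_mean, tb.D_mean, d, r.sigma)
        ts = rate_theory.TimestepSpec.from_rules(self.order2, dens)
        return {
            "rcut_per_rule": dict(self.cutoffs.rcut_by_rule),
            "rcut_system": self.rcut_sys,
            "dt_max_per_rule": dict(ts.dt_by_rule),
            "dt_max_system": ts.dt_max,
            "limiting_rule": ts.limiting_rule,
            "grid_shape": self.grid.shape,
            "rules": [{
                "name": r.name, "text": r.text,
                "kon_macro": r.kon_macro, "koff_macro": r.koff_macro,
                "ka_intrinsic": r.ka_intrinsic, "kb_intrinsic": r.kb_intrinsic,
                "ka2d": r.ka2d_intrinsic, "kclose": r.kclose,
            } for r in self.order2],
        }

    # -- species bookkeeping ----------------------------------------------

    @staticmethod
    def _complex_label(names: Counter, n_bonds: int, n_members: int,
                       n_lipid: int) -> str:
        parts = []
        for name in sorted(names):
            c = names[name]
            parts.append(f"{name}{c if c > 1 else ''}")
        label = ".".join(parts)
        if n_members > 2 and n_bonds >= n_members:
            label += "r"                      # closed ring
        if n_lipid > 0:
            label += "@m"                     # bound to the implicit membrane
        return label

    def count_species(self) -> dict:
        st = self.state
        out: Counter = Counter()
        for cid in sorted(st.complexes):
            if not self.owns_gid(cid):
                continue
            rows = st.complexes[cid].rows
            names = Counter(st.type_names[t] for t in st.type_id[rows])
            n_bonds = int(np.sum(st.bound_gid[rows] >= 0)) // 2
            n_lip = int(st.n_lipid[rows].sum())
            out[self._complex_label(names, n_bonds, len(rows), n_lip)] += 1
        return dict(out)

    # -- main loop ---------------------------------------------------------

    def run(self, n_steps: int | None = None,
            record_every: int | None = None, observer=None) -> list:
        n = self.config.n_iterations if n_steps is None else n_steps
        every = max(int(self.config.output_every if record_every is None
                        else record_every), 1)
        if not self.records:
            self.records.append({"time": self.t, "counts": self.count_species()})
        for _ in range(n):
            self.step()
            if self.istep % every == 0:
                self.records.append({"time": self.t,
                                     "counts": self.count_species()})
            if observer is not None:
                observer(self)
        return self.records

    def step(self) -> None:
        self.step_core(self.istep)
        self.finish_step()
        self.istep += 1
        self.t += self.dt

    def step_core(self, istep: int) -> None:
        """Phases a-e; deltas are committed separately by finish_step()."""
        st = self.state
        self.il_delta = {}
        self._il_pool_frozen = dict(self.il_pool)

        self._creations(istep)
        reacted_mols, no_move = self._first_order(istep)
        rows = st.live_rows()
        st.invalidate_sites()
        self.grid.assign(st.com[rows], rows)
        cands = partition.pair_candidates(
            st, self.grid, self.rules, self.rcut_sys, rows) \
            if self.order2 else partition.PairCandidates.empty(self.rules)
        self._pair_and_surface_phase(istep, cands, reacted_mols, no_move)
        self._propagate(istep, cands, no_move)

    def finish_step(self) -> None:
        """Commit per-step deltas (overridden for cross-rank reduction)."""
        for rid, d in self.il_delta.items():
            self.il_pool[rid] = max(self.il_pool.get(rid, 0) + d, 0)

    # -- phase a: creations ------------------------------------------------

    def _creations(self, istep: int) -> None:
        if not self.creation_rules:
            return
        base_cells = np.arange(self.grid.n_cells)
        owned = self.owned_cell_mask(base_cells)
        vcell = float(np.prod(self.grid.cell_len))
        nx, ny, _nz = self.grid.shape
        for rule in self.creation_rules:
            lam = (rule.k_macro or 0.0) * vcell * self.dt
            if lam <= 0:
                continue
            b = _rng.key_base(self.seed, istep,
                              _rng.ZEROTH * 64 + rule.rule_id)
            counts = _poisson_from_uniform(_rng.uniform(b, base_cells), lam)
            counts[~owned] = 0
            t = self.model.types[rule.reactants[0].mol]
            pb = _rng.key_base(self.seed, istep, _rng.PLACE)
            for cell in np.nonzero(counts)[0]:
                k = min(int(counts[cell]), _CREATION_CAP)
                ix = cell % nx
                iy = (cell // nx) % ny
                iz = cell // (nx * ny)
                for idx in range(k):
                    uxyz = _rng.uniform(pb, int(cell),
                                        np.array([idx * 4, idx * 4 + 1,
                                                  idx * 4 + 2]))
                    pos = (np.array([ix, iy, iz], dtype=float) + uxyz) \
                        * self.grid.cell_len
                    if t.is_2d:
                        pos[2] = 0.0
                    gid = (istep + 1) * self.grid.n_cells * _CREATION_CAP \
                        + int(cell) * _CREATION_CAP + idx
                    self.state.add_molecule(t.type_id, pos, gid=gid)

    # -- phase b: first-order events ---------------------------------------

    def _first_order(self, istep: int) -> tuple:
        st = self.state
        dt = self.dt
        events = []  # (glo, ghi, tag, payload)
        rows = st.live_rows()

        # bond dissociations: intrinsic kb per bond, drawn once per bond
        if len(rows) and len(self._kb):
            sub = st.bound_gid[rows] >= 0
            if sub.any():
                br, bs = np.nonzero(sub)
                brows = rows[br]
                pg = st.bound_gid[brows, bs]
                mine = st.gid[brows] < pg
                brows, bs, pg = brows[mine], bs[mine], pg[mine]
                if len(brows):
                    rid = st.bond_rule[brows, bs]
                    kb = self._kb[rid]
                    base = _rng.key_base(self.seed, istep, _rng.FIRST)
                    u = _rng.uniform(base, st.gid[brows], pg)
                    hit = u < kb * dt
                    for r, s, g2 in zip(brows[hit], bs[hit], pg[hit]):
                        events.append((int(st.gid[r]), int(g2), "diss",
                                       (int(r), int(s))))

        # loop closures (geometry is rigid: cache per complex topology)
        if self.closure_rules:
            for cid in sorted(self._closure_dirty):
                cl = st.loop_closure_candidates(cid, self.closure_rules) \
                    if cid in st.complexes else []
                if cl:
                    self._closure_cache[cid] = cl
                else:
                    self._closure_cache.pop(cid, None)
            self._closure_dirty.clear()
            base = _rng.key_base(self.seed, istep, _rng.LOOP)
            for cid in sorted(self._closure_cache):
                for (ra, sa, rb, sb, rule) in self._closure_cache[cid]:
                    p = min((rule.kclose or 0.0) * dt, 1.0)
                    if p <= 0:
                        continue
                    ga, gb = int(st.gid[ra]), int(st.gid[rb])
                    glo, ghi = min(ga, gb), max(ga, gb)
                    u = float(_rng.uniform(base, glo,
                                           ghi * 64 + sa * 8 + sb)[0])
                    if u < p:
                        events.append((glo, ghi, "close",
                                       (ra, sa, rb, sb, rule)))

        # unimolecular decay
        if self.decay_rules:
            base = _rng.key_base(self.seed, istep, _rng.FIRST + 16)
            for rule in self.decay_rules:
                t = self.model.types.get(rule.reactants[0].mol)
                if t is None:
                    continue
                rr = rows[st.type_id[rows] == t.type_id]
                if len(rr) == 0:
                    continue
                u = _rng.uniform(base, st.gid[rr], rule.rule_id)
                hit = u < (rule.k_intrinsic or 0.0) * dt
                for r in rr[hit]:
                    g = int(st.gid[r])
                    events.append((g, g, "decay", (int(r),)))

        # implicit-lipid unbinding
        for rule in self.il_rules:
            kb = rule.kb_intrinsic or 0.0
            if kb <= 0:
                continue
            lr = rows[(st.n_lipid[rows] > 0)
                      & (st.lipid_rule[rows] == rule.rule_id)]
            base = _rng.key_base(self.seed, istep, _rng.IL_UNBIND)
            for r in lr:
                sites = np.nonzero((st.bound_gid[r] == -2)
                                   & (st.bond_rule[r] == rule.rule_id))[0]
                for s in sites:
                    u = float(_rng.uniform(base, int(st.gid[r]), int(s))[0])
                    if u < kb * dt:
                        g = int(st.gid[r])
                        events.append((g, g, "ilu", (int(r), int(s), rule)))

        # canonical one-hop conflict resolution, then execute in order
        events.sort(key=lambda e: (e[0], e[1], e[2]))
        first_of: dict = {}
        for k, ev in enumerate(events):
            first_of.setdefault(ev[0], k)
            first_of.setdefault(ev[1], k)
        reacted: set = set()
        no_move: set = set()
        for k, ev in enumerate(events):
            glo, ghi, tag, payload = ev
            if first_of[glo] != k or first_of[ghi] != k:
                continue
            if tag == "diss":
                r, s = payload
                self._mark_dirty(int(st.complex_id[r]))
                rB, _sB, _split = st.unbind(r, s)
                for rr in (r, rB):
                    cid = int(st.complex_id[rr])
                    self._mark_dirty(cid)
                    no_move.add(cid)
                reacted.update((glo, ghi))
            elif tag == "close":
                ra, sa, rb, sb, rule = payload
                if st.bound_gid[ra, sa] != -1 or st.bound_gid[rb, sb] != -1:
                    continue
                st.bind(ra, sa, rb, sb, rule)
                cid = int(st.complex_id[ra])
                self._mark_dirty(cid)
                no_move.add(cid)
                reacted.update((glo, ghi))
            elif tag == "decay":
                (r,) = payload
                self._mark_dirty(int(st.complex_id[r]))
                st.remove_molecule(r)
                reacted.add(glo)
            elif tag == "ilu":
                r, s, rule = payload
                st.unbind_surface(r, s)
                if self.owns_gid(glo):
                    self.il_delta[rule.rule_id] = \
                        self.il_delta.get(rule.rule_id, 0) + 1
                cid = int(st.complex_id[r])
                self._mark_dirty(cid)
                no_move.add(cid)
                if st.mol_comp_Dt[r][2] > 0:   # lifted off the membrane
                    self.state.com[st.complexes[cid].rows, 2] += 1e-3
                    st.invalidate_sites()
                reacted.add(glo)
        return reacted, no_move

    def _mark_dirty(self, cid: int) -> None:
        self._closure_dirty.add(cid)

    # -- phase c/d: pair reactions & implicit-surface binding --------------

    def _pair_probabilities(self, cands) -> np.ndarray:
        st = self.state
        n = len(cands)
        p = np.zeros(n)
        if n == 0:
            return p
        ilo, ihi = cands.rlo, cands.rhi
        slo, shi = cands.slo, cands.shi
        rid, r0 = cands.rule_id, cands.r0
        sp = st.site_positions()
        Di = st.mol_comp_Dt[ilo]
        Dj = st.mol_comp_Dt[ihi]
        for rule in self.order2:
            m = rid == rule.rule_id
            if not m.any():
                continue
            rcut_m = self.cutoffs.rcut_by_rule[rule.name]
            idx = np.nonzero(m)[0]
            on_mem = (Di[idx, 2] == 0.0) & (Dj[idx, 2] == 0.0)
            if rule.dimensionality == 2:
                use2d = np.ones(len(idx), dtype=bool)
            elif rule.projects_to_2d:
                use2d = on_mem
            else:
                use2d = np.zeros(len(idx), dtype=bool)
            sub3 = idx[~use2d]
            if len(sub3):
                D3 = Di[sub3].mean(axis=1) + Dj[sub3].mean(axis=1)
                # transiently overlapped pairs (concurrent moves can land two
                # sites inside sigma) are resolved by evaluating at contact
                r3 = np.maximum(r0[sub3], rule.sigma)
                ok = (r3 <= rcut_m) & (D3 > 0)
                if ok.any():
                    pv = np.zeros(len(sub3))
                    pv[ok] = fpr_kernels.p_react_3d(
                        r3[ok], self.dt, rule.ka_intrinsic, rule.sigma, D3[ok])
                    # reflecting boundaries: add the method-of-images term
                    # for every box face within reach, so pairs near a wall
                    # keep the exact free-space flux (the lost spherical cap
                    # comes back as the mirror partner's contribution)
                    si = sp[ilo[sub3[ok]], slo[sub3[ok]]]
                    sj = sp[ihi[sub3[ok]], shi[sub3[ok]]]
                    Dv = D3[ok]
                    for ax in range(3):
                        for wall in (0.0, self.box[ax]):
                            simg = sj.copy()
                            simg[:, ax] = 2.0 * wall - simg[:, ax]
                            rimg = np.linalg.norm(si - simg, axis=1)
                            near = rimg <= rcut_m
                            if near.any():
                                add = np.zeros(len(rimg))
                                add[near] = fpr_kernels.p_react_3d(
                                    np.maximum(rimg[near], rule.sigma),
                                    self.dt, rule.ka_intrinsic, rule.sigma,
                                    Dv[near])
                                okk = np.nonzero(ok)[0]
                                pv[okk] += add
                    p[sub3] = np.clip(pv, 0.0, 1.0)
            sub2 = idx[use2d]
            if len(sub2):
                ka2 = (rule.ka_intrinsic if rule.dimensionality == 2
                       else rule.ka2d_intrinsic)
                dxy = np.linalg.norm(
                    sp[ilo[sub2], slo[sub2], :2]
                    - sp[ihi[sub2], shi[sub2], :2], axis=1)
                dxy = np.maximum(dxy, rule.sigma)
                D2 = (Di[sub2, :2].mean(axis=1) + Dj[sub2, :2].mean(axis=1))
                ok = (dxy <= rcut_m) & (D2 > 0)
                if ok.any():
                    pv = np.zeros(len(sub2))
                    oki = np.nonzero(ok)[0]
                    si = sp[ilo[sub2], slo[sub2], :2]
                    sj = sp[ihi[sub2], shi[sub2], :2]
                    imgs = []
                    for ax in range(2):
                        for wall in (0.0, self.box[ax]):
                            simg = sj.copy()
                            simg[:, ax] = 2.0 * wall - simg[:, ax]
                            imgs.append(np.linalg.norm(si - simg, axis=1))
                    for Dval in np.unique(np.round(D2[oki], 12)):
                        g = oki[np.round(D2[oki], 12) == Dval]
                        pv[g] = fpr_kernels.p_react_2d(
                            dxy[g], self.dt, ka2, rule.sigma, float(Dval),
                            rmax=rcut_m)
                        for rimg in imgs:     # in-plane wall images
                            near = g[rimg[g] <= rcut_m]
                            if len(near):
                                pv[near] += fpr_kernels.p_react_2d(
                                    np.maximum(rimg[near], rule.sigma),
                                    self.dt, ka2, rule.sigma, float(Dval),
                                    rmax=rcut_m)
                    p[sub2] = np.clip(pv, 0.0, 1.0)
        return p

    def _pair_and_surface_phase(self, istep: int, cands, reacted_mols: set,
                                no_move: set) -> None:
        st = self.state
        p = self._pair_probabilities(cands)
        events = []
        for rule in self.order2:
            m = np.nonzero(cands.rule_id == rule.rule_id)[0]
            if len(m) == 0:
                continue
            base = _rng.key_base(self.seed, istep,
                                 _rng.PAIR * 64 + rule.rule_id)
            u = _rng.uniform(base, cands.glo[m],
                             cands.ghi[m] * 64 + cands.slo[m] * 8
                             + cands.shi[m])
            for k in m[np.nonzero(u < p[m])[0]]:
                events.append((int(cands.glo[k]), int(cands.ghi[k]), "pair",
                               (int(cands.rlo[k]), int(cands.rhi[k]),
                                int(cands.slo[k]), int(cands.shi[k]), rule)))

        rows = st.live_rows()
        sp_frozen = st.site_positions().copy() if len(rows) else None
        for rule in self.il_rules:
            free_n = self._il_pool_frozen.get(rule.rule_id, 0)
            if free_n <= 0:
                continue
            rho = free_n / self.config.area
            binder = rule.reactants[rule.binder_index]
            t = self.model.types[binder.mol]
            s = t.site_index(binder.site)
            rr = rows[(st.type_id[rows] == t.type_id)
                      & (st.bound_gid[rows, s] == -1)]
            if len(rr) == 0:
                continue
            z = sp_frozen[rr, s, 2]
            near = z <= self._il_zcut[rule.rule_id]
            rr, z = rr[near], z[near]
            if len(rr) == 0:
                continue
            # effective per-lipid capture rate: the pair's macroscopic
            # association rate (intrinsic rate convolved with diffusion),
            # i.e. the same per-trap rate an explicit membrane particle
            # realizes; a bare intrinsic rate would ignore the lateral
            # search for individual lipids
            k_trap = 1.0 / (1.0 / rule.ka_intrinsic
                            + 1.0 / (4.0 * math.pi * rule.sigma * rule.D_pair))
            Dz = st.mol_comp_Dt[rr, 2]
            pz = np.zeros(len(rr))
            moving = Dz > 0
            if moving.any():
                pz[moving] = fpr_kernels.p_bind_implicit_surface(
                    z[moving], self.dt, k_trap, rule.sigma, rho,
                    Dz[moving])
            planar = ~moving
            if planar.any() and rule.h:
                pz[planar] = np.clip(
                    (k_trap / rule.h) * rho * self.dt, 0.0, 1.0)
            base = _rng.key_base(self.seed, istep, _rng.IL_BIND)
            u = _rng.uniform(base, st.gid[rr], s)
            for r in rr[(u < pz)]:
                g = int(st.gid[r])
                events.append((g, g, "ilb", (int(r), int(s), rule)))

        # one-hop conflict voiding; first-order reacted molecules block
        events.sort(key=lambda e: (e[0], e[1], e[2]))
        first_of: dict = {g: -1 for g in reacted_mols}
        for k, ev in enumerate(events):
            first_of.setdefault(ev[0], k)
            first_of.setdefault(ev[1], k)
        for k, ev in enumerate(events):
            glo, ghi, tag, payload = ev
            if first_of[glo] != k or first_of[ghi] != k:
                continue
            if tag == "pair":
                ra, rb, sa, sb, rule = payload
                if self._execute_association(ra, sa, rb, sb, rule, cands,
                                             sp_frozen):
                    for rr2 in (ra, rb):
                        cid = int(st.complex_id[rr2])
                        no_move.add(cid)
                        self._mark_dirty(cid)
                    reacted_mols.update((glo, ghi))
            elif tag == "ilb":
                r, s, rule = payload
                cid = int(st.complex_id[r])
                rws = st.complexes[cid].rows
                spz = float(st.site_positions(np.array([r]))[0, s, 2])
                st.com[rws, 2] += rule.sigma - spz
                st.invalidate_sites()
                st.bind_surface(r, s, rule)
                if self.owns_gid(glo):
                    self.il_delta[rule.rule_id] = \
                        self.il_delta.get(rule.rule_id, 0) - 1
                cid = int(st.complex_id[r])
                no_move.add(cid)
                self._mark_dirty(cid)
                reacted_mols.add(glo)

    def _execute_association(self, ra, sa, rb, sb, rule, cands,
                             sp_frozen) -> bool:
        st = self.state
        if st.bound_gid[ra, sa] != -1 or st.bound_gid[rb, sb] != -1:
            return False
        cidA = int(st.complex_id[ra])
        cidB = int(st.complex_id[rb])
        if cidA == cidB:
            return False
        saved, _stat_cid, _mov_cid = st.place_bond_geometry(ra, sa, rb, sb, rule)
        if self._steric_violation(cidA, cidB, (ra, sa, rb, sb), cands,
                                  sp_frozen):
            st.restore_coords(saved)
            return False
        st.bind(ra, sa, rb, sb, rule)
        return True

    def _steric_violation(self, cidA, cidB, new_bond, cands,
                          sp_frozen) -> bool:
        """A reactive site pair other than the new bond inside its sigma,
        either across the merging complexes or against third parties."""
        st = self.state
        ra, sa, rb, sb = new_bond
        rowsA = st.complexes[cidA].rows
        rowsB = st.complexes[cidB].rows
        spA = st.site_positions(rowsA)
        spB = st.site_positions(rowsB)
        for rule in self.order2:
            pa, pb = rule.reactants
            for (p1, p2) in ((pa, pb), (pb, pa)):
                t1 = self.model.types[p1.mol]
                t2 = self.model.types[p2.mol]
                selA = st.type_id[rowsA] == t1.type_id
                selB = st.type_id[rowsB] == t2.type_id
                if not selA.any() or not selB.any():
                    continue
                m1 = rowsA[selA]
                m2 = rowsB[selB]
                for i1 in t1.sites_matching(p1.site):
                    for i2 in t2.sites_matching(p2.site):
                        q1 = spA[selA][:, i1]
                        q2 = spB[selB][:, i2]
                        d = np.linalg.norm(q1[:, None, :] - q2[None, :, :],
                                           axis=2)
                        close = d < rule.sigma * _STERIC_MARGIN
                        if not close.any():
                            continue
                        for a_i, b_i in zip(*np.nonzero(close)):
                            pair = (int(m1[a_i]), i1, int(m2[b_i]), i2)
                            if pair in ((ra, sa, rb, sb), (rb, sb, ra, sa)):
                                continue
                            return True
        # third parties (frozen positions): candidates with one side merged
        if len(cands) == 0:
            return False
        merged_rows = np.concatenate([rowsA, rowsB])
        ini = np.isin(cands.rlo, merged_rows)
        inj = np.isin(cands.rhi, merged_rows)
        ext = np.nonzero(ini ^ inj)[0]
        if len(ext) == 0:
            return False
        rowmap = {}
        for k, r in enumerate(rowsA):
            rowmap[int(r)] = spA[k]
        for k, r in enumerate(rowsB):
            rowmap[int(r)] = spB[k]
        for k in ext:
            i, j = int(cands.rlo[k]), int(cands.rhi[k])
            si, sj = int(cands.slo[k]), int(cands.shi[k])
            if ini[k]:
                pi = rowmap[i][si]
                pj = sp_frozen[j, sj]
            else:
                pi = sp_frozen[i, si]
                pj = rowmap[j][sj]
            if np.linalg.norm(pi - pj) < cands.sigma[k] * _STERIC_MARGIN:
                return True
        return False

    # -- phase e: propagation ----------------------------------------------

    def _propagate(self, istep: int, cands, no_move: set) -> None:
        st = self.state
        rows = st.live_rows()
        if len(rows) == 0:
            return
        # gid order makes every per-complex float reduction independent of
        # local row layout (required for rank-count invariance)
        rows = rows[np.argsort(st.gid[rows], kind="stable")]
        cid_rows = st.complex_id[rows]
        uniq, first_idx, inv = np.unique(cid_rows, return_index=True,
                                         return_inverse=True)
        U = len(uniq)
        Dt_u = st.mol_comp_Dt[rows[first_idx]]
        Drot_u = st.mol_comp_Drot[rows[first_idx]]
        counts = np.bincount(inv, minlength=U)
        movable = np.ones(U, dtype=bool)
        if no_move:
            movable &= ~np.isin(uniq, np.fromiter(no_move, np.int64,
                                                  len(no_move)))
        base = _rng.key_base(self.seed, istep, _rng.DIFF)
        gauss = np.stack([_rng.normal(base, uniq, ch) for ch in range(6)],
                         axis=1)
        rot_rows = self._rot_type[st.type_id[rows]]
        any_arm = np.zeros(U, dtype=bool)
        np.maximum.at(any_arm, inv, rot_rows)
        need_rot = (any_arm | (counts > 1)) & (Drot_u > 0) & movable
        on_mem = Dt_u[:, 2] == 0.0

        comp_com = np.stack(
            [np.bincount(inv, weights=st.com[rows, ax], minlength=U)
             for ax in range(3)], axis=1) / counts[:, None]

        dx = gauss[:, :3] * np.sqrt(2.0 * Dt_u * self.dt)
        dx[~movable] = 0.0
        ang = gauss[:, 3:] * np.sqrt(2.0 * Drot_u * self.dt)[:, None]
        ang[~need_rot] = 0.0
        ang[on_mem, 0] = 0.0
        ang[on_mem, 1] = 0.0
        dx = self._fold(comp_com, dx)

        # overlap screening against frozen step-start neighbor positions
        if len(cands):
            sp = st.site_positions()
            n = len(cands)
            ii, jj = cands.rlo, cands.rhi
            si, sj = cands.slo, cands.shi
            sg, d0 = cands.sigma, cands.r0
            row_to_u = np.full(st.n, -1, dtype=np.int64)
            row_to_u[rows] = inv
            ui = row_to_u[ii]
            uj = row_to_u[jj]

            def proposed_sites(rows_side, sites_side, u_side, dx_a, Rm_a):
                spo = sp[rows_side, sites_side]
                rel = spo - comp_com[u_side]
                return comp_com[u_side] + np.einsum(
                    "nij,nj->ni", Rm_a[u_side], rel) + dx_a[u_side]

            Rm = quat_to_matrix(quat_from_euler_small(ang))
            viol_u = np.zeros(U, dtype=bool)
            for (us, rs, ss, ro, so) in ((ui, ii, si, jj, sj),
                                         (uj, jj, sj, ii, si)):
                mv = (us >= 0) & movable[np.clip(us, 0, U - 1)]
                if mv.any():
                    dn = np.linalg.norm(
                        proposed_sites(rs[mv], ss[mv], us[mv], dx, Rm)
                        - sp[ro[mv], so[mv]], axis=1)
                    bad = (dn < sg[mv]) & (dn < d0[mv])
                    viol_u[us[mv][bad]] = True

            # Metropolis-style rejection: an overlapping proposal leaves the
            # complex in place for this step.  Re-drawing alternative moves
            # instead would sample only the outward part of the proposal
            # distribution for near-contact pairs and measurably deplete the
            # contact shell (and with it the association flux), so rejected
            # complexes simply do not move.
            if viol_u.any():
                dx[viol_u] = 0.0
                ang[viol_u] = 0.0

        # commit
        Rq = quat_from_euler_small(ang)
        Rm = quat_to_matrix(Rq)
        rel = st.com[rows] - comp_com[inv]
        st.com[rows] = comp_com[inv] + np.einsum("uij,uj->ui", Rm[inv], rel) \
            + dx[inv]
        rot_members = need_rot[inv] & rot_rows
        if rot_members.any():
            rr = rows[rot_members]
            st.quat[rr] = quat_normalize(quat_multiply(
                Rq[inv[rot_members]], st.quat[rr]))
        # members of rotated multi-molecule complexes also reorient
        multi_rot = need_rot[inv] & ~rot_rows & (counts[inv] > 1)
        if multi_rot.any():
            rr = rows[multi_rot]
            st.quat[rr] = quat_normalize(quat_multiply(
                Rq[inv[multi_rot]], st.quat[rr]))
        st.invalidate_sites()

    def _fold(self, com: np.ndarray, dx: np.ndarray) -> np.ndarray:
        """Mirror-reflect complex-COM targets at the box faces."""
        tgt = com + dx
        fold = tgt.copy()
        for ax in range(3):
            m = fold[:, ax] < 0
            fold[m, ax] = -fold[m, ax]
            m = fold[:, ax] > self.box[ax]
            fold[m, ax] = 2 * self.box[ax] - fold[m, ax]
            np.clip(fold[:, ax], 0.0, self.box[ax], out=fold[:, ax])
        return dx + (fold - tgt)


def _poisson_from_uniform(u: np.ndarray, lam: float) -> np.ndarray:
    """Inverse-CDF Poisson sampling from keyed uniforms (small lambda)."""
    out = np.zeros(len(u), dtype=np.int64)
    if lam <= 0:
        return out
    p = math.exp(-lam)
    cdf = np.full(len(u), p)
    term = np.full(len(u), p)
    k = 0
    pending = u > cdf
    while pending.any() and k < 200:
        k += 1
        term = term * lam / k
        cdf = cdf + term
        out[pending & (u <= cdf)] = k
        pending = u > cdf
    out[pending] = k
    return out
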