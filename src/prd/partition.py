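"""Sub-volume (cell-list) partitioning and neighbor enumeration.

Pairwise reaction probabilities fall to zero beyond the cutoff Rcut, so
instead of looping over all pairs the box is divided into rectangular
sub-volumes with side length >= Rcut in each dimension.  A molecule then
only needs to be compared against molecules in its own cell and the
"forward" half (13) of the 26 neighboring cells, which enumerates every
unordered cell pair exactly once.

Too many cells wastes memory and bookkeeping when cells outnumber
molecules, so the total cell count is capped (y then z then x reduced,
largest first) while the x dimension keeps the minimal Rcut-derived size
whenever possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAX_TOTAL_CELLS = 50_000

# forward half-shell of the 27-neighborhood: self + 13 offsets, chosen so
# that offset > (0,0,0) in lexicographic (z, y, x) order
_FORWARD_OFFSETS = np.array(
    [(dx, dy, dz)
     for dz in (0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
     if (dz, dy, dx) > (0, 0, 0)], dtype=np.int64)
assert len(_FORWARD_OFFSETS) == 13


@dataclass
class SubvolumeGrid:
    """Rectangular cell grid over the box."""
    box: np.ndarray
    shape: tuple                      # (nx, ny, nz)
    cell_len: np.ndarray              # (3,) nm
    rcut: float
    cell_of_row: np.ndarray = field(default=None, repr=False)
    _order: np.ndarray = field(default=None, repr=False)
    _starts: np.ndarray = field(default=None, repr=False)

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def cell_index(self, pos: np.ndarray) -> np.ndarray:
        """Flat cell index per position (clipped into the box)."""
        nx, ny, nz = self.shape
        idx = np.empty(len(pos), dtype=np.int64)
        ix = np.clip((pos[:, 0] / self.cell_len[0]).astype(np.int64), 0, nx - 1)
        iy = np.clip((pos[:, 1] / self.cell_len[1]).astype(np.int64), 0, ny - 1)
        iz = np.clip((pos[:, 2] / self.cell_len[2]).astype(np.int64), 0, nz - 1)
        idx = (iz * self.shape[1] + iy) * self.shape[0] + ix
        return idx

    def x_column(self, cell: np.ndarray) -> np.ndarray:
        return cell % self.shape[0]

    def assign(self, positions: np.ndarray, rows: np.ndarray) -> None:
        """Bucket the given rows by cell (counting-sort layout for lookups)."""
        cells = self.cell_index(positions)
        order = np.argsort(cells, kind="stable")
        self.cell_of_row = cells
        self._rows = rows[order]
        self._cells_sorted = cells[order]
        self._starts = np.searchsorted(self._cells_sorted,
                                       np.arange(self.n_cells + 1))

    def rows_in_cell(self, cell: int) -> np.ndarray:
        return self._rows[self._starts[cell]:self._starts[cell + 1]]

    def occupied_cells(self) -> np.ndarray:
        return np.unique(self._cells_sorted)


def build_grid(box, rcut: float, max_total_cells: int = MAX_TOTAL_CELLS) -> SubvolumeGrid:
    """Grid with cell side >= rcut per dimension, capped in total count.

    ``n_d = floor(L_d / rcut)`` (at least 1); if the product exceeds the cap
    the dimensions are reduced uniformly, largest count first, y/z before x.
    """
    box = np.asarray(box, dtype=np.float64)
    if rcut <= 0:
        raise ValueError("rcut must be positive")
    counts = np.maximum(np.floor(box / rcut).astype(np.int64), 1)
    # reduce to the cap: shrink the largest of (ny, nz) first, then nx
    while int(np.prod(counts)) > max_total_cells:
        yz = max(counts[1], counts[2])
        if yz > 1:
            d = 1 if counts[1] >= counts[2] else 2
        else:
            d = 0
        counts[d] = max(counts[d] - max(counts[d] // 8, 1), 1)
    shape = (int(counts[0]), int(counts[1]), int(counts[2]))
    return SubvolumeGrid(box=box, shape=shape, cell_len=box / counts, rcut=rcut)


def forward_neighbors(grid: SubvolumeGrid, cell: int) -> np.ndarray:
    """The <=13 in-box forward neighbor cells of ``cell``."""
    nx, ny, nz = grid.shape
    ix = cell % nx
    iy = (cell // nx) % ny
    iz = cell // (nx * ny)
    n = _FORWARD_OFFSETS + (ix, iy, iz)
    ok = ((n[:, 0] >= 0) & (n[:, 0] < nx) & (n[:, 1] >= 0) & (n[:, 1] < ny)
          & (n[:, 2] >= 0) & (n[:, 2] < nz))
    n = n[ok]
    return (n[:, 2] * ny + n[:, 1]) * nx + n[:, 0]


def candidate_row_pairs(grid: SubvolumeGrid) -> tuple:
    """All unordered row pairs from same-cell and forward-neighbor cells.

    Returns two int arrays (rows_i, rows_j); no distance or rule filtering.
    Each unordered pair appears exactly once.  Fully vectorized: for every
    molecule and every one of the 14 (self + forward) cell offsets, the
    occupants of the target cell are gathered by repeat/cumsum indexing.
    """
    rows_sorted = grid._rows
    m = len(rows_sorted)
    if m == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z.copy()
    nx, ny, nz = grid.shape
    cells = grid._cells_sorted
    ix = cells % nx
    iy = (cells // nx) % ny
    iz = cells // (nx * ny)
    pos = np.arange(m)
    starts = grid._starts
    out_i, out_j = [], []
    offsets = np.vstack([[0, 0, 0], _FORWARD_OFFSETS])
    for k, (dx, dy, dz) in enumerate(offsets):
        jx, jy, jz = ix + dx, iy + dy, iz + dz
        ok = ((jx >= 0) & (jx < nx) & (jy >= 0) & (jy < ny)
              & (jz >= 0) & (jz < nz))
        if not ok.any():
            continue
        src = pos[ok]
        ncell = (jz[ok] * ny + jy[ok]) * nx + jx[ok]
        s = starts[ncell]
        cnt = starts[ncell + 1] - s
        tot = int(cnt.sum())
        if tot == 0:
            continue
        rep_src = np.repeat(src, cnt)
        csum = np.concatenate(([0], np.cumsum(cnt)[:-1]))
        jpos = np.repeat(s, cnt) + (np.arange(tot) - np.repeat(csum, cnt))
        if k == 0:  # same cell: count each unordered pair once
            keep = jpos > rep_src
            rep_src, jpos = rep_src[keep], jpos[keep]
        out_i.append(rows_sorted[rep_src])
        out_j.append(rows_sorted[jpos])
    if not out_i:
        z = np.zeros(0, dtype=np.int64)
        return z, z.copy()
    return np.concatenate(out_i), np.concatenate(out_j)


@dataclass
class PairCandidates:
    """Array-of-columns view of the reactive candidate pairs, canonically
    ordered by (gid_lo, gid_hi, rule_id)."""
    glo: np.ndarray
    ghi: np.ndarray
    rlo: np.ndarray        # row of the gid_lo molecule
    rhi: np.ndarray
    slo: np.ndarray        # reacting site index on each side
    shi: np.ndarray
    rule_id: np.ndarray
    r0: np.ndarray         # site-site separation, nm
    sigma: np.ndarray      # per-pair rule sigma (overlap checks)
    rules: list            # rule_id -> ReactionRule (model order)

    def __len__(self) -> int:
        return len(self.glo)

    @classmethod
    def empty(cls, rules) -> "PairCandidates":
        z = np.zeros(0, dtype=np.int64)
        f = np.zeros(0)
        return cls(z, z.copy(), z.copy(), z.copy(), z.copy(), z.copy(),
                   z.copy(), f, f.copy(), rules)


def pair_candidates(state, grid: SubvolumeGrid, rules, rcut: float,
                    rows: np.ndarray | None = None) -> PairCandidates:
    """Reactive pair candidates within ``rcut``, canonically ordered.

    For every order-2 rule and every unordered molecule pair whose types,
    free-site states and context match the rule with site-site separation
    r0 <= rcut, emit the pair exactly once, sorted by (gid_lo, gid_hi,
    rule_id, site pair).  When several rules match the same site pair the
    most specific one (most context conditions) wins.

    The grid must have been assigned with the molecule COM positions of
    ``rows`` and its cell size must include the site-arm allowance so that
    site-site proximity is never missed by COM binning.
    """
    all_rules = list(rules)
    ri, rj = candidate_row_pairs(grid)
    if len(ri) == 0:
        return PairCandidates.empty(all_rules)
    # COM-distance prefilter: site-site separation <= rcut implies COM
    # separation <= rcut + both site arms
    lmax = float(np.linalg.norm(state.type_site_offsets, axis=2).max()) \
        if state.type_site_offsets.size else 0.0
    dcom = state.com[ri] - state.com[rj]
    keep = np.einsum("ij,ij->i", dcom, dcom) <= (rcut + 2 * lmax) ** 2
    ri, rj = ri[keep], rj[keep]
    if len(ri) == 0:
        return PairCandidates.empty(all_rules)
    sp = state.site_positions()
    tid = state.type_id
    order2 = sorted(
        (r for r in all_rules if r.order == 2 and not r.implicit_surface),
        key=lambda r: (-sum(len(p.context) for p in r.reactants), r.rule_id))
    cols = {k: [] for k in ("glo", "ghi", "rlo", "rhi", "slo", "shi",
                            "rid", "r0", "spec")}
    for spec_rank, rule in enumerate(order2):
        seen_orient = set()
        ra_, rb_ = rule.reactants
        # heteromeric rules match both row orderings in one pass (swap);
        # homomeric rules need both site orientations enumerated
        orients = ((ra_, rb_),) if ra_.mol != rb_.mol else ((ra_, rb_),
                                                            (rb_, ra_))
        for (pa, pb) in orients:
          for sa in state.model.types[pa.mol].sites_matching(pa.site):
           for sb in state.model.types[pb.mol].sites_matching(pb.site):
            ta = state.model.types[pa.mol].type_id
            tb = state.model.types[pb.mol].type_id
            okey = (ta, sa, tb, sb, tuple(pa.context), tuple(pb.context))
            if okey in seen_orient:     # identical homomeric orientation
                continue
            seen_orient.add(okey)
            m = (tid[ri] == ta) & (tid[rj] == tb)
            if ta != tb:
                m |= (tid[ri] == tb) & (tid[rj] == ta)
            if not m.any():
                continue
            ii, jj = ri[m], rj[m]
            if ta != tb:                # normalize so ii carries pattern a
                swap = tid[ii] != ta
                ii2 = np.where(swap, jj, ii)
                jj = np.where(swap, ii, jj)
                ii = ii2
            free = (state.bound_gid[ii, sa] == -1) \
                & (state.bound_gid[jj, sb] == -1)
            ii, jj = ii[free], jj[free]
            if len(ii) == 0:
                continue
            ok = _context_mask(state, ii, pa) & _context_mask(state, jj, pb)
            ii, jj = ii[ok], jj[ok]
            if len(ii) == 0:
                continue
            d = np.linalg.norm(sp[ii, sa] - sp[jj, sb], axis=1)
            near = (d <= rcut) \
                & (state.complex_id[ii] != state.complex_id[jj])
            ii, jj, d = ii[near], jj[near], d[near]
            if len(ii) == 0:
                continue
            gi = state.gid[ii]
            gj = state.gid[jj]
            flip = gi > gj
            cols["glo"].append(np.where(flip, gj, gi))
            cols["ghi"].append(np.where(flip, gi, gj))
            cols["rlo"].append(np.where(flip, jj, ii))
            cols["rhi"].append(np.where(flip, ii, jj))
            cols["slo"].append(np.where(flip, sb, sa))
            cols["shi"].append(np.where(flip, sa, sb))
            cols["rid"].append(np.full(len(ii), rule.rule_id, dtype=np.int64))
            cols["r0"].append(d)
            cols["spec"].append(np.full(len(ii), spec_rank, dtype=np.int64))
    if not cols["glo"]:
        return PairCandidates.empty(all_rules)
    a = {k: np.concatenate(v) for k, v in cols.items()}
    # specificity dedup on (glo, ghi, slo, shi)
    order = np.lexsort((a["spec"], a["shi"], a["slo"], a["ghi"], a["glo"]))
    for k in a:
        a[k] = a[k][order]
    dup = np.zeros(len(a["glo"]), dtype=bool)
    if len(dup) > 1:
        dup[1:] = ((a["glo"][1:] == a["glo"][:-1])
                   & (a["ghi"][1:] == a["ghi"][:-1])
                   & (a["slo"][1:] == a["slo"][:-1])
                   & (a["shi"][1:] == a["shi"][:-1]))
    keep = ~dup
    for k in a:
        a[k] = a[k][keep]
    order = np.lexsort((a["shi"], a["slo"], a["rid"], a["ghi"], a["glo"]))
    for k in a:
        a[k] = a[k][order]
    sig = np.array([r.sigma for r in all_rules]) if all_rules else np.zeros(0)
    return PairCandidates(a["glo"], a["ghi"], a["rlo"], a["rhi"],
                          a["slo"], a["shi"], a["rid"], a["r0"],
                          sig[a["rid"]], all_rules)


def _context_mask(state, rows_arr: np.ndarray, pat) -> np.ndarray:
    ok = np.ones(len(rows_arr), dtype=bool)
    t = state.model.types[pat.mol]
    for cs, cond in pat.context:
        ci = t.site_index(cs)
        bound = state.bound_gid[rows_arr, ci] != -1
        ok &= bound if cond == "bound" else ~bound
    return ok
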