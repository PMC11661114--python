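"""Reference solutions, estimators, scaling metrics and benchmark builders.

Everything the simulator is validated against lives here: the closed-form
reversible bimolecular time course, auto-generated mass-action ODEs for
ring-oligomer assembly, the iterative ring-equilibrium solver, a 1D-in-z
method-of-lines diffusion-adsorption reference for membrane binding, MSD
estimation, the strong/weak scaling metrics, and programmatic builders for
the benchmark systems (bimolecular association in 3D, 2D, 3D->2D with
explicit or implicit membrane species, trimer/hexamer ring assembly, and
hexagonal lattice formation), each with a ``scale`` knob that shrinks box
and copy numbers together for desk-scale runs at unchanged concentrations
and rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import model_io as mio
from ._units import rate1_to_display


# --------------------------------------------------------------------------
# closed-form and ODE references

def reversible_bimolecular_equilibrium(A0, B0, kon, koff) -> float:
    """Equilibrium bound concentration x of A + B <-> AB (quadratic root).

    Units: any consistent set (kon in 1/(conc time), koff in 1/time).
    """
    if kon == 0:
        return 0.0
    Kd = koff / kon
    b = A0 + B0 + Kd
    disc = b * b - 4.0 * A0 * B0
    return (b - math.sqrt(max(disc, 0.0))) / 2.0


def analytic_reversible_bimolecular(A0, B0, kon, koff, t, x0=0.0) -> dict:
    """Closed-form time course of A + B <-> AB.

    Returns {"A": ..., "B": ..., "AB": ...} concentration arrays at times
    ``t``.  The bound concentration follows the two-root logistic form with
    equilibrium at the smaller root of kon(A0-x)(B0-x) = koff x.
    """
    t = np.asarray(t, dtype=float)
    if kon == 0:
        x = x0 * np.exp(-koff * t)
    else:
        Kd = koff / kon
        b = A0 + B0 + Kd
        disc = math.sqrt(max(b * b - 4.0 * A0 * B0, 0.0))
        xm = (b - disc) / 2.0
        xp = (b + disc) / 2.0
        e = np.exp(-kon * (xp - xm) * t)
        x = (xm * (xp - x0) - xp * (xm - x0) * e) / ((xp - x0) - (xm - x0) * e)
    return {"A": A0 - x, "B": B0 - x, "AB": x}


def equilibrium_deff(A0, B0, kon, koff, D_mono, D_dimer) -> float:
    """Population-weighted diffusion of A-containing species at equilibrium:
    ([A] D_A + [AB] D_dimer) / ([A] + [AB])."""
    x = reversible_bimolecular_equilibrium(A0, B0, kon, koff)
    fa = A0 - x
    return (fa * D_mono + x * D_dimer) / (fa + x)


def assembly_ode(n_max: int, kon: float, koff: float, kclose: float,
                 c_tot: float, t_eval, ring: bool = True,
                 sigma: float | None = None,
                 D_monomer: float | None = None) -> dict:
    """Mass-action ODEs for ring-oligomer assembly, integrated stiffly.

    Species: linear chains C_1..C_{n_max} (each with one free head and one
    free tail site) and, if ``ring``, the closed n_max-ring R.  Statistical
    factors follow the per-distinguishable-site-pair convention:

    * join C_i + C_j -> C_{i+j}: flux 2 kon_ij c_i c_j for i != j (head-tail
      and tail-head pairings) and kon_ii c_i^2 for i == j;
    * every bond breaks at its intrinsic rate; chain C_n fragments via each
      of its n-1 bonds, the ring opens via each of its n bonds to C_n;
    * the open n_max-chain closes at kclose (first-order; the ends do not
      diffuse relative to each other).

    If ``sigma`` (nm) and ``D_monomer`` (nm^2/us) are given, the
    macroscopic rates are made diffusion-aware: the intrinsic pair (ka, kb)
    is recovered from (kon, koff) for the monomer-monomer encounter and
    reconvolved per species pair with the Einstein-Stokes complex diffusion
    D_k = D_monomer / k, so the slowdown of larger oligomers is part of the
    reference.  The bond equilibrium constant ka/kb (and hence the
    equilibrium ladder) is unchanged by this.  Otherwise a single (kon,
    koff) applies to every channel.

    Chains longer than n_max are sterically excluded (the ring geometry
    folds the chain back onto itself).  Units: kon in 1/(conc time), koff
    and kclose in 1/time; ``c_tot`` total monomer concentration.
    """
    n = n_max
    nsp = n + (1 if ring else 0)

    kon_pair = np.full((n + 1, n + 1), kon)
    koff_pair = np.full((n + 1, n + 1), koff)
    ring_open = koff          # per-bond ring-opening rate
    if sigma is not None and D_monomer is not None:
        from . import rate_theory as rt
        from ._units import UM_INV_S_TO_NM3_US
        # kon arrives in uM^-1 s^-1; convert to nm^3/us for the intrinsic
        # inversion, then scale each channel by its encounter factor
        kon_nm = kon * UM_INV_S_TO_NM3_US
        ka = rt.ka_from_kon_3d(kon_nm, sigma, 2 * D_monomer)
        for i in range(1, n + 1):
            for j in range(1, n + 1):
                Dij = D_monomer / i + D_monomer / j
                kon_ij = rt.kon_from_ka_3d(ka, sigma, Dij)
                kon_pair[i, j] = kon * kon_ij / kon_nm
                koff_pair[i, j] = koff * kon_ij / kon_nm
        # ring bonds open at the intrinsic rate: the complex stays intact,
        # so there is no diffusional re-encounter to convolve
        ring_open = koff * ka / kon_nm

    def rhs(_t, y):
        dy = np.zeros(nsp)
        for i in range(1, n + 1):
            for j in range(i, n + 1 - i):
                flux = (kon_pair[i, j] * y[i - 1] * y[j - 1]
                        * (2.0 if i != j else 1.0))
                dy[i - 1] -= flux
                dy[j - 1] -= flux
                dy[i + j - 1] += flux
        for m in range(2, n + 1):
            cm = y[m - 1]
            for k in range(1, m):       # bond k -> fragments (k, m-k)
                kf = koff_pair[k, m - k]
                dy[m - 1] -= kf * cm
                dy[k - 1] += kf * cm
                dy[m - k - 1] += kf * cm
        if ring:
            dy[n - 1] += -kclose * y[n - 1] + n * ring_open * y[n]
            dy[n] = kclose * y[n - 1] - n * ring_open * y[n]
        return dy

    y0 = np.zeros(nsp)
    y0[0] = c_tot
    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), y0, t_eval=t_eval,
                    method="LSODA", rtol=1e-9, atol=1e-12 * max(c_tot, 1.0))
    if not sol.success:
        raise RuntimeError(f"assembly ODE integration failed: {sol.message}")
    out = {f"C{i}": sol.y[i - 1] for i in range(1, n + 1)}
    if ring:
        out["ring"] = sol.y[n]
    return out


def ring_equilibrium(Keq_bond: float, kclose_ratio: float, n_max: int,
                     total: float) -> dict:
    """Equilibrium species ladder with ring closure, by monomer bisection.

    Detailed balance of the assembly kinetics gives chains
    ``c_n = K^(n-1) c1^n`` (K = kon/koff per site pair) and the ring
    ``c_R = (kclose_ratio / n_max) K^(n_max - 1) c1^n_max`` with
    ``kclose_ratio = kclose / koff``.  The monomer concentration is solved
    so total monomers are conserved to 1e-10 relative.
    """
    if total <= 0:
        raise ValueError("total must be positive")

    def conserved(c1):
        s = 0.0
        for m in range(1, n_max + 1):
            s += m * (Keq_bond ** (m - 1)) * c1 ** m
        s += n_max * (kclose_ratio / n_max) * (Keq_bond ** (n_max - 1)) \
            * c1 ** n_max
        return s - total

    if Keq_bond == 0 and kclose_ratio == 0:
        c1 = total
    else:
        c1 = brentq(conserved, 0.0, total, xtol=1e-14 * total, rtol=1e-12)
    out = {f"C{m}": (Keq_bond ** (m - 1)) * c1 ** m
           for m in range(1, n_max + 1)}
    out["ring"] = (kclose_ratio / n_max) * (Keq_bond ** (n_max - 1)) \
        * c1 ** n_max
    check = sum(m * out[f"C{m}"] for m in range(1, n_max + 1)) \
        + n_max * out["ring"]
    if abs(check - total) > 1e-8 * total:
        raise RuntimeError("ring equilibrium failed to conserve monomers")
    return out


def adsorption_1d(Lz: float, Dz: float, ka: float, kb: float,
                  c0_vol: float, rho_l0: float, t_eval,
                  n_cells: int = 120) -> dict:
    """Method-of-lines reference for 3D -> surface adsorption kinetics.

    Solves dc/dt = Dz c'' on z in (0, Lz) with a reactive bottom boundary
    (flux = ka * rho_free * c(0), rho_free = rho_l0 - b) and reflecting
    top; the bound surface density b obeys db/dt = ka rho_free c(0) - kb b.
    Units nm/us; c in nm^-3, rho in nm^-2.  Returns bound density b(t) and
    mean volume concentration.
    """
    dz = Lz / n_cells

    def rhs(_t, y):
        c = y[:-1]
        b = y[-1]
        rho_free = max(rho_l0 - b, 0.0)
        dc = np.empty_like(c)
        dc[1:-1] = Dz * (c[2:] - 2 * c[1:-1] + c[:-2]) / dz ** 2
        flux_bot = ka * rho_free * c[0]          # nm^-2 / us
        dc[0] = Dz * (c[1] - c[0]) / dz ** 2 - flux_bot / dz + kb * b / dz
        dc[-1] = Dz * (c[-2] - c[-1]) / dz ** 2
        db = flux_bot - kb * b
        return np.concatenate([dc, [db]])

    y0 = np.concatenate([np.full(n_cells, c0_vol), [0.0]])
    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), y0, t_eval=t_eval,
                    method="BDF", rtol=1e-7, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"adsorption reference failed: {sol.message}")
    return {"bound": sol.y[-1], "c_mean": sol.y[:-1].mean(axis=0)}


# --------------------------------------------------------------------------
# estimators

def msd_estimator(positions: np.ndarray, axis: int, lags) -> dict:
    """Mean-squared displacement per lag with standard errors and fitted D.

    ``positions``: (T, N) coordinate samples along one axis at uniform
    sampling interval; ``lags``: iterable of integer lag counts.  D is the
    origin-constrained slope of MSD(lag)/2 per unit lag (the caller scales
    by the sampling interval).  Requires >= 100 displacement samples per
    lag.
    """
    positions = np.asarray(positions)
    out_lags, msd, se = [], [], []
    for lag in lags:
        disp = positions[lag:] - positions[:-lag]
        d2 = (disp ** 2).ravel()
        if len(d2) < 100:
            raise ValueError(f"lag {lag}: only {len(d2)} displacement samples")
        out_lags.append(lag)
        msd.append(float(d2.mean()))
        se.append(float(d2.std(ddof=1) / math.sqrt(len(d2))))
    lags_a = np.asarray(out_lags, dtype=float)
    msd_a = np.asarray(msd)

    # origin-constrained WLS slope per particle group; the spread across
    # groups gives an error estimate robust to the overlapping-window and
    # cross-lag correlations of MSD samples
    def fit(block):
        m = np.array([((block[lag:] - block[:-lag]) ** 2).mean()
                      for lag in lags])
        floor = 1e-12 * max(float(msd_a.max()), 1.0)
        w = 1.0 / np.maximum(np.asarray(se), floor) ** 2
        return float(np.sum(w * lags_a * m) / np.sum(w * lags_a ** 2) / 2.0)

    n_groups = min(10, positions.shape[1])
    bounds = np.linspace(0, positions.shape[1], n_groups + 1).astype(int)
    d_groups = [fit(positions[:, bounds[g]:bounds[g + 1]])
                for g in range(n_groups) if bounds[g + 1] > bounds[g]]
    D = float(np.mean(d_groups))
    se_D = float(np.std(d_groups, ddof=1) / math.sqrt(len(d_groups))) \
        if len(d_groups) > 1 else float("nan")
    return {"lags": lags_a, "msd": msd_a, "se": np.asarray(se),
            "D": D, "se_D": se_D}


@dataclass
class ScalingReport:
    """Strong/weak scaling metrics from wall-clock timings."""
    p: list = field(default_factory=list)
    speedup: dict = field(default_factory=dict)       # S(p) = T1/Tp
    e_strong: dict = field(default_factory=dict)      # T1/(p Tp)
    e_weak: dict = field(default_factory=dict)        # T1w/Tpw


def scaling_metrics(strong: dict | None = None,
                    weak: dict | None = None) -> ScalingReport:
    """Compute S(p), Estrong(p), Eweak(p) from {p: wall seconds} timings.

    ``strong`` holds fixed-size timings (Tcomp + Tcomm), ``weak`` holds
    fixed-per-rank-size timings; both need p=1.  Linear scaling gives
    S(p) = p and efficiencies of 1.
    """
    rep = ScalingReport()
    if strong:
        if 1 not in strong:
            raise ValueError("strong timings require p=1")
        t1 = strong[1]
        for p, tp in sorted(strong.items()):
            rep.speedup[p] = t1 / tp
            rep.e_strong[p] = t1 / (p * tp)
    if weak:
        if 1 not in weak:
            raise ValueError("weak timings require p=1")
        t1 = weak[1]
        for p, tp in sorted(weak.items()):
            rep.e_weak[p] = t1 / tp
    rep.p = sorted(set(list((strong or {}).keys())
                       + list((weak or {}).keys())))
    return rep


# --------------------------------------------------------------------------
# benchmark builders

_POINT = np.zeros((1, 3))


def _ring_monomer(name: str, interior_deg: float, arm: float, Dt, Drot):
    """Two-site monomer whose arms subtend the ring's interior angle."""
    half = math.radians(interior_deg) / 2.0
    offs = np.array([[math.cos(half), math.sin(half), 0.0],
                     [math.cos(half), -math.sin(half), 0.0]]) * arm
    return mio.MoleculeType(name, ["c", "q"], offs, Dt, Drot)


def _triskelion(arm_td: float, Dt, Drot):
    """Three coplanar legs at 120 degrees plus a central adaptor site."""
    sites, offs = [], []
    for k in range(3):
        a = 2.0 * math.pi * k / 3.0
        sites.append(f"td{k + 1}")
        offs.append([arm_td * math.cos(a), arm_td * math.sin(a), 0.0])
    sites.append("ap")
    offs.append([0.0, 0.0, 0.0])
    return mio.MoleculeType("trisk", sites, np.array(offs), Dt, Drot)


BENCHMARKS = ("bimol3d", "bimol2d", "bimol3d2d", "implicit2d",
              "trimer", "trimer-small", "hexamer", "hexamer-small",
              "lattice")


def build_benchmark(name: str, scale: float = 1.0, seed: int = 0,
                    dt: float | None = None, n_iterations: int = 0,
                    output_every: int = 100) -> mio.Model:
    """Parse-ready model for a named benchmark system.

    ``scale`` < 1 shrinks box volume and copy numbers together (desk-scale
    variants at unchanged concentrations, diffusion constants, rates and
    timestep).  The box x-length carries the full scale factor so that the
    x-asymmetric geometry (and hence domain decomposition) is preserved.
    """
    if name not in BENCHMARKS:
        raise ValueError(f"unknown benchmark {name!r}; choose from {BENCHMARKS}")
    s = float(scale)

    def scaled_box(box):
        return [box[0] * s, box[1], box[2]]

    def n_of(n):
        return max(int(round(n * s)), 2)

    types: dict = {}
    rules: list = []
    membrane = False
    il_copies = 0
    box = [20000.0, 2000.0, 2000.0]
    dt_use = 0.1 if dt is None else dt

    if name == "bimol3d":
        types["A"] = mio.MoleculeType("A", ["b"], _POINT, [10, 10, 10], 0.0)
        types["B"] = mio.MoleculeType("B", ["b"], _POINT, [10, 10, 10], 0.0)
        rules.append(mio.ReactionRule(
            name="ab", order=2, text="A(b) + B(b) <-> A(b!1).B(b!1)",
            reactants=[mio.SitePattern("A", "b"), mio.SitePattern("B", "b")],
            kon_macro=100.0, koff_macro=10.0, sigma=2.0))
        copies = {"A": n_of(10000), "B": n_of(10000)}
    elif name == "bimol2d":
        membrane = True
        types["C"] = mio.MoleculeType("C", ["b"], _POINT, [2, 2, 0], 0.0,
                                      is_2d=True)
        types["D"] = mio.MoleculeType("D", ["b"], _POINT, [2, 2, 0], 0.0,
                                      is_2d=True)
        r = mio.ReactionRule(
            name="cd", order=2, text="C(b) + D(b) <-> C(b!1).D(b!1)",
            reactants=[mio.SitePattern("C", "b"), mio.SitePattern("D", "b")],
            ka_intrinsic=0.53, kb_intrinsic=15.9, sigma=2.0)
        r.dimensionality = 2
        rules.append(r)
        copies = {"C": n_of(10000), "D": n_of(10000)}
    elif name == "bimol3d2d":
        membrane = True
        types["E"] = mio.MoleculeType("E", ["b"], _POINT, [10, 10, 10], 0.0)
        types["F"] = mio.MoleculeType("F", ["b"], _POINT, [2, 2, 0], 0.0,
                                      is_2d=True)
        rules.append(mio.ReactionRule(
            name="ef", order=2, text="E(b) + F(b) <-> E(b!1).F(b!1)",
            reactants=[mio.SitePattern("E", "b"), mio.SitePattern("F", "b")],
            kon_macro=55.0, koff_macro=5.5, sigma=1.0))
        copies = {"E": n_of(10000), "F": n_of(10000)}
    elif name == "implicit2d":
        membrane = True
        types["G"] = mio.MoleculeType("G", ["b"], _POINT, [10, 10, 10], 0.0)
        types["H"] = mio.MoleculeType("H", ["head"], _POINT, [2, 2, 0], 0.0,
                                      is_2d=True, is_implicit_surface=True)
        rules.append(mio.ReactionRule(
            name="gh", order=2, text="G(b) + H(head) <-> G(b!1).H(head!1)",
            reactants=[mio.SitePattern("G", "b"),
                       mio.SitePattern("H", "head")],
            kon_macro=55.0, koff_macro=5.5, sigma=1.0, h=2.0))
        copies = {"G": n_of(10000), "H": n_of(10000)}
        il_copies = n_of(10000)
    elif name.startswith("trimer") or name.startswith("hexamer"):
        trimer = name.startswith("trimer")
        small = name.endswith("small")
        interior = 60.0 if trimer else 120.0
        sigma = 0.73 if trimer else 1.0
        if small:
            box = [5000.0, 100.0, 100.0]
            kon, koff = (10.86, 901.6) if trimer else (11.16, 926.3)
            n0 = 6022
        else:
            kon, koff = (38.96, 6.47) if trimer else (43.08, 7.15)
            n0 = 20000
        types["A"] = _ring_monomer("A", interior, 1.0, [10, 10, 10], 0.1)
        rules.append(mio.ReactionRule(
            name="cq", order=2, text="A(c) + A(q) <-> A(c!1).A(q!1)",
            reactants=[mio.SitePattern("A", "c"), mio.SitePattern("A", "q")],
            kon_macro=kon, koff_macro=koff, sigma=sigma,
            is_loop_closure_eligible=True))
        copies = {"A": n_of(n0)}
    elif name == "lattice":
        membrane = True
        types["trisk"] = _triskelion(10.0, [13, 13, 13], 0.03)
        types["AP"] = mio.MoleculeType("AP", ["t", "l"],
                                       np.zeros((2, 3)), [25, 25, 25], 0.5)
        types["L"] = mio.MoleculeType("L", ["head"], _POINT, [0.5, 0.5, 0],
                                      0.01, is_2d=True,
                                      is_implicit_surface=True)
        rules.append(mio.ReactionRule(
            name="ap_lipid", order=2,
            text="AP(l) + L(head) <-> AP(l!1).L(head!1)",
            reactants=[mio.SitePattern("AP", "l"),
                       mio.SitePattern("L", "head")],
            kon_macro=3.22, koff_macro=0.97, sigma=1.0, h=2.0))
        rules.append(mio.ReactionRule(
            name="ap_trisk", order=2,
            text="AP(t) + trisk(ap) <-> AP(t!1).trisk(ap!1)",
            reactants=[mio.SitePattern("AP", "t"),
                       mio.SitePattern("trisk", "ap")],
            kon_macro=0.12, koff_macro=0.03, sigma=1.0, h=30.0))
        rules.append(mio.ReactionRule(
            name="tt", order=2,
            text="trisk(td*) + trisk(td*) <-> trisk(td!1).trisk(td!1)",
            reactants=[mio.SitePattern("trisk", "td*"),
                       mio.SitePattern("trisk", "td*")],
            kon_macro=1.67, koff_macro=9.98, sigma=5.0, h=30.0,
            is_loop_closure_eligible=True))
        rules.append(mio.ReactionRule(
            name="tt_coop", order=2,
            text="AP(t!1).trisk(ap!1,td*) + trisk(td*) <-> "
                 "AP(t!1).trisk(ap!1,td!2).trisk(td!2)",
            reactants=[mio.SitePattern("trisk", "td*", [("ap", "bound")]),
                       mio.SitePattern("trisk", "td*")],
            kon_macro=18.01, koff_macro=9.82, sigma=5.0, h=30.0,
            dG_coop=2.3, is_loop_closure_eligible=True))
        copies = {"trisk": n_of(10000), "AP": n_of(10000),
                  "L": n_of(204082)}
        il_copies = n_of(204082)
    else:  # pragma: no cover
        raise AssertionError(name)

    config = mio.SimulationConfig(
        box=scaled_box(box), dt=dt_use, n_iterations=n_iterations,
        seed=seed, output_every=output_every, membrane=membrane,
        copies=copies, implicit_lipid_copies=il_copies)
    return mio.model_from_objects(types, rules, config)


def build_ring_state(model, composition: dict, seed: int = 0):
    """State populated with pre-assembled chains and rings.

    ``composition`` maps ("chain", k) / ("ring", k) to complex counts.
    Each complex is assembled with the model's own association geometry,
    then given a random pose inside the box.  Used to start equilibrium
    (stationarity) validations from the theoretical species distribution,
    since absolute ring turnover can be far slower than any desk-scale run.
    """
    from .rigid_body import State, quat_from_axis_angle, quat_multiply, \
        quat_normalize, quat_to_matrix
    from .serial_engine import Engine
    from .partition import PairCandidates

    rng = np.random.default_rng(seed)
    rule = next(r for r in model.rules if r.order == 2)
    arm = model.type_list[0].max_site_extent
    spacing = 2 * arm + rule.sigma + 1.0
    total = sum(k * n for (_, k), n in composition.items())
    st = State(model, capacity=total + 4)
    eng = Engine(model, state=st)
    empty = PairCandidates.empty(model.rules)
    box = model.config.box
    margin = max(spacing * 2, 5.0)
    for (kind, k), n in sorted(composition.items()):
        for _ in range(n):
            base_rows = []
            for m in range(k):
                r = st.add_molecule(0, [100.0 + spacing * m, 100.0, 100.0])
                base_rows.append(r)
            sp = st.site_positions().copy()
            for m in range(k - 1):
                ok = eng._execute_association(
                    base_rows[m], 0, base_rows[m + 1], 1, rule, empty, sp)
                assert ok
                st.invalidate_sites()
            if kind == "ring" and k >= 3:
                cands = st.loop_closure_candidates(
                    int(st.complex_id[base_rows[0]]), [rule])
                assert len(cands) == 1
                ra, sa, rb, sb, _ = cands[0]
                st.bind(ra, sa, rb, sb, rule)
            # random pose inside the box
            rows_c = np.array(base_rows)
            com = st.com[rows_c].mean(axis=0)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            q = quat_from_axis_angle(axis, rng.uniform(0, 2 * np.pi))
            R = quat_to_matrix(q)
            target = margin + rng.uniform(0, 1, 3) * (box - 2 * margin)
            st.com[rows_c] = (st.com[rows_c] - com) @ R.T + target
            st.quat[rows_c] = quat_normalize(
                quat_multiply(q[None, :], st.quat[rows_c]))
            st.invalidate_sites()
    return st


def ring_composition_counts(eq: dict, volume_nm3: float, n_max: int) -> dict:
    """Integer chain/ring complex counts from an equilibrium table (uM)."""
    from ._units import uM_to_copies
    comp = {}
    for k in range(1, n_max + 1):
        n = int(round(uM_to_copies(eq[f"C{k}"], volume_nm3)))
        if n > 0:
            comp[("chain", k)] = n
    n = int(round(uM_to_copies(eq["ring"], volume_nm3)))
    if n > 0:
        comp[("ring", n_max)] = n
    return comp


def benchmark_reference_rates(model: mio.Model) -> dict:
    """Macroscopic display-unit rates of a built benchmark (for reports)."""
    out = {}
    for r in model.rules:
        if r.order != 2:
            continue
        out[r.name] = {
            "kon_display": (r.kon_macro / mio.kon3d_to_internal(1.0)
                            if (r.dimensionality == 3 and r.kon_macro)
                            else r.kon_macro),
            "koff_s": rate1_to_display(r.koff_macro) if r.koff_macro else None,
        }
    return out
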