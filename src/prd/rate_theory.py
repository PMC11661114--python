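"""Closed-form rate theory for diffusion-influenced reactions.

Single-particle reaction-diffusion algorithms parameterize binding by the
*intrinsic* rate ``ka`` entering the radiation boundary condition at the
contact radius sigma, while well-mixed kinetics are governed by the
*macroscopic* (diffusion-convolved) rate ``kon``.  In 3D the two are linked
through the diffusion-limited rate ``kD = 4 pi sigma D``::

    1/kon = 1/ka + 1/(4 pi sigma D)

In 2D there is no time-independent macroscopic rate in an infinite plane; at
finite surface density a steady-state rate exists within the mean "trap"
radius ``b_rho`` set by the density of reactive partners, and is used to
build the well-mixed reference kinetics for membrane-bound reactions.

This module also provides the per-reaction cutoff radius ``Rcut`` (the
separation beyond which a pair cannot react within one timestep, which sets
the minimal sub-volume and ghost-region sizes), the density-limited maximal
timestep, and completion of partially specified reaction rules (2D
projections via the length scale h, macroscopic off-rates, loop-closure
rates).

All functions take and return internal units (nm, us) unless noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._units import C0_NM3


class DiffusionLimitedError(ValueError):
    """Macroscopic rate at or above the diffusion-limited rate 4*pi*sigma*D:
    no finite intrinsic rate reproduces it."""


def k_diffusion_3d(sigma: float, D: float) -> float:
    """Smoluchowski diffusion-limited rate 4*pi*sigma*D (nm^3/us)."""
    return 4.0 * math.pi * sigma * D


def ka_from_kon_3d(kon: float, sigma: float, D: float) -> float:
    """Intrinsic 3D rate from the macroscopic one.

    Parameters are in internal units: kon in nm^3/us, sigma nm, D = D1+D2 in
    nm^2/us.  Raises :class:`DiffusionLimitedError` if ``kon >= 4 pi sigma D``.
    """
    if kon < 0:
        raise ValueError("kon must be non-negative")
    if kon == 0:
        return 0.0
    kD = k_diffusion_3d(sigma, D)
    if kon >= kD:
        raise DiffusionLimitedError(
            f"kon={kon:.6g} nm^3/us >= diffusion-limited 4*pi*sigma*D={kD:.6g}"
        )
    return 1.0 / (1.0 / kon - 1.0 / kD)


def kon_from_ka_3d(ka: float, sigma: float, D: float) -> float:
    """Macroscopic 3D rate from the intrinsic one (inverse of ka_from_kon_3d)."""
    if ka < 0:
        raise ValueError("ka must be non-negative")
    if ka == 0:
        return 0.0
    return 1.0 / (1.0 / ka + 1.0 / k_diffusion_3d(sigma, D))


def b_rho_2d(S: float, n_max: int, sigma: float) -> float:
    """Mean-separation trap radius for a 2D reaction at finite density.

    ``b_rho = 2 * sqrt(S / (pi * n_max) + sigma^2)`` where S is the membrane
    area (nm^2) and n_max the larger of the two partner copy numbers.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if S <= 0:
        raise ValueError("S must be positive")
    return 2.0 * math.sqrt(S / (math.pi * n_max) + sigma * sigma)


def kon2d_steady_state(ka2d: float, D: float, sigma: float, b_rho: float) -> float:
    """Steady-state macroscopic 2D association rate (nm^2/us).

    ``kon2D = [ 1/ka2D + (1/(8 pi D)) * ( 4 ln(b/sigma)/(1-sigma^2/b^2)^2
    - 2/(1-sigma^2/b^2) - 1 ) ]^-1`` with b the trap radius from
    :func:`b_rho_2d`.  Increasing in both ka2d and D.
    """
    if b_rho <= sigma:
        raise ValueError("b_rho must exceed sigma")
    if ka2d < 0:
        raise ValueError("ka2d must be non-negative")
    s = 1.0 - (sigma * sigma) / (b_rho * b_rho)
    geom = (4.0 * math.log(b_rho / sigma) / (s * s) - 2.0 / s - 1.0) / (8.0 * math.pi * D)
    if ka2d == 0.0:
        return 0.0
    return 1.0 / (1.0 / ka2d + geom)


def rcut_for_rule(sigma: float, d: int, D_pair: float, dt: float,
                  l1: float = 0.0, l2: float = 0.0) -> float:
    """Per-reaction cutoff ``Rcut = sigma + 3*sqrt(2 d D dt) + l1 + l2``.

    ``d`` is the dimensionality of the relative diffusion (3 or 2), ``D_pair``
    the summed pair diffusion constant, and ``l1``, ``l2`` the displacements of
    the reactive sites from their molecules' centers of mass (a rotating arm
    can carry a site further than center-of-mass diffusion alone).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if min(sigma, D_pair, l1, l2) < 0:
        raise ValueError("arguments must be non-negative")
    return sigma + 3.0 * math.sqrt(2.0 * d * D_pair * dt) + l1 + l2


def rcut_system(rcuts: Iterable[float]) -> float:
    """System cutoff: the maximum per-rule cutoff (0.0 for no order-2 rules)."""
    rcuts = list(rcuts)
    return max(rcuts) if rcuts else 0.0


def timestep_limit(d: int, D1: float, D2: float, rho: float, sigma: float) -> float:
    """Density-limited maximal timestep (us) for one reactant pair.

    ``dt_max = [ (3/(4 pi rho) + sigma^d)^(1/d) - sigma ]^2 / (18 d (D1+D2))``
    with ``rho = max(N1, N2) / L^d`` the denser partner's number density.
    The construction equates the 3-sigma diffusional reach entering the
    cutoff with the nearest-neighbor spacing, so that a particle encounters
    at most ~one partner per step.  The system limit is the minimum over all
    reaction pairs.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    reach = (3.0 / (4.0 * math.pi * rho) + sigma ** d) ** (1.0 / d) - sigma
    return reach * reach / (18.0 * d * (D1 + D2))


def k_loop_closure(kf: float, dG_coop: float = 0.0) -> float:
    """Loop-closure rate ``kclose = kf * c0 * exp(-dG_coop)`` in us^-1.

    ``kf`` is the intrinsic association rate in nm^3/us; ``c0`` is the 1 M
    standard state (0.6022 nm^-3); ``dG_coop`` is in kBT (positive =
    penalized closure).
    """
    return kf * C0_NM3 * math.exp(-dG_coop)


@dataclass
class CutoffSpec:
    """Per-rule and system reaction cutoffs."""
    rcut_by_rule: dict = field(default_factory=dict)  # rule name -> nm
    rcut: float = 0.0                                 # system max, nm

    @classmethod
    def from_rules(cls, rules: Sequence, dt: float) -> "CutoffSpec":
        """Build from completed ReactionRule objects (order-2 only)."""
        per = {}
        for r in rules:
            if r.order != 2:
                continue
            per[r.name] = rcut_for_rule(r.sigma, r.dimensionality, r.D_pair,
                                        dt, r.l1, r.l2)
        return cls(per, rcut_system(per.values()))


@dataclass
class TimestepSpec:
    """Density-limited timestep; system value is the min over rules."""
    dt_by_rule: dict = field(default_factory=dict)
    dt_max: float = math.inf
    limiting_rule: str | None = None

    @classmethod
    def from_rules(cls, rules: Sequence, densities: dict) -> "TimestepSpec":
        """``densities`` maps rule name -> (rho, D1, D2, d, sigma)."""
        per = {}
        worst = (math.inf, None)
        for r in rules:
            if r.order != 2 or r.name not in densities:
                continue
            rho, D1, D2, d, sigma = densities[r.name]
            per[r.name] = timestep_limit(d, D1, D2, rho, sigma)
            if per[r.name] < worst[0]:
                worst = (per[r.name], r.name)
        return cls(per, worst[0], worst[1])


def complete_rates(rule) -> None:
    """Fill the derived members of a partially specified ReactionRule in place.

    Exactly one of the (macroscopic, intrinsic) rate pairs must be given;
    the other is derived, along with the 2D projections ``ka2D = ka3D / h``
    and ``kb2D = kb3D``, the macroscopic off-rate ``koff = kon * kb / ka``,
    and the loop-closure rate ``kclose = kf * c0 * exp(-dG_coop)``.
    Works on any object exposing the ReactionRule fields (internal units).
    """
    if rule.order != 2:
        if rule.k_intrinsic is None:
            rule.k_intrinsic = rule.k_macro
        return
    has_macro = rule.kon_macro is not None
    has_intr = rule.ka_intrinsic is not None
    if has_macro == has_intr:
        raise ValueError(
            f"rule {rule.name}: exactly one of macroscopic/intrinsic rate "
            "pairs may be supplied")
    if rule.dimensionality == 3:
        if has_macro:
            rule.ka_intrinsic = ka_from_kon_3d(rule.kon_macro, rule.sigma, rule.D_pair)
            if rule.koff_macro is not None:
                rule.kb_intrinsic = (
                    rule.koff_macro * rule.ka_intrinsic / rule.kon_macro
                    if rule.kon_macro > 0 else rule.koff_macro)
        else:
            rule.kon_macro = kon_from_ka_3d(rule.ka_intrinsic, rule.sigma, rule.D_pair)
            if rule.kb_intrinsic is not None:
                rule.koff_macro = rule.kon_macro * rule.kb_intrinsic / rule.ka_intrinsic
    else:  # pure-2D rule: table lists intrinsic 2D rates
        if has_macro:
            raise ValueError(
                f"rule {rule.name}: 2D rules take intrinsic rates "
                "(no single macroscopic 2D rate exists)")
        if rule.b_rho is not None:
            rule.kon_macro = kon2d_steady_state(
                rule.ka_intrinsic, rule.D_pair, rule.sigma, rule.b_rho)
            if rule.kb_intrinsic is not None and rule.kon_macro > 0:
                rule.koff_macro = (rule.kon_macro * rule.kb_intrinsic
                                   / rule.ka_intrinsic)
    # 3D -> 2D projection for rules that can also run on the membrane
    if rule.projects_to_2d:
        if rule.h is None or rule.h <= 0:
            raise ValueError(f"rule {rule.name}: 2D projection requires h > 0")
        rule.ka2d_intrinsic = rule.ka_intrinsic / rule.h
        rule.kb2d_intrinsic = rule.kb_intrinsic
    if rule.is_loop_closure_eligible and rule.ka_intrinsic is not None:
        rule.kclose = k_loop_closure(rule.ka_intrinsic, rule.dG_coop)
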