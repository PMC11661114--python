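"""Per-pair reaction probabilities and event sampling.

The association step of the algorithm asks, for a reactive pair at initial
separation ``r0``: what is the probability that the pair, diffusing with
relative diffusion constant ``D = D1 + D2`` and subject to a radiation
boundary condition at contact ``sigma`` parameterized by the intrinsic rate
``ka``, reacts within one timestep ``dt``?

In 3D this has a closed form (the spatial integral of the radiation-boundary
Green's function)::

    p(dt | r0) = (sigma/r0) * ka/(ka + kD)
                 * [ erfc(x) - exp(2xy + y^2) erfc(x + y) ]

    x = (r0 - sigma)/sqrt(4 D dt),  y = alpha sqrt(dt),
    alpha = (sqrt(D)/sigma) (1 + ka/kD),  kD = 4 pi sigma D

evaluated here with the scaled complementary error function
(``exp(2xy+y^2) erfc(x+y) = erfcx(x+y) exp(-x^2)``) so large arguments do
not overflow.

In 2D no closed form exists; the same survival problem is integrated
numerically (Crank-Nicolson on the radial backward equation with a Robin
boundary at sigma) and tabulated per (rule, dt) for linear interpolation in
``r0``.

Binding of a 3D molecule to an implicit membrane (lipids as a depletable
surface density rather than explicit particles) uses the 1D half-space
analog of the same radiation-boundary formula with surface reactivity
``kappa = ka * rho_free`` (nm/us), so the continuum adsorption boundary
condition ``flux = ka * rho_free * c(z=0)`` is recovered.
"""

from __future__ import annotations

import math
import warnings
from typing import Union

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import erfc, erfcx

ArrayLike = Union[float, np.ndarray]


class OverlapError(ValueError):
    """Pair separation below contact: caller must resolve overlap first."""


def _survival_bracket(x: np.ndarray, y) -> np.ndarray:
    """erfc(x) - exp(2xy + y^2) erfc(x+y), computed stably."""
    return erfc(x) - erfcx(x + y) * np.exp(-x * x)


def p_react_3d(r0: ArrayLike, dt: float, ka: float, sigma: float,
               D: float) -> np.ndarray:
    """3D pair-reaction probability from the radiation-boundary Green's function.

    Vectorized over ``r0`` (nm, must be >= sigma). ``ka`` nm^3/us, ``D``
    summed pair diffusion nm^2/us. Monotone non-increasing in r0,
    non-decreasing in ka and dt; clipped to [0, 1].
    """
    r0 = np.asarray(r0, dtype=np.float64)
    D = np.asarray(D, dtype=np.float64)  # may vary per pair (complex-size D)
    if np.any(r0 < sigma):
        raise OverlapError("r0 < sigma: resolve overlap before evaluating")
    if ka < 0:
        raise ValueError("ka must be non-negative")
    if ka == 0.0 or dt <= 0.0:
        return np.zeros_like(r0)
    kD = 4.0 * np.pi * sigma * D
    alpha = (np.sqrt(D) / sigma) * (1.0 + ka / kD)
    x = (r0 - sigma) / np.sqrt(4.0 * D * dt)
    y = alpha * math.sqrt(dt)
    p = (sigma / r0) * (ka / (ka + kD)) * _survival_bracket(x, y)
    return np.clip(p, 0.0, 1.0)


def p_ultimate_3d(r0: ArrayLike, ka: float, sigma: float, D: float) -> np.ndarray:
    """dt -> infinity limit of :func:`p_react_3d` (ultimate capture probability)."""
    r0 = np.asarray(r0, dtype=np.float64)
    kD = 4.0 * math.pi * sigma * D
    return (sigma / r0) * (ka / (ka + kD))


class GreensFunction2D:
    """Tabulated 2D radiation-boundary reaction probability for one (rule, dt).

    Solves the radial backward (survival) equation

        dS/dt = D (S'' + S'/r),   D * S'(sigma) = (ka2d / (2 pi sigma)) S(sigma)

    from S(0)=1 to t=dt by Crank-Nicolson on a uniform radial grid, and
    serves ``p(dt | r0) = 1 - S(dt | r0)`` by linear interpolation.  The
    outer boundary is reflecting, placed far enough that it is unreachable
    within dt.
    """

    def __init__(self, ka2d: float, D: float, sigma: float, dt: float,
                 rmax: float, n_grid: int = 1200, n_sub: int = 256):
        if sigma <= 0 or D <= 0 or dt <= 0:
            raise ValueError("sigma, D, dt must be positive")
        if ka2d < 0:
            raise ValueError("ka2d must be non-negative")
        self.ka2d, self.D, self.sigma, self.dt = ka2d, D, sigma, dt
        ell = math.sqrt(4.0 * D * dt)
        self.rmax = max(rmax, sigma + ell) + 8.0 * ell
        self.r = np.linspace(sigma, self.rmax, n_grid)
        if ka2d == 0.0:
            self.p = np.zeros(n_grid)
            return
        dr = self.r[1] - self.r[0]
        h2 = ka2d / (2.0 * math.pi * sigma * D)  # Robin coefficient, 1/nm
        # tridiagonal backward operator L (rows = grid nodes)
        lo = np.zeros(n_grid)
        di = np.zeros(n_grid)
        up = np.zeros(n_grid)
        ri = self.r[1:-1]
        di[1:-1] = -2.0 * D / dr**2
        up[1:-1] = D / dr**2 + D / (2.0 * dr * ri)
        lo[1:-1] = D / dr**2 - D / (2.0 * dr * ri)
        # contact node: ghost from D S' = D h2 S  ->  S_{-1} = S_1 - 2 dr h2 S_0
        di[0] = D * (-2.0 / dr**2 - 2.0 * h2 / dr + h2 / sigma)
        up[0] = 2.0 * D / dr**2
        # reflecting outer node: ghost S_N = S_{N-2}
        di[-1] = -2.0 * D / dr**2
        lo[-1] = 2.0 * D / dr**2
        tau = dt / n_sub
        # banded forms of (I -/+ tau/2 L) for solve_banded
        ab = np.zeros((3, n_grid))
        ab[0, 1:] = -0.5 * tau * up[:-1]
        ab[1, :] = 1.0 - 0.5 * tau * di
        ab[2, :-1] = -0.5 * tau * lo[1:]
        S = np.ones(n_grid)
        for _ in range(n_sub):
            rhs = S + 0.5 * tau * (
                di * S
                + np.concatenate((up[:-1] * S[1:], [0.0]))
                + np.concatenate(([0.0], lo[1:] * S[:-1])))
            S = solve_banded((1, 1), ab, rhs)
        self.p = np.clip(1.0 - S, 0.0, 1.0)

    def __call__(self, r0: ArrayLike) -> np.ndarray:
        r0 = np.asarray(r0, dtype=np.float64)
        if np.any(r0 < self.sigma - 1e-9):
            raise OverlapError("r0 < sigma: resolve overlap before evaluating")
        return np.interp(np.maximum(r0, self.sigma), self.r, self.p,
                         right=0.0)


_GF2D_CACHE: dict = {}


def p_react_2d(r0: ArrayLike, dt: float, ka2d: float, sigma: float, D: float,
               rmax: float | None = None) -> np.ndarray:
    """2D pair-reaction probability (memoized numerical Green's function).

    ``ka2d`` in nm^2/us; ``D`` the summed in-plane pair diffusion nm^2/us.
    """
    if rmax is None:
        rmax = sigma + 4.0 * math.sqrt(4.0 * D * dt)
    key = (round(ka2d, 12), round(D, 12), round(sigma, 12), round(dt, 12),
           round(rmax, 6))
    gf = _GF2D_CACHE.get(key)
    if gf is None:
        gf = GreensFunction2D(ka2d, D, sigma, dt, rmax)
        _GF2D_CACHE[key] = gf
    return gf(r0)


def p_bind_implicit_surface(z_height: ArrayLike, dt: float, ka: float,
                            sigma: float, rho_lipid: float,
                            D_z: float) -> np.ndarray:
    """Per-step binding probability of a 3D molecule to an implicit membrane.

    The free-lipid pool is a uniform surface density ``rho_lipid`` (nm^-2)
    at z=0; contact is at height sigma.  The 1D half-space radiation-boundary
    absorption probability is used with surface reactivity
    ``kappa = ka * rho_lipid`` (nm/us), which reproduces the continuum
    adsorption boundary condition flux = ka * rho_free * c(0).  Executing a
    binding decrements the free-lipid count by one (and unbinding restores
    it); that bookkeeping lives in the engine.
    """
    z = np.asarray(z_height, dtype=np.float64)
    D_z = np.asarray(D_z, dtype=np.float64)   # may vary per molecule
    if rho_lipid < 0:
        raise ValueError("negative lipid density")
    if rho_lipid == 0.0 or ka == 0.0 or dt <= 0.0:
        return np.zeros_like(z)
    kappa = ka * rho_lipid
    x = np.maximum(z - sigma, 0.0) / np.sqrt(4.0 * D_z * dt)
    y = kappa * np.sqrt(dt / D_z)
    return np.clip(_survival_bracket(x, y), 0.0, 1.0)


def sample_first_order(N: int, k: float, dt: float, rng) -> int:
    """Number of first-order events among N eligible members in one step.

    Uses the per-step probability ``p = k*dt`` literally (the algorithm's
    stated convention), warning when k*dt > 0.1 where the linearization of
    1 - exp(-k dt) degrades, and refusing k*dt > 1.
    """
    if N < 0:
        raise ValueError("N must be non-negative")
    if k < 0:
        raise ValueError("k must be non-negative")
    p = k * dt
    if p > 1.0:
        raise ValueError(f"k*dt = {p:.3g} > 1: timestep too large for rate {k:.3g}")
    if p > 0.1:
        warnings.warn(f"k*dt = {p:.3g} > 0.1: first-order sampling accuracy degrades",
                      stacklevel=2)
    if N == 0 or p == 0.0:
        return 0
    return int(rng.binomial(N, p))


def sample_zeroth_order(k_total: float, dt: float, rng) -> int:
    """Poisson creation count for a 0th-order source with total propensity
    ``k_total`` (events/us, i.e. rate density times region volume)."""
    if k_total < 0:
        raise ValueError("rate must be non-negative")
    if k_total == 0.0 or dt <= 0.0:
        return 0
    return int(rng.poisson(k_total * dt))
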