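"""Counter-based (keyed) random numbers.

Every stochastic decision in the engines is drawn from a stateless hash of
``(seed, step, channel, id...)`` rather than from a sequential generator.
Two consequences:

* a simulation is reproducible bit-for-bit from its seed alone, and
* the draw for a given event does not depend on *which processor* evaluates
  it or in what order events are enumerated, so a spatially decomposed run
  produces bitwise-identical trajectories to the single-rank run.

The hash is a splitmix64-style finalizer applied after folding the key words
together; it passes the usual equidistribution smoke tests and is more than
adequate for Monte Carlo acceptance draws.  All arithmetic is modulo 2^64 on
uint64 numpy arrays (wrap-around is intentional).
"""

from __future__ import annotations

import numpy as np

_P1 = np.uint64(0x9E3779B97F4A7C15)
_P2 = np.uint64(0xBF58476D1CE4E5B9)
_P3 = np.uint64(0x94D049BB133111EB)
_P4 = np.uint64(0xD6E8FEB86659FD93)
_MASK = (1 << 64) - 1

# channel codes (third key word) -- keep stable, they define the trajectory
PAIR = 1          # pair-reaction acceptance draw, ids = (gid_lo, gid_hi)
FIRST = 2         # first-order Bernoulli, ids = (gid, reaction_index)
LOOP = 3          # loop-closure Bernoulli, ids = (gid_lo, gid_hi)
ZEROTH = 4        # creation count, ids = (cell_index, rule_index)
DIFF = 5          # diffusion gaussians, ids = (lead_gid, axis_channel)
RETRY = 6         # overlap-rejection resample, ids = (lead_gid, attempt*8+ch)
PLACE = 7         # placement randomness, ids = (gid, channel)
IL_BIND = 8       # implicit-lipid binding Bernoulli, ids = (gid, site)
IL_UNBIND = 9     # implicit-lipid unbinding Bernoulli, ids = (gid, site)


def _mix(h: np.ndarray) -> np.ndarray:
    h = h ^ (h >> np.uint64(30))
    h = h * _P2
    h = h ^ (h >> np.uint64(27))
    h = h * _P3
    h = h ^ (h >> np.uint64(31))
    return h


def _u64(x) -> np.ndarray:
    """Coerce ids (python int or integer ndarray) to a uint64 array."""
    if isinstance(x, int):
        return np.atleast_1d(np.uint64(x & _MASK))
    return np.atleast_1d(np.asarray(x)).astype(np.uint64)


def key_base(seed: int, step: int, channel: int) -> np.uint64:
    """Precompute the scalar part of the key (seed, step, channel)."""
    h = np.array([seed & _MASK], dtype=np.uint64) * _P1
    h = _mix(h ^ (np.array([step & _MASK], dtype=np.uint64) * _P2))
    h = _mix(h ^ (np.array([channel & _MASK], dtype=np.uint64) * _P3))
    return h[0]


def hashed_u64(base: np.uint64, a, b=0) -> np.ndarray:
    """Vectorized 64-bit hash of (base, a, b)."""
    a = _u64(a)
    b = _u64(b)
    h = _mix(base ^ (a * _P2))
    h = _mix(h ^ (b * _P4))
    return h


def uniform(base: np.uint64, a, b=0) -> np.ndarray:
    """Keyed uniforms in the open interval (0, 1)."""
    h = hashed_u64(base, a, b)
    return ((h >> np.uint64(11)).astype(np.float64) + 0.5) * (2.0 ** -53)


def normal(base: np.uint64, a, channel) -> np.ndarray:
    """Keyed standard normals via Box-Muller.

    ``channel`` distinguishes independent normal streams for the same id
    (e.g. x/y/z displacement, three rotation angles).
    """
    a = _u64(a)
    ch = np.uint64(int(channel) & _MASK)
    u1 = uniform(base, a, ch * np.uint64(2))
    u2 = uniform(base, a, ch * np.uint64(2) + np.uint64(1))
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)
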