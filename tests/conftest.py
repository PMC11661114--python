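"""Shared fixtures: small in-memory models built programmatically."""

from __future__ import annotations

import math

import numpy as np
import pytest

from prd import model_io as mio


def make_ab_model(box=(2000, 300, 300), copies=150, dt=1.0, seed=5,
                  kon=100.0, koff=10.0, sigma=2.0):
    """Point-site A + B <-> A.B model (3D)."""
    A = mio.MoleculeType("A", ["b"], np.zeros((1, 3)), [10, 10, 10], 0.0)
    B = mio.MoleculeType("B", ["b"], np.zeros((1, 3)), [10, 10, 10], 0.0)
    rule = mio.ReactionRule(
        name="ab", order=2, text="A(b) + B(b) <-> A(b!1).B(b!1)",
        reactants=[mio.SitePattern("A", "b"), mio.SitePattern("B", "b")],
        kon_macro=kon, koff_macro=koff, sigma=sigma)
    cfg = mio.SimulationConfig(box=list(box), dt=dt, n_iterations=0,
                               seed=seed, output_every=100,
                               copies={"A": copies, "B": copies})
    return mio.model_from_objects({"A": A, "B": B}, [rule], cfg)


def make_ring_model(interior_deg=60.0, sigma=0.73, arm=1.0,
                    box=(800, 100, 100), copies=600, dt=0.1, seed=7,
                    kon=10.86, koff=901.6):
    """Two-site ring-forming monomer (trimer geometry by default)."""
    half = math.radians(interior_deg) / 2.0
    offs = np.array([[math.cos(half), math.sin(half), 0.0],
                     [math.cos(half), -math.sin(half), 0.0]]) * arm
    A = mio.MoleculeType("A", ["c", "q"], offs, [10, 10, 10], 0.1)
    rule = mio.ReactionRule(
        name="cq", order=2, text="A(c) + A(q) <-> A(c!1).A(q!1)",
        reactants=[mio.SitePattern("A", "c"), mio.SitePattern("A", "q")],
        kon_macro=kon, koff_macro=koff, sigma=sigma,
        is_loop_closure_eligible=True)
    cfg = mio.SimulationConfig(box=list(box), dt=dt, n_iterations=0,
                               seed=seed, output_every=100,
                               copies={"A": copies})
    return mio.model_from_objects({"A": A}, [rule], cfg)


def equilibrated_ab_state(model, n_each, n_bound, seed=0):
    """State with n_bound A.B dimers (sites in contact at sigma) and
    n_each - n_bound free monomers of each type, uniformly placed."""
    from prd.rigid_body import State
    rng = np.random.default_rng(seed)
    sigma = model.rules[0].sigma
    box = model.config.box
    st = State(model, 2 * n_each)
    ta = model.types["A"].type_id
    tb = model.types["B"].type_id
    for _ in range(n_each - n_bound):
        st.add_molecule(ta, rng.uniform(0, 1, 3) * box)
    for _ in range(n_each - n_bound):
        st.add_molecule(tb, rng.uniform(0, 1, 3) * box)
    for _ in range(n_bound):
        pos = rng.uniform(0, 1, 3) * (box - sigma)
        ra = st.add_molecule(ta, pos)
        rb = st.add_molecule(tb, pos + [sigma, 0.0, 0.0])
        st.bind(ra, 0, rb, 0, model.rules[0])
    return st


@pytest.fixture
def ab_model():
    return make_ab_model()


@pytest.fixture
def ring_model():
    return make_ring_model()
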