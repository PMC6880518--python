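"""Shared fixtures: minimal models and a reusable division fixture."""
from __future__ import annotations

import numpy as np
import pytest

from nestforce import reactions
from nestforce.core_model import Domain, Model, PhysicsParams, SystemState


@pytest.fixture
def simple_state():
    """3D box with one generic mobile species, no rules."""
    model = Model("simple")
    model.register_species("A", default_radius=1e-6)
    physics = PhysicsParams(domain=Domain.box(2e-5, 3), max_timestep=1e-6)
    return SystemState(model, physics, seed=0)


@pytest.fixture
def nested_state():
    """cell ⊃ raft ⊃ protein chain for containment/viscosity tests."""
    model = Model("nested")
    model.register_species("Cell", default_radius=5e-6,
                           interior_viscosity=2e-3)
    model.register_species("Raft", default_radius=1e-6,
                           interior_viscosity=1e-2)
    model.register_species("Carrier", default_radius=1e-6)  # inherits
    model.register_species("P", default_radius=1e-7)
    physics = PhysicsParams(domain=Domain.box(2e-5, 3), medium_viscosity=1e-3)
    state = SystemState(model, physics, seed=0)
    center = np.full(3, 1e-5)
    cell = state.spawn_particle("Cell", center)
    raft = state.spawn_particle("Raft", center, cell)
    prot = state.spawn_particle("P", center, raft)
    return state, cell, raft, prot


def make_division_state(seed: int, n_contents: int, a_division: float = 100.0,
                        content_split=None):
    """Compartment of radius 1 μm holding ``n_contents`` cargo particles.

    Cold (T = 0) and lightly damped: enough friction that cargo knocked by
    the shrinking shell settles well within the division (m/γ is ~4% of the
    separation time) but little enough that drag does not press contents
    through the sweeping wall beyond the containment tolerance.
    """
    model = Model("division")
    model.register_species("Comp", default_radius=1e-6)
    model.register_species("Cargo", default_radius=5e-8)
    rule = reactions.divide("split", "Comp", rate=0.0, a_division=a_division,
                            content_split=content_split)
    model.add_rule(rule)
    physics = PhysicsParams(domain=Domain.box(1e-5, 3), temperature=0.0,
                            medium_viscosity=1e-5, granularity=2.0,
                            max_timestep=2e-6, tol_contain=2e-8,
                            semi_implicit_friction=True)
    state = SystemState(model, physics, seed=seed)
    center = np.full(3, 5e-6)
    comp = state.spawn_particle("Comp", center)
    rng = state.rng
    for _ in range(n_contents):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = (1e-6 - 6e-8) * rng.random() ** (1 / 3)
        state.spawn_particle("Cargo", center + u * r, comp)
    return state, comp, rule


def run_division(state, comp, rule, max_steps: int = 20000):
    """Start and drive one division to completion; returns the transition."""
    import nestforce as nf

    tr = reactions.start_division(state, comp, rule)
    steps = 0
    while state.transitions and steps < max_steps:
        nf.step(state)
        steps += 1
    assert not state.transitions, "division did not complete"
    return tr, steps
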