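"""Force terms: Hertz contact, reactive barrier, division, thermal, and fields.

Every pair force is reported as a magnitude along a contact normal computed
by the collision module; Newton's third law is enforced at the point of
application in the engine.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core_model import ModelError, ParticleHandle, SystemState


def effective_modulus(e1: float, nu1: float, e2: float, nu2: float) -> float:
    """Pair effective modulus E* = ((1-ν1²)/E1 + (1-ν2²)/E2)⁻¹ (Pa)."""
    if not (e1 > 0 and e2 > 0):
        raise ModelError("elastic moduli must be > 0")
    if not (0 <= nu1 < 0.5 and 0 <= nu2 < 0.5):
        raise ModelError("Poisson ratios must satisfy 0 <= nu < 0.5")
    return 1.0 / ((1.0 - nu1**2) / e1 + (1.0 - nu2**2) / e2)


def effective_radius(r1: float, r2: float) -> float:
    """Harmonic pair radius r = (1/r1 + 1/r2)⁻¹ (m)."""
    if not (r1 > 0 and r2 > 0):
        raise ModelError("radii must be > 0")
    return 1.0 / (1.0 / r1 + 1.0 / r2)


def hertz_force(d: float, r1: float, r2: float, e_star: float) -> float:
    """Elastic soft-sphere repulsion F = (4/3)·E*·sqrt(r_eff·d³) (N).

    ``d`` is the overlap depth; zero overlap gives zero force and the law is
    continuous in d >= 0.
    """
    if d < 0:
        raise ModelError("overlap depth must be >= 0")
    return (4.0 / 3.0) * e_star * math.sqrt(effective_radius(r1, r2) * d**3)


def reactive_force(w: float, d_star: float) -> float:
    """Constant barrier force F = W/d*; crossing the full overlap costs W."""
    if not d_star > 0:
        raise ModelError("d_star must be > 0")
    if w < 0:
        raise ModelError("barrier work W must be >= 0")
    return w / d_star


def division_force(m: float, a_division: float) -> float:
    """Per-particle division push F = m·a so all members share acceleration a."""
    if not m > 0 or not a_division > 0:
        raise ModelError("division force requires m > 0 and a > 0")
    return m * a_division


def thermal_force(gamma: float, temperature: float, dt: float,
                  rng: np.random.Generator, dimension: int) -> np.ndarray:
    """One Gaussian kick vector with per-component variance 2γk_BT/Δt.

    The variance follows fluctuation–dissipation so the integrator reproduces
    an equilibrium velocity variance of k_BT/m and a long-time MSD of 2dDt.
    """
    from .units import KB

    if gamma < 0 or temperature < 0 or not dt > 0:
        raise ModelError("thermal force requires gamma, T >= 0 and dt > 0")
    sigma = math.sqrt(2.0 * gamma * KB * temperature / dt)
    if sigma == 0.0:
        return np.zeros(dimension)
    return rng.normal(0.0, sigma, size=dimension)


def thermal_forces(gammas: np.ndarray, temperature: float, dt: float,
                   rng: np.random.Generator, dimension: int) -> np.ndarray:
    """Vectorized :func:`thermal_force` for a population (shape (n, d))."""
    from .units import KB

    n = gammas.shape[0]
    if temperature == 0.0 or n == 0:
        return np.zeros((n, dimension))
    sigma = np.sqrt(2.0 * gammas * KB * temperature / dt)
    return rng.normal(0.0, 1.0, size=(n, dimension)) * sigma[:, None]


@dataclass
class ForceField:
    """A global force acting on single particles, independent of the others.

    ``evaluate(particle, t)`` must be pure and return a finite D-vector in
    newtons; ``applies_to`` filters by species/attributes.
    """

    name: str
    evaluate: Callable[[ParticleHandle, float], np.ndarray]
    applies_to: Callable[[ParticleHandle], bool] | None = None

    def matches(self, p: ParticleHandle) -> bool:
        return self.applies_to is None or bool(self.applies_to(p))


def sum_external_forces(state: SystemState, fields: list[ForceField],
                        p: ParticleHandle, t: float) -> np.ndarray:
    """Vector sum of all matching global fields on one particle."""
    total = np.zeros(state.physics.dimension)
    for ff in fields:
        if ff.matches(p):
            f = np.asarray(ff.evaluate(p, t), dtype=float)
            if not np.all(np.isfinite(f)):
                raise ModelError(f"force field {ff.name!r} returned a non-finite force")
            total += f
    return total


def accumulate_field_forces(state: SystemState, out: np.ndarray, t: float) -> None:
    """Add all registered field forces into the per-slot accumulator ``out``."""
    fields = state.model.force_fields
    if not fields:
        return
    for pid in state.particle_ids():
        p = state.particle(pid)
        slot = state.meta[pid].slot
        if not state.mobile[slot]:
            continue
        for ff in fields:
            if ff.matches(p):
                f = np.asarray(ff.evaluate(p, t), dtype=float)
                if not np.all(np.isfinite(f)):
                    raise ModelError(
                        f"force field {ff.name!r} returned a non-finite force")
                out[slot] += f


def dipole_field(name: str, pole_a, pole_b, strength: float,
                 side_of: Callable[[ParticleHandle], str],
                 applies_to: Callable[[ParticleHandle], bool] | None = None
                 ) -> ForceField:
    """Two-pole steering field: a constant-magnitude pull toward one pole.

    ``side_of(p)`` returns ``"a"`` or ``"b"`` (e.g. from a vesicle's coat
    attribute); the force on the particle points from its position toward
    the selected pole with the given magnitude.  Particles for which
    ``side_of`` returns anything else feel no force.
    """
    pa = np.asarray(pole_a, dtype=float)
    pb = np.asarray(pole_b, dtype=float)

    def evaluate(p: ParticleHandle, t: float) -> np.ndarray:
        side = side_of(p)
        if side == "a":
            target = pa
        elif side == "b":
            target = pb
        else:
            return np.zeros_like(pa)
        delta = target - p.position
        dist = float(np.linalg.norm(delta))
        if dist == 0.0:
            return np.zeros_like(pa)
        return strength * delta / dist

    return ForceField(name=name, evaluate=evaluate, applies_to=applies_to)


def pair_contact_force(state: SystemState, sp_a, sp_b, depth: float,
                       r_a: float, r_b: float) -> float:
    """Contact force magnitude for a non-reactive pair (Hertz by default)."""
    e_star = effective_modulus(sp_a.elastic_modulus, sp_a.poisson_ratio,
                               sp_b.elastic_modulus, sp_b.poisson_ratio)
    law = state.model.contact_law
    if law is not None:
        return law(depth, effective_radius(r_a, r_b), e_star)
    return hertz_force(depth, r_a, r_b, e_star)
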