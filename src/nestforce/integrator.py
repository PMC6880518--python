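"""Langevin propagation: adaptive timestep, kick-drift-kick, boundaries.

The kick applies deterministic forces, friction (-γv) and the pre-drawn
thermal force over half a step; drift advances positions over the full step
and then applies the domain boundary.  Immobile particles are skipped
entirely.
"""
from __future__ import annotations

import math

import numpy as np

from .core_model import MEDIUM, NumericalBlowupError, SystemState


def adaptive_timestep(state: SystemState) -> float:
    """Δt = r_min / (v_max · g), clamped to (0, max_timestep].

    ``r_min`` is the smallest current radius; ``v_max`` the largest current
    speed, floored by the thermal speed sqrt(k_B T / m) of the lightest
    mobile particle so cold starts still pick a finite step.  With no
    velocity scale at all the step is ``max_timestep``.
    """
    ph = state.physics
    slots = state.alive_slots()
    if slots.size == 0:
        return ph.max_timestep
    r_min = float(state.rad[slots].min())
    mob = slots[state.mobile[slots]]
    v_max = 0.0
    if mob.size:
        v_max = float(np.sqrt((state.vel[mob] ** 2).sum(axis=1)).max())
        if ph.temperature > 0:
            m_min = float(state.masses(mob).min())
            v_max = max(v_max, math.sqrt(ph.boltzmann * ph.temperature / m_min))
    dt = ph.max_timestep
    if v_max > 0.0:
        dt = min(r_min / (v_max * ph.granularity), dt)
    # divisions accelerate from rest: cap the step so the first kick cannot
    # displace a particle by more than r_min/g before velocity feedback kicks in
    a_max = max((tr.a_division for tr in state.transitions
                 if tr.kind == "division"), default=0.0)
    if a_max > 0.0:
        dt = min(dt, math.sqrt(2.0 * r_min / (a_max * ph.granularity)))
    return dt


def kick(state: SystemState, slots: np.ndarray, forces: np.ndarray,
         thermal: np.ndarray, dt_half: float) -> None:
    """Half-step velocity update v += (F - γv + f_thermal)/m · Δt/2.

    ``forces``/``thermal`` are indexed like ``slots``.  With
    ``physics.semi_implicit_friction`` the friction term is folded into the
    denominator, which stays stable when γΔt/m approaches 1.
    """
    if slots.size == 0:
        return
    m = state.masses(slots)
    gamma = state.frictions(slots)
    v = state.vel[slots]
    if state.physics.semi_implicit_friction:
        state.vel[slots] = (v + dt_half * (forces + thermal) / m[:, None]) / \
            (1.0 + gamma[:, None] * dt_half / m[:, None])
    else:
        state.vel[slots] = v + dt_half * (forces + thermal - gamma[:, None] * v) \
            / m[:, None]
    if not np.all(np.isfinite(state.vel[slots])):
        raise NumericalBlowupError(
            "velocities became non-finite during kick; "
            "increase granularity g or reduce max_timestep")


def second_kick(state: SystemState, slots: np.ndarray, forces: np.ndarray,
                thermal: np.ndarray, dt_half: float) -> None:
    """Second half-step velocity update, with forces recomputed after drift.

    Identical update rule to :func:`kick`; the thermal force is the one
    drawn at the start of the step (treated as constant over Δt).
    """
    kick(state, slots, forces, thermal, dt_half)


def drift(state: SystemState, slots: np.ndarray, dt: float) -> None:
    """Position update x += v·Δt followed by boundary handling."""
    if slots.size == 0:
        return
    state.pos[slots] += state.vel[slots] * dt
    if not np.all(np.isfinite(state.pos[slots])):
        raise NumericalBlowupError(
            "positions became non-finite during drift; "
            "increase granularity g or reduce max_timestep")
    boundary_apply(state, slots)


def boundary_apply(state: SystemState, slots: np.ndarray) -> list[int]:
    """Apply the domain boundary to top-level particles after a drift.

    reflective: mirror the position into the box and flip the normal
    velocity component; periodic: wrap; absorbing: remove the particle
    (with its contents).  Contained particles are confined by their parent
    shell instead and are left alone.  Returns ids of absorbed particles.
    """
    domain = state.physics.domain
    lo = np.asarray(domain.lo)
    hi = np.asarray(domain.hi)
    top = np.fromiter(
        (s for s in slots if state.meta[int(state.ids[s])].parent == MEDIUM),
        dtype=np.intp)
    if top.size == 0:
        return []
    pos = state.pos[top]
    if domain.boundary == "reflective":
        vel = state.vel[top]
        for _ in range(64):  # folds; a sane Δt never needs more than one
            below = pos < lo
            above = pos > hi
            if not (below.any() or above.any()):
                break
            pos = np.where(below, 2 * lo - pos, pos)
            pos = np.where(above, 2 * hi - pos, pos)
            vel = np.where(below | above, -vel, vel)
        state.pos[top] = pos
        state.vel[top] = vel
        return []
    if domain.boundary == "periodic":
        lengths = domain.lengths
        state.pos[top] = lo + np.mod(pos - lo, lengths)
        return []
    # absorbing
    outside = np.flatnonzero(np.any((pos < lo) | (pos > hi), axis=1))
    removed = []
    for s in top[outside]:
        pid = int(state.ids[s])
        removed.append(pid)
        if state.record_events:
            state.events.append((state.time, "absorbed", pid))
        state.remove_particle(pid)
    return removed
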