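"""Reaction semantics: stochastic lower-order rules with arbitrary rate
functions, continuous radius change, compartment division, and
force-mediated bimolecular fuse/transform/nest/unnest reactions.

Lower-order (0th/1st) reactions are sampled per step against their
exponential firing probability; bimolecular reactions are triggered purely
geometrically while the pair force is switched from the contact law to the
constant barrier force W/d*.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

import numpy as np

from . import collision, forces
from .core_model import (MEDIUM, ModelError, ParticleHandle, PlacementError,
                         SystemState, validate_attributes)

FUSE = "fuse"
TRANSFORM = "transform"
NEST = "nest"
UNNEST = "unnest"

_DIVISION_STALL_LIMIT = 200_000


@dataclass(frozen=True)
class Pattern:
    """Reactant pattern: species name, attribute predicate, containment context.

    ``inside`` constrains where the particle lives: ``None`` (anywhere),
    ``"medium"`` (top level), or a species name (directly inside a particle
    of that species).
    """

    species: str
    where: Callable[[ParticleHandle], bool] | None = None
    inside: str | None = None

    def matches(self, state: SystemState, p: ParticleHandle) -> bool:
        if p.species_name != self.species:
            return False
        if self.inside is not None:
            parent = state.meta[p.id].parent
            if self.inside == MEDIUM:
                if parent != MEDIUM:
                    return False
            else:
                if parent == MEDIUM or \
                        state.meta[parent].species.name != self.inside:
                    return False
        return self.where is None or bool(self.where(p))


def as_pattern(spec: "Pattern | str") -> Pattern:
    return spec if isinstance(spec, Pattern) else Pattern(species=spec)


@dataclass
class Rule:
    """Declarative reaction description; build via the module-level helpers."""

    name: str
    order: int
    kind: str  # "create", "first", "divide", or a bimolecular kind
    pattern_a: Pattern | None = None
    pattern_b: Pattern | None = None
    rate: float | None = None
    rate_fn: Callable[[ParticleHandle], float] | None = None
    post_fn: Callable | None = None
    # order-0 creation
    product: str | None = None
    placement: str = "random_in_domain"
    placement_ref: str | None = None  # species of the reference container
    product_radius: float | None = None
    product_attributes: Mapping[str, Any] | None = None
    # bimolecular
    d_star: float | None = None
    d_star_fraction: float | None = None
    w: float = 0.0
    # division
    a_division: float | None = None
    radius_fns: Callable[[ParticleHandle], tuple[float, float]] | None = None
    attr_fns: Callable[[ParticleHandle, np.random.Generator],
                       tuple[dict, dict]] | None = None
    content_split: Callable[[ParticleHandle, np.random.Generator], int] | None = None

    def pair_d_star(self, r_a: float, r_b: float) -> float:
        """Absolute trigger overlap for a concrete pair."""
        if self.d_star is not None:
            return self.d_star
        return self.d_star_fraction * min(r_a, r_b)


def zeroth(name: str, product: str, rate: float | Callable[[SystemState], float],
           placement: str = "random_in_domain", placement_ref: str | None = None,
           radius: float | None = None,
           attributes: Mapping[str, Any] | None = None,
           post_fn: Callable | None = None) -> Rule:
    """∅ → product at a global rate (1/s); products grow in continuously."""
    r = Rule(name=name, order=0, kind="create", product=product,
             placement=placement, placement_ref=placement_ref,
             product_radius=radius, product_attributes=attributes,
             post_fn=post_fn)
    if callable(rate):
        r.rate_fn = rate  # type: ignore[assignment]
    else:
        if rate < 0:
            raise ModelError(f"rule {name!r}: rate must be >= 0")
        r.rate = float(rate)
    if placement not in ("random_in_domain", "inside", "surface"):
        raise ModelError(f"rule {name!r}: unknown placement {placement!r}")
    if placement != "random_in_domain" and placement_ref is None:
        raise ModelError(f"rule {name!r}: placement {placement!r} needs a "
                         "placement_ref species")
    return r


def first(name: str, pattern: Pattern | str,
          rate: float | Callable[[ParticleHandle], float],
          post_fn: Callable) -> Rule:
    """First-order rule: each matching particle fires independently.

    ``rate`` is either a constant (1/s) or an arbitrary function of the
    particle (attributes, content, ...) returning a propensity.
    """
    r = Rule(name=name, order=1, kind="first", pattern_a=as_pattern(pattern),
             post_fn=post_fn)
    if callable(rate):
        r.rate_fn = rate
    else:
        if rate < 0:
            raise ModelError(f"rule {name!r}: rate must be >= 0")
        r.rate = float(rate)
    return r


def divide(name: str, pattern: Pattern | str,
           rate: float | Callable[[ParticleHandle], float],
           a_division: float,
           radius_fns: Callable[[ParticleHandle], tuple[float, float]] | None = None,
           attr_fns: Callable[[ParticleHandle, np.random.Generator],
                              tuple[dict, dict]] | None = None,
           content_split: Callable[[ParticleHandle, np.random.Generator], int]
           | None = None) -> Rule:
    """Compartment division p → p1 + p2 pushed apart with acceleration ``a``.

    Defaults: volume-halving child radii, attribute maps copied from the
    parent, contents assigned by independent fair coin.
    """
    if not a_division > 0:
        raise ModelError(f"rule {name!r}: division acceleration must be > 0")
    r = Rule(name=name, order=1, kind="divide", pattern_a=as_pattern(pattern),
             a_division=float(a_division), radius_fns=radius_fns,
             attr_fns=attr_fns, content_split=content_split)
    if callable(rate):
        r.rate_fn = rate
    else:
        if rate < 0:
            raise ModelError(f"rule {name!r}: rate must be >= 0")
        r.rate = float(rate)
    return r


def bimolecular(name: str, pattern_a: Pattern | str, pattern_b: Pattern | str,
                kind: str, *, d_star: float | None = None,
                d_star_fraction: float | None = None, w: float = 0.0,
                product: str | None = None,
                post_fn: Callable | None = None) -> Rule:
    """Force-mediated pair reaction.

    kind ``fuse``: a + b → product at overlap depth > d*;
    ``transform``: post_fn rewrites both at depth > d*;
    ``nest``: b shuttles into a (triggered at full containment);
    ``unnest``: b (a child of a) shuttles out (triggered when fully outside).
    While the pair overlaps, the contact force is replaced by the constant
    barrier force W/d*.
    """
    if kind not in (FUSE, TRANSFORM, NEST, UNNEST):
        raise ModelError(f"rule {name!r}: unknown bimolecular kind {kind!r}")
    if (d_star is None) == (d_star_fraction is None):
        raise ModelError(f"rule {name!r}: give exactly one of d_star / "
                         "d_star_fraction")
    if d_star is not None and not d_star > 0:
        raise ModelError(f"rule {name!r}: d_star must be > 0")
    if d_star_fraction is not None and not 0 < d_star_fraction:
        raise ModelError(f"rule {name!r}: d_star_fraction must be > 0")
    if w < 0:
        raise ModelError(f"rule {name!r}: barrier W must be >= 0")
    if kind == FUSE and product is None:
        raise ModelError(f"rule {name!r}: fuse requires a product species")
    if kind == TRANSFORM and post_fn is None:
        raise ModelError(f"rule {name!r}: transform requires a post_fn")
    return Rule(name=name, order=2, kind=kind, pattern_a=as_pattern(pattern_a),
                pattern_b=as_pattern(pattern_b), d_star=d_star,
                d_star_fraction=d_star_fraction, w=float(w), product=product,
                post_fn=post_fn)


def should_fire(rate: float, dt: float, rng: np.random.Generator) -> bool:
    """True with probability 1 - exp(-rate·Δt)."""
    if rate < 0:
        raise ModelError("negative reaction rate")
    if not dt > 0:
        raise ModelError("dt must be > 0")
    if rate == 0.0:
        return False
    return bool(rng.random() < -math.expm1(-rate * dt))


@dataclass
class ReactantView:
    """Frozen snapshot of a reactant consumed by a bimolecular reaction."""

    id: int
    species_name: str
    attributes: dict[str, Any]
    position: np.ndarray
    radius: float
    target_radius: float
    mass: float


@dataclass
class Transition:
    """An in-progress continuous structural change (division or shell crossing)."""

    kind: str
    participants: list[int]
    axis: np.ndarray | None = None
    start_time: float = 0.0
    steps: int = 0
    # division bookkeeping
    child1: int | None = None
    child2: int | None = None
    half1: list[int] = field(default_factory=list)
    half2: list[int] = field(default_factory=list)
    r_start: float = 0.0
    rt1: float = 0.0
    rt2: float = 0.0
    a_division: float = 0.0
    #: shells fully apart, force off; waiting for contents to settle inside
    settling: bool = False


class ReactionContext:
    """Mutation helpers handed to user post-reaction functions."""

    def __init__(self, state: SystemState):
        self.state = state
        self.rng = state.rng

    def remove(self, p: ParticleHandle | int) -> None:
        pid = p.id if isinstance(p, ParticleHandle) else p
        self.state.remove_particle(pid)

    def spawn_at(self, species: str, position, parent: Any = MEDIUM, *,
                 radius: float | None = None, attributes=None,
                 velocity=None, ramp: bool = True) -> ParticleHandle:
        pid = self.state.spawn_particle(species, position, parent,
                                        radius=radius, attributes=attributes,
                                        velocity=velocity, ramp=ramp)
        return self.state.particle(pid)

    def spawn_inside(self, species: str, parent: ParticleHandle, *,
                     radius: float | None = None, attributes=None,
                     ramp: bool = True) -> ParticleHandle:
        """Spawn at a uniformly random position inside ``parent``."""
        sp = self.state.model.species_def(species)
        target = radius if radius is not None else sp.default_radius
        room = parent.radius - target
        if room < 0:
            raise PlacementError(
                f"{species} of radius {target:g} cannot fit inside "
                f"{parent.species_name} {parent.id}")
        x = parent.position + _uniform_in_ball(self.rng, room,
                                               self.state.physics.dimension)
        pid = self.state.spawn_particle(species, x, parent.id, radius=target,
                                        attributes=attributes, ramp=ramp)
        return self.state.particle(pid)

    def spawn_at_surface(self, species: str, ref: ParticleHandle, *,
                         radius: float | None = None, attributes=None,
                         ramp: bool = True, tries: int = 32) -> ParticleHandle:
        """Spawn outside ``ref``, shells barely touching at final size."""
        state = self.state
        sp = state.model.species_def(species)
        target = radius if radius is not None else sp.default_radius
        dist = ref.radius + target * (1.0 + 1e-9)
        parent = state.meta[ref.id].parent
        for _ in range(tries):
            u = _random_unit(self.rng, state.physics.dimension)
            x = ref.position + dist * u
            try:
                pid = state.spawn_particle(species, x, parent, radius=target,
                                           attributes=attributes, ramp=ramp)
            except PlacementError:
                continue
            return state.particle(pid)
        raise PlacementError(
            f"no room at the surface of {ref.species_name} {ref.id} "
            f"for a {species} of radius {target:g}")


def _random_unit(rng: np.random.Generator, dim: int) -> np.ndarray:
    while True:
        v = rng.normal(size=dim)
        n = float(np.linalg.norm(v))
        if n > 1e-12:
            return v / n


def _uniform_in_ball(rng: np.random.Generator, r: float, dim: int) -> np.ndarray:
    if r <= 0:
        return np.zeros(dim)
    return _random_unit(rng, dim) * r * rng.random() ** (1.0 / dim)


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def grow_step(state: SystemState, pid: int, dt: float) -> float:
    """Advance one particle's continuous radius ramp; returns the new radius."""
    slot = state.meta[pid].slot
    _grow_slots(state, np.asarray([slot], dtype=np.intp), dt)
    return float(state.rad[slot])


def _grow_slots(state: SystemState, slots: np.ndarray, dt: float) -> None:
    r = state.rad[slots]
    target = state.target_rad[slots]
    step = state.grow_rate[slots] * dt
    delta = target - r
    move = np.sign(delta) * np.minimum(np.abs(delta), step)
    state.rad[slots] = r + move
    done = state.rad[slots] == target
    if done.any():
        state.grow_rate[slots[done]] = 0.0


def apply_growth(state: SystemState, dt: float) -> None:
    """Vectorized radius ramps for every particle with an active target."""
    slots = state.alive_slots()
    growing = slots[state.grow_rate[slots] > 0.0]
    if growing.size:
        _grow_slots(state, growing, dt)


# ---------------------------------------------------------------------------
# lower order firing
# ---------------------------------------------------------------------------

def apply_lower_order(state: SystemState, dt: float) -> int:
    """Fire order-0/1 rules, run growth ramps and division bookkeeping.

    Returns the number of reactions applied.  At most one reaction fires per
    particle per step; simultaneous candidates are resolved by a uniform
    random choice.
    """
    for meta in state.meta.values():
        meta.reacted = False

    for tr in list(state.transitions):
        if tr.kind == "division":
            division_progress(state, tr, dt)

    apply_growth(state, dt)

    rng = state.rng
    ctx = ReactionContext(state)
    n_applied = 0

    # order 0: the number of creations in dt is Poisson(rate*dt)
    for rule in state.model.rules:
        if rule.order != 0:
            continue
        rate = rule.rate if rule.rate_fn is None else float(rule.rate_fn(state))
        if rate < 0:
            raise ModelError(f"rule {rule.name!r} produced a negative rate")
        n_new = int(rng.poisson(rate * dt)) if rate > 0 else 0
        for _ in range(n_new):
            _spawn_created(state, ctx, rule)
            n_applied += 1
            if state.record_events:
                state.events.append((state.time, rule.name))

    # order 1 (incl. division starts): decide everything on the current
    # population snapshot, then resolve one reaction per particle.
    first_rules = [r for r in state.model.rules if r.order == 1]
    if not first_rules:
        return n_applied
    fired: dict[int, list[Rule]] = {}
    for rule in first_rules:
        matches = _matching_particles(state, rule.pattern_a)
        if not matches:
            continue
        if rule.rate_fn is None:
            p_fire = -math.expm1(-rule.rate * dt)
            if p_fire <= 0.0:
                continue
            draws = rng.random(len(matches))
            hits = [pid for pid, u in zip(matches, draws) if u < p_fire]
        else:
            hits = []
            for pid in matches:
                rate = float(rule.rate_fn(state.particle(pid)))
                if rate < 0:
                    raise ModelError(
                        f"rule {rule.name!r} produced a negative rate")
                if should_fire(rate, dt, rng):
                    hits.append(pid)
        for pid in hits:
            fired.setdefault(pid, []).append(rule)

    for pid in sorted(fired):
        meta = state.meta.get(pid)
        if meta is None or meta.reacted or meta.transition is not None:
            continue
        candidates = fired[pid]
        rule = candidates[0] if len(candidates) == 1 else \
            candidates[int(rng.integers(len(candidates)))]
        meta.reacted = True
        if rule.kind == "divide":
            start_division(state, pid, rule)
        else:
            p = state.particle(pid)
            rule.post_fn(p, ctx)
            if pid in state.meta:  # post_fn may have removed the particle
                validate_attributes(state.meta[pid].species,
                                    state.meta[pid].attributes)
        if state.record_events:
            state.events.append((state.time, rule.name, pid))
        n_applied += 1
    return n_applied


def _matching_particles(state: SystemState, pattern: Pattern) -> list[int]:
    out = []
    for pid in state.particle_ids():
        meta = state.meta[pid]
        if meta.reacted or meta.transition is not None:
            continue
        if pattern.matches(state, ParticleHandle(state, pid)):
            out.append(pid)
    return out


def _spawn_created(state: SystemState, ctx: ReactionContext, rule: Rule) -> None:
    sp = state.model.species_def(rule.product)
    radius = rule.product_radius if rule.product_radius is not None \
        else sp.default_radius
    if rule.placement == "random_in_domain":
        domain = state.physics.domain
        x = np.asarray(domain.lo) + state.rng.random(state.physics.dimension) \
            * domain.lengths
        p = ctx.spawn_at(rule.product, x, MEDIUM, radius=radius,
                         attributes=rule.product_attributes, ramp=True)
    else:
        hosts = [pid for pid in state.particle_ids()
                 if state.meta[pid].species.name == rule.placement_ref]
        if not hosts:
            raise PlacementError(
                f"rule {rule.name!r}: no {rule.placement_ref!r} particle to "
                f"place the product {rule.placement}")
        host = state.particle(hosts[int(state.rng.integers(len(hosts)))])
        if rule.placement == "inside":
            p = ctx.spawn_inside(rule.product, host, radius=radius,
                                 attributes=rule.product_attributes)
        else:
            p = ctx.spawn_at_surface(rule.product, host, radius=radius,
                                     attributes=rule.product_attributes)
    if rule.post_fn is not None:
        rule.post_fn(p, ctx)


# ---------------------------------------------------------------------------
# compartment division
# ---------------------------------------------------------------------------

def _default_child_radii(state: SystemState, r: float) -> tuple[float, float]:
    if state.physics.dimension == 3:
        rt = r * 2.0 ** (-1.0 / 3.0)  # volume halving
    else:
        rt = r * 2.0 ** (-1.0 / 2.0)  # area halving
    return rt, rt


def start_division(state: SystemState, pid: int, rule: Rule) -> Transition:
    """Replace a particle by two children sharing its position and radius.

    Contents are assigned to the children (fair coin by default) and ignore
    relations are installed so the separating halves pass through each other
    force-free until fully apart.
    """
    meta = state.meta.get(pid)
    if meta is None:
        raise ModelError(f"unknown particle id {pid}")
    if meta.transition is not None:
        raise ModelError(f"particle {pid} is already in a transition")
    parent_handle = state.particle(pid)
    slot = meta.slot
    pos = state.pos[slot].copy()
    vel = state.vel[slot].copy()
    r_start = float(state.rad[slot])
    density = float(state.dens[slot])
    grandparent = meta.parent
    species = meta.species

    if rule.radius_fns is not None:
        rt1, rt2 = rule.radius_fns(parent_handle)
    else:
        rt1, rt2 = _default_child_radii(state, r_start)
    if not (rt1 > 0 and rt2 > 0):
        raise ModelError(f"rule {rule.name!r}: child radii must be > 0")
    if rule.attr_fns is not None:
        attrs1, attrs2 = rule.attr_fns(parent_handle, state.rng)
    else:
        attrs1, attrs2 = dict(meta.attributes), dict(meta.attributes)
    axis = _random_unit(state.rng, state.physics.dimension)

    contents = state.children_of(pid)
    sides = []
    for cid in contents:
        if rule.content_split is not None:
            side = int(rule.content_split(state.particle(cid), state.rng))
            if side not in (1, 2):
                raise ModelError(
                    f"rule {rule.name!r}: content split must return 1 or 2")
        else:
            side = 1 + int(state.rng.integers(2))
        sides.append(side)

    c1 = state.spawn_particle(species, pos, grandparent, radius=r_start,
                              density=density, velocity=vel, attributes=attrs1,
                              mobile=True)
    c2 = state.spawn_particle(species, pos, grandparent, radius=r_start,
                              density=density, velocity=vel, attributes=attrs2,
                              mobile=True)
    eps = 1e-3 * r_start
    state.pos[state.meta[c1].slot] += eps * axis
    state.pos[state.meta[c2].slot] -= eps * axis

    half1, half2 = [c1], [c2]
    for cid, side in zip(contents, sides):
        target = c1 if side == 1 else c2
        state.reparent(cid, target)
        (half1 if side == 1 else half2).append(cid)

    tr = Transition(kind="division", participants=[c1, c2] + contents,
                    axis=axis, start_time=state.time, child1=c1, child2=c2,
                    half1=half1, half2=half2, r_start=r_start, rt1=rt1,
                    rt2=rt2, a_division=rule.a_division)
    state.meta[c1].ignore.add(c2)
    state.meta[c2].ignore.add(c1)
    for cid in half1[1:]:
        state.meta[cid].ignore.add(c2)
    for cid in half2[1:]:
        state.meta[cid].ignore.add(c1)
    for member in tr.participants:
        state.meta[member].transition = tr
    state.remove_particle(pid)
    state.transitions.append(tr)
    if state.record_events:
        state.events.append((state.time, rule.name, pid, c1, c2))
    return tr


def division_progress(state: SystemState, tr: Transition, dt: float) -> str:
    """Interpolate child radii with separation progress; finish when apart.

    Returns ``"completed"`` or ``"ongoing"``.  Child radii follow
    r(s) = r_start + s·(r_target − r_start) with s the center separation as
    a fraction of the summed target radii.  Once the shells are fully
    outside one another the division force stops and the ignore relations
    are removed; the transition lingers in a *settling* phase until every
    content has been pressed back inside its shell (the containment
    invariant stays suspended until then).
    """
    tr.steps += 1
    if tr.child1 not in state.meta or tr.child2 not in state.meta:
        # a half was consumed or absorbed mid-division: dissolve the transition
        _finish_division(state, tr)
        return "completed"
    if tr.settling:
        if _contents_settled(state, tr):
            _finish_division(state, tr)
            return "completed"
    else:
        s1 = state.meta[tr.child1].slot
        s2 = state.meta[tr.child2].slot
        sep = float(np.linalg.norm(state.pos[s1] - state.pos[s2]))
        s = min(sep / (tr.rt1 + tr.rt2), 1.0)
        state.rad[s1] = tr.r_start + s * (tr.rt1 - tr.r_start)
        state.rad[s2] = tr.r_start + s * (tr.rt2 - tr.r_start)
        state.target_rad[s1] = state.rad[s1]
        state.target_rad[s2] = state.rad[s2]
        if sep >= float(state.rad[s1] + state.rad[s2]) * (1.0 - 1e-12):
            tr.settling = True
            for member in tr.participants:
                meta = state.meta.get(member)
                if meta is not None:
                    meta.ignore.clear()
            if _contents_settled(state, tr):
                _finish_division(state, tr)
                return "completed"
    if tr.steps > _DIVISION_STALL_LIMIT:
        raise ModelError(
            f"division of {tr.child1}/{tr.child2} stalled after "
            f"{tr.steps} steps; increase a_division or check the model")
    return "ongoing"


def _contents_settled(state: SystemState, tr: Transition) -> bool:
    tol = state.physics.tol_contain
    for child in (tr.child1, tr.child2):
        cmeta = state.meta.get(child)
        if cmeta is None:
            continue
        cpos = state.pos[cmeta.slot]
        cr = float(state.rad[cmeta.slot])
        for cid in state.children.get(child, ()):
            meta = state.meta[cid]
            gap = float(np.linalg.norm(state.pos[meta.slot] - cpos))
            if gap + float(state.rad[meta.slot]) > cr + tol:
                return False
    return True


def _finish_division(state: SystemState, tr: Transition) -> None:
    for member in tr.participants:
        meta = state.meta.get(member)
        if meta is None:
            continue
        meta.ignore.clear()
        meta.transition = None
        # restore the species' default mobility (e.g. immobile cells)
        if member in (tr.child1, tr.child2):
            state.mobile[meta.slot] = meta.species.mobile
            if not meta.species.mobile:
                state.vel[meta.slot] = 0.0
    for child, rt in ((tr.child1, tr.rt1), (tr.child2, tr.rt2)):
        meta = state.meta.get(child)
        if meta is not None:
            state.rad[meta.slot] = rt
            state.target_rad[meta.slot] = rt
    state.transitions.remove(tr)
    if state.record_events:
        state.events.append((state.time, "division_complete", tr.child1, tr.child2))


def accumulate_division_forces(state: SystemState, out: np.ndarray) -> None:
    """Add ±m·a along the division axis for every member of each half."""
    for tr in state.transitions:
        if tr.kind != "division" or tr.settling:
            continue
        for half, sign in ((tr.half1, 1.0), (tr.half2, -1.0)):
            slots = np.fromiter(
                (state.meta[pid].slot for pid in half if pid in state.meta),
                dtype=np.intp)
            if slots.size:
                # F = m·a per member, along ±axis (shared acceleration)
                m = state.masses(slots)
                out[slots] += (sign * tr.a_division) * m[:, None] * tr.axis


# ---------------------------------------------------------------------------
# bimolecular phase
# ---------------------------------------------------------------------------

def _bimolecular_rules(state: SystemState) -> list[Rule]:
    return [r for r in state.model.rules if r.order == 2]


def _pair_rule_index(state: SystemState) -> dict[tuple[str, str], list[Rule]]:
    """Order-2 rules indexed by (pattern_a species, pattern_b species)."""
    model = state.model
    cached = getattr(model, "_pair_rule_index", None)
    if cached is not None and cached[0] == len(model.rules):
        return cached[1]
    index: dict[tuple[str, str], list[Rule]] = {}
    for rule in model.rules:
        if rule.order == 2:
            key = (rule.pattern_a.species, rule.pattern_b.species)
            index.setdefault(key, []).append(rule)
    model._pair_rule_index = (len(model.rules), index)
    return index


def _match_pair(state: SystemState, rule: Rule, pair: collision.OverlapPair
                ) -> tuple[int, int] | None:
    """Orient a detected pair against a rule; returns (a, b) ids or None.

    For ``nest``/``fuse``/``transform`` the pair must be siblings
    (free_free); for ``unnest`` the pair must be a child against its own
    parent shell.  ``a`` is always the rule's pattern_a (shell/container
    for nest/unnest).
    """
    ha = ParticleHandle(state, pair.id_a)
    hb = ParticleHandle(state, pair.id_b)
    if rule.kind == UNNEST:
        if pair.relation != collision.INNER_SHELL:
            return None
        # pair is (inner, shell): rule orientation is (shell, inner)
        if rule.pattern_a.matches(state, hb) and rule.pattern_b.matches(state, ha):
            return pair.id_b, pair.id_a
        return None
    if pair.relation != collision.FREE_FREE:
        return None
    if rule.pattern_a.matches(state, ha) and rule.pattern_b.matches(state, hb):
        cand = (pair.id_a, pair.id_b)
    elif rule.pattern_a.matches(state, hb) and rule.pattern_b.matches(state, ha):
        cand = (pair.id_b, pair.id_a)
    else:
        return None
    if rule.kind == NEST:
        # the entering particle must actually fit inside the container
        sa = state.meta[cand[0]].slot
        sb = state.meta[cand[1]].slot
        if state.rad[sb] >= state.rad[sa]:
            return None
    return cand


def _trigger_condition(state: SystemState, rule: Rule, a: int, b: int,
                       pair: collision.OverlapPair) -> bool:
    sa = state.meta[a].slot
    sb = state.meta[b].slot
    if rule.kind in (FUSE, TRANSFORM):
        d_star = rule.pair_d_star(float(state.rad[sa]), float(state.rad[sb]))
        return pair.depth > d_star
    dist = float(np.linalg.norm(state.pos[sa] - state.pos[sb]))
    if rule.kind == NEST:
        # entering particle b fully inside container a
        return dist + float(state.rad[sb]) <= float(state.rad[sa])
    # UNNEST: inner particle b fully outside shell a
    return dist >= float(state.rad[sa]) + float(state.rad[sb])


def apply_pair_phase(state: SystemState, pairs: list[collision.OverlapPair],
                     dt: float) -> int:
    """Resolve every detected overlap: forces and bimolecular triggers.

    Rebuilds ``state.pair_force`` (consumed by both kicks) and executes
    triggered reactions.  Returns the number of reactions executed.
    """
    state.pair_force[: state._n] = 0.0
    rule_index = _pair_rule_index(state)
    contact_on = state.model.pair_contact
    crossing = getattr(state, "_crossing", None)
    if crossing is None:
        crossing = state._crossing = set()
    for pid in crossing:
        meta = state.meta.get(pid)
        if meta is not None and meta.transition is not None \
                and getattr(meta.transition, "kind", None) in ("nesting", "unnesting"):
            meta.transition = None
    crossing.clear()

    contact_batch: list[collision.OverlapPair] = []
    triggers: list[tuple[collision.OverlapPair, Rule, int, int]] = []
    for pair in pairs:
        ma = state.meta.get(pair.id_a)
        mb = state.meta.get(pair.id_b)
        if ma is None or mb is None:
            continue
        matched = None
        na, nb = ma.species.name, mb.species.name
        for key in ((na, nb), (nb, na)) if na != nb else ((na, nb),):
            for rule in rule_index.get(key, ()):
                oriented = _match_pair(state, rule, pair)
                if oriented is not None:
                    matched = (rule, oriented)
                    break
            if matched is not None:
                break
        if matched is None:
            if contact_on:
                contact_batch.append(pair)
            continue
        rule, (a, b) = matched
        if rule.kind == UNNEST and pair.relation == collision.INNER_SHELL:
            # shell crossing in progress (or trigger deferred by the
            # one-reaction-per-step lock): suspend the containment invariant
            inner = state.meta[pair.id_a]
            if inner.transition is None:
                inner.transition = Transition(kind="unnesting",
                                              participants=[pair.id_a],
                                              start_time=state.time)
                crossing.add(pair.id_a)
        if all(not state.meta[x].reacted for x in _locked_ids(rule, a, b)) \
                and _trigger_condition(state, rule, a, b, pair):
            triggers.append((pair, rule, a, b))
            continue
        # reactive force replaces the contact force while the pair overlaps
        if rule.w > 0.0:
            d_star = rule.pair_d_star(
                float(state.rad[ma.slot]), float(state.rad[mb.slot]))
            mag = forces.reactive_force(rule.w, d_star)
            fvec = mag * pair.normal
            state.pair_force[ma.slot] += fvec
            state.pair_force[mb.slot] -= fvec

    if contact_batch:
        _apply_contact_batch(state, contact_batch)
    n_reactions = _execute_triggers(state, triggers)
    return n_reactions


def _apply_contact(state: SystemState, pair: collision.OverlapPair) -> None:
    ma = state.meta[pair.id_a]
    mb = state.meta[pair.id_b]
    mag = forces.pair_contact_force(
        state, ma.species, mb.species, pair.depth,
        float(state.rad[ma.slot]), float(state.rad[mb.slot]))
    fvec = mag * pair.normal
    state.pair_force[ma.slot] += fvec
    state.pair_force[mb.slot] -= fvec


def _apply_contact_batch(state: SystemState,
                         batch: list[collision.OverlapPair]) -> None:
    """Vectorized Hertz forces for all plain contact pairs of a step."""
    if state.model.contact_law is not None:
        for pair in batch:
            _apply_contact(state, pair)
        return
    sa = np.fromiter((state.meta[p.id_a].slot for p in batch),
                     dtype=np.intp, count=len(batch))
    sb = np.fromiter((state.meta[p.id_b].slot for p in batch),
                     dtype=np.intp, count=len(batch))
    depth = np.fromiter((p.depth for p in batch), dtype=float, count=len(batch))
    normals = np.stack([p.normal for p in batch])
    e_star = 1.0 / ((1.0 - state.prat[sa] ** 2) / state.emod[sa]
                    + (1.0 - state.prat[sb] ** 2) / state.emod[sb])
    r_eff = 1.0 / (1.0 / state.rad[sa] + 1.0 / state.rad[sb])
    mag = (4.0 / 3.0) * e_star * np.sqrt(r_eff * depth**3)
    fvec = mag[:, None] * normals
    np.add.at(state.pair_force, sa, fvec)
    np.subtract.at(state.pair_force, sb, fvec)


def _locked_ids(rule: Rule, a: int, b: int) -> tuple[int, ...]:
    """Participants that take the one-reaction-per-step lock.

    Nesting and unnesting leave the shell untouched, so only the moving
    particle is locked; a shell can admit or release several particles in
    one step.
    """
    if rule.kind in (NEST, UNNEST):
        return (b,)
    return (a, b)


def _execute_triggers(state: SystemState,
                      triggers: list[tuple[collision.OverlapPair, Rule, int, int]]
                      ) -> int:
    """One reaction per particle per step; ties broken uniformly at random."""
    if not triggers:
        return 0
    by_particle: dict[int, list[int]] = {}
    for idx, (_, rule, a, b) in enumerate(triggers):
        for pid in _locked_ids(rule, a, b):
            by_particle.setdefault(pid, []).append(idx)
    executed = 0
    ctx = ReactionContext(state)
    for pid in sorted(by_particle):
        meta = state.meta.get(pid)
        if meta is None or meta.reacted:
            continue
        live = [i for i in by_particle[pid]
                if _trigger_alive(state, triggers[i])]
        if not live:
            continue
        choice = live[0] if len(live) == 1 else \
            live[int(state.rng.integers(len(live)))]
        _, rule, a, b = triggers[choice]
        _execute_one(state, ctx, rule, a, b)
        executed += 1
    return executed


def _trigger_alive(state: SystemState, trig) -> bool:
    _, rule, a, b = trig
    if a not in state.meta or b not in state.meta:
        return False
    return all(not state.meta[x].reacted for x in _locked_ids(rule, a, b))


def _snapshot(state: SystemState, pid: int) -> ReactantView:
    meta = state.meta[pid]
    return ReactantView(id=pid, species_name=meta.species.name,
                        attributes=dict(meta.attributes),
                        position=state.pos[meta.slot].copy(),
                        radius=float(state.rad[meta.slot]),
                        target_radius=float(state.target_rad[meta.slot]),
                        mass=float(state.masses(
                            np.asarray([meta.slot], dtype=np.intp))[0]))


def _execute_one(state: SystemState, ctx: ReactionContext, rule: Rule,
                 a: int, b: int) -> None:
    for pid in _locked_ids(rule, a, b):
        state.meta[pid].reacted = True
    if state.record_events:
        state.events.append((state.time, rule.name, a, b))
    if rule.kind == FUSE:
        apply_fusion(state, a, b, rule)
    elif rule.kind == TRANSFORM:
        pa, pb = state.particle(a), state.particle(b)
        rule.post_fn(pa, pb, ctx)
        for pid in (a, b):
            if pid in state.meta:
                validate_attributes(state.meta[pid].species,
                                    state.meta[pid].attributes)
                state.meta[pid].reacted = True
    elif rule.kind == NEST:
        # b is already fully inside a: reparent with no positional jump
        state.reparent(b, a)
        if rule.post_fn is not None:
            rule.post_fn(state.particle(a), state.particle(b), ctx)
    elif rule.kind == UNNEST:
        meta_b = state.meta[b]
        if meta_b.transition is not None and meta_b.transition.kind == "unnesting":
            meta_b.transition = None
            state._crossing.discard(b)
        state.reparent(b, state.meta[a].parent)
        if rule.post_fn is not None:
            rule.post_fn(state.particle(a), state.particle(b), ctx)


def bimolecular_check(state: SystemState, pair: collision.OverlapPair,
                      rule: Rule) -> tuple[int, int] | None:
    """Check one detected overlap against one rule; execute if triggered.

    Returns the oriented (a, b) reactant ids when the reaction fired, else
    ``None`` (no match, lock held, or trigger condition not yet met).  The
    engine's pair phase batches this logic; this entry point serves direct
    driving and tests.
    """
    oriented = _match_pair(state, rule, pair)
    if oriented is None:
        return None
    a, b = oriented
    if any(state.meta[x].reacted for x in _locked_ids(rule, a, b)):
        return None
    if not _trigger_condition(state, rule, a, b, pair):
        return None
    _execute_one(state, ReactionContext(state), rule, a, b)
    return a, b


def apply_fusion(state: SystemState, a: int, b: int, rule: Rule) -> int:
    """a + b → product at the mass-weighted centroid, volume conserved.

    Contents of both reactants move into the product; momentum is conserved.
    The post function may rewrite attributes or set a new target radius
    (which is then reached by a continuous ramp).  Returns the product id.
    """
    va = _snapshot(state, a)
    vb = _snapshot(state, b)
    ma_slot = state.meta[a].slot
    mb_slot = state.meta[b].slot
    mtot = va.mass + vb.mass
    centroid = (va.mass * va.position + vb.mass * vb.position) / mtot
    velocity = (va.mass * state.vel[ma_slot] + vb.mass * state.vel[mb_slot]) / mtot
    if state.physics.dimension == 3:
        radius = (va.radius**3 + vb.radius**3) ** (1.0 / 3.0)
    else:
        radius = math.hypot(va.radius, vb.radius)
    density = mtot / (math.pi * radius**2 if state.physics.dimension == 2
                      else (4.0 / 3.0) * math.pi * radius**3)
    parent = state.meta[a].parent
    contents = state.children_of(a) + state.children_of(b)
    # the product may transiently breach its parent shell; contact forces
    # resolve that, so placement checks are skipped here
    pid = state.spawn_particle(rule.product, state.pos[ma_slot], MEDIUM,
                               radius=radius, density=density,
                               velocity=velocity)
    slot = state.meta[pid].slot
    state.pos[slot] = centroid
    if parent != MEDIUM:
        state.reparent(pid, parent)
    for cid in contents:
        state.reparent(cid, pid)
    state.remove_particle(a)
    state.remove_particle(b)
    state.meta[pid].reacted = True
    if rule.post_fn is not None:
        ctx = ReactionContext(state)
        rule.post_fn(state.particle(pid), va, vb, ctx)
        if pid in state.meta:
            validate_attributes(state.meta[pid].species,
                                state.meta[pid].attributes)
    return pid
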