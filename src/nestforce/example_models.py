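"""Runnable scenario families and the analysis helpers used to validate them.

Four families ship with the package: the correctness suite (birth, decay,
reversible bimolecular), vesicular transport between two compartments,
a yeast colony with a non-spatial cell-cycle clock, and a lipid-raft
membrane patch.  Builders are deterministic given a seed; every default
number is either the literature value or an explicitly scaled desk-size
stand-in (see the docstrings).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import reactions, units
from .core_model import (MEDIUM, Domain, Model, ModelError, PhysicsParams,
                         PlacementError, SystemState)
from .forces import dipole_field
from .reactions import (FUSE, NEST, TRANSFORM, UNNEST, Pattern, bimolecular,
                        divide, first, zeroth)
from .units import KB


@dataclass
class ScenarioSpec:
    name: str
    builder: Callable[..., SystemState]
    description: str
    default_steps: int = 100


SCENARIOS: dict[str, ScenarioSpec] = {}


def register_scenario(name: str, description: str, default_steps: int = 100):
    def deco(fn):
        SCENARIOS[name] = ScenarioSpec(name=name, builder=fn,
                                       description=description,
                                       default_steps=default_steps)
        return fn
    return deco


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ModelError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None


def list_scenarios() -> list[ScenarioSpec]:
    return [SCENARIOS[k] for k in sorted(SCENARIOS)]


def _disc_density(radius: float, rho3d: float = 1000.0) -> float:
    """2D density giving a unit-thickness disc the mass of the 3D sphere."""
    return rho3d * (4.0 / 3.0) * radius


# ---------------------------------------------------------------------------
# correctness suite
# ---------------------------------------------------------------------------

@register_scenario("birth", "zeroth-order creation ∅ → A at constant rate k")
def birth_scenario(seed: int = 0, k: float = 10.0, max_timestep: float = 0.1,
                   box: float = 2e-5) -> SystemState:
    """∅ → A at k (1/s).  A is immobile so the step cost stays O(1)."""
    model = Model("birth")
    model.register_species("A", default_radius=1e-6, mobile=False)
    model.add_rule(zeroth("birth", "A", rate=k))
    physics = PhysicsParams(domain=Domain.box(box, 3),
                            max_timestep=max_timestep, growth_time=1e-3)
    return SystemState(model, physics, seed=seed)


@register_scenario("decay", "first-order decay A → ∅ at constant rate k")
def decay_scenario(seed: int = 0, k: float = 1.0, n0: int = 1000,
                   max_timestep: float = 0.01, box: float = 2e-5) -> SystemState:
    model = Model("decay")
    model.register_species("A", default_radius=1e-6, mobile=False)

    def die(p, ctx):
        ctx.remove(p)

    model.add_rule(first("decay", "A", rate=k, post_fn=die))
    physics = PhysicsParams(domain=Domain.box(box, 3),
                            max_timestep=max_timestep)
    state = SystemState(model, physics, seed=seed)
    rng = state.rng
    for _ in range(n0):
        x = rng.random(3) * box
        state.spawn_particle("A", x)
    return state


@register_scenario("reversible_bimolecular",
                   "A + B ⇌ C, diffusion-limited forward (W = 0)")
def reversible_scenario(seed: int = 0, n_pairs: int = 20, k_back: float = 0.0,
                        radius: float = 5e-8, box: float = 3e-6,
                        ballistic_fraction: float = 0.5,
                        d_star_fraction: float = 0.1,
                        w: float = 0.0,
                        temperature: float = 310.0) -> SystemState:
    """Diffusion-limited A + B → C (optionally reversible at k_back).

    The solvent viscosity is chosen so the ballistic length
    sqrt(k_B T m)/γ equals ``ballistic_fraction`` of the particle radius,
    which keeps motion diffusive on the capture scale while allowing a
    desk-size timestep (the physics are otherwise literal SI).
    """
    model = Model("reversible")
    rho = 1000.0
    m = rho * (4.0 / 3.0) * math.pi * radius**3
    ell = ballistic_fraction * radius
    gamma = math.sqrt(KB * temperature * m) / ell
    eta = gamma / (6.0 * math.pi * radius)
    for name in ("A", "B", "C"):
        model.register_species(name, default_radius=radius)
    model.add_rule(bimolecular("forward", "A", "B", FUSE, product="C",
                               d_star_fraction=d_star_fraction, w=w))
    if k_back > 0:
        def split(p, ctx):
            pos = p.position
            domain = ctx.state.physics.domain
            ctx.remove(p)
            ctx.spawn_at("A", pos, ramp=False)
            # place B just clear of A so the pair does not instantly re-fuse
            for _ in range(64):
                u = reactions._random_unit(ctx.rng, 3)
                x = pos + (2.0 * radius * 1.05) * u
                if domain.contains(x):
                    ctx.spawn_at("B", x, ramp=False)
                    return
            raise PlacementError("no room to place the dissociation product")
        model.add_rule(first("backward", "C", rate=k_back, post_fn=split))
    physics = PhysicsParams(domain=Domain.box(box, 3), temperature=temperature,
                            medium_viscosity=eta,
                            max_timestep=0.05 * m / gamma,
                            growth_time=10 * 0.05 * m / gamma)
    state = SystemState(model, physics, seed=seed)
    rng = state.rng
    for name in ("A", "B"):
        for _ in range(n_pairs):
            state.spawn_particle(name, radius + rng.random(3) * (box - 2 * radius))
    return state


@register_scenario("bimolecular_rate",
                   "A + B → C at constant concentration (rate measurement)")
def bimolecular_rate_scenario(seed: int = 0, n_pairs: int = 40,
                              box: float = 3e-6, radius: float = 5e-8,
                              ballistic_fraction: float = 0.3,
                              d_star_fraction: float = 0.1, w: float = 0.0,
                              temperature: float = 310.0) -> SystemState:
    """Scattering fixture: every fusion respawns its reactants uniformly.

    Concentrations stay constant, so the macroscopic rate constant is simply
    V·(events)/(N_A·N_B·T_window) — no depletion, no consumption-window
    ambiguity.  Fired events are on ``state.events`` under rule name
    ``"forward"``.  The viscosity keeps the ballistic length at
    ``ballistic_fraction``·radius (diffusive on the capture scale).
    """
    model = Model("bimolecular_rate")
    rho = 1000.0
    m = rho * (4.0 / 3.0) * math.pi * radius**3
    gamma = math.sqrt(KB * temperature * m) / (ballistic_fraction * radius)
    eta = gamma / (6.0 * math.pi * radius)
    for name in ("A", "B", "C"):
        model.register_species(name, default_radius=radius)

    def respawn(product, va, vb, ctx):
        state = ctx.state
        ctx.remove(product)
        span = box - 2 * radius
        for name in ("A", "B"):
            x = radius + ctx.rng.random(3) * span
            ctx.spawn_at(name, x, ramp=False)

    model.add_rule(bimolecular("forward", "A", "B", FUSE, product="C",
                               d_star_fraction=d_star_fraction, w=w,
                               post_fn=respawn))
    physics = PhysicsParams(domain=Domain.box(box, 3), temperature=temperature,
                            medium_viscosity=eta,
                            max_timestep=0.05 * m / gamma,
                            growth_time=0.5 * m / gamma)
    state = SystemState(model, physics, seed=seed)
    rng = state.rng
    for name in ("A", "B"):
        for _ in range(n_pairs):
            state.spawn_particle(name,
                                 radius + rng.random(3) * (box - 2 * radius))
    return state


def smoluchowski_rate(d_sum: float, r_sum: float) -> float:
    """Encounter-limited rate 4π(D_A+D_B)(r_A+r_B) for 3D spheres (m³/s)."""
    return 4.0 * math.pi * d_sum * r_sum


@register_scenario("free_diffusion", "non-interacting Langevin spheres")
def free_diffusion_scenario(seed: int = 0, n: int = 1000, radius: float = 1e-6,
                            viscosity: float = 1e-3, temperature: float = 310.0,
                            box: float = 2e-4, dt_fraction: float = 0.02
                            ) -> SystemState:
    """n ideal spheres (contact disabled): pure Langevin diffusion.

    max_timestep is ``dt_fraction``·m/γ so the explicit friction kick stays
    deep in its stability region.
    """
    model = Model("free_diffusion")
    model.register_species("A", default_radius=radius)
    model.pair_contact = False
    rho = 1000.0
    m = rho * (4.0 / 3.0) * math.pi * radius**3
    gamma = 6.0 * math.pi * viscosity * radius
    physics = PhysicsParams(domain=Domain.box(box, 3), temperature=temperature,
                            medium_viscosity=viscosity,
                            max_timestep=dt_fraction * m / gamma)
    state = SystemState(model, physics, seed=seed)
    rng = state.rng
    margin = 0.1 * box
    for _ in range(n):
        x = margin + rng.random(3) * (box - 2 * margin)
        state.spawn_particle("A", x)
    return state


def correctness_suite() -> dict[str, ScenarioSpec]:
    """The three elementary validation scenarios."""
    return {k: SCENARIOS[k] for k in ("birth", "decay", "reversible_bimolecular")}


# ---------------------------------------------------------------------------
# vesicular transport
# ---------------------------------------------------------------------------

#: literature initial volumes (m^3) of the two compartments, directed case
V1_DIRECTED = 0.118 * units.um**3
V2_DIRECTED = 0.013 * units.um**3
#: control: equal initial volumes
V_CONTROL = 0.065 * units.um**3
#: SNARE copy numbers per type (directed: 90%/10%; control: 50%/50%)
SNARES_DIRECTED = (90000, 10000)
SNARES_CONTROL = (50000, 50000)
CELL_RADIUS = 2.5 * units.um


def _radius_from_volume(v: float) -> float:
    return (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)


@register_scenario("vesicle_transport",
                   "two compartments exchanging SNAREs via coated vesicles")
def vesicle_transport_scenario(seed: int = 0, directed: bool = True,
                               scale: float = 2e-3,
                               vesicle_radius: float = 1e-7,
                               k_bud: float = 2.5e5,
                               field_strength: float = 7.5e-13,
                               viscosity: float = 1e-5,
                               snare_per_vesicle: int = 4) -> SystemState:
    """Vesicle transport in a cell of radius 2.5 μm.

    Directed: compartment 1 is nine times bigger (V1 ≈ 0.118 μm³,
    V2 ≈ 0.013 μm³) and a two-pole steering field routes X-coated vesicles
    to compartment 1 and Y-coated ones to compartment 2.  Control: equal
    volumes, no field, pure Brownian motion.

    Desk scaling: SNARE copy numbers are multiplied by ``scale`` and the
    cytosol viscosity is lowered to make vesicle transits resolvable in
    ~10^4 steps; the contrast between the directed and the Brownian run is
    unaffected.
    """
    if not 0 < scale <= 1:
        raise ModelError("scale must be in (0, 1]")
    snares = SNARES_DIRECTED if directed else SNARES_CONTROL
    n1 = int(round(snares[0] * scale))
    n2 = int(round(snares[1] * scale))
    if n1 == 0 or n2 == 0:
        raise ModelError("scale so small that SNARE counts round to zero")

    model = Model("vesicle_transport")
    model.register_species("Cell", default_radius=CELL_RADIUS, mobile=False,
                           interior_viscosity=viscosity)
    model.register_species(
        "Comp",
        attribute_schema=[("tag", "string"), ("snare_x", "integer"),
                          ("snare_y", "integer")],
        default_radius=_radius_from_volume(V1_DIRECTED), mobile=False)
    model.register_species(
        "V",
        attribute_schema=[("coat", "string"), ("snare_x", "integer"),
                          ("snare_y", "integer")],
        default_radius=vesicle_radius)

    v_ves = (4.0 / 3.0) * math.pi * vesicle_radius**3

    def bud_rate(p):
        # budding frequency grows with compartment volume and stops when the
        # compartment is nearly used up
        v = (4.0 / 3.0) * math.pi * p.target_radius**3
        if v < 3.0 * v_ves:
            return 0.0
        return k_bud * v / V1_DIRECTED

    def bud(p, ctx):
        attrs = p.attributes
        total = attrs["snare_x"] + attrs["snare_y"]
        if total <= 0:
            return
        p_x = attrs["snare_x"] / total
        coat = "X" if ctx.rng.random() < p_x else "Y"
        key = "snare_x" if coat == "X" else "snare_y"
        carry = min(snare_per_vesicle, attrs[key])
        vattrs = {"coat": coat, "snare_x": carry if coat == "X" else 0,
                  "snare_y": carry if coat == "Y" else 0}
        try:
            ctx.spawn_at_surface("V", p, attributes=vattrs)
        except Exception:
            return  # no room this step; try again later
        p.set_attr(key, attrs[key] - carry)
        new_r = (p.target_radius**3 - vesicle_radius**3) ** (1.0 / 3.0)
        p.retarget_radius(new_r)

    model.add_rule(first("bud", "Comp", rate=bud_rate, post_fn=bud))

    def fuse_post(product, va, vb, ctx):
        comp = va if va.species_name == "Comp" else vb
        ves = vb if comp is va else va
        # compartments are tethered at the field poles: undo the centroid
        # displacement so repeated fusions do not walk them off their pole
        product.position = comp.position
        # budding debits target volumes, so fusion must credit them too;
        # otherwise every mid-growth fusion leaks volume
        product.retarget_radius(
            (comp.target_radius**3 + ves.target_radius**3) ** (1.0 / 3.0))
        product.set_attr("tag", comp.attributes["tag"])
        product.set_attr("snare_x",
                         comp.attributes["snare_x"] + ves.attributes["snare_x"])
        product.set_attr("snare_y",
                         comp.attributes["snare_y"] + ves.attributes["snare_y"])

    model.add_rule(bimolecular("fuse", "Comp", "V", FUSE, product="Comp",
                               d_star_fraction=0.5, w=0.0, post_fn=fuse_post))

    dim = 3
    box = 6e-6
    center = np.full(dim, box / 2.0)
    offset = np.zeros(dim)
    offset[0] = 1.2e-6
    pole1 = center + offset
    pole2 = center - offset

    if directed:
        model.add_force_field(dipole_field(
            "motor", pole1, pole2, field_strength,
            side_of=lambda p: {"X": "a", "Y": "b"}.get(p.attributes["coat"], ""),
            applies_to=lambda p: p.species_name == "V"))

    rho = 1000.0
    m_ves = rho * v_ves
    gamma_ves = 6.0 * math.pi * viscosity * vesicle_radius
    physics = PhysicsParams(domain=Domain.box(box, dim), temperature=310.0,
                            medium_viscosity=1e-3,
                            max_timestep=0.1 * m_ves / gamma_ves,
                            growth_time=40 * 0.1 * m_ves / gamma_ves,
                            tol_contain=0.2 * vesicle_radius)
    physics_spawn_fraction = 0.25  # see SystemState setup below
    state = SystemState(model, physics, seed=seed)
    state.spawn_fraction = physics_spawn_fraction

    cell = state.spawn_particle("Cell", center)
    if directed:
        r1 = _radius_from_volume(V1_DIRECTED)
        r2 = _radius_from_volume(V2_DIRECTED)
    else:
        r1 = r2 = _radius_from_volume(V_CONTROL)
    state.spawn_particle("Comp", pole1, cell, radius=r1,
                         attributes={"tag": "C1", "snare_x": n1, "snare_y": n1})
    state.spawn_particle("Comp", pole2, cell, radius=r2,
                         attributes={"tag": "C2", "snare_x": n2, "snare_y": n2})
    return state


def compartment_volumes(state: SystemState) -> dict[str, float]:
    """Current volume (m³) per compartment tag, from the target radii."""
    out = {}
    for pid, meta in state.meta.items():
        if meta.species.name == "Comp":
            r = float(state.target_rad[meta.slot])
            out[meta.attributes["tag"]] = (4.0 / 3.0) * math.pi * r**3
    return out


def snare_totals(state: SystemState) -> dict[str, int]:
    """Total SNARE copies of each type over compartments and vesicles."""
    tx = ty = 0
    for meta in state.meta.values():
        if meta.species.name in ("Comp", "V"):
            tx += meta.attributes["snare_x"]
            ty += meta.attributes["snare_y"]
    return {"X": tx, "Y": ty}


def snare_x_fraction(state: SystemState, tag: str = "C1") -> float:
    """Fraction of all compartment-held SNARE X sitting in one compartment."""
    x_tag = x_all = 0
    for meta in state.meta.values():
        if meta.species.name == "Comp":
            x_all += meta.attributes["snare_x"]
            if meta.attributes["tag"] == tag:
                x_tag += meta.attributes["snare_x"]
    return x_tag / x_all if x_all else float("nan")


# ---------------------------------------------------------------------------
# yeast colony
# ---------------------------------------------------------------------------

#: stages of the Erlang cell-cycle clock (CV of the period = 1/sqrt(N))
CYCLE_STAGES = 60
#: literature cell-cycle period
CYCLE_PERIOD = 120.0 * units.minute


@register_scenario("yeast", "yeast cells with a non-spatial cell-cycle clock")
def yeast_scenario(seed: int = 0, scale: float = 0.01, n_cells: int = 4,
                   box: float = 1.2e-5, cell_radius: float = 2e-6,
                   pheromone_radius: float = 3e-7, viscosity: float = 1e-5,
                   k_emit_factor: float = 2.0, inhibition: float = 0.05,
                   a_division: float = 5e3, emit: bool = True) -> SystemState:
    """2D yeast colony.

    Cells are immobile particles whose cell cycle runs as a non-spatial
    Erlang clock in their attributes: a ``cycle`` reaction increments the
    ``phase`` attribute through ``CYCLE_STAGES`` stages, so the mean
    inter-division time is the 120 min literature period multiplied by
    ``scale`` (desk default 0.01 → 72 s), with a small CV.  Bound
    pheromones divide the clock rate by (1 + inhibition·bound).  P cells
    emit P-factor, M cells emit M-factor and the protease Sxa2; pheromones
    diffuse in the medium and are absorbed at the domain border.
    """
    if not 0 < scale <= 1:
        raise ModelError("scale must be in (0, 1]")
    period = CYCLE_PERIOD * scale
    k_stage = CYCLE_STAGES / period

    model = Model("yeast")
    model.register_species(
        "Cell",
        attribute_schema=[("mating", "string"), ("phase", "integer"),
                          ("bound", "integer")],
        default_radius=cell_radius, mobile=False,
        attribute_defaults={"mating": "P"})
    for name in ("Pfac", "Mfac", "Sxa2"):
        model.register_species(name, default_radius=pheromone_radius,
                               default_density=_disc_density(pheromone_radius))

    def cycle_rate(p):
        return k_stage / (1.0 + inhibition * p.attributes["bound"])

    def tick(p, ctx):
        p.set_attr("phase", p.attributes["phase"] + 1)

    model.add_rule(first("cycle", "Cell", rate=cycle_rate, post_fn=tick))

    def div_attrs(p, rng):
        a = dict(p.attributes)
        b = dict(p.attributes)
        a["phase"] = b["phase"] = 0
        a["bound"] = p.attributes["bound"] // 2
        b["bound"] = p.attributes["bound"] - a["bound"]
        # the mating type can switch at fission
        if rng.random() < 0.5:
            b["mating"] = "M" if p.attributes["mating"] == "P" else "P"
        return a, b

    model.add_rule(divide(
        "fission", Pattern("Cell", where=lambda p: p.attributes["phase"] >= CYCLE_STAGES),
        rate=50.0 * k_stage, a_division=a_division,
        radius_fns=lambda p: (cell_radius, cell_radius),
        attr_fns=div_attrs))

    if emit:
        k_emit = k_emit_factor / period

        def emitter(species):
            def post(p, ctx):
                try:
                    ctx.spawn_at_surface(species, p)
                except Exception:
                    pass  # crowded surface; skip this emission
            return post

        model.add_rule(first("emit_p", Pattern("Cell", where=lambda p: p.attributes["mating"] == "P"),
                             rate=k_emit, post_fn=emitter("Pfac")))
        model.add_rule(first("emit_m", Pattern("Cell", where=lambda p: p.attributes["mating"] == "M"),
                             rate=k_emit, post_fn=emitter("Mfac")))
        model.add_rule(first("emit_sxa2", Pattern("Cell", where=lambda p: p.attributes["mating"] == "M"),
                             rate=0.5 * k_emit, post_fn=emitter("Sxa2")))

    def bind_post(cell, pher, ctx):
        cell.set_attr("bound", cell.attributes["bound"] + 1)
        ctx.remove(pher)

    model.add_rule(bimolecular(
        "bind_p", Pattern("Cell", where=lambda p: p.attributes["mating"] == "M"),
        "Pfac", TRANSFORM, d_star_fraction=0.5, post_fn=bind_post))
    model.add_rule(bimolecular(
        "bind_m", Pattern("Cell", where=lambda p: p.attributes["mating"] == "P"),
        "Mfac", TRANSFORM, d_star_fraction=0.5, post_fn=bind_post))

    def annihilate(a, b, ctx):
        ctx.remove(a)
        ctx.remove(b)

    model.add_rule(bimolecular("degrade_p", "Sxa2", "Pfac", TRANSFORM,
                               d_star_fraction=0.5, post_fn=annihilate))

    # the adaptive formula cuts the step whenever mobile pheromones exist;
    # semi-implicit friction keeps the kick stable at those coarse steps
    physics = PhysicsParams(domain=Domain.box(box, 2, boundary="absorbing"),
                            dimension=2, temperature=310.0,
                            medium_viscosity=viscosity,
                            max_timestep=period / 400.0,
                            semi_implicit_friction=True,
                            growth_time=period / 100.0,
                            tol_contain=0.2 * pheromone_radius)
    state = SystemState(model, physics, seed=seed)
    state.spawn_fraction = 0.25

    rng = state.rng
    for i in range(n_cells):
        for _ in range(100):
            x = np.asarray([0.3, 0.3]) * box + rng.random(2) * 0.4 * box
            ok = all(np.linalg.norm(x - state.pos[m.slot]) > 2.5 * cell_radius
                     for m in state.meta.values())
            if ok:
                break
        mating = "P" if i % 2 == 0 else "M"
        state.spawn_particle("Cell", x,
                             attributes={"mating": mating, "phase": 0, "bound": 0})
    return state


# ---------------------------------------------------------------------------
# lipid raft
# ---------------------------------------------------------------------------

#: entry barrier of the receptor protein (J)
LRP_BARRIER = 12e-21
#: raft / membrane viscosity ratio
RAFT_VISCOSITY_FACTOR = 10.0
#: raft area fraction of the membrane patch
RAFT_AREA_FRACTION = 0.25


@register_scenario("lipid_raft",
                   "membrane patch with one raft and two nesting proteins")
def lipid_raft_scenario(seed: int = 0, n_each: int = 200, box: float = 1e-6,
                        protein_radius: float = 1e-8,
                        temperature: float = 310.0,
                        ballistic_fraction: float = 1.5,
                        granularity: float = 2.0) -> SystemState:
    """2D membrane with a static lipid raft covering 25% of the area.

    200 LRP 5/6 and 200 CK1-γ proteins start outside the raft.  Entering
    the raft is a nesting reaction with barrier W = 12e-21 J for LRP 5/6
    and W = 0 for CK1-γ; leaving is free for both.  The raft interior is 10
    times more viscous than the membrane, so the diffusion coefficient
    inside is 10 times lower.  The membrane viscosity is chosen so the
    ballistic length is ``ballistic_fraction``·protein_radius (desk-size
    steps at literal thermal energies); friction is integrated
    semi-implicitly so the step can sit at the stability edge.
    """
    raft_radius = math.sqrt(RAFT_AREA_FRACTION / math.pi) * box
    rho2d = _disc_density(protein_radius)
    m = rho2d * math.pi * protein_radius**2
    ell = ballistic_fraction * protein_radius
    gamma = math.sqrt(KB * temperature * m) / ell
    eta = gamma / (6.0 * math.pi * protein_radius)

    model = Model("lipid_raft")
    model.register_species("Raft", default_radius=raft_radius, mobile=False,
                           interior_viscosity=RAFT_VISCOSITY_FACTOR * eta)
    model.register_species("LRP", default_radius=protein_radius,
                           default_density=rho2d)
    model.register_species("CK1", default_radius=protein_radius,
                           default_density=rho2d)

    d_cross = 2.0 * protein_radius  # full shell-crossing distance
    model.add_rule(bimolecular("lrp_enter", "Raft", "LRP", NEST,
                               d_star=d_cross, w=LRP_BARRIER))
    model.add_rule(bimolecular("ck1_enter", "Raft", "CK1", NEST,
                               d_star=d_cross, w=0.0))
    model.add_rule(bimolecular("lrp_exit", "Raft", "LRP", UNNEST,
                               d_star=d_cross, w=0.0))
    model.add_rule(bimolecular("ck1_exit", "Raft", "CK1", UNNEST,
                               d_star=d_cross, w=0.0))

    physics = PhysicsParams(domain=Domain.box(box, 2), dimension=2,
                            temperature=temperature, medium_viscosity=eta,
                            granularity=granularity,
                            max_timestep=0.5 * m / gamma,
                            semi_implicit_friction=True,
                            tol_contain=protein_radius)
    state = SystemState(model, physics, seed=seed)
    center = np.full(2, box / 2.0)
    state.spawn_particle("Raft", center)
    rng = state.rng
    for name in ("LRP", "CK1"):
        placed = 0
        while placed < n_each:
            x = protein_radius + rng.random(2) * (box - 2 * protein_radius)
            if np.linalg.norm(x - center) > raft_radius + protein_radius:
                state.spawn_particle(name, x)
                placed += 1
    return state


def raft_occupancy(state: SystemState) -> dict[str, int]:
    """Number of each protein species currently nested inside the raft."""
    raft = next(pid for pid, m in state.meta.items()
                if m.species.name == "Raft")
    out = {"LRP": 0, "CK1": 0}
    for cid in state.children_of(raft):
        out[state.meta[cid].species.name] += 1
    return out


# ---------------------------------------------------------------------------
# analysis helpers
# ---------------------------------------------------------------------------

def estimate_rate(times, counts, order: int) -> tuple[float, float]:
    """Rate constant and its standard error from a counts time series.

    order 0: linear fit, rate = slope (counts/s).
    order 1: log-linear fit of the survival curve, rate = -slope (1/s).
    order 2 (equal reactant counts): linear fit of 1/N, slope = k/V·...
    (returned in 1/(count·s); multiply by the volume for m³/s).
    """
    t = np.asarray(times, dtype=float)
    n = np.asarray(counts, dtype=float)
    if t.size < 3:
        raise ModelError("need at least 3 points to estimate a rate")
    if order == 0:
        y = n
        sign = 1.0
    elif order == 1:
        if np.any(n <= 0):
            keep = n > 0
            t, n = t[keep], n[keep]
            if t.size < 3:
                raise ModelError("survival curve hit zero too early; "
                                 "use more particles or shorter horizon")
        y = np.log(n)
        sign = -1.0
    elif order == 2:
        if np.any(n <= 0):
            keep = n > 0
            t, n = t[keep], n[keep]
            if t.size < 3:
                raise ModelError("counts hit zero; shorten the fit window")
        y = 1.0 / n
        sign = 1.0
    else:
        raise ModelError("order must be 0, 1 or 2")
    (slope, _), cov = np.polyfit(t, y, 1, cov=True)
    return sign * float(slope), float(math.sqrt(cov[0, 0]))


def msd(frames: np.ndarray, dt: float, max_lag: int | None = None,
        n_lags: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble + time-origin averaged mean squared displacement.

    ``frames`` has shape (T, N, d) sampled every ``dt`` seconds; returns
    (lag_times, msd_values) on a grid of ``n_lags`` lags up to ``max_lag``
    frames (default T//2).
    """
    frames = np.asarray(frames)
    t_frames = frames.shape[0]
    if max_lag is None:
        max_lag = t_frames // 2
    lags = np.unique(np.linspace(1, max_lag, n_lags).astype(int))
    out = np.empty(lags.size)
    for i, lag in enumerate(lags):
        disp = frames[lag:] - frames[:-lag]
        out[i] = float(np.mean(np.sum(disp**2, axis=-1)))
    return lags * dt, out


def occupancy(state: SystemState, species: str, container_species: str) -> float:
    """Fraction of a species' particles nested inside containers of a kind."""
    total = inside = 0
    for meta in state.meta.values():
        if meta.species.name != species:
            continue
        total += 1
        if meta.parent != MEDIUM and \
                state.meta[meta.parent].species.name == container_species:
            inside += 1
    return inside / total if total else float("nan")
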