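"""Reaction semantics: firing, growth, division, bimolecular triggers."""
import math

import numpy as np
import pytest

import nestforce as nf
from nestforce import collision, reactions
from nestforce.core_model import (MEDIUM, Domain, Model, ModelError,
                                  PhysicsParams, SystemState)
from nestforce.reactions import (FUSE, NEST, TRANSFORM, UNNEST, Pattern,
                                 bimolecular, divide, first, should_fire,
                                 zeroth)

from conftest import make_division_state, run_division


class TestShouldFire:
    def test_zero_rate_never(self):
        rng = np.random.default_rng(0)
        assert not any(should_fire(0.0, 1.0, rng) for _ in range(100))

    def test_log2_rate_fires_half_the_time(self):
        # rate*dt = ln 2 -> p = 1 - exp(-ln 2) = 0.5
        rng = np.random.default_rng(1)
        n = 100_000
        hits = sum(should_fire(math.log(2), 1.0, rng) for _ in range(n))
        sigma = math.sqrt(n * 0.25)
        assert abs(hits - n / 2) < 3 * sigma

    def test_huge_rate_always(self):
        rng = np.random.default_rng(2)
        assert all(should_fire(1e12, 1.0, rng) for _ in range(100))

    def test_negative_rate_rejected(self):
        with pytest.raises(ModelError):
            should_fire(-1.0, 1.0, np.random.default_rng(0))


def immobile_box(seed=0, box=2e-5, max_timestep=0.01):
    model = Model()
    model.register_species("A", [("b", "number"), ("c", "number")],
                           default_radius=1e-6, mobile=False)
    physics = PhysicsParams(domain=Domain.box(box, 3),
                            max_timestep=max_timestep)
    return Model, SystemState(model, physics, seed=seed)


class TestLowerOrder:
    def test_decay_matches_exponential(self):
        # survival of per-particle Bernoulli(1 - e^{-k dt}) is exactly e^{-kt}
        _, state = immobile_box(seed=3)
        k = 1.0
        state.model.add_rule(first("decay", "A", rate=k,
                                   post_fn=lambda p, ctx: ctx.remove(p)))
        n0 = 2000
        for _ in range(n0):
            state.spawn_particle("A", 1e-6 + state.rng.random(3) * 1.8e-5)
        checkpoints = []
        while state.time < 3.0:
            nf.step(state)
            checkpoints.append((state.time, state.n_particles))
        for t, n in checkpoints[::60]:
            p = math.exp(-k * t)
            sd = math.sqrt(n0 * p * (1 - p))
            assert abs(n - n0 * p) < 4 * max(sd, 1.0)

    def test_attribute_dependent_rate(self):
        # propensity b*c*k evaluated per particle: firing prob 1 - e^{-bck dt}
        _, state = immobile_box(seed=4, max_timestep=0.05)
        k = 2.0
        state.model.add_rule(first(
            "anneal", "A", rate=lambda p: p.attributes["b"] * p.attributes["c"] * k,
            post_fn=lambda p, ctx: ctx.remove(p)))
        n0 = 4000
        b, c = 3.0, 0.7
        for _ in range(n0):
            state.spawn_particle("A", 1e-6 + state.rng.random(3) * 1.8e-5,
                                 attributes={"b": b, "c": c})
        nf.step(state)
        dt = state.time
        p_fire = 1 - math.exp(-b * c * k * dt)
        fired = n0 - state.n_particles
        sd = math.sqrt(n0 * p_fire * (1 - p_fire))
        assert abs(fired - n0 * p_fire) < 4 * sd

    def test_zero_order_poisson_counts(self):
        _, state = immobile_box(seed=5, max_timestep=0.5)
        state.model.add_rule(zeroth("birth", "A", rate=10.0))
        while state.time < 20.0:
            nf.step(state)
        n = state.n_particles
        # Poisson(200): 4 sigma window
        assert abs(n - 200) < 4 * math.sqrt(200)

    def test_one_reaction_per_particle_per_step(self):
        # two always-firing rules touch a particle once per step in total
        _, state = immobile_box(seed=6, max_timestep=0.1)
        log = []
        state.model.add_rule(first(
            "r1", "A", rate=1e9,
            post_fn=lambda p, ctx: log.append(("r1", p.id))))
        state.model.add_rule(first(
            "r2", "A", rate=1e9,
            post_fn=lambda p, ctx: log.append(("r2", p.id))))
        pid = state.spawn_particle("A", np.full(3, 1e-5))
        nf.step(state)
        assert len(log) == 1
        # over many steps both rules win sometimes (uniform tie-break)
        for _ in range(60):
            nf.step(state)
        assert {name for name, _ in log} == {"r1", "r2"}

    def test_negative_rate_names_rule(self):
        _, state = immobile_box(seed=7)
        state.model.add_rule(first("bad_rule", "A", rate=lambda p: -1.0,
                                   post_fn=lambda p, ctx: None))
        state.spawn_particle("A", np.full(3, 1e-5))
        with pytest.raises(ModelError, match="bad_rule"):
            nf.step(state)

    def test_pattern_containment_context(self):
        model = Model()
        model.register_species("Shell", default_radius=1e-6)
        model.register_species("P", default_radius=1e-8, mobile=False)
        physics = PhysicsParams(domain=Domain.box(1e-5, 3), max_timestep=0.1)
        state = SystemState(model, physics, seed=8)
        shell = state.spawn_particle("Shell", np.full(3, 5e-6))
        inside = state.spawn_particle("P", np.full(3, 5e-6), shell)
        outside = state.spawn_particle("P", np.full(3, 2e-6))
        removed = []
        state.model.add_rule(first(
            "only_inside", Pattern("P", inside="Shell"), rate=1e9,
            post_fn=lambda p, ctx: (removed.append(p.id), ctx.remove(p))))
        nf.step(state)
        assert removed == [inside]
        assert outside in state.meta


class TestGrowth:
    def test_ramp_reaches_target_after_growth_time(self, simple_state):
        simple_state.physics.growth_time = 1e-3
        pid = simple_state.spawn_particle("A", np.full(3, 1e-5), ramp=True)
        slot = simple_state.meta[pid].slot
        r_seen = [simple_state.rad[slot]]
        t = 0.0
        while t < 1.1e-3:
            reactions.grow_step(simple_state, pid, 1e-4)
            t += 1e-4
            r_seen.append(float(simple_state.rad[slot]))
        assert simple_state.rad[slot] == 1e-6  # exact arrival
        gaps = [abs(1e-6 - r) for r in r_seen]
        assert all(g2 <= g1 for g1, g2 in zip(gaps, gaps[1:]))  # monotone

    def test_fixed_point(self, simple_state):
        pid = simple_state.spawn_particle("A", np.full(3, 1e-5))
        r0 = simple_state.particle(pid).radius
        reactions.grow_step(simple_state, pid, 1.0)
        assert simple_state.particle(pid).radius == r0

    def test_shrink_ramp(self, simple_state):
        simple_state.physics.growth_time = 1e-3
        pid = simple_state.spawn_particle("A", np.full(3, 1e-5))
        simple_state.particle(pid).retarget_radius(0.5e-6)
        for _ in range(11):
            reactions.grow_step(simple_state, pid, 1e-4)
        assert simple_state.particle(pid).radius == 0.5e-6


class TestDivision:
    def test_contents_partition_exactly(self):
        state, comp, rule = make_division_state(seed=1, n_contents=10)
        before = set(state.children_of(comp))
        tr, _ = run_division(state, comp, rule)
        got1 = set(state.children_of(tr.child1))
        got2 = set(state.children_of(tr.child2))
        assert got1 | got2 == before
        assert got1 & got2 == set()
        state.validate_invariants()

    def test_default_split_is_fair_coin(self):
        state, comp, rule = make_division_state(seed=2, n_contents=0)
        # statistical check on the split function across many draws
        model = state.model
        counts = []
        for seed in range(6):
            st, cp, rl = make_division_state(seed=100 + seed, n_contents=60)
            tr = reactions.start_division(st, cp, rl)
            counts.append(len(tr.half1) - 1)
        total = sum(counts)
        n = 6 * 60
        assert abs(total - n / 2) < 3 * math.sqrt(n * 0.25)

    def test_custom_split_and_attrs(self):
        # all contents to child 1; child attribute maps rewritten at fission
        model = Model()
        model.register_species("Cell", [("mating", "string")],
                               default_radius=1e-6)
        model.register_species("Cargo", default_radius=5e-8)
        rule = reactions.divide(
            "fission", "Cell", rate=0.0, a_division=1e4,
            content_split=lambda p, rng: 1,
            attr_fns=lambda p, rng: ({"mating": "P"}, {"mating": "M"}))
        model.add_rule(rule)
        physics = PhysicsParams(domain=Domain.box(1e-5, 3), temperature=0.0,
                                medium_viscosity=1e-8, max_timestep=1e-6,
                                granularity=2.0, tol_contain=2e-8)
        state = SystemState(model, physics, seed=3)
        cell = state.spawn_particle("Cell", np.full(3, 5e-6),
                                    attributes={"mating": "P"})
        for _ in range(5):
            state.spawn_particle("Cargo", np.full(3, 5e-6), cell)
        tr, _ = run_division(state, cell, rule)
        assert len(state.children_of(tr.child1)) == 5
        assert state.children_of(tr.child2) == []
        assert state.meta[tr.child1].attributes == {"mating": "P"}
        assert state.meta[tr.child2].attributes == {"mating": "M"}

    def test_radius_interpolation_endpoints(self):
        state, comp, rule = make_division_state(seed=4, n_contents=0)
        r0 = state.particle(comp).radius
        tr = reactions.start_division(state, comp, rule)
        s1 = state.meta[tr.child1].slot
        # at zero separation the children keep the parent radius
        reactions.division_progress(state, tr, 1e-9)
        assert state.rad[s1] == pytest.approx(r0, rel=1e-3)
        while state.transitions:
            nf.step(state)
        # at completion the radii equal the targets and ignores are empty
        assert state.rad[s1] == pytest.approx(tr.rt1, rel=1e-12)
        assert state.meta[tr.child1].ignore == set()
        assert tr.rt1 == pytest.approx(r0 * 2 ** (-1 / 3))

    def test_membership_constant_during_separation(self):
        state, comp, rule = make_division_state(seed=5, n_contents=20)
        tr = reactions.start_division(state, comp, rule)
        half1 = set(state.children_of(tr.child1))
        half2 = set(state.children_of(tr.child2))
        while state.transitions:
            nf.step(state)
            assert set(state.children_of(tr.child1)) == half1
            assert set(state.children_of(tr.child2)) == half2

    def test_particle_in_transition_cannot_divide_again(self):
        state, comp, rule = make_division_state(seed=6, n_contents=2)
        tr = reactions.start_division(state, comp, rule)
        with pytest.raises(ModelError):
            reactions.start_division(state, tr.child1, rule)


def reactive_pair_state(kind, d_star=None, w=0.0, post_fn=None, product=None,
                        radius_b=None, seed=0, d_star_fraction=None,
                        temperature=0.0):
    """Two mobile species in a quiet box with one bimolecular rule."""
    model = Model()
    model.register_species("X", default_radius=1e-6)
    model.register_species("Y", default_radius=radius_b or 1e-6)
    if product:
        model.register_species(product, default_radius=1e-6)
    model.add_rule(bimolecular("rxn", "X", "Y", kind, d_star=d_star,
                               d_star_fraction=d_star_fraction, w=w,
                               product=product, post_fn=post_fn))
    physics = PhysicsParams(domain=Domain.box(2e-5, 3),
                            temperature=temperature, medium_viscosity=1e-3,
                            max_timestep=1e-7, tol_contain=2e-7)
    return SystemState(model, physics, seed=seed)


class TestBimolecular:
    def test_fusion_triggers_once_beyond_dstar(self):
        state = reactive_pair_state(FUSE, d_star=1e-7, product="Z")
        center = np.full(3, 1e-5)
        a = state.spawn_particle("X", center)
        b = state.spawn_particle("Y", center + np.array([1.85e-6, 0, 0]))
        nf.step(state)  # overlap depth 0.15e-6 > d* -> exactly one fusion
        assert a not in state.meta and b not in state.meta
        names = [m.species.name for m in state.meta.values()]
        assert names == ["Z"]
        assert sum(1 for e in state.events if e[1] == "rxn") == 1

    def test_fusion_below_dstar_does_not_trigger(self):
        state = reactive_pair_state(FUSE, d_star=2e-7, product="Z")
        center = np.full(3, 1e-5)
        state.spawn_particle("X", center)
        state.spawn_particle("Y", center + np.array([1.85e-6, 0, 0]))
        nf.step(state)
        names = sorted(m.species.name for m in state.meta.values())
        assert names == ["X", "Y"]

    def test_fusion_product_geometry(self):
        # equal masses -> midpoint; volume conserved
        state = reactive_pair_state(FUSE, d_star=1e-8, product="Z")
        center = np.full(3, 1e-5)
        off = np.array([1.9e-6, 0, 0])
        state.spawn_particle("X", center - off / 2)
        state.spawn_particle("Y", center + off / 2)
        nf.step(state)
        (pid,) = state.particle_ids()
        p = state.particle(pid)
        assert np.allclose(p.position, center)
        assert p.radius == pytest.approx(2 ** (1 / 3) * 1e-6, rel=1e-9)

    def test_fusion_merges_contents_and_runs_post(self):
        seen = {}

        def post(product, va, vb, ctx):
            seen["names"] = (va.species_name, vb.species_name)

        state = reactive_pair_state(FUSE, d_star=1e-8, product="Z",
                                    post_fn=post)
        center = np.full(3, 1e-5)
        a = state.spawn_particle("X", center)
        cargo = state.spawn_particle("Y", center, a, radius=1e-7)
        b = state.spawn_particle("Y", center + np.array([1.9e-6, 0, 0]))
        nf.step(state)
        (pid,) = [p for p in state.particle_ids()
                  if state.meta[p].parent == MEDIUM]
        assert state.children_of(pid) == [cargo]
        assert seen["names"] == ("X", "Y")

    def test_transform_mutates_both(self):
        model = Model()
        model.register_species("Cell", [("bound", "integer")],
                               default_radius=1e-6, mobile=False)
        model.register_species("L", default_radius=1e-7)

        def bind(cell, lig, ctx):
            cell.set_attr("bound", cell.attributes["bound"] + 1)
            ctx.remove(lig)

        model.add_rule(bimolecular("bind", "Cell", "L", TRANSFORM,
                                   d_star=1e-8, post_fn=bind))
        physics = PhysicsParams(domain=Domain.box(2e-5, 3), temperature=0.0,
                                medium_viscosity=1e-3, max_timestep=1e-7)
        state = SystemState(model, physics, seed=1)
        center = np.full(3, 1e-5)
        cell = state.spawn_particle("Cell", center)
        state.spawn_particle("L", center + np.array([1.05e-6, 0, 0]))
        nf.step(state)
        assert state.meta[cell].attributes["bound"] == 1
        assert state.n_particles == 1

    def test_nest_trigger_reparents_without_jump(self):
        state = reactive_pair_state(NEST, d_star=2e-7, radius_b=2e-7)
        center = np.full(3, 1e-5)
        shell = state.spawn_particle("X", center)
        # fully contained already: |x| + r_in <= r_shell
        inner = state.spawn_particle("Y", center + np.array([5e-7, 0, 0]))
        pos_before = state.particle(inner).position
        nf.step(state)
        assert state.meta[inner].parent == shell
        assert np.allclose(state.particle(inner).position, pos_before,
                           atol=1e-9)

    def test_nest_not_triggered_while_crossing(self):
        state = reactive_pair_state(NEST, d_star=2e-7, radius_b=2e-7)
        center = np.full(3, 1e-5)
        shell = state.spawn_particle("X", center)
        inner = state.spawn_particle("Y", center + np.array([9.5e-7, 0, 0]))
        nf.step(state)  # dist + r_in = 1.15e-6 > r_shell: still outside
        assert state.meta[inner].parent == MEDIUM

    def test_unnest_trigger(self):
        state = reactive_pair_state(UNNEST, d_star=2e-7, radius_b=2e-7)
        center = np.full(3, 1e-5)
        shell = state.spawn_particle("X", center)
        inner = state.spawn_particle("Y", center, shell)
        # teleport the child fully outside: |x| >= r_in + r_shell
        state.pos[state.meta[inner].slot] = center + np.array([1.21e-6, 0, 0])
        nf.step(state)
        assert state.meta[inner].parent == MEDIUM

    def test_contained_particle_never_exits_without_rule(self):
        # inward contact force keeps a nested particle inside its shell
        model = Model()
        model.register_species("Shell", default_radius=1e-6, mobile=False)
        model.register_species("P", default_radius=1e-7)
        physics = PhysicsParams(domain=Domain.box(1e-5, 3), temperature=310.0,
                                medium_viscosity=1e-5,
                                max_timestep=2e-9, tol_contain=5e-8)
        state = SystemState(model, physics, seed=9)
        center = np.full(3, 5e-6)
        shell = state.spawn_particle("Shell", center)
        inner = state.spawn_particle("P", center + np.array([8e-7, 0, 0]),
                                     shell)
        for _ in range(2000):
            nf.step(state)
            assert state.meta[inner].parent == shell
        state.validate_invariants()

    def test_newtons_third_law_on_pair_forces(self):
        state = reactive_pair_state(FUSE, d_star=1.9e-6, product="Z", w=1e-20)
        center = np.full(3, 1e-5)
        a = state.spawn_particle("X", center)
        b = state.spawn_particle("Y", center + np.array([1.5e-6, 0, 0]))
        pairs = collision.detect_overlaps(state)
        reactions.apply_pair_phase(state, pairs, 1e-7)
        fa = state.pair_force[state.meta[a].slot]
        fb = state.pair_force[state.meta[b].slot]
        assert np.allclose(fa, -fb)
        assert np.linalg.norm(fa) == pytest.approx(1e-20 / 1.9e-6)

    def test_hertz_newton_pairs(self, simple_state):
        a = simple_state.spawn_particle("A", np.full(3, 1e-5))
        b = simple_state.spawn_particle(
            "A", np.full(3, 1e-5) + np.array([1.4e-6, 0, 0]))
        pairs = collision.detect_overlaps(simple_state)
        reactions.apply_pair_phase(simple_state, pairs, 1e-7)
        fa = simple_state.pair_force[simple_state.meta[a].slot]
        fb = simple_state.pair_force[simple_state.meta[b].slot]
        assert np.allclose(fa, -fb)
        assert fa[0] < 0  # a (left of b) is pushed further left: apart

    def test_bimolecular_check_direct(self):
        state = reactive_pair_state(FUSE, d_star=1e-7, product="Z")
        rule = state.model.rules[0]
        center = np.full(3, 1e-5)
        a = state.spawn_particle("X", center)
        b = state.spawn_particle("Y", center + np.array([1.85e-6, 0, 0]))
        (pair,) = collision.detect_overlaps(state)
        assert reactions.bimolecular_check(state, pair, rule) == (a, b)
        names = [m.species.name for m in state.meta.values()]
        assert names == ["Z"]

    def test_bimolecular_check_below_threshold_is_noop(self):
        state = reactive_pair_state(FUSE, d_star=3e-7, product="Z")
        rule = state.model.rules[0]
        center = np.full(3, 1e-5)
        state.spawn_particle("X", center)
        state.spawn_particle("Y", center + np.array([1.85e-6, 0, 0]))
        (pair,) = collision.detect_overlaps(state)
        assert reactions.bimolecular_check(state, pair, rule) is None
        assert state.n_particles == 2

    def test_rule_validation(self):
        with pytest.raises(ModelError):
            bimolecular("r", "A", "B", "teleport", d_star=1e-8)
        with pytest.raises(ModelError):
            bimolecular("r", "A", "B", FUSE, d_star=1e-8)  # no product
        with pytest.raises(ModelError):
            bimolecular("r", "A", "B", FUSE, product="C")  # no d*
        with pytest.raises(ModelError):
            bimolecular("r", "A", "B", FUSE, product="C", d_star=1e-8,
                        w=-1.0)
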