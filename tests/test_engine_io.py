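"""Step loop order, observers, text outputs, snapshots, determinism."""
import json
import math
import os

import numpy as np
import pytest

import nestforce as nf
from nestforce import engine_io, example_models
from nestforce.core_model import (MEDIUM, Domain, Model, ModelError,
                                  PhysicsParams, SystemState)
from nestforce.engine_io import (CountsObserver, RunConfig, TrajectoryObserver,
                                 load_snapshot, run, species_counts,
                                 state_fingerprint, write_counts,
                                 write_snapshot, write_trajectory)


def diffusing_state(seed=0, n=30, with_decay=True):
    """Small mobile system exercising RNG, reactions and removal."""
    model = Model()
    model.register_species("A", default_radius=1e-6)
    if with_decay:
        model.add_rule(nf.first("decay", "A", rate=2e4,
                                post_fn=lambda p, ctx: ctx.remove(p)))
    physics = PhysicsParams(domain=Domain.box(1e-4, 3), temperature=310.0,
                            medium_viscosity=1e-3, max_timestep=4e-6)
    state = SystemState(model, physics, seed=seed)
    for _ in range(n):
        state.spawn_particle("A", 1e-5 + state.rng.random(3) * 8e-5)
    return state


class TestStep:
    def test_empty_system_advances_by_max_timestep(self):
        model = Model()
        physics = PhysicsParams(domain=Domain.box(1e-5, 3), max_timestep=0.5)
        state = SystemState(model, physics)
        dt = nf.step(state)
        assert dt == 0.5 and state.time == 0.5

    def test_loop_order_matches_component_sequence(self, monkeypatch):
        trace = []
        from nestforce import collision, integrator, reactions

        originals = {
            "lower": reactions.apply_lower_order,
            "kick": integrator.kick,
            "drift": integrator.drift,
            "detect": collision.detect_overlaps,
            "pair": reactions.apply_pair_phase,
        }
        monkeypatch.setattr(engine_io.reactions, "apply_lower_order",
                            lambda *a, **k: (trace.append("lower"),
                                             originals["lower"](*a, **k))[1])
        monkeypatch.setattr(engine_io.integrator, "kick",
                            lambda *a, **k: (trace.append("kick"),
                                             originals["kick"](*a, **k))[1])
        monkeypatch.setattr(engine_io.integrator, "drift",
                            lambda *a, **k: (trace.append("drift"),
                                             originals["drift"](*a, **k))[1])
        monkeypatch.setattr(engine_io.collision, "detect_overlaps",
                            lambda *a, **k: (trace.append("detect"),
                                             originals["detect"](*a, **k))[1])
        monkeypatch.setattr(engine_io.reactions, "apply_pair_phase",
                            lambda *a, **k: (trace.append("pair"),
                                             originals["pair"](*a, **k))[1])
        state = diffusing_state(with_decay=False)
        nf.step(state)
        assert trace == ["lower", "kick", "drift", "detect", "pair", "kick"]

    def test_single_particle_matches_integrator_path(self):
        # engine step == bare integrator under the same seed: component
        # equivalence for a rule-free single particle
        def engine_path():
            state = diffusing_state(seed=3, n=1, with_decay=False)
            for _ in range(50):
                nf.step(state)
            return state.pos[state.alive_slots()][0].copy()

        def manual_path():
            from nestforce import forces, integrator

            state = diffusing_state(seed=3, n=1, with_decay=False)
            ph = state.physics
            for _ in range(50):
                dt = integrator.adaptive_timestep(state)
                slots = state.alive_slots()
                th = forces.thermal_forces(state.frictions(slots),
                                           ph.temperature, dt, state.rng,
                                           ph.dimension)
                z = np.zeros_like(th)
                integrator.kick(state, slots, z, th, dt / 2)
                integrator.drift(state, slots, dt)
                integrator.kick(state, slots, z, th, dt / 2)
                state.time += dt
            return state.pos[state.alive_slots()][0].copy()

        assert np.array_equal(engine_path(), manual_path())

    def test_observer_purity(self):
        state = diffusing_state(seed=4)
        obs = CountsObserver(every_steps=1)
        before = state_fingerprint(state)
        obs.record(state)
        TrajectoryObserver().record(state)
        assert state_fingerprint(state) == before


class TestCountsAndTrajectory:
    def test_species_counts_with_context(self, nested_state):
        state, cell, raft, prot = nested_state
        counts = species_counts(state)
        assert counts[("Cell", MEDIUM)] == 1
        assert counts[("Raft", "Cell")] == 1
        assert counts[("P", "Raft")] == 1

    def test_counts_csv_format(self, tmp_path):
        state = diffusing_state(seed=5, n=3, with_decay=False)
        obs = CountsObserver()
        obs.record(state)
        path = tmp_path / "counts.csv"
        write_counts(obs.rows, str(path))
        lines = path.read_text().splitlines()
        assert lines[0] == "time,species,count,compartment_context"
        assert lines[1] == "0.0,A,3,medium"

    def test_trajectory_frame_count(self, tmp_path):
        state = diffusing_state(seed=6, n=2, with_decay=False)
        obs = TrajectoryObserver(every_steps=5)
        obs.record(state)
        for _ in range(20):
            nf.step(state, [obs])
        # frames at t=0 plus every 5th step
        assert len(obs.frames) == 1 + 20 // 5
        path = tmp_path / "traj.xyz"
        write_trajectory(obs.frames, str(path))
        lines = path.read_text().splitlines()
        assert lines[0] == "2"
        assert lines[1].startswith("time=")
        assert len(lines) == 5 * (2 + 2)


class TestSnapshot:
    def test_empty_round_trip(self, tmp_path):
        model = Model()
        physics = PhysicsParams(domain=Domain.box(1e-5, 3))
        state = SystemState(model, physics, seed=1)
        p1 = tmp_path / "a.json"
        write_snapshot(state, str(p1))
        loaded = load_snapshot(str(p1), model)
        assert loaded.n_particles == 0
        p2 = tmp_path / "b.json"
        write_snapshot(loaded, str(p2))
        assert p1.read_text() == p2.read_text()

    def test_populated_round_trip_idempotent(self, tmp_path, nested_state):
        state, cell, raft, prot = nested_state
        state.meta[prot].attributes  # touch
        p1 = tmp_path / "a.json"
        write_snapshot(state, str(p1))
        loaded = load_snapshot(str(p1), state.model)
        p2 = tmp_path / "b.json"
        write_snapshot(loaded, str(p2))
        assert p1.read_text() == p2.read_text()
        assert loaded.meta[prot].parent == raft
        assert loaded.local_viscosity_of(prot) == 1e-2

    def test_restart_equals_uninterrupted(self, tmp_path):
        state_a = diffusing_state(seed=7)
        for _ in range(60):
            nf.step(state_a)

        state_b = diffusing_state(seed=7)
        for _ in range(30):
            nf.step(state_b)
        snap = tmp_path / "mid.json"
        write_snapshot(state_b, str(snap))
        resumed = load_snapshot(str(snap), state_b.model)
        for _ in range(30):
            nf.step(resumed)

        assert state_a.particle_ids() == resumed.particle_ids()
        sa = state_a.alive_slots()
        sb = resumed.alive_slots()
        assert np.array_equal(state_a.pos[sa], resumed.pos[sb])
        assert np.array_equal(state_a.vel[sa], resumed.vel[sb])
        assert state_a.time == resumed.time

    def test_snapshot_rejects_foreign_json(self, tmp_path):
        bad = tmp_path / "x.json"
        bad.write_text(json.dumps({"hello": 1}))
        with pytest.raises(ModelError):
            load_snapshot(str(bad), Model())


class TestRunDriver:
    def test_same_seed_byte_identical_counts(self, tmp_path):
        outs = []
        for sub in ("r1", "r2"):
            config = RunConfig(scenario="decay", seed=42, n_steps=50,
                               out_dir=str(tmp_path / sub),
                               scenario_params={"n0": 100})
            result = run(config)
            outs.append(open(result.paths["counts"], "rb").read())
        assert outs[0] == outs[1]

    def test_decay_run_matches_theory(self, tmp_path):
        config = RunConfig(scenario="decay", seed=3, t_end=3.0,
                           scenario_params={"n0": 1000, "k": 1.0,
                                            "max_timestep": 0.05})
        result = run(config)
        n = result.state.n_particles
        expect = 1000 * math.exp(-3.0)
        sd = math.sqrt(1000 * math.exp(-3) * (1 - math.exp(-3)))
        assert abs(n - expect) < 4 * sd

    def test_unknown_scenario(self):
        with pytest.raises(ModelError):
            run(RunConfig(scenario="nope", n_steps=1))

    def test_end_condition_validation(self):
        with pytest.raises(ModelError):
            RunConfig(scenario="decay")
        with pytest.raises(ModelError):
            RunConfig(scenario="decay", t_end=1.0, n_steps=5)

    def test_vesicle_smoke_run_writes_outputs(self, tmp_path):
        config = RunConfig(scenario="vesicle_transport", seed=1, n_steps=300,
                           out_dir=str(tmp_path / "v"),
                           observe=("counts", "trajectory"))
        result = run(config)
        for key in ("counts", "trajectory", "snapshot", "log"):
            assert os.path.exists(result.paths[key])
        # total SNARE copies conserved across budding/fusion
        totals = example_models.snare_totals(result.state)
        assert totals["X"] == 2 * (180 + 20) // 2 or totals["X"] == 200
        assert totals["X"] + totals["Y"] == 400


class TestCLI:
    def test_list_and_run(self, tmp_path):
        from click.testing import CliRunner

        from nestforce.cli import main

        runner = CliRunner()
        res = runner.invoke(main, ["list-scenarios"])
        assert res.exit_code == 0
        assert "decay" in res.output
        res = runner.invoke(main, [
            "run", "decay", "--seed", "1", "--n-steps", "10",
            "--out", str(tmp_path / "out")])
        assert res.exit_code == 0
        assert (tmp_path / "out" / "counts.csv").exists()
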