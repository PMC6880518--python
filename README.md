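# nestforce

Force-based, particle simulation of dynamically nestable compartments.

Particles are attributed hollow spheres moving in continuous 2D/3D space
under the Langevin equation. Everything structural is mediated by forces:

- **Excluded volume** — Hertz soft-sphere contact between siblings, and an
  inward shell force on contained particles.
- **Bimolecular reactions** — while a reactive pair overlaps, the contact
  force is replaced by a constant barrier force `W/d*`; the reaction
  (fuse / transform / nest / unnest) triggers geometrically once the pair
  overlaps beyond `d*` (or, for nesting, once the entering particle is
  fully contained; for unnesting, fully outside). A high barrier `W` makes
  the reaction rare; `W = 0` is diffusion limited.
- **Compartment division** — continuous: two children are pushed apart with
  a per-particle force `m·a` (uniform acceleration for shells and all
  contents), child radii interpolate with separation progress, and
  temporary *ignore relations* suppress unphysical contact between the
  separating halves.
- **Zeroth/first-order reactions** — sampled stochastically each step with
  arbitrary user rate functions of a particle's attributes and content,
  which also enables non-spatial intra-particle dynamics (e.g. a whole
  cell cycle as attributes of one cell).

Diffusion follows Stokes–Einstein (`D = k_BT/6πηr`) with the viscosity of
the innermost enclosing compartment; the timestep adapts as
`Δt = r_min/(v_max·g)`; integration is kick-drift-kick with a
fluctuation–dissipation thermal force.

## CLI

```bash
nestforce list-scenarios
nestforce run decay --seed 1 --t-end 3 --out out/ --observe counts,trajectory
nestforce run lipid_raft --seed 0 --n-steps 2000 --out out/
nestforce validate            # quick physics self-checks
```

Outputs are plain text: a counts CSV (`time,species,count,compartment_context`),
an extended-XYZ-style trajectory (`species x y z radius parent_id`), a JSON
snapshot that round-trips losslessly (including the RNG state, so a run can
be restarted bit-exactly), and a run log.

## Scenarios

| name | description |
| --- | --- |
| `birth`, `decay`, `reversible_bimolecular` | correctness suite vs closed-form kinetics |
| `free_diffusion` | non-interacting Langevin spheres (MSD / Maxwell checks) |
| `bimolecular_rate` | constant-concentration A+B→C rate measurement |
| `vesicle_transport` | two compartments exchanging SNAREs via coated vesicles, directed by a two-pole force field (or Brownian control) |
| `yeast` | immobile cells with a non-spatial Erlang cell-cycle clock, pheromone secretion/binding, continuous fission |
| `lipid_raft` | 2D membrane, one static raft (25% area, 10× viscosity) with an entry barrier for one of two proteins |

Scenario builders default to desk-scale parameters (documented in their
docstrings); the literature-scale values are exposed as parameters.

## Library use

```python
import numpy as np
import nestforce as nf

model = nf.Model()
model.register_species("Cell", [("phase", "integer")], default_radius=2e-6)
model.add_rule(nf.first("tick", "Cell", rate=0.5,
                        post_fn=lambda p, ctx: p.set_attr("phase", p.attributes["phase"] + 1)))
physics = nf.PhysicsParams(domain=nf.Domain.box(2e-5, 3), max_timestep=1e-3)
state = nf.SystemState(model, physics, seed=1)
state.spawn_particle("Cell", np.full(3, 1e-5))
for _ in range(1000):
    nf.step(state)
```

Rule builders: `zeroth`, `first`, `divide`, `bimolecular` (kinds `fuse`,
`transform`, `nest`, `unnest`); global force fields via
`nf.ForceField` / `nf.dipole_field`.

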