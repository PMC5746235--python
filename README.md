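# vortexsim

Finite-volume simulation of cooperating bacterial colonies — a swarming
species that carries a non-motile, antibiotic-degrading partner — as a
system of coupled nonlinear reaction–diffusion equations solved on a
**vectorizable random lattice** (VRL): one node drawn uniformly in every
cell of a regular reference lattice, subject to per-axis minimum-distance
constraints, linked through its Delaunay triangulation.  The random lattice
removes the grid-symmetry artifacts that regular meshes imprint on
compact-support (porous-medium-type) diffusion fronts.

## What is in here

| module | contents |
| --- | --- |
| `vortexsim.mesh` | VRL construction (rejection-sampled nodes, Delaunay adjacency), Voronoi geometry clipped to the rectangular domain, finite-volume weights `w_ij = f_ij/(l_ij A_i)`, neighbor statistics |
| `vortexsim.operators` | Discrete Laplacian and nonlinear divergence `div[psi grad phi]` built from skew-symmetric two-point edge fluxes (exactly mass-conserving, no-flux boundaries), total-mass accounting |
| `vortexsim.integrators` | Forward-Euler and Crank–Nicolson diffusion steps; the nonlinear (k = 1) CN relation is solved by a lagged-coefficient Gauss–Seidel splitting started from the previous time level |
| `vortexsim.biology` | The model: rate laws, 1-/2-/3-species right-hand sides, dead-mass accumulators, and the builder/explorer phase controller (hysteresis on the mean colony density, per-connected-component for separated colonies) |
| `vortexsim.scenarios` | Initial-condition catalogue (single species, mixed colony, two colonies, antibiotic half-plane, three species, sensitivity sweep), colony radius / cross-section / ring-count diagnostics, the experiment runner |
| `vortexsim.interface` | TOML/JSON configuration, CSV + legacy-VTK output, JSON run manifests |
| `vortexsim.cli` | `vortexsim mesh-stats \| run \| sweep` |

## CLI

```bash
# neighbor statistics of a 100x100 VRL as JSON
vortexsim mesh-stats --nx 100 --ny 100 --d 0.5 --seed 1

# run the mixed-colony scenario and write diagnostics/snapshots/manifest
vortexsim run --scenario mixed --mesh-seed 0 --horizon 20 --out-dir out/

# parameter-sensitivity sweep of the mixed scenario
vortexsim sweep --out-dir sweep_out/
```

Configuration files (TOML or JSON) accept `[mesh]`, `[params]`, `[phase]`,
`[integrator]` and `[run]` sections; every key defaults to the standard
table of simulation values and unknown keys are rejected by name.  See
`tests/test_interface.py` for examples.

## Notes on model form

Two printed-formula details are configurable because the literal forms
contradict the qualitative behavior the model is meant to produce (see the
flags' docstrings): `Params.nutrient_shielded_mortality` selects the
antibiotic kill-rate form for the swarming species (default couples the
kill rate to growth activity, the β-lactam mechanism, under which a lone
swarmer colony collapses and cooperation is required for expansion), and
`Params.literal_algae_diffusion` selects whether the algal transport terms
act on the algae themselves (default, which makes the three-species system
reduce exactly to the two-species one without algae) or on the carrier
species as printed.
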