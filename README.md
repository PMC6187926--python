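# microtrap

Steady-state simulation of the microenvironment of 3D multicellular
aggregates (toroids and spheroids) held in microfluidic traps: creeping flow
of the culture medium, oxygen and glucose transport with Michaelis–Menten
consumption, and surface shear stress.

The device model is a rectangular perfusion channel with an oxygen-permeable
PDMS lid, containing either a U-shaped barrier or a microwell that holds a
toroidal (horizontal or vertical orientation) or spheroidal cell aggregate.
Oxygen reaches the tissue both from the medium and through the PDMS; glucose
only from the medium. Solubility partition jumps at the medium/PDMS/tissue
interfaces are handled by solving in the partition-scaled variable
`phi = c / S`, which is continuous across interfaces.

## What's inside

| module | role |
| --- | --- |
| `microtrap.params` | physical constants, species definitions, Knudsen helper |
| `microtrap.geometry` | signed-distance device/aggregate geometry, voxelization into a labeled Cartesian grid |
| `microtrap.flow` | staggered-grid (MAC) finite-volume Stokes solver with optional inertia correction |
| `microtrap.transport` | conservative advection–diffusion–reaction solver in the partition-scaled variable |
| `microtrap.analytic` | closed forms and independent 1D oracles (constant-rate sphere, hypoxic radius, radial BVP, slab resistance, manufactured solutions) |
| `microtrap.postprocess` | region averages/minima, hypoxic fraction, maximum surface shear, VTI/CSV/JSON outputs |
| `microtrap.pipeline` | scenario orchestration, parameter sweeps, YAML config, CLI |
| `microtrap.fixtures` | synthetic, self-describing test fixtures at ci/desk/full scales |

## Command line

```sh
microtrap run config.yaml          # run one scenario, write VTI/CSV/JSON
microtrap sweep config.yaml --axis aspect_ratio --values 1.5,2,2.5
microtrap dump-grid config.yaml --out grid.vti
microtrap validate                 # fast end-to-end sanity checks
microtrap fixtures generate validation_sphere_desk
```

Configuration is YAML with lengths in micrometres, concentrations in mM
(1 mM = 1 mol/m³) and the flow rate in µL/min; unknown keys are rejected.
Example:

```yaml
name: reference_toroid
spacing_um: 12
coarse_ok: true
geometry:
  trap_kind: u_barrier          # or microwell
  aggregate_kind: toroid_horizontal
  minor_radius: 80
  aspect_ratio: 2.0
  trap_height: 600
  margin: 1
  half_width_symmetry: true
physical:
  Q_ul_per_min: 5.0
species: [oxygen, glucose]
solver:
  transport_residual_tol: 1.0e-6
```

## Notes on numerics

- Uniform voxel (stair-step) geometry; no external mesher. Resolution
  requirements are quantified by the grid-independence check.
- Flow: Stokes limit by default (Re « 1 at 5 µL/min); symmetric MAC saddle
  system solved directly when small, otherwise by equilibrated MINRES with a
  geometric-multigrid block preconditioner, followed by an exact discrete
  divergence projection.
- Transport: harmonic-mean face coefficients of `D·S` implement the flux
  continuity + concentration jump interface conditions; first-order upwind
  advection on medium faces; Picard iteration with a lagged Michaelis–Menten
  denominator (M-matrix, positivity-preserving).
- Surface shear: tangential velocity probed along the analytic SDF normal at
  fixed wall distances and extrapolated quadratically to the true surface —
  exact for linear and parabolic profiles, robust on voxel boundaries.
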