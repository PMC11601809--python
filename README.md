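# valvekit

Toolkit for studying how chordae tendineae (CDT) geometry shapes
atrioventricular-valve closure:

- **Synthetic valve generation** — stereotypical mitral (two-leaflet) and
  tricuspid (three-leaflet) quad-meshed surfaces lofted between a
  saddle-shaped elliptic annulus and a free edge with commissural dips,
  plus papillary tip points; uniform annular dilation with preserved
  leaflet/commissure heights.
- **Parametric branched chordae** — primary chords along the free edge
  (chords/cm) and secondary chords over the leaflet body (chords/cm²,
  blue-noise sampled), each emanating from the nearest papillary tip with
  a one-level branch fan controlled by branch length, branch count,
  branch radius and cross-sectional area.
- **Closure simulation** — damped explicit dynamic relaxation of an
  incompressible isotropic-exponential (Lee–Sacks form) membrane coupled
  to linear-truss chordae, with a follower pressure ramp (default
  100 mmHg MV / 23.7 mmHg TV over 0.005 s), penalty leaflet contact, and
  pinned annulus/papillary nodes. Mass-proportional damping plus
  dynamic-relaxation kinetic damping (velocities zeroed at kinetic-energy
  peaks; disable via `kinetic_damping: false`) drive the system to its
  quasi-static closed state. Units: mm / N / MPa / s.
- **Closure metrics** — regurgitant orifice area (grid raycast along the
  annulus normal), contact area (elements with non-zero contact
  traction), billowing volume above the annulus plane, and first
  principal strain summaries.
- **Studies** — one-at-a-time parameter sweeps, baseline normalization,
  re-quantification by insertion points / total CSA, and OLS
  linear/quadratic/exponential trend fits (statsmodels).
- **FEBio export** — a FEBio 4.0 input deck carrying the full
  configuration (generalized-alpha dynamic analysis, shell thickness,
  truss modulus/CSA, Lee–Sacks coefficients, dt bounds, pressure ramp,
  fixed node sets) so the same problem can be run in FEBio externally.
  Mesh I/O: VTK XML (.vtu/.vtp), STL, OBJ, PLY.

The packaged valve dimensions (annulus semi-axes 20×15 mm, saddle 3 mm,
leaflet heights 15/11 mm, …) are toolkit defaults chosen at healthy adult
scale; override them in the `valve:` config block.

## CLI

```sh
valvekit generate   --config cfg.yaml --out out/        # valve.vtu + sidecar
valvekit chordae    --config cfg.yaml --out out/        # chordae.vtp + summary
valvekit simulate   --config cfg.yaml --out out/        # closed.vtu + diagnostics
valvekit metrics    --config cfg.yaml --out out/        # metrics.csv
valvekit sweep      --param chordae.secondary.density --values 1:10:10 \
                    --config cfg.yaml --out out/        # sweep.csv
valvekit export-feb --config cfg.yaml --out out/        # valve.feb
```

Every run writes a `manifest.json` (seed, version, resolved config);
`--dry-run` prints the resolved config and writes nothing. Config is YAML
with blocks `valve / chordae / material / simulation / metrics` merged
over the defaults in `valvekit.study_runner.DEFAULT_CONFIG`; materials
are `mv_lee_sacks`, `tv_lee_sacks`, or a mapping of overrides.

Example config:

```yaml
valve:
  kind: mv
  mesh_target_elems: 3000
chordae:
  primary:   {density: 2.0, branch_length: 3.5, n_branches: 3, branch_radius: 1.0, csa: 1.0}
  secondary: {density: 3.0, branch_length: 3.5, n_branches: 4, branch_radius: 1.0, csa: 1.0}
material: mv_lee_sacks
simulation:
  pressure_peak: 100.0
```

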