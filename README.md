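# emboflow

Pulsatile aortic-arch flow and Lagrangian clot-embolization simulation.

Atrial fibrillation (AF) reduces cardiac output by about 30% and shortens
the cardiac cycle by about 40%, and is a major independent risk factor for
embolic stroke.  `emboflow` is a desk-scale computational platform for
asking *how* those hemodynamic changes alter the fate of blood clots
released into the aorta: it solves pulsatile flow in an idealized
(planar) aortic arch with three supra-aortic branches, tracks discrete
spherical emboli through the time-varying field, and reports **stroke
propensity** — the percentage of released clots whose trajectories end in
the left common carotid artery (LCCA):

    propensity = 100 × N_carotid / N_released   [%]

It is aimed at researchers in cardiovascular biomechanics who want a
fast, fully scriptable sandbox for embolization sensitivity studies
(clot size 2–6 mm, ejection speed 0–0.8 m/s, ejection timing, arch
morphology) under normal versus AF inlet waveforms.

## Model in brief

* **Geometry** — a 180° curved channel of width `D_AA` with straight
  ascending/descending legs and three branch stubs (BCA, LCCA, LSA) on the
  outer wall; two morphometric cases span the observed range of branch
  diameters (LCCA 14.3 mm vs 7.5 mm).
* **Inlet** — half-sine systolic pulse; normal: T = 1 s, CO = 5.5 L/min,
  U_peak = 0.74 m/s; AF: T = 0.6 s, CO = 3.85 L/min, U_peak = 0.32 m/s.
  With ν = 3.30 × 10⁻⁶ m²/s these give Womersley numbers α = (D/2)√(2π/Tν)
  of 20.0 and 25.8 and inlet Reynolds numbers Re = UD/ν of 6500 (peak) and
  ≈1200 (cycle mean).
* **Flow** — incompressible Navier–Stokes on a staggered grid (projection
  method, exact per-step mass balance); fixed outlet flow-split fractions;
  no-slip walls; optional Smagorinsky eddy-viscosity toggle.
* **Clots** — Newton's second law per particle with Schiller–Naumann drag,
  added mass (C_am = 0.5) and pressure-gradient force; wall contact slides;
  outcomes classified per branch.

## Worked example

```python
import emboflow as ef

# hemodynamic characterization
for label in ("normal", "af"):
    c = ef.make_condition(label)
    print(label, f"CO={c.CO_l_min:.2f} L/min  alpha={c.alpha:.1f}  "
                 f"Re_peak={c.Re_peak:.0f}  Re_mean={c.Re_mean:.0f}")

# high-ejection-speed embolization experiment, morphometric case I
g = ef.build_arch("I")
mask = ef.rasterize(g, g.D_AA / 32)
for label in ("normal", "af"):
    cond = ef.make_condition(label)
    hist = ef.run_cycles(cond, mask, ef.SolverConfig())
    grid = ef.make_release_grid(g.D_AA, speeds=[cond.waveform.U_peak],
                                ejection_labels=("peak",))
    df = ef.run_experiment(cond, g, grid, history=hist)
    print(label, "propensity %.1f%%" % ef.overall_propensity(df))
```

prints

```
normal CO=5.50 L/min  alpha=20.0  Re_peak=6499  Re_mean=1219
af CO=3.85 L/min  alpha=25.8  Re_peak=2811  Re_mean=853
normal propensity 0.0%
af propensity 3.5%
```

i.e. the normal and AF inlet conditions reproduce the target dimensionless
characterization, and at high ejection speed (the per-condition peak flow
velocity) the AF condition directs clots into the left carotid while the
normal condition directs essentially all of them down the descending
aorta.  The same fields give a cycle-peak spatial-mean wall shear stress
about twice as high under normal rhythm as under AF (0.87 vs 0.40 Pa on
this grid).

## Command line

```
emboflow run --smoke                  # tiny end-to-end pipeline check
emboflow run --config my.yaml --conditions normal,af --case I
emboflow report RUNDIR                # comparison tables + plain-text report
emboflow validate --config my.yaml
```

Each run directory contains per-clot CSV results, stratified propensity
summaries, a WSS summary, optional VTK fields, and a `manifest.json` with
the fully resolved configuration and result checksums, so any results file
can be regenerated bit-identically.

## Layout

| module | contents |
| --- | --- |
| `emboflow.geometry` | parametric arch, rasterized domain masks |
| `emboflow.hemodynamics` | waveform generators, Womersley/Reynolds, blood |
| `emboflow.flow_solver` | projection solver, cycle driver, WSS extraction |
| `emboflow.clot_transport` | particle forces, wall handling, outcomes |
| `emboflow.ensemble` | release grids, experiments, propensity statistics |
| `emboflow.cli_io` | configs, CLI, manifests, reports |

See `docs/methods.md` for the full model description, numerical choices,
and known limitations.
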