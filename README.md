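# kneesim

A desk-scale, subject-specific knee musculoskeletal simulator. It predicts
total, medial and lateral tibiofemoral contact force (TFCF) curves over
activity cycles from triangle-mesh knee geometry, ligament and muscle
tables, and motion/ground-reaction inputs, using:

- **piecewise ligament bundle mechanics** — 22 bundles across 10 ligaments,
  quadratic toe region up to twice the linear strain limit, then linear;
  slack lengths calibrated from reference strains at full extension;
- **elastic-foundation contact** — five cartilage/meniscus contact pairs
  against the femoral cartilage; per-vertex force `PM * A_i * d_i` from
  ray-cast penetration depths, with the composite pressure module computed
  from each layer's modulus, Poisson ratio and thickness;
- **cubic-polynomial muscle recruitment** — minimize `sum V_i (f_i/N_i)^3`
  subject to the equilibrium system with non-negative muscle forces;
  maximum isometric force from muscle volume and fiber length at
  27 N/cm²;
- **force-dependent kinematics (FDK)** — an 11-DOF knee (6 tibiofemoral +
  5 patellofemoral, the patellar tendon rigid); flexion is driven, the 10
  secondary coordinates are iterated per frame to quasi-static equilibrium
  with a 1 N residual-force threshold;
- **curve validation metrics** — cycle normalization to 101 points, RMSE,
  R², and the Sprague–Geers magnitude/phase/combined error.

Because no real subject data ship with the package, `kneesim.fixtures`
generates everything synthetically and deterministically per seed:
parametric knee surfaces (STL), ligament/muscle attachments, and five
activity profiles (walking, stair ascent/descent, sit-to-stand,
stand-to-sit) with flexion and GRF waveforms, virtual noisy markers, and
pseudo-reference curves for metric testing.

## Layout

| module | role |
| --- | --- |
| `kneesim.mesh` | labeled triangle meshes, binary/ASCII STL I/O, welding |
| `kneesim.morph` | affine scaling, RBF (triharmonic + affine) morphing, surface projection, length–mass–fat scale factors |
| `kneesim.kinematics` | poses, weighted Kabsch marker fits, the 11-DOF joint parameterization and rigid patellar tendon elimination |
| `kneesim.ligaments` | bundle force law and the default 22-bundle table |
| `kneesim.contact` | materials, pressure module, ray-cast penetration, contact pairs |
| `kneesim.recruitment` | muscle strength, recruitment solver, moment arms, intersegmental loads |
| `kneesim.model` | knee model assembly and generalized-force evaluation |
| `kneesim.fdk` | per-frame FDK solver and the trial driver emitting TFCF curves |
| `kneesim.metrics` | cycle normalization, RMSE / R² / Sprague–Geers, peak extraction |
| `kneesim.fixtures` | seeded synthetic geometry, activities, markers, pseudo-references |
| `kneesim.config` | model/trial YAML round trip |
| `kneesim.cli` | `kneesim` command line |

## Command line

```sh
# write synthetic STL geometry, marker/GRF streams, model.yaml, trial.yaml
kneesim generate-fixtures --activity walk --seed 7 --out fixtures/

# run the simulation pipeline and emit 101-point TFCF curve files
kneesim simulate --model fixtures/model.yaml --trial fixtures/walk_trial.yaml \
    --out results/ --threshold 1.0

# compare two curve files (RMSE, R^2, Sprague-Geers)
kneesim validate --predicted results/walk_curves.csv --reference ref.csv
```

`simulate` writes `<activity>_curves.csv` (percent cycle and TFCF
total/medial/lateral in body weights), `<activity>_frames.csv` (per-frame
convergence and forces), `<activity>_contacts.csv` (per-pair contact
summaries) and a run log with per-frame iteration counts.

## Conventions

Units are mm / N / N·mm; joint axes x = medial–lateral (flexion axis),
y = anterior, z = superior; positive flexion swings the tibia posteriorly.
The femur is the ground body. Moment residuals converge against the force
threshold times a configurable characteristic lever (default 10 mm).
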