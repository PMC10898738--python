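# tenodesis-fe

Finite-element model assembly and analysis for anterior cruciate ligament
reconstruction (ACLR) with optional lateral extra-articular tenodesis (LET).

Rupture of the anterior cruciate ligament is usually treated by replacing
the ligament with a tendon graft passed through bone tunnels. When rotational
instability persists, surgeons add a lateral extra-articular tenodesis: a
strip of iliotibial band fixed through a lateral femoral tunnel. How much
pretension to apply to each graft — and how the two pretensions interact —
is an open surgical question. This package provides the simulation plumbing
to study it: it assembles complete FEBio (spec 3.0) knee models for four
surgical families (injured, native, standalone ACLR, combined ACLR–LET),
generates pivot-shift loading protocols, sweeps graft pretension grids, and
analyzes the resulting kinematics and graft stresses. It is aimed at
biomechanics researchers building graft-pretension sensitivity studies.

## What is inside

* **Surgical geometry** (`mesh_geometry`) — tunnel drilling into tetrahedral
  bone meshes (centroid-in-cylinder element removal, with a `tunnel_wall`
  node set on newly exposed faces), graft sweeping along planned
  trajectories (circular 4 mm bundles or 10 mm flat straps), tibial
  compartment centers at 25 %/75 % of the plateau width and their femoral
  projections. Units are mm throughout (mm–N–MPa system).
* **Constitutive models** (`materials`) — uncoupled transversely isotropic
  Mooney–Rivlin grafts with the piecewise toe/linear fiber law

  σ_f(λ) = 0 for λ ≤ 1; c₃(e^{c₄(λ−1)} − 1) for 1 < λ < λ*; c₅λ + c₆ for λ ≥ λ*,

  c₆ fixed by continuity at the fiber-straightening stretch λ*; the
  incompressible uniaxial closed form
  σ(λ) = 2(λ² − 1/λ)(c₁ + c₂/λ) + σ_f(λ) used for bounded nonlinear
  least-squares fitting to uniaxial test data; tension-only nonlinear
  springs; in-situ ligament prestrain as a fiber pre-stretch.
* **Loading protocols** (`loading_protocols`) — the pivot-shift profile
  (25 N anterior–posterior force, 7 N·m varus and 5 N·m internal torque via
  logistics centered at 25° of flexion with a 20–30° transition band, 20 N
  constant compression), quaternion SLERP over flexion-sampled femoral
  orientations to orient the graft pretension force at any fixation angle,
  and the per-surgery step plans (2 steps for native/injured, 5 for ACLR,
  7 for ACLR–LET) plus pretension grids (default 9 × 12 = 108 pairs).
* **Deck I/O** (`febio_io`) — validated FEBio spec-3.0 XML export, an
  inverse parser for round-trip checking, and CSV solver-log readers for
  rigid-body kinematics and element von Mises stresses.
* **Analysis** (`analysis`) — external tibial rotation (ETR) and posterior
  tibial translation (PTT) extraction from rigid transforms, reduction-phase
  ranges, mean absolute error against the native-knee reference, pretension
  ranking, peri-tunnel stress maxima, combined-versus-standalone stress
  comparison, contour matrices, and prestrain calibration by MSE against an
  experimental laxity line.
* **Synthetic fixtures** (`synthetic_fixtures`) — phantom knees, programmed
  kinematics, synthetic uniaxial data, randomized model specs, and the
  packaged published pretension summary table.

## Worked example

```python
from tenodesis_fe.analysis import rank_combinations, stress_reduction_summary
from tenodesis_fe.synthetic_fixtures import table1_fixture

combined, standalone = table1_fixture()
print(rank_combinations(combined, by="etr").head(3).to_string(index=False))
s = stress_reduction_summary(combined, standalone)
print("max decrease %.2f MPa at %g N" % (s.max_delta, s.max_at_tension))
```

prints

```
 aclr_tension  let_tension  etr_mae  ptt_mae  max_von_mises
         80.0          5.0    0.659    1.017         21.734
         60.0          5.0    0.691    1.128         20.022
         70.0          5.0    0.701    1.075         21.083
max decrease 4.04 MPa at 40 N
```

— the best rotational restoration among the combined-surgery pretension
pairs is 80 N on the reconstruction graft with a minimal 5 N on the
tenodesis graft (ETR error 0.659° versus the native knee, peri-tunnel graft
stress 21.734 MPa), and adding the tenodesis lowers graft stress most
(4.04 MPa) at the lowest reconstruction pretension of 40 N.

Model decks are built from the shell:

```sh
tenodesis-fe build --surgery aclr_let --aclr-tension 80 --let-tension 40 -o model.feb
tenodesis-fe grid -o decks/            # 108-pair pretension manifest
tenodesis-fe analyze --kin aclr.csv --ref native.csv --out results.csv
```

## Scope

The package exports solver-ready decks and parses solver outputs; it does
not itself solve the nonlinear FE problem, and it does not segment imaging
data. See `docs/methods.md` for modeling assumptions, parameter defaults,
and known limitations.
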