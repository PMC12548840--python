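# lumbarlift

Lumbar-spine loading during deadlift variants: synthetic motion trials,
Newton–Euler inverse dynamics, and a parametric L1–L5 finite-element
stress model.

## The problem

Deadlift ("hard pull") variants load the lumbar spine very differently.
The straight-leg deadlift (SLDL) starts with the trunk almost parallel to
the floor, so the extensor moment the lumbar joint must produce — and the
stress the L5 vertebra and the L4–L5 disc must carry — is substantially
higher than in the traditional (DL) or hexagonal-barbell (TBDL) variant.
`lumbarlift` implements that comparison end to end as a tested pipeline
for biomechanists and strength-training researchers:

1. **synthgen** — synthetic deadlift trials: 100 Hz marker trajectories, a
   500 Hz force-plate series and exact per-frame segment states for each
   variant (flexion ranges 32–90° DL, 0–90° SLDL, 35–90° TBDL; 120 kg
   barbell; double-peak torque profiles with first peaks 749/893/640 N·m).
   Trials are constructed so the rigid-body balance closes exactly: inverse
   dynamics on noise-free output recovers the prescribed torque to machine
   precision.
2. **kinematics** — zero-phase 4th-order Butterworth filtering (10 Hz
   kinematics, 100 Hz forces) and the sagittal L5→L1 flexion angle; range
   of motion = max − min.
3. **dynamics** — the lumbar joint moment from the single supra-L1 trunk
   segment,

   τ = I_c·α + ω×(I_c·ω) + m·r_c×(a_c − g) − Σ r_k×F_k,

   with the torso mass from an elliptical-frustum model, and the four lift
   phases (first pull / transition / second pull / standing) delimited by
   the two torque peaks and the trough between them.
4. **femodel / fesolver** — an idealised parametric L1–L5 column (5
   cortical shells + 5 cancellous cores, 4 nucleus + 12 annulus-layer
   parts, 8 endplates, 6 ligament truss groups; tied interfaces), a 13-row
   linear-elastic material table (cortical 12 000 MPa, cancellous 100 MPa,
   nucleus 1 MPa, ν clamped at 0.4999, …), and a constant-strain
   tetrahedral solver. Load cases pair a 1425 N vertical compression on the
   superior L1 endplate with the action's first-peak torque as a sagittal
   moment couple; the inferior L5 surface is fixed.
5. **stressstats** — 3×3 regional disc statistics with the standardised
   "quantitative difference" vs the central region E (β = 0.8, γ = 1.27),
   damage-threshold screening (cortical 1000 MPa, trabecular 3.0 MPa, disc
   40 MPa), literature-validation arithmetic and a parameter-sensitivity
   driver.

Because the geometry is idealised rather than CT-derived, absolute stress
magnitudes are not meaningful; orderings (SLDL > DL > TBDL; L5 the peak
vertebra; periphery over disc centre; cortical over cancellous) and
percentage contrasts are the reproduction surface.

## Worked example

```sh
lumbarlift all --out runs/demo --coarse
```

or stage by stage via the numbered drivers:

```sh
python analysis/01_simulate_trials.py
python analysis/02_flexion_kinematics.py
python analysis/03_inverse_dynamics.py
python analysis/04_fe_stress.py
```

which printed, on the default configuration:

```
DL: flexion ROM 58.16 deg
SLDL: flexion ROM 89.86 deg
TBDL: flexion ROM 54.94 deg
DL: first peak 753.8 N*m, second peak 608.9 N*m, 4 phases ...
SLDL: first peak 900.2 N*m, second peak 719.1 N*m, 4 phases ...
TBDL: first peak 645.8 N*m, second peak 530.6 N*m, 4 phases ...
SLDL vs DL L5 cancellous peak increase: 19.2%
SLDL vs DL L4-L5 disc peak increase: 19.2%
```

The flexion ranges of motion land on the per-variant study values (58°,
90°, 55°) within the 0.5 mm marker noise; the recovered first-peak torques
sit within 1% of the prescribed 749/893/640 N·m; and the straight-leg
variant raises the L4–L5 disc and L5 cancellous peak stresses by ≈19%
over the traditional deadlift — the moment-dominated load case makes the
contrast track the torque ratio 893/749.

`analysis/05–07` add the regional disc tables (central region E always
the softest), the threshold screening and the sensitivity grading.

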