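# Methods

This note documents the models behind `lumbarlift`, the defaults and why
they were chosen, the numerical choices, and what the synthetic data can
and cannot show about real lifting.

## 1. Synthetic trials

Each trial prescribes two curves over a 2 s lift (one metronome cycle):

* **Flexion** θ(t): a cosine ramp from the bottom position
  (`flexion_end_deg`) to lockout (`flexion_start_deg`), monotone with zero
  end slopes. Defaults per variant: 32–90° (DL), 0–90° (SLDL, trunk
  horizontal at the start), 35–90° (TBDL). The range of motion is the
  difference, i.e. 58°/90°/55°.
* **Torque** τ(t): a monotone piecewise-cubic (PCHIP) spline through five
  knots — baseline at the start of the pull, first peak, trough, second
  peak, end. PCHIP is C¹ and does not overshoot, so the curve has exactly
  two interior maxima and one interior minimum by construction. First
  peaks are 749/893/640 N·m (DL/SLDL/TBDL); the straight-leg peak arrives
  earlier (peak time fraction 0.28 vs 0.35). Only the first peaks and the
  qualitative shape are anchored by data; the remaining knots are shape
  parameters: baseline = 60 % of the first peak (so the first-pull phase is
  non-empty), trough = 50 %, second peak = 80 %, end = 30 %.

The trunk above L1 is a single rigid segment rotating about a fixed joint
centre in the sagittal plane. Its mass comes from the elliptical-frustum
torso model

m = ρ·(πh/3)·(a₁b₁ + a₂b₂ + √(a₁b₁a₂b₂)),

with default semi-axes 0.17/0.12 → 0.16/0.11 m, height 0.5 m and density
1050 kg/m³, giving ≈ 31 kg; the centroid sits 0.25 m along the trunk axis
and the transverse inertia is the slender-rod value mh²/12. These are
ordinary adult-male torso numbers; the closed form is exact for similar
end ellipses ("regular" frustum) and is also what the mass operation
implements for non-similar ones (the discrepancy from the true tapered
volume is then a fraction of a percent, and a test pins it).

**Closure.** Given θ(t) and the trunk terms, the barbell (static weight
m_b·g on a vertical line) is placed at the sagittal moment arm that makes
the rigid-body balance produce exactly the prescribed torque at every
frame. The generator therefore ships three mutually consistent artefacts:
marker tables (trunk line L5/L1/L3/T2/C7, pelvis, barbell midpoints, mm),
a force-plate series (vertical force = subject + barbell weight), and the
exact analytic segment states. Inverse dynamics evaluated on the stored
states reproduces the truth torque to machine precision; the marker route
(filtering + finite differences) reproduces it to a few tenths of a
percent.

**Noise.** Isotropic Gaussian marker noise, default SD 0.5 mm, is added
after the kinematic construction; the force plate receives 4 N of noise
per mm of marker noise so one switch scales both sensors, and a zero
marker SD silences everything. Equal seeds give bitwise-identical trials;
different seeds differ only in the noise.

## 2. Kinematics and inverse dynamics

Channels are filtered with a 4th-order Butterworth low-pass applied
forward and backward (zero phase; the magnitude response is squared, so
the gain at the cutoff is ½): 10 Hz for kinematics, 100 Hz for forces —
the standard motion-capture practice. Flexion is the angle of the
filtered L5→L1 marker line against vertical in the sagittal plane; the
definition is a parameter (`lower_label`/`upper_label`) so a T2-based
trunk line can be swapped in.

The joint moment is the canonical rigid-body balance about the L1 joint
centre,

τ = I_c·α + ω×(I_c·ω) + m·r_c×(a_c − g) − Σ r_k×F_k,

reported as the sagittal component with extensor effort positive.
Derivatives are second-order central differences (one-sided at the ends).
The barbell force is recovered from the filtered vertical ground reaction
minus the subject's weight (quasi-static barbell) and applied at the
barbell marker midpoint. No multi-joint recursive chain is built: with a
single suspended segment the recursion has one step.

Phases: peaks are strict local maxima with prominence ≥ 5 % of the series
range (ties broken earliest); the two most prominent peaks and the
minimum between them cut the lift into first pull / transition / second
pull / standing, which tile the frame range exactly.

## 3. The finite-element model

CT-derived geometry is out of scope, so the lumbar column is idealised:
five elliptical vertebral bodies (default 32 × 45 mm cross-section,
28 mm tall; no posterior arch), four 10 mm discs, 0.5 mm endplates above
and below each disc. Each vertebra splits into a 1 mm cortical shell and
a cancellous core; each disc into a central nucleus (40 % of the radius)
and three concentric annulus layers (20 % each). Six ligament chains run
as 30 mm² truss elements on the outer surface (anterior/posterior
longitudinal, flavum, inter-/supraspinous, intertransverse), tied to
mesh nodes.

The mesh is a structured extrusion of a polar ring/sector template, with
rings placed on every material boundary and clustered near the surface so
the shell is resolved; triangular prisms are split into three tetrahedra
with the smallest-global-index diagonal rule, which keeps shared faces
conforming — all interfaces share nodes, the tied-contact idealisation.
Meshing is fully deterministic. Default target edge 2 mm (the reference
resolution); the pipeline and all shipped analyses run at the desk-scale
5 mm preset (≈ 50 k tets, 27 k DOF), where one solve takes a few seconds.

Materials are the standard 13-row lumbar table (cortical 12 000 MPa/0.3,
annulus layers 550/490/440 MPa, cancellous 100 MPa/0.2, endplate 25 MPa,
ligaments 8–15 MPa, nucleus 1 MPa/0.5). Everything is solved as isotropic
linear elastic — the annulus' transverse isotropy and any hyperelastic or
viscous behaviour are deliberately not modelled — and the nucleus' ν is
clamped to 0.4999. Constant-strain tetrahedra are known to lock as
ν → 0.5; at these element counts the nucleus is orders of magnitude
softer than its annulus regardless, so the clamped linear element is
accepted and documented rather than replaced by a mixed formulation.

Load cases fix the inferior L5 surface and load the superior L1 endplate
with 1425 N of evenly distributed vertical compression (the constant
shipped for the 120 kg condition) plus the action's first-peak torque as
a sagittal moment, realised as a linear force-couple distribution that
reproduces the requested moment exactly and adds no net force. On this
geometry the moment term dominates disc and vertebral stress (the
vertical-only contribution is ~1–2 %), so percentage contrasts between
actions track the torque ratios: SLDL vs DL ≈ 893/749 − 1 ≈ 19 %.

The solver assembles symmetric sparse stiffness from the element
matrices, removes fixed DOFs (non-homogeneous Dirichlet values are
supported for the benchmark oracles), factorises directly
(scipy spsolve), enforces a 1e-8 relative residual, and reports
per-element Cauchy stress and von Mises intensity. Rigid-body modes of
disconnected, unconstrained components are detected combinatorially
(connected components of the element graph) because a sparse LU may
factor such systems without complaint.

## 4. Regional statistics, risk, validation, sensitivity

The L4–L5 disc's elements are tiled 3×3 by terciles (equal counts) of the
two transverse centroid coordinates; rows follow the sagittal axis with
the anterior third first (A,B,C / D,E,F / G,H,I; E central and containing
the nucleus centroid). Per region: mean, SD and CV = SD/mean of the
element von Mises stresses, and the standardised contrast against E,

QD = |mean_r − mean_E| / √((s_r² + s_E²)/2),

classified as not significant (≤ 0.8), significant (0.8–1.27) or very
significant (≥ 1.27). The contrast formula itself is a design choice (the
convention the thresholds β/γ are attached to is not fully specified in
the source material); element-wise samples stand in for per-subject
replicates, so the QD magnitudes here are far larger than tabulated
per-subject values — the classes and the centre-vs-periphery ordering are
the reproducible content.

Risk screening is straight arithmetic: exceedance = (peak − threshold)/
threshold × 100 against 1000 MPa (cortical), 3.0 MPa (trabecular) and
40 MPa (disc), with a strict flag. Validation is the same arithmetic
against literature means ± SD for the four published reference
indicators; the reference simulated values are shipped as inputs because
they belong to the subject-specific model this package does not rebuild.

Sensitivity re-solves the DL case at both ends of each fluctuation
(cortical E ±10 %, nucleus E ±20 %, vertical load ±5 %, moment ±5 %) and
grades the L5 cortical peak-stress change (≥5 % high, 3–5 % medium, <3 %
low). Two exact properties anchor the driver: a pure vertical-load change
maps one-to-one onto stress (linearity), and on a parallel two-material
column a modulus change moves stress by strictly less than the
perturbation, following σ₁ = F·E₁/(E₁A₁ + E₂A₂). Note a structural
limitation: the idealised column is statically determinate, so element
stresses depend on moduli only through within-section stiffness shares —
the cortical-modulus case grades *low* here even though a subject-specific
indeterminate model grades it high. The load parameters behave as
expected (moment ≈ ±5 %).

## 5. Problem sizes and determinism

Shipped analyses use 201-frame trials (2 s at 100 Hz), the 5 mm mesh
preset and direct factorisation; the full pipeline (three actions,
regional stats, sensitivity) completes in about a minute and a half on
one core. All randomness flows from a single integer seed through
`numpy.random.default_rng`; meshing, assembly and factorisation are
deterministic, so identical configurations give byte-identical summaries.

## 6. What the synthetic data does not show

The generator emulates the *measurement structure* of a lifting session
(marker layout subset, sampling rates, sensor noise, force plate) and the
*mechanical structure* asserted by the torque/flexion templates. It does
not emulate soft-tissue artefact, marker occlusion, multi-segment spine
kinematics, muscle co-contraction or subject variability; passing the
round-trip tests therefore validates the estimators' internal
consistency, not their robustness to those real-world effects. Likewise
the FE magnitudes inherit the idealised geometry: orderings and
percentage contrasts, not MPa values, are what the model is meant to
reproduce.
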