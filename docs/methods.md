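# Methods

`vtexit` is a desk-scale platform for studying non-invasive localization
of post-infarct ventricular tachycardia (VT) exit sites from body-surface
ECGs and implanted-device electrograms (EGMs). It simulates libraries of
focal paced beats and figure-of-eight VT beats on synthetic ventricular
anatomies, and trains a convolutional regressor that maps the
multi-channel traces of a beat to its source site in universal
ventricular coordinates (UVC). This note describes each model stage, its
assumptions, the tunable parameters, and what the synthetic setting does
and does not establish.

## Anatomy

The ventricle is a truncated prolate-ellipsoid shell: two concentric
ellipsoids of revolution (endocardium with semi-axes `(a, a, c)`,
epicardium with `(a + w, a + w, c + w)`) cut by a flat base plane. The
defaults — long axis 90 mm (`c = 45`), endocardial short semi-axis
`a = 25` mm, wall `w = 10` mm, truncation at 0.7 of the long axis — give
a wall volume of about 115 mL, within the range of a dilated post-infarct
LV. Coordinates are mm, right-handed, apex at the origin, long axis
along +z; phi = 0 (the septal reference direction, +x) marks the
mid-anteroseptum and the anterior wall lies toward +y.

Meshing is structured: nodes sit on rays from the shared ellipsoid
center, with the transmural layer at fraction `u` at radius
`(1-u) r_endo(theta) + u r_epi(theta)`. This tiles the shell exactly
(verified against the closed-form shell volume to <1% at 3 mm
resolution), keeps surface nodes exactly on the labelled surfaces, and
gives each hexahedral cell a conforming six-tetrahedron "fan"
decomposition; pole cells collapse two vertices and drop the degenerate
tetrahedra. The resolution parameter `target_edge_length` bounds node
spacing via the epicardial surface; the seed jitters interior nodes by
5% of the edge length only (element-shape regularization — surface and
base nodes are never jittered, so boundary conditions stay exact).

Myofiber direction is the standard rule-based transmural rotation: the
local circumferential direction rotated about the transmural axis by a
helix angle linear in normalized wall depth, +60 deg at the endocardium
to -60 deg at the epicardium by default. The recomputed helix-angle field
reproduces this ramp exactly by construction.

Cohorts of "virtual patients" are generated by perturbing the three
geometric axes uniformly by ±10% and jittering the surface-electrode
template by ±10 mm; the default cohort size is 5.

### Electrodes

Surface electrodes (RA, LA, LL, V1–V6) sit on a fixed template of unit
directions scaled by `torso_scale` (default 120 mm), precordials
anterior to the heart; the right-leg ground is not modelled. Device
electrodes mimic a generic high-voltage device: left-pectoral CAN,
SVC coil superior to the base, RV coil/ring/tip descending inside the
cavity along the septal side (tip ~3 mm from the apex), and a
quadripolar LV lead (LV1–LV4, 10 mm spacing) on the lateral epicardium,
offset 1 mm outward to keep the 1/r source kernel regular. All
placements are deterministic functions of the anatomy.

## Activation model

Excitation spread is a graph eikonal model: every mesh edge gets a
traversal time `length / (mult * v(theta))` with
`v(theta) = sqrt((cv_l cos theta)^2 + (cv_t sin theta)^2)` the
elliptical anisotropic speed about the fiber direction, and activation
times are shortest arrivals over this weighted graph (Dijkstra via
`scipy.sparse.csgraph`, virtual super-source for offset sources). Since
an edge borders several elements, its effective speed is the maximum
over incident elements of `mult_e * v(theta_e)` — one conductive
neighbor suffices for local conduction, which also fixes the fiber
ambiguity at element interfaces. Defaults `cv_long = 0.6 m/s`,
`cv_trans = 0.24 m/s` are standard working-myocardium values.

The graph solution is exact on its own metric (asserted against an
independent Bellman–Ford relaxation in the tests) and overestimates the
continuum front arrival by the usual metric-graph stretch; on a slab
meshed with the same hex-fan decomposition the overestimate stays below
15%, which is the accuracy class this localization study needs — the
localizer sees consistently generated traces, not absolute conduction
times.

The "reaction" half is a stereotyped action potential: resting -85 mV,
plateau +20 mV, 2 ms linear upstroke, 280 ms APD, 40 ms linear
repolarization. Each node's transmembrane trace is this template shifted
by its activation time. No restitution, repolarization gradients, or
diastolic re-entry dynamics are modelled.

## Forward model

Electrode potentials use the infinite-volume-conductor pseudo-ECG
source integral, `phi(x) = k * sum_e vol_e grad(Vm)|_e . grad_c(1/|x - c_e|)`,
with element-wise linear shape-function gradients. Being linear in Vm it
collapses to a lead-field matrix `L` (electrodes x nodes) computed once
per anatomy, so a beat costs one `L @ Vm` product. The gain `k` is 1:
traces are z-score normalized per channel before storage, so absolute
scale carries no information. No torso inhomogeneities, electrode
impedance, or device sensing filters are modelled; what the electrodes
retain is the source-to-sensor geometry, which is the signal the
localizer exploits.

Derived channels: the 12 standard leads (Wilson central terminal from
RA/LA/LL; Einthoven and Goldberger closures hold to machine precision)
plus four vector combinations X = V6 - V1, Y = aVF,
Z = V2 - (V6 + I)/2, M = V1+V2+V3-V4-V5-V6 — a declared set
approximating orthogonal-axis and magnitude-like summaries; and eight
device EGM vectors (RV_TIP-RV_RING, RV_COIL-CAN, SVC_COIL-CAN,
RV_COIL-SVC_COIL, three adjacent LV bipoles, LV4-CAN) mixing near- and
far-field sensing. Every derived channel's coefficients sum to zero
(reference invariance), asserted at construction.

## UVC

On the idealized anatomy the universal ventricular coordinates have
closed-form surrogates with the same semantics as PDE-based
constructions on patient meshes: `rho` is the transmural family
fraction solved from the concentric-ellipsoid implicit equations by
bisection; `z` is the polar-angle fraction along the node's own layer
between its base angle and the apical pole (this keeps the apex cap
non-degenerate — points below the apex node still receive distinct small
z); `phi` is the azimuth from the septal reference, positive anterior.
Boundary values are exact on labelled nodes. The 17-AHA segmentation
uses ring cuts at z = 0.2 / 0.45 / 0.7 and sectors anchored so phi = 0
is mid-anteroseptal (segment 2/8); apical quadrants put the septal
segment 14 at phi in [-45, 45) deg.

UVC-to-Cartesian back-mapping returns the mesh node minimizing the
weighted squared UVC distance with weights (1, 1, 1/pi^2) — a half-turn
in phi counts like the full unit span of z or rho — with ties broken to
the lowest node index. Localization error (LE) is the Euclidean mm
distance after back-mapping.

## VT substrate

A substrate is two transmural inexcitable lobes framing a slow corridor,
all boxes in (z, phi): corridor half-width 0.08 rad, lobe half-extents
(dz = 0.12, dphi = 0.25 rad), isthmus velocity multiplier 0.25. Centers
are placed at AHA-segment centroids (segments 1–16; the apex cap is
excluded as rotationally degenerate) with seeded jitter kept inside the
segment and z clamped so corridor and mouths fit below the base. A VT
beat is a single eikonal activation initiated at the exit site — the
excitable node at the seeded corridor mouth, and by construction the
point of earliest systolic activation. Full periodic re-entry is out of
scope; the observable used for localization (one systolic activation
sequence per cycle) is preserved. The cycle length reported as metadata
is the corridor transit time (conduction restricted to isthmus tissue
plus a small mouth margin) plus the return path around the scar with
the corridor blocked; with default parameters it falls in the
clinically typical 200–300 ms band.

## Localizer

The reference architecture is a 1-D convolutional encoder — blocks
(24, k7, s2), (32, k5, s2), (48, k5, s2) with ReLU — over the
(channels x 350-sample) beat window, global average pooling, a
32-unit dense layer, and 4 outputs: (z, rho, sin phi, cos phi). The
circular coordinate is regressed through its sine/cosine pair so sites
straddling the phi = ±pi seam are not penalized as full-turn errors;
the four targets are comparably scaled, so the loss is an equal-weight
MSE. Training uses Adam (lr 2e-3 base, 1e-3 transfer), mini-batches of
32/16, an id-level validation split, and early stopping on validation
loss with restoration of the best parameters. The implementation is a
compact NumPy network (im2col convolutions, manual backprop, verified
against finite differences), which makes runs bit-reproducible for a
fixed seed and lets transfer-learning freeze policies address exact
parameter tensors: `freeze_encoder` keeps the conv stack bit-identical,
`freeze_all_but_last` re-trains only the output layer, `none` continues
ordinary training. ECG (16-channel) and EGM (8-channel) modes are
separate models.

Predicted z and rho outside [0, 1] are clipped (and logged); phi comes
from atan2 of the sin/cos outputs; inputs of a different length are
linearly resampled to the model window; channel names must match the
training mode exactly — no silent reordering.

## Evaluation protocol

Two rotating held-out scenarios mirror the study design. Scenario 1
("seen pacing, unseen VT"): base training includes every anatomy's paced
beats; transfer fine-tuning excludes the held-out anatomy's VT beats;
testing uses exactly those VT beats. Scenario 2 ("fully unseen"):
the held-out anatomy is excluded from both stages. Every run carries a
data-leakage audit of its train/transfer/test id sets. Summary
statistics report both flavours of "mean ± sd": across-torso (mean and
population sd of per-anatomy mean LEs — the headline format) and pooled
over episodes; population sd is used to match ± summaries over a full
cohort.

## Problem sizes and defaults

The desk-scale study conditions — fixed up front as the package's
defaults — are 5 anatomies, 500 paced + 60 VT beats per anatomy,
4.5 mm meshes for the scenario pipeline (3 mm default elsewhere), 1 ms
sampling, 350-sample windows, 30 base / 60 transfer epochs. A full
scenario evaluation runs in minutes on one CPU; the simulated-beat
counts scale to the thousands-of-beats regime by config.

## What the synthetic setting shows — and what it does not

The generator produces noiseless, normalization-consistent traces on an
idealized LV-only anatomy inside a homogeneous infinite conductor, with
scar shapes from a two-parameter family. Passing the suite therefore
demonstrates that the pipeline is internally correct (oracle-verified
solvers, exact lead algebra, leak-free protocols) and that the
localizer can invert the forward model it was trained under — desk-scale
localization errors (~5 mm mean) are accordingly better than what
patient-derived torso models with heterogeneous tissue, measurement
noise, and richer infarct morphology would yield, and the margin between
the two scenarios is compressed because the virtual patients differ only
by smooth geometric perturbation. Absolute error levels here should not
be read as clinical performance; the clinically motivated acceptance
bound (mean LE <= 17 mm for useful ablation pre-planning) is the
meaningful reference point.

## Numerical choices and degenerate inputs

- Bisection tolerances: transmural depth 60 iterations, base angle 80;
  both far below mesh resolution.
- Zero-offset eikonal sources get weight 1e-300 (sparse graphs treat
  stored zeros as absent edges); arrivals below 1e-200 are snapped to 0.
- Constant trace channels z-score to exact zeros.
- Non-viable substrates (blocked corridor, empty mouth, unresolvable
  lobes at coarse resolution) raise typed errors; the library builder
  retries with fresh seeded jitter up to 8 times before failing.
- All randomness flows from per-stage seeds derived by SHA-256/
  SeedSequence splitting of one global seed; every artifact stores its
  config snapshot, and stage caching hashes those snapshots.

## Known limitations

LV-only anatomy (no RV, septal UVC approximations rather than
biventricular coordinates); no torso conductivity heterogeneity; single
stereotyped action potential; single-beat VT surrogate instead of
sustained re-entry; scar family limited to two-lobe transmural boxes;
the declared 4 ECG vector combinations and 8 EGM vectors are one
reasonable choice among several and are configurable.
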