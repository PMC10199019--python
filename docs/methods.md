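# Methods

`vfpinn` reconstructs three-dimensional flow-induced vocal-fold dynamics,
glottal aerodynamics and voice acoustics from a sparse sequence of 2D edge
profiles — the quantity an endoscopic camera actually records.  This note
describes the models, the numerical choices, what the synthetic-data
generator does and does not emulate, and the design decisions taken where
the design was genuinely open.

## Solid model and modal reduction

The tissue is linear elastic with a two-layer (cover/body) transversely
isotropic constitutive law, fiber axis along the anterior–posterior (z)
direction, discretized with 4-node tetrahedra (consistent mass).  Dirichlet
attachments (lateral, anterior, posterior faces) are removed by row/column
elimination, and the generalized eigenproblem `K U = ω² M U` is solved in
shift-invert mode at σ = 0 (ARPACK through `scipy.sparse.linalg.eigsh`).
Modes are mass-orthonormalized — the derivation of the decoupled modal
oscillators requires unit modal mass — and sign-fixed (largest entry
positive) so repeated runs are bit-identical.

With Rayleigh damping `C = α M + β K` the dynamics reduce to independent
oscillators

    b̈_j + (α + β ω_j²) ḃ_j + ω_j² b_j = U_jᵀ F(t),

which is the search space of both the forward simulator and the inverse
network.  Default Rayleigh parameters are α = 60 s⁻¹ and β = 6×10⁻⁵ s
(dimensionally, α multiplies velocity → s⁻¹; β multiplies stiffness-weighted
velocity → s).

Default material constants (configurable) are in the low-kPa range measured
for vocal-fold tissue, cover softer than body, ten-fold longitudinal
stiffening from the fiber structure, near-incompressible Poisson ratios:

| layer | E_t (kPa) | E_l (kPa) | G_l (kPa) | ν_t = ν_lt | ρ (kg/m³) |
|-------|-----------|-----------|-----------|------------|-----------|
| cover | 1.2       | 12        | 4.8       | 0.45       | 1040      |
| body  | 2.4       | 24        | 9.6       | 0.45       | 1040      |

These values, with the default geometry, place the first eigenfrequencies
near 110–130 Hz and the flow-induced limit cycle near 150 Hz — the
physiological register of a mid-size mammalian larynx.

## Synthetic geometry

The fold is a generic extruded cross-section: span 10 mm (z), depth 8 mm
(x), vertical thickness tapering 8 → 3 mm toward the medial edge, rest
half-gap g₀ = 0.2 mm to the midline symmetry plane at x = 0.  Only the left
fold is meshed; the right fold is its mirror image.  A structured hex grid
(default 8×6×10) is mapped onto the shape and each hex splits into six
tetrahedra around a common diagonal — deterministic, conforming, and easy
to check against analytic volumes.  Cover/body labels come from the
parametric distance to the medial surface (cover thickness 1.5 mm).

The medial gap profile is `g(y) = g₀ + b (2y/T − 1)²`.  The convexity
parameter defaults to **b = 0** (a parallel rest channel).  This is a
physical requirement, not an aesthetic one: with a pronounced convex bulge
the minimum-area section is pinned at mid-height, the quasi-steady Bernoulli
loading stays in phase with the displacement, and every damped configuration
we examined decays to a static deflection.  With a parallel channel the
separation point travels with the mucosal wave, the loading acquires the
phase lag that feeds energy into the structure, and the model phonates
robustly at the prescribed 1 kPa subglottal pressure — including at the
full Rayleigh damping above.

## Glottal flow

The channel between the folds is sliced into 100 horizontal sections
spanning the current inferior–superior extent of the deformed medial
surface.  The local gap is `2·max(0, −x)` (symmetry doubling); section areas
integrate the gap along the span (trapezoid on current column positions,
hat-kernel interpolation of the gap to section heights).  Flow separation is
pinned at the minimum-area section:

    Q = √(2 P_sub / ρ_air) · A_min,
    P(y) = P_sub − ½ ρ_air (Q/A(y))²  upstream of separation, 0 after.

At the separation section these two relations give P = 0 identically.  An
area floor of 10⁻⁸ m² keeps 1/A² finite through closure; it is orders of
magnitude below open-phase areas (~10⁻⁵ m²) and never binds while the
glottis is open.  Defaults: P_sub = 1.0 kPa, ρ_air = 1.1 kg/m³.

Every flow operator runs on plain arrays (forward simulation) or on the
package's autodiff tensors (training) through one shared implementation.
During training the hinge and the minimum are mollified (softplus of width
τ_gap, log-sum-exp soft-minimum of temperature τ_min); evaluation uses the
exact operations (τ = 0).

## Contact

Midline collision is a penalty pressure on medial faces whose centroid
crosses x = 0: `p_c = k_c1·dx·(1 + k_c2·dx²)`, lumped to nodes by one-point
quadrature, directed along −x.  The default is a **linear** penalty
(k_c1 = 5×10⁶ Pa/m, k_c2 = 0).  The cubic stiffening term is implemented and
configurable, but any coefficient strong enough to limit penetration
markedly also compresses the collision impulse to time scales far below the
20 frames/cycle of the imaging protocol.  The inverse problem then becomes
unidentifiable: the modal-equation residual of the *true* trajectory,
evaluated with finite differences at the observation spacing, grows to tens
of percent (and far beyond for soft-spring/strong-cubic combinations),
drowning the information the equation loss is supposed to contribute.  With
the linear default the true-trajectory residual stays at ~0.2% of the
signal, penetration is bounded to ~0.5 mm (about a third of the ~1.6 mm
lateral vibration amplitude — the usual laxity of penalty contact), and the
limit cycle is strictly periodic.

## Forward simulation (ground-truth generator)

The modal oscillators are integrated with an explicit central-difference
scheme (damping treated semi-implicitly in the standard way), force lagged
one step, dt = 10⁻⁵ s for 250 ms — cheap because the system is diagonal in
modal space.  The initial condition is a small seeded random modal
perturbation (~0.1 mm surface displacement) that breaks symmetry; the
flutter instability then grows into a limit cycle within ~50 ms.  A steady
cycle is detected when consecutive peak-to-peak amplitudes of A_min(t)
agree within 2%; the packaged conditions settle to amplitude changes below
0.1%.

From one steady cycle the generator extracts `n` equispaced time-labeled 2D
profiles (default 20 — for the ~150 Hz cycle a ~3 kHz frame rate, matching
clinical high-speed endoscopy) plus the full-field ground truth used only
for evaluation.

What the generator emulates: self-sustained flow-induced oscillation with a
traveling mucosal wave, glottal closure with a closed phase in Q(t),
realistic amplitudes (≈1.6 mm lateral / 0.8 mm vertical) and frequency
(~150 Hz), and the exact observation protocol (20 top-view profiles over
one cycle).  What it does not emulate: subject-specific anatomy, camera
segmentation noise, out-of-plane projection distortion, measurement jitter
in the time labels, and any non-periodicity across cycles.  Passing the
acceptance pipeline therefore demonstrates methodological correctness of
the inverse machinery under clean periodic observations, not robustness to
real endoscopic image quality.

## Observation operator

The top (endoscopic) view reduces the medial surface to the medial-most
visible edge: at each of 64 fixed spanwise stations, the maximum of x over
the vertical direction.  The surface is first hat-kernel-interpolated to
the stations along the span, then reduced — this matches a dense sampling
of the piecewise-bilinear surface exactly at τ = 0; during training a
log-sum-exp soft maximum (τ_proj = 2 µm) keeps the reduction smooth.  A
frontal view (reduce y instead of x) is provided for ventral–dorsal imaging
geometries.  The data loss is the pointwise MSE between predicted and
observed edge coordinates on the fixed stations.

## Inverse model

An LSTM encoder (hidden size 128, one layer) consumes the
nondimensionalized profile sequence; its final hidden/cell states seed an
LSTM decoder that is also fed the per-step profiles (teacher forcing — the
observed profiles are always available in this inverse setting, at
inference as well as training); a four-layer residual MLP with layer norms
(width 128, ReLU) maps decoder hiddens to the modal coefficients.  The total
loss is `L_f = W_e L_e + W_d L_d`, with the equation loss the mean squared
residual of the modal oscillators (time derivatives by central differences
with periodic wrap — the observations span one cycle; one-sided second-order
stencils are available for non-periodic data) and the loading recomputed
from the reconstructed shapes through the differentiable flow and contact
operators at every evaluation.

Normalization and optimization choices that the source protocol leaves
open, and how they were resolved:

* **Input/output scales.** Edge coordinates are divided by the rest gap;
  network outputs are mapped to modal coefficients by a data-derived scale
  (observed motion amplitude over a typical surface mode entry) times a
  per-mode compliance factor `(ω₁/ω_j)^p` with p = 2 by default.  Without
  the per-mode factor, stiff modes absorb optimization noise that the
  20-sample equation residual cannot discriminate, and large-basis
  inversions converge roughly an order of magnitude worse in our
  calibration runs.
* **Loss weights.** The protocol values W_e = 10⁴, W_d = 10⁻⁵ remain the
  defaults, but they balance the two terms only under the originators' unit
  convention.  `auto_balance=True` replaces them by 1/L_e(0) and 1/L_d(0)
  so both terms start at magnitude one; the pipeline uses this setting.
* **Learning rate.** Adam with ReduceLROnPlateau from 10⁻² down to
  5×10⁻⁵ is the protocol default; under our normalization the replication
  pipeline runs at an initial 10⁻³, which converged markedly better in
  calibration.
* **Initialization.** The MLP output layer starts near zero so the first
  iterate is the rest configuration; a random start can put the surface
  deep into contact, where the penalty forces dwarf every other term.

## Evaluation

Displacement error is `‖U_pred − U_true‖₂ / ‖U_true‖₂` over the full nodal
displacement field, reported in percent with mean and SD over 16 equispaced
points across the cycle.  Flow-rate and mean-intraglottal-pressure errors
are per-time relative errors (times where the reference is identically
zero — full closure — are excluded).  Acoustics follow the measurement
protocol: the monopole source pressure `p' = ρ_air/(4πr)·dQ/dt` at r = 1 m,
resampled to 48 kHz (band-limited polyphase), low-pass filtered at 20 kHz
(zero-phase 4th-order Butterworth — family unspecified in the protocol,
zero-phase chosen to avoid waveform lag in the derivative), then
`SPL = 20 log₁₀(p_rms/20 µPa) + 20 log₁₀(0.12)` and
`P_A = 4π(0.12)²·p_rms²/(ρ_air c)` with c = 343 m/s (the intensity
convention is the plane progressive-wave impedance; the protocol leaves I
undefined, which shifts absolute power but no relative comparison).

## Mode-count protocol

The acceptance pipeline generates ground truth on the 100-mode basis
(~2.9k-tet mesh) and inverts with truncations of the same basis.  Because
prediction lives in the truncated span, the M-orthogonal truncation error
of the true motion is a hard floor for each inversion (the acceptance
script reports it for 20 modes — ≈15% on the packaged conditions — and it
vanishes by construction at 100).  This makes the
mode-count error trend structurally non-increasing — the property the
sweep verifies — while the absolute floors reflect how much collision-driven
high-mode content this compact fold carries.

## Problem sizes

The packaged runs use a 2 880-tet fold (≈1.5k free DOFs), 100 retained
modes, 250 ms of forward simulation at dt = 10⁻⁵ s, 20 profiles × 64
stations per cycle, and training capped at 6 000 epochs per inversion —
sizes chosen so the full pipeline is a desktop-scale computation rather
than a GPU-days one, while keeping every stage of the original protocol.

## Known limitations

* Quasi-steady 1D Bernoulli flow with a fixed separation criterion; no
  viscous losses, no vocal-tract acoustic loading.
* Penalty contact admits visible interpenetration (a property of penalty
  methods at physically meaningful stiffness, sharpened here by the
  identifiability constraint above).
* tet4 elements with near-incompressible Poisson ratio are on the stiff
  side (mild volumetric locking); eigenfrequencies carry the usual
  first-order-element discretization error.
* The inverse problem's unobservable subspace (vertical and interior
  motion) is constrained only through the equation loss; its accuracy
  degrades if the observation sampling cannot resolve the loading's
  harmonic content (see the contact discussion).
* Training is full-batch on a single observed cycle; no minibatch or
  multi-cycle support.
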