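# Methods

This note documents the models, estimators and numerical choices behind
`mitralflow`, and what the synthetic data do and do not establish about
measurements on a physical pulse duplicator.

## The dissipation operator

The central quantity is the planar viscous energy dissipation per unit
out-of-plane depth,

    VED = (μ/2) ∫_A Σ_{i,j∈{x,y}} (∂u_i/∂x_j + ∂u_j/∂x_i)² dA ,

with the sum over all ordered index pairs.  Expanding the sum gives the
standard two-dimensional dissipation function

    Φ = 2μ(u_x² + v_y²) + μ(u_y + v_x)² ,

which the implementation evaluates (the pairwise form is asserted
against it in the tests on random fields).  Units: with u in m/s and A
in m², VED is W per metre of depth; TVED, its time integral over 1 s,
is J/m.

Numerics:

* velocity gradients are second-order central differences, with
  second-order one-sided stencils at grid and mask edges; a node whose
  stencil cannot be formed from valid neighbours (fewer than two usable
  consecutive neighbours along an axis) is excluded from the integral;
* the area integral uses trapezoidal weights (half weight on boundary
  rows/columns), so a constant integrand integrates to the exact
  domain area (n−1)(m−1)·h²;
* signed node steps are used along each axis, so fields whose y
  coordinate descends with row index (the image convention: row 0 is
  the top of the frame, physical y points up) differentiate correctly.

Exactness and convergence: linear fields (solid rotation, pure shear)
are differentiated exactly, giving the rigid-motion null (VED = 0 to
machine precision) and the closed-form shear value μγ²A to 1e−10
relative; for the smooth Lamb–Oseen vortex the operator converges to
the analytic dissipation integral with observed order ≈ 2.  VED is
invariant under constant velocity offsets (Galilean invariance) and
non-negative by construction.

TVED is integrated on a refined grid by trapezoid after periodic
extension: one second exceeds both the rest cycle (60/70 s) and the
exercise cycle (60/110 s), so the recorded cycle is tiled by the cycle
period, with linear interpolation in phase and the first sample closing
the cycle.

Peak reporting: the two diastolic peaks are maxima of the VED series
restricted to two configurable phase windows, by default [0, 0.15] and
[0.45, 0.65] of the cycle.  The first window catches the remnant of the
atrial (A) wave that spills past the cycle boundary; the second the
early-filling (E) crest.  A monotone series inside a window returns the
endpoint maximum with a warning.

## The synthetic duplicator

The generator produces the four raw-data types of the rig with the
study's pump settings as defaults (rest 70 bpm / 60.08 mL, exercise
110 bpm / 90.13 mL; water/glycerol analogue μ = 4.2 cP, ρ = 1100 kg/m³;
pressure sampling every 4 ms; camera 1000 fps at 1632 × 1200 px).

**Activation waveform.** Diastolic inflow is two raised-cosine lobes —
passive early filling (E) then atrial contraction (A) — placed by
onset/width fractions of the cycle.  Raised cosines are smooth, have
closed-form means, and carry two free timing fractions; the rig's
actual waveform is known only qualitatively, so the default timing
(E lobe at 0.47–0.71 of the cycle, A lobe at 0.92–1.10, E/A amplitude
ratio 1.5) is a physiological placeholder, not a calibration.  The A
lobe deliberately wraps past the cycle boundary so its crest and
decaying remnant appear just after cycle start, which is where the
measured dissipation traces place their first peak.

**Transmitral jet.** The jet is a kinematic prescription (no
Navier–Stokes solve): a vertical planar jet with Gaussian cross
profile, e⁻² width `width`, σ = width/4.  Reading the profile as an
axisymmetric orifice velocity profile gives an effective orifice area
2πσ²; the jet amplitude is scaled so the cycle-integrated volumetric
inflow equals the stroke volume exactly (closed form), which the tests
verify to 1 % from the sampled frames.  Consequences worth noting: at
fixed stroke volume a narrower jet is a faster jet with a sharper shear
layer, and dissipation grows steeply (≈ σ⁻⁵) as the width shrinks.

**Valve models.** The normal valve is a wide jet (24 mm) at both
conditions.  The calcified valve is narrower (19 mm at rest) and
narrows further under exercise (16 mm), representing jet contraction
through a rigid, tunnel-like orifice at higher flow; this
flow-dependent narrowing is what makes the rest→exercise TVED rise
disproportionate for the calcified model.  With a flow-independent
width the kinematic model's percent rise would be identical for any
width (pure amplitude scaling), so the narrowing is the model's
expression of the mechanism, chosen once as part of the study
conditions.  The *magnitudes* of VED, TVED and the percent rises on
these desk-scale fields are not comparable to rig measurements; only
orderings and operator properties are asserted anywhere.

**Particle images.** Tracers are seeded uniformly at the configured
density (Poisson count), rendered as 2D Gaussian blobs with e⁻²
diameter equal to `particle_diameter` (default 3 px, the image of a
~50 μm tracer), advected by the locally interpolated velocity over the
frame interval, with optional additive Gaussian noise.  Particles
advected off the frame are dropped and none are injected — the simplest
consistent contract.  A displacement anywhere above ¼ of the final
16 px interrogation window (4 px) is refused with the offending
maximum named, matching the classical one-quarter rule.

**Pressure traces.** Canonical piecewise-smooth shapes: LV baseline
5 mmHg with a ~120 mmHg raised-cosine systolic peak; LA below LV in
systole (small v wave) and above it throughout diastole by the
configured offset, modulated by the E/A waveform with unit diastolic
time-average and a positive floor (0.15 of the mean) so the gradient
never reverses mid-diastole.  Only the diastolic LA−LV difference is
contractually meaningful; the round trip through
`catheter_mean_gradient` recovers the generating offset within 2 %
(noise-free), limited by the 4 ms sampling of the window edges.

**Doppler envelopes.** Half-sine E and A lobes at the beat's timing
fractions, sampled at 250 Hz, with lobe peaks chosen analytically to
carry a target mean gradient when the pipeline needs one.

All generators take one integer seed per call and are bit-reproducible;
there is no global random state.

## PIV estimator

Standard multi-pass FFT cross-correlation:

* passes at 64 then 16 px windows, 50 % overlap (node step =
  window·(1−overlap); output grid dimensions follow
  floor((image−window)/step)+1);
* windows are mean-subtracted and zero-padded to twice their size, so
  the circular FFT correlation is linear (no wrap-around bias); the
  residual peak search is limited to ±window/2 lags;
* between passes the validated coarse field is bilinearly interpolated
  to the finer grid and rounded to whole pixels, and the second window
  is shifted by that predictor (discrete window offset; full image
  deformation is an extension point, not implemented);
* sub-pixel refinement is the three-point Gaussian fit per axis, the
  standard PIV estimator, falling back to a parabolic fit when a
  correlation neighbour is non-positive; a peak on the search-region
  border marks the node invalid rather than raising;
* vector validation is the normalized median test on the 8-neighbour
  residuals (threshold 2.0, noise floor ε = 0.1 px, the common
  literature defaults); outliers are replaced by the neighbour median
  and flagged; windows with no texture are flagged invalid, never
  fatal; masked nodes are never examined and never feed medians.

Measured on rendered images (density 0.02 px⁻², no noise): bias
< 0.1 px and RMS < 0.2 px across uniform displacements in [−4, 4] px
(peak locking dominates the sub-pixel bias, worst near half-pixel
displacements), interior R² > 0.98 on a slow solid-rotation field, and
a full 1632 × 1200 pair processes in well under two minutes on one CPU.

Coordinates: displacements are estimated in image axes (x right, y
down); conversion to physical velocities flips the sign of v and maps
node rows to descending physical y.  A fixture test pins this contract.

## Gradients and valve area

* **Diastole detection.** Maximal intervals where LA ≥ LV.  Crossovers
  are located on a 20 ms moving average of the pressure difference —
  without it, sensor noise near the small diastolic offsets fragments
  the windows and the debounce then keeps only high-gradient fragments,
  biasing the mean upward (22 % at a 1.3 mmHg offset with 0.15 mmHg
  noise).  Each detected edge is refined back against the raw
  difference sign, and the integrand is always the raw difference, so
  noise-free results are unaffected by the smoothing.  Intervals
  shorter than 20 ms are discarded as chatter.
* **Catheter mean gradient.** Trapezoidal time average of LA − LV over
  the union of diastolic windows.
* **Doppler mean gradient.** Time average of the instantaneous
  simplified-Bernoulli pressure 4v² (v in m/s, result in mmHg) over the
  flow period — the maximal intervals where the envelope exceeds a
  threshold (default 0 m/s; configurable for noisy envelopes), each
  extended to the bounding below-threshold samples so the zero
  crossings are integrated.  This is the clinical convention (mean of
  4v², not 4·(mean v)²): a constant 1 m/s envelope gives exactly
  4 mmHg and a half-sine lobe of peak 1 m/s exactly 2 mmHg.  The
  blood-analogue density difference from blood is ignored, as in
  clinical practice.
* **Gorlin valve area.** MVA = 0.85·CO/(44.3·HR·FP·√ΔP) with CO in
  mL/min (HR × stroke volume), FP the diastolic flow period in s/beat
  (0.465 s at rest), ΔP in mmHg, result in cm².  Exercise MVA is not
  computed: the exercise flow period is not defined for the duplicator.

## Pipeline

One run = one cell (valve × condition), five replicate recordings by
default.  Replicates differ in pressure-sensor noise (0.15 mmHg) and
1 % beat-to-beat stroke-volume jitter, seeded as base·1000+replicate;
reported scalars are replicate means and the replicate VED traces feed
a one-way ANOVA (each recording a group of samples).  Problem sizes per
replicate — 128 frames per cycle on a 64 × 64 grid (8 cm domain,
1.25 mm spacing), one rendered 384 × 384 PIV check frame at the E-wave
peak with a 50 μs pulse separation — keep a full four-cell study at a
few seconds while resolving the jet's shear layer with several nodes
per σ.  Runs are deterministic under a fixed seed (byte-identical
summaries) and write all intermediate artifacts (traces, envelope,
field and image samples, VED series, summary CSV/JSON) when an output
directory is configured.

## Known limitations

* Flow fields are kinematic: no continuity constraint, no vortex
  dynamics, no valve-leaflet mechanics; VED magnitudes and percent
  rises on synthetic fields are desk-scale stand-ins, and passing tests
  demonstrate correctness of the *estimators*, not agreement with rig
  physics.
* The planar dissipation integral ignores out-of-plane gradients, as
  any single-plane PIV estimate must.
* The PIV implementation offers discrete window shifting only (no
  window deformation), so strongly sheared flows at large displacement
  lose accuracy; the one-quarter rule is enforced at render time.
* Doppler envelopes are ideal maximal-velocity curves; spectral
  broadening, beam misalignment and pressure-recovery effects — the
  suspected sources of catheter/Doppler discrepancy — are not modelled.
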