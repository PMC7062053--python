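# Methods

This package re-creates, at desk scale, a computational chain for
thoracic-aorta haemodynamics: calibrating wall stiffness to a measured pulse
wave velocity, tuning Windkessel outlet boundary conditions to a flow-split
target, decomposing wall shear stress into axial and circumferential
components and their ratio (SSR), extracting jet markers from 4D-flow-style
velocity fields, and comparing control / stable / dilating groups. The
original workflow runs a 3D fluid–structure-interaction solver on
patient-specific meshes; here every step is exercised on synthetic data with
closed-form ground truth, with a 1D pulse-wave model standing in for the 3D
solver. What a green test establishes is therefore that the *procedures*
(calibration loops, estimators, statistics) behave as specified — not that
any patient-level result is reproduced.

## Fluid and wall constants

Blood is incompressible and Newtonian: density ρ_f = 1050 kg m⁻³, dynamic
viscosity μ = 0.035 kg (m s)⁻¹. The wall carries density 1100 kg m⁻³ and
Poisson ratio 0.45 as metadata; neither enters the 1D surrogate (see below).

## 1D pulse-wave surrogate (`pulsewave`)

Area–flow formulation on a straight elastic tube:

    ∂A/∂t + ∂Q/∂x = −ψ(x,t)
    ∂Q/∂t + ∂(Q²/A + c₀²A²/(2A₀))/∂x = −8πν Q/A

with a **linear tube law** P = P_ref + ρ_f c₀² (A−A₀)/A₀ whose linearised
wave speed is exactly the Moens–Korteweg speed c₀ = √(E·h/(2ρ_f·r)). The
(1−ν²) factor that appears in thin-shell derivations is deliberately
omitted so the calibration loop is exact at its fixed point; ν stays
metadata. The density in the Moens–Korteweg relation is taken as the fluid
density (the classical convention; the source text leaves it unsubscripted).

Numerics: two-step (Richtmyer) Lax–Wendroff on 200 uniform cells, fixed time
step at CFL 0.9 against an a-priori speed bound, with a runtime check that
raises (naming the required Δt) if the realised wave speed outruns the grid.
The inlet prescribes Q(t) and resolves the area from the outgoing Riemann
invariant (Newton); the outlet couples the incoming invariant to a
backward-Euler 2-element Windkessel, Q = P/R + C·dP/dt. ψ(x,t) is an
optional distributed, pressure-driven mid-tube sink (Gaussian bump of area
one times (P−P_ref,sink)/R_branch) standing in for the supra-aortic
branches, which are otherwise out of scope. Cycles repeat until the
recorded flow field changes by < 0.5% (relative L2) cycle-to-cycle.
P_ref = 9975 Pa (~75 mmHg) sets a physiological operating pressure so the
branch sink and Windkessel see realistic transmural values. Halving Δx and
Δt moves the measured PWV by < 1% (grid independence, tested).

### Transit-time PWV

`measure_pwv` divides the plane separation by the difference of
systolic-peak times, refined by a quadratic fit around the discrete maximum
(25 ms frames are too coarse for a raw argmax). On a 0.3 m tube the
Windkessel reflection is strong and the system is acoustically short, so
raw peak timing at the periodic steady state is ill-posed — the outlet peak
can even *lead* the inlet. The calibration loop therefore measures on the
**forward-running wave** (linear separation Q_f = (δQ + δP/Z_c)/2 with
Z_c = ρ_f c₀/A₀) and estimates the delay by circular cross-correlation with
parabolic refinement (`method="xcorr"`). Empirically this estimator is
smooth and monotone in E and sits within ±3% of c₀ across E ∈ [0.85, 9] MPa
at physiological amplitude, whereas raw peaks are bistable near E ≈ 3 MPa
(a re-reflected crest competes with the primary one). Peak-based
measurement remains the default of the public function.

## Calibration loops (`calibration`)

**Stiffness.** E₀ = 2·PWV_target²·r·ρ_f/h; each iteration simulates the
tube, measures PWV_i, and stops once |ε| = |PWV_i−PWV_target|/PWV_target ≤
5% (the source procedure's tolerance). The update is multiplicative,
E_{i+1} = E_i·(PWV_target/PWV_i)², whose fixed point is PWV_i = PWV_target;
re-evaluating the Moens–Korteweg formula at PWV_i (the literally printed
rule) is a fixed point of the formula itself and cannot steer a biased
simulator — it is kept behind `update="printed"` and shown non-convergent
in a test. A 0.7 damping factor on the log-E step engages only if ε
oscillates without shrinking. Across targets 6.2–20.7 m s⁻¹ the loop
converges in ≤ 3 (in practice 1–2) iterations because the measured PWV is
within a few percent of c₀ and PWV(E) ≈ a·√E.

**Flow split.** The descending/ascending ratio is the cycle-mean outlet
flow over inlet flow of the branch-sink model. R is tuned by a secant
iteration on log R (the ratio is monotone decreasing in R: higher R raises
pressure and branch leak), replacing manual trial and error; the stopping
band is ±5% of the target. C is not identifiable from a flow ratio and is
closed by a fixed time constant, RC = T/3 — a mid-range arterial value. The
loop accepts any `ratio_fn(R)`, which the tests exploit with analytic toy
junctions and a 50-point grid-search oracle.

## Synthetic cohort (`synthetic`)

The generator's defaults are the stated world of the emulated study:

- Inlet flow: cycle mean 83 mL s⁻¹ (~5 L min⁻¹ cardiac output), period
  900 ms (67 bpm), peak/mean 3.5, systolic fraction 0.35 — a raised-sine
  systolic bump on a diastolic baseline, renormalised to the exact mean.
- Geometry: candy-cane centerline (40 mm ascending limb, 180° arch of
  30 mm radius, 60 mm descending limb), lumen radius 12.5 mm, wall 1.25 mm,
  five segments with the ascending half split into proximal/distal.
- Jet: parabolic axial profile recentred d mm off the centerline with
  support radius R−d (no-slip preserved, flow rate exact), tilted by the
  jet angle with the in-plane component added so the axial flow rate is
  unchanged. Optional Womersley harmonics (Bessel-series profiles validated
  against a 30-digit sympy evaluation) give unsteady realism.
- Swirl: u_θ = k·ρ² about the jet centre — chosen over solid-body rotation
  because its wall shear is non-zero (μkR for a centred jet), giving SSR an
  analytic value kπR⁴/(4Q). k is modulated along the vessel by a
  raised-cosine envelope over the distal ascending segment (baseline 0.15),
  where the study's group differences concentrate.
- Groups: target PWVs drawn uniformly within each group's measured range
  (controls 6.4–11.1, stable 6.2–12.5, dilating 6.8–20.7 m s⁻¹); helical
  strength multipliers 1× / 2× / 6× of k₀ = 7.5×10³ (m s)⁻¹ (k₀ set so a
  control-level centred jet has peak-systolic SSR ≈ 0.5); jet offsets and
  angles grow with severity (0.5–1.5 / 1.5–3 / 2.5–4 mm and 2–6 / 5–12 /
  8–18°). The multipliers and ranges are configuration expressing the
  qualitative group effect, not measured effect sizes.
- MRI degradation: box averaging to 2.5 mm voxels (the fine default of
  0.625 mm makes this an exact 4³ block mean) and ~25 ms frames, plus
  additive Gaussian velocity noise with σ = venc·√2/(π·SNR) per component —
  the standard phase-contrast noise propagation — at venc 200 cm s⁻¹ and
  SNR 20. Phase wrapping beyond ±venc is available but off by default.

What the generator does **not** emulate: k-space acquisition, eddy-current
or background-phase offsets, gating/breathing artefacts, branch outflow in
the 3D fields, wall motion, or turbulence. Consequently SSR magnitudes here
are not comparable with patient values (the swirl needed for control-level
SSR ≈ 0.5 implies wall tangential velocities ~1 m s⁻¹, and dilating-group
SSR reaches ~10–20 at the envelope peak); only orderings and procedural
tolerances carry over.

## Markers (`markers`)

All plane markers act on the forward flow (v·t̂ > 0) at peak systole (peak
of the plane's own flow curve, parabolically refined; the nearest stored
frame supplies the field). Flow displacement is measured from the
centerline intersection with the plane (a lumen-centroid reference is
optional); the jet angle is the angle between the centerline tangent and
the velocity at the forward maximum.

**Wall shear.** The estimator samples the velocity-gradient tensor just
inside the wall by central differences of mask-normalised trilinear
interpolation (normalised convolution removes the zero-padding bias near
the wall), forms the viscous traction t = −μ(∇u+∇uᵀ)·n̂ with n̂ the outward
normal, and projects it on the axial (centerline tangent projected to the
surface) and circumferential (n̂ × axial) directions. The traction is
evaluated at depths of 1.5 and 3 fine voxels and linearly extrapolated to
the wall, removing the leading O(depth/R) bias: Poiseuille axial shear
4μQ/(πR³) and swirl circumferential shear μkR are reproduced within ~2% at
0.25 mm resolution (≤5% across 0.25–0.5 mm), and solid-body rotation gives
zero. A plain 3-point no-slip-anchored slope fit is kept as
`method="slope"`; it matches Poiseuille but is blind to rigid rotation and
wrong for any flow with non-zero wall-parallel swirl, which is why the
traction estimator is the default. Vertices whose stencil leaves the lumen
are flagged invalid and excluded from statistics.

**SSR.** SSR = |WSS_circ| / max(|WSS_ax|, 10⁻³ Pa). Magnitudes make the
ratio invariant to the axial sign convention; the 10⁻³ Pa floor guards the
flow-reversal instants where the ratio is undefined — floored vertices are
flagged and excluded from regional means (a signed variant is not provided;
the reported regional values are all magnitudes). Because both WSS
components are linear in velocity, SSR is exactly invariant under uniform
velocity scaling (tested to 1e-12, floored vertices excluded — the fixed
floor breaks homogeneity by construction).

**Marker ground-truth plane.** Generator-truth validation uses a plane in
the proximal ascending segment, below the helical envelope: inside the
envelope the velocity maximum can be swirl-dominated and the closed-form
jet truth no longer applies. Error tables report relative errors in percent
except the jet angle, whose error is the absolute difference in degrees;
error reductions are averaged per case (which can differ from the reduction
of the group means when an individual reference error is near zero — both
are reported by the analysis driver).

## Regional statistics (`regional`)

Quadrants are 90° sectors about a user-fixed anterior axis carried along
the vessel by rotation-minimizing (double-reflection) frames — Frenet
frames would flip on straight sections. Two label conventions are supported
(anterior/left/posterior/right and interior/anterior/exterior/posterior);
their mapping onto patient image axes is a convention choice, not a claim.
The cumulative analysis region defaults to the distal ascending segment
(arithmetic midpoint split of the ascending range), summarised by the
ECDF's 90th percentile (linear interpolation between closest ranks).

Group comparison: Kruskal–Wallis with tie correction, p from the χ²
approximation (scipy) or from exact permutation — all partitions of the
pooled sample into the observed group sizes are enumerated with vectorised
rank-sum gathers (34 650 partitions at 3×4), which makes the 2000-cohort
type-I-error check cheap. The post hoc is Scheffé on the original values,
as the emulated protocol states, even though a rank-based test is the more
conventional companion to Kruskal–Wallis; Dunn's test (Bonferroni) is
available behind a flag. Group tables report mean ± s.e.m.

## Known limitations

- The 1D surrogate has a single outlet plus a lumped sink; no branched
  network, no 3-element Windkessel, no viscoelastic or anisotropic wall.
- Transit-time PWV on a 0.3 m tube is only well-posed on the
  forward-separated wave; raw peak timing is reported faithfully but can
  fail (and says so) when the outlet reflection reshapes the crest.
- WSS/SSR absolute values are estimator- and resolution-dependent; the
  package validates against closed forms, not against any scanner- or
  solver-derived value.
- With the prescribed 2× multiplier the stable group's SSR sits midway
  between control and dilating rather than at the control level; only the
  dilating-exceeds-both ordering is asserted.
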