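# Methods

## Scope

`wallstrain` analyzes transverse B-mode cine loops of a pulsatile
thick-walled vessel phantom: it meshes the wall between two contours,
tracks speckle motion over one cardiac cycle, computes the per-frame mean
principal Green–Lagrange strain ε̄ρ(t), its cycle maximum ε̄ρ⁺, and the
pulse-pressure-normalized ε̄ρ⁺/PP. A paired synthetic-data generator
produces cine loops with closed-form ground truth so that every stage —
and the chain as a whole — can be validated quantitatively.

## Phantom mechanics

The idealized model is a 28-mm vessel with a 50-mm spherical sac and a
uniformly 2.5-mm wall of compliant silicone. The imaging plane through the
sac's maximal diameter is treated as a plane-strain thick-walled cylinder
(inner radius a = 25 mm, outer radius b = 27.5 mm). For an incremental
internal pressure p (mm Hg, converted to kPa) the radial displacement is
the Lamé solution

    u(r) = (1 + ν) p a² / (Y (b² − a²)) · ((1 − 2ν) r + b²/r),   a ≤ r ≤ b.

Assumptions: quasi-static response (the phantom's compliance was validated
at 1.2 Hz and is taken as frequency-independent at 70 bpm), linear
elasticity (peak wall strain ≲ 5%), near-incompressibility (ν = 0.495;
the ν = 0.5 limit is the same closed form with the (1 − 2ν) term zero),
and axisymmetry. The 2D cross-section model of a spherical sac is a
deliberate simplification: the analysis of real loops is 2D, so a 2D
ground truth is the consistent target, and a closed form beats a
finite-element simulation for testability.

The Young's modulus is not a free parameter: `calibrate_modulus` inverts
the Lamé expression so the diameter compliance 100·Δd/d at 100 mm Hg hits
a target (default 6%, the center of the phantom's validated 5–7% band).
Compliance is linear in 1/Y, so the inversion is exact and round-trips to
1e-6.

The true wall deformation metric is the circumferential Green–Lagrange
strain of the radial displacement field, ε(r) = u/r + u²/(2r²); the
area-weighted wall mean uses the polar weight r dr and a 2001-point
trapezoidal quadrature. At default conditions the quadratic term
contributes ~2%, which is why the pipeline uses finite rather than
infinitesimal strain throughout.

## Plug packing as pressure damping

Embolization-plug packing is represented by a single damping factor
δ ∈ [0, 1] applied to the pulsatile pressure component only:

    p_eff(t) = p_dia + (p(t) − p_dia) (1 − δ).

δ = 0 is the empty sac, δ = 1 freezes the wall at end-diastole. Damping
the pulsatile component but not the mean mirrors the benchtop observation
that sac pressure stays close to lumen pressure while pulsatile strain
falls. Because ε̄ρ⁺/PP always divides by the *undamped* circuit pulse
pressure, the true normalized strain is strictly decreasing in δ — the
in-silico analogue of strain falling with packing volume. The mapping from
packing percentage to δ is a configuration input, not a physical claim; no
validated model links plug count to damping. The defaults
(sequential 100–400% → 0.05/0.20/0.40/0.60, immediate → 0.10/0.35/0.60/0.85)
are monotone in packing volume with immediate deployment damping more at
equal packing. Plug expansion over time follows one exponential clock,
δ(t) = δ_final·(1 − e^(−t/τ)) with τ = 5 min, so a deployment is ~95%
expanded at the 15-minute observation ("total expansion within 15
minutes"); sequential deployment keeps all previously deployed levels
fully expanded and applies the clock only to the newest increment.

## Pressure waveforms and cycle detection

`synth_waveform` produces either a raised-cosine ("sine") or a skewed
cycle (raised-cosine upstroke over the first third, slower cosine decay
over the remainder), starting exactly at the diastolic minimum so frame 0
of a driven cine is the end-diastolic reference. The default drive is the
skewed shape with p_sys/p_dia = 130.4/47.0 mm Hg, making the drive's pulse
pressure equal the benchtop circuit's mean lumen pulse pressure of
83.4 mm Hg. Cycle boundaries are detected automatically as local pressure
minima with a prominence guard of 10% of the global excursion; the first
and last samples also qualify when they sit within 5% of the excursion
above the global minimum, since recordings deliberately started at
end-diastole have no interior minimum at their edges. A k-cycle recording
therefore yields k or k−1 complete windows depending on its end phase.

## Speckle simulation

Scatterers fill the wall annulus uniformly (Poisson count at 30/mm²,
standard-normal amplitudes; ~12,000 at default geometry). Each frame
displaces every scatterer radially by the Lamé field at the damped
incremental pressure, then renders: each scatterer carries a round-trip
carrier phase exp(i·4π·z/λ) (λ = c/f at 5 MHz, c = 1.54 mm/µs), the
complex field is splatted bilinearly onto the 256×256 grid (0.25 mm/px,
64-mm field of view) and convolved with an anisotropic Gaussian envelope
(σ_axial = 0.3 mm, σ_lateral = 0.6 mm), envelope-detected, log-compressed
over 40 dB, degraded with additive Gaussian noise (σ = 0.05 on the [0, 1]
image), and clipped. The carrier phase matters: axial motion then
translates the interference pattern exactly with the tissue, as in real
speckle. Default block correlation between consecutive frames is ~0.96.

What the generator does *not* emulate: RF-domain physics, attenuation and
shadowing, out-of-plane motion, probe-geometry-dependent beam width,
reverberation, and any real plug material in the sac. Passing tests
therefore demonstrate the correctness and noise robustness of the analysis
chain on speckle with realistic statistics — not performance on clinical
images.

All randomness flows from one integer seed through independent
`numpy` `SeedSequence` streams (scatterers; per-frame noise), so two runs
with equal configurations are bit-identical.

## Wall meshing

The region of interest between the inner and outer contour is meshed with
a structured annular layout: contours are parameterized by polar angle
about the inner contour's centroid (a star-shape assumption appropriate
for aneurysm cross-sections), n_circ circumferential stations and
n_layers+1 radial node layers are placed so edges ≈ 1.25 mm, and each quad
is split into two positively oriented triangles. For the default wall this
gives 3 × 132 = 396 nodes and 528 elements, total area within 2% of the
polygon area between the contours, minimum interior angle ≥ 20°. The
construction is deterministic; contours crossing or a target edge coarser
than the wall gap raise errors. For synthetic runs the contours are exact
circles from the configuration — standing in for manual wall delineation —
and can be perturbed to emulate operator error.

## Speckle tracking

Nodal motion is estimated by normalized cross-correlation (NCC) block
matching: 17×17-px blocks (halfwidth 8), ±10-px search, batched FFT
cross-correlation with integral-image window statistics. The integer peak
is refined to subpixel in three stages, each addressing a measured failure
mode of the plain estimator:

1. **Separable parabolic fit** of the correlation surface about the peak —
   the classical estimator, skipped when the peak is an exact integer
   match (fitting a parabola through a perfect peak with asymmetric
   shoulders would bias it).
2. **Iterative image-domain refinement** (3 iterations): the moving block
   is re-sampled by cubic-spline interpolation at the current estimate and
   the residual offset re-estimated from a 3×3 NCC neighborhood. The
   parabolic fit alone peak-locks severely on this speckle — up to 33%
   underestimation of a 0.1-px axial shift, where the PSF is narrow —
   because its gain depends on the peak shape; iterating to the fixed
   point where the residual vanishes removes the bias (the fit's gain then
   only affects convergence speed). Residual bias is ≲ 0.01 px.
3. **Forward–backward symmetrization**: the time-reversed estimate is
   averaged in with opposite sign, cancelling the odd part of the
   speckle-pattern-dependent bias.

Two temporal modes exist. The default, **reference tracking**, measures
each frame's cumulative displacement directly against the end-diastolic
frame-0 template, with the search window re-centered at the previous
frame's estimate so large cyclic excursions stay inside the search range.
The classical **incremental** mode (frame-to-frame estimation, blocks
re-centered at node + cumulative displacement, increments accumulated) is
retained as an option, but measurement shows its weakness: each node
carries a persistent, speckle-realization-specific subpixel bias that is
nearly identical between consecutive frame pairs, so accumulation grows it
linearly — ~1–2 px of cumulative error over 64 noiseless frames versus
~0.1–0.3 px for reference tracking, whose error cannot accumulate.

Each per-frame field is regularized on the mesh graph: nodes that are
invalid (no block support, zero-variance block) or score below the 0.5
NCC threshold are replaced by valid-neighbor means (field median as last
resort), then the field is decomposed into its global rigid part —
translation plus the antisymmetric (rotation) component of a least-squares
affine fit — and a residual, and only the residual undergoes 60 rounds of
Laplacian smoothing at weight 0.5 (a smoothing length of ~5 edges ≈ 6 mm,
a few block widths). Exempting the rigid part is essential on a mesh only
three node-layers thick: plain neighbor averaging flattens the genuine
radial gradient of a rotation field (u_θ = θ·r), and the flattened field
reads as ~1.4% shear strain for a 1° rigid rotation. With the exemption, a
rigidly translating and rotating phantom (0.72 mm translation, 1°
rotation) reads |ε̄ρ⁺| ≈ 0.001 — the noise floor — while the pulsating
phantom reads ≈ 0.049.

Tracking contains no randomness; identical inputs give identical outputs.

## Strain computation

Per element, the deformation gradient comes from constant-strain-triangle
kinematics on the reference (frame-0) mesh, F = I + ∂u/∂X via linear shape
functions; elements with degenerate reference triangles are skipped and
logged. E = ½(FᵀF − I) is symmetrized against rounding; principal strains
are its eigenvalues in descending order. Green–Lagrange strain is used for
exact rigid-motion invariance; at phantom strain levels it differs from
infinitesimal strain by ≲ 2%.

ε̄ρ(t) is the reference-area-weighted mean of the first principal strain
over valid elements (area weighting chosen over a plain element mean; for
this regular mesh the two differ negligibly). ε̄ρ⁺ is the maximum over the
cycle window, and the normalization PP is the lumen pulse pressure of the
same acquisition — the circuit's pulse pressure, not the damped sac
pressure, which is precisely what makes ε̄ρ⁺/PP sensitive to packing.

## Validation strategy and problem sizes

The test suite validates each operation against closed forms and the full
chain against the generator's analytic truth, at two scales: a fast
configuration (16 frames, 128×128 px, 0.5 mm/px) for unit-level checks,
and the default 64-frame 256×256 loop for the end-to-end properties. On
the default loop:

- feeding exact analytic nodal displacements into the strain pipeline
  reproduces the closed-form mean strain within 3% relative
  (discretization only; measured ≈ 0.07%);
- the full chain — simulate, mesh, track, strain, normalize — recovers the
  true ε̄ρ⁺/PP within 15% relative (measured ≈ 3–7% across seeds);
- recovered ε̄ρ⁺/PP decreases strictly across δ ∈ {0, 0.25, 0.5, 0.75, 1}
  (Spearman ρ = −1);
- drives with 40 and 80 mm Hg pulse pressure give the same ε̄ρ⁺/PP within
  5% (measured ≈ 1–3%);
- a rigidly moving phantom reads |ε̄ρ⁺| < 0.002 versus ≥ 0.02 when
  pulsating.

`scripts/acceptance.py` recomputes all of these from scratch at the
default problem sizes, seeded from the command line, in about two minutes
on one CPU.

## Numerical choices and degenerate inputs

- Pressures in mm Hg externally, converted once (1 mm Hg = 0.133322 kPa).
- Mesh coordinates are physical mm with the pixel-center, origin-top-left
  image convention; pixel spacing 0.25 mm/px by default.
- Zero-variance correlation windows score −∞ during peak search; a
  zero-variance template flags the node invalid with zero displacement.
- Subpixel steps are clamped to ±0.5 px (parabolic) and ±1 px per
  refinement iteration; non-finite fit values fall back to the integer
  peak.
- Blocks partially outside the image are clamped to full support; points
  with no overlap at all are flagged invalid.
- Cycle detection requires a non-constant trace and at least two
  end-diastolic boundaries; empty windows and out-of-range indices raise.
- The excluded sac volume is kept at full precision (20.05 cm³ for the
  default geometry); the conventional 20.0 figure arises from differencing
  the two 1-dp-rounded volumes.

## Known limitations

- The damping map packing% → δ is a modeling convenience; absolute
  percent-change-vs-baseline numbers from `run_experiment` characterize
  the configured map, not plug physics. In particular the strain
  *increase* observed at low packing volumes on the bench (attributed to
  plugs adding intrasac volume before acting in aggregate) is outside the
  δ ∈ [0, 1] damping model, which can only reduce strain.
- The plane-strain cylinder ground truth ignores the sphere's meridional
  curvature; absolute strain magnitudes are phantom-model-specific.
- Star-shaped contour parameterization limits meshing to non-convoluted
  walls (adequate for near-circular cross-sections).
- The tracker assumes locally translational motion over a block; strong
  in-plane rotation (> a few degrees per cycle) or through-plane motion
  degrades it in ways the generator does not emulate.
- No statistical machinery is included: the benchtop design this mirrors
  tested each condition once, and the package likewise reports single
  deterministic runs per condition.
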