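# Methods

`islandmech` measures force and motion in confined epithelial monolayers:
circular micropatterned islands (~1 mm in the laboratory) adhering to soft
elastic gels with fluorescent tracer particles. The chain is

1. **Image correlation (DIC/PIV)** — cell velocities from consecutive
   phase-contrast frames; substrate displacements from particle images
   against a traction-free (trypsinized) reference.
2. **Traction force microscopy (FTTC)** — tractions from substrate
   displacements via the elastic half-space kernel in Fourier space.
3. **Monolayer stress microscopy (MSM)** — the in-plane stress tensor of
   the cell sheet from the tractions, by a plane-stress finite-element
   solve of the in-plane force balance.
4. **Kinematics and validation** — radial decompositions, trajectory
   integration, and the standard data-quality metrics.

A synthetic-island generator produces ground truth for every stage, so the
whole inverse chain is testable without laboratory data.

## Conventions (fixed once, used everywhere)

* Image coordinates: `x` along columns, `y` along rows increasing
  downward; arrays are indexed `[y, x]`; physical units µm, min, Pa.
* `T` is the traction exerted **by the cells on the substrate**. In-plane
  force balance of the monolayer then reads

      ∇·σ − T/h = 0,

  where σ is the in-plane stress tensor of the sheet and `h` its height.
  With this sign a contractile island has radially inward edge tractions
  (`T·r̂ < 0`) and positive (tensile) stress. The equivalent equation with
  `+T/h` holds if `T` is read as the substrate-on-cell traction; the
  literature uses both and rarely says which face is meant, so the package
  pins the convention here and enforces it with sign tests.
* Radial/tangential decompositions are taken about the island centroid;
  the degenerate isotropic stress state returns orientation θ = 0.

## Substrate model and FTTC

The gel is a linear elastic half-space (Boussinesq). For wavevector
k = (kx, ky), k = |k|, the surface displacement response kernel is

    G(k) = 2(1+ν)/(E k³) · [[(1−ν)k² + ν ky²,  −ν kx ky],
                            [−ν kx ky,          (1−ν)k² + ν kx²]]

with `u(k) = G(k)·T(k)`. Its determinant is `(2(1+ν)/(Ek³))²(1−ν)k⁴ > 0`
for every nonzero mode and all ν ∈ [0, 0.5], so the inversion is defined up
to and including the incompressible limit. Numerical choices:

* The zero mode carries rigid translation / net force and is set to zero
  in both directions.
* On even grids the cross term `Gxy` is odd in kx (and ky) and would break
  the Hermitian symmetry a real field requires on the self-mapped Nyquist
  lines; it is zeroed there in both forward and inverse, keeping the two
  exact mutual inverses (round-trip ~1e−15 relative).
* Tikhonov regularization `T = (G² + λ²I)⁻¹ G u` with λ in the kernel's
  units (µm/Pa); λ = 0 by default. Under white displacement noise a small
  λ > 0 reduces the reconstruction error (tested), but no automatic λ
  selection is attempted.
* Padding/windowing: the plain transforms are exact for fields compactly
  supported in the frame, which synthetic islands are, so both default to
  off at the operator level. DIC-derived fields are cropped by the subset
  margin and are *not* compactly supported; the pipeline therefore pads
  2× by default. Both switches are recorded in the field metadata.
* Substrate Poisson ratio is set to 0.45 (near-incompressible
  polyacrylamide); results depend weakly on it. Gel thickness (100–120 µm
  in the experiments) is recorded but the half-space kernel is always
  used: the displacement decay length at the island's traction
  wavelengths is much smaller than the thickness. Finite-thickness kernels
  are out of scope.

## Monolayer stress microscopy

Force balance plus compatibility needs a constitutive closure. The sheet is
modelled as a homogeneous thin layer with

    σij = (K1 − 2/3·K2)·tr(ε̇)·δij + 2·K2·ε̇ij,      tr(ε̇) = ε̇xx + ε̇yy,

which reads as a viscous fluid if ε̇ is a strain rate or an elastic solid
if it is a strain; the recovered stresses are identical either way, because
the FEM computes `σ = K·K⁻¹·f`-like compositions in which the magnitude,
units and even the sign of the constitutive scale cancel. Only the
dimensionless ratio survives, expressed as the plane-stress Poisson-like
ratio

    ν_m = (K1 − 2/3·K2) / (K1 + 4/3·K2),

default 0.5 (equivalently K1 = 8/3·K2), configurable; the island-average
tension varies only modestly over ν_m ∈ [0.2, 0.5] (tested as a bounded
spread, not a fixed number). Monolayer height defaults to h = 5 µm; since
no measurement of h enters, the h-independent line tension σ·h can always
be formed by the caller.

Discretization:

* One bilinear quadrilateral (Q4) element per traction-grid cell inside
  the island mask; element centres coincide with the traction sample
  sites; 2×2 Gauss stiffness; sparse LU factorization.
* Loading: the default "lumped" scheme assigns each element's total force
  `−T·a²/h` in tributary quarters to its corners — exactly the consistent
  load vector for the piecewise-constant representation the cell-centred
  samples natively have. The alternative "consistent" scheme interpolates
  T to the nodes first and integrates the bilinear interpolant; the extra
  interpolation acts as a smoothing half-step and measured slightly less
  accurate on the recovery benchmark, which is why it is not the default.
  With a closed-form traction (synthetic benchmarks) a third path
  integrates the load by per-element Gauss quadrature.
* After assembly the nodal force vector has its residual net force and
  moment projected out (the residual is interpolation round-off, reported
  in the metadata). The three Dirichlet pins — vertical motion at the
  leftmost node, both components at the rightmost, ties broken by y — then
  carry exactly zero reaction, which is why relocating them changes the
  stresses only at solver precision.
* Tractions must be balanced before solving: net force and moment below
  1e−6 of the RMS traction scale, else the solve refuses and points to
  `enforce_equilibrium`. That correction is the minimal least-squares
  projection onto {uniform x, uniform y, rigid rotation about the
  centroid}, which removes a uniform offset or a rotation-like moment
  exactly.
* Element stresses are evaluated at element centres (the superconvergent
  point of Q4) and reported on the traction grid; arithmetic node
  averages are available separately. No extrapolation or patch recovery
  is attempted — plain nodal smoothing measurably *worsened* the
  benchmark because its bias exceeds the noise it removes.

## Image correlation

Subset-based normalized cross-correlation: for each node of a regular grid
(default 48 px subsets / 12 px spacing for cells, 32 px / 8 px for
particles, matching the acquisition the package emulates, at 10-minute
frame intervals), the subset of the first image is located in a search
window of the second; three-point Gaussian interpolation of the peak gives
subpixel displacement; the peak value is the quality score. Details:

* A perfect peak (NCC = 1) means exact integer alignment, and the
  three-point fit is skipped — it would otherwise be nudged by the
  asymmetric side lobes of the specific speckle realization.
* Subsets whose contrast is negligible relative to the image are flagged
  missing, as are non-finite or out-of-range correlation values; flagged
  nodes (quality below 0.5 by default) are inpainted by iterated 3×3
  neighbour means, because the Fourier traction inverse needs complete
  fields. Flagging is monotone in the threshold.
* Optional iterative refinement (off by default; the laboratory DIC
  algorithm this emulates is iterative): the current field is smoothed
  with a 3×3 node box, the deformed image is warped back by it, and the
  correlation is repeated for an increment. The predictor smoothing
  matters: without it, per-node estimator noise is re-imprinted as
  intra-subset distortion and the pass does not converge. The pass removes
  the shear-induced error of translation-only matching (0.15 px → 0.07 px
  on the 2 px warp benchmark).
* Translation-only subsets measure the amplitude-weighted mean
  displacement of their particles. For a warp with curvature the subset
  average differs from the centre value by ≈ |∇²u|·S²/24 (S = subset
  size); this bias is irreducible at fixed S and bounds what any
  benchmark of this estimator can demand.

## Trajectories

Forward Euler with one step per frame — x(t+dt) = x(t) + dt·v(x(t), t) —
with bilinear interpolation in space and piecewise-constant velocity in
time. Higher-order schemes would pretend to information between the
10-minute frames. Seeds default to every 4th grid node inside the mask;
trajectories that leave the mask or the grid are truncated and flagged.
Forward-then-backward integration returns to the seed up to the scheme's
O(dt) asymmetry (tested as a convergence rate, not a fixed tolerance).

## Validation metrics

* `rms_traction_ratio`: RMS |T| outside / inside the island, excluding a
  2-node ring around the boundary (the experiments' boundary-detection
  margin is not published; ours is explicit and configurable). Noise-free
  synthetic reconstructions give ~1e−15; the full image-correlation
  pipeline gives a few 0.01 because subset jitter (~0.02 px) is amplified
  by the kernel inverse at the grid Nyquist — the pipeline report's
  threshold of 0.1 comes from that noise-amplification estimate, set
  before the closed-loop runs.
* `edge_traction_sign`: mean radial traction in the outer 20% annulus;
  negative = inward.
* `normalize_tension`: island-average contractile tension (σ1+σ2)/2
  divided by its pre-treatment mean; idempotent; the pre-treatment mean of
  the output is exactly 1.

## The synthetic island

The generator emulates the study conditions at desk scale: a 52 µm-radius
island on a 256² grid at 0.65 µm/px stands in for the 1 mm island (the
ratio of DIC-subset size to pixel is preserved, which is what the
estimators care about), 6 kPa substrate, 10-min frames, mean inward cell
speed 0.3 µm/min with 0.1 µm/min smooth fluctuations of 13 µm correlation
length, K2 = 1e4 (Pa·min) so stresses land at a few hundred Pa, tractions
at tens-to-hundreds of Pa and gel displacements near one pixel — the
magnitudes typical of epithelial islands on soft gels. Particle images use
0.03 particles/px² with Gaussian spots of σ = 1.5 px (≈30 particles per
32 px subset; the real bead density per area is not published, so this is
a package default).

Two ground-truth constructions:

* **Axisymmetric contractile base (closed form).** The cubic inward
  profile v_r = −(c)·r·(1 − α r²/R²) with α = (1+ν_m)/(3+ν_m) is the
  unique such profile whose constitutive stress satisfies the free-edge
  condition exactly: σrr = σ0(1 − r²/R²), σθθ = σ0(1 − β r²/R²) with
  β = (1+3ν_m)/(3+ν_m), and T_r = −h σ0 (3−β) r/R², inward everywhere.
  Two sign facts are built in. First, the island-average tension equals a
  positive multiple of the *boundary flux* of the velocity — for any flow
  tapered to zero at the edge it is identically zero — so a contractile
  island must keep inward flow at its edge, which this profile does.
  Second, the passive constitutive law maps inward flow to compression;
  the generator therefore applies the law with the active-contraction
  sign (σ = −D ε̇): contraction of the actomyosin network generates
  tension. The MSM inverse is unaffected (sign of the constitutive scale
  cancels), and the pointwise operator `stress_from_strainrate` keeps the
  plain passive form.
* **Random fluctuation field (closed form).** A finite sum of Fourier
  modes with Gaussian spectrum exp(−k²L_c²/4), multiplied by a radial
  quintic-smoothstep taper. The same seed defines the same *continuous*
  field at every grid resolution (modes are fixed in physical k), which is
  what grid-refinement studies need. Because the field is an analytic
  expression, strain rates, stress and traction are differentiated in
  closed form (`FluctuationSolution`), giving exact continuum ground truth;
  the package's finite-difference operators are separate and are tested to
  converge to that truth. The taper is quintic (C²) deliberately: a C¹
  taper leaves t″ ≠ 0 at the ramp ends, so the traction — which contains
  t″ — jumps at the island edge, an unresolvable feature that caps FEM
  recovery accuracy; with the C² taper the recovery converges ~O(Δx²)
  (2.2% at 128², 0.4–0.6% at 256² across seeds).

Speckle images are rendered analytically (sums of Gaussians at exact
positions, particles seeded into a margin beyond the frame), so a uniform
shift really is a shift and there are no resampling artefacts.

**What the generator does not emulate** — and hence what passing tests do
not show about laboratory data: realistic phase-contrast cell texture
(cell images are advected speckle), camera noise, photobleaching and
focus drift, bead polydispersity and out-of-plane displacement, finite gel
thickness, irregular island boundaries, and cell-scale heterogeneity of
material properties. The closed-loop results certify the *algorithms* on
idealized imagery; accuracy on real images is bounded below by these
effects.

## Benchmark sizes and runtimes

The standard benchmarks run at 256² (island radius 80 px) with a 128²
half-resolution companion for convergence; the end-to-end image pipeline
demo uses a 320² frame so the subset margin still leaves a cell-free
border. The full test suite runs in under a minute on one core; the
acceptance script in ~10 s.

## Known limitations

* Half-space substrate only; no finite-thickness or layered kernels, no
  out-of-plane components.
* No automatic regularization selection (L-curve/Bayesian) for the
  traction inverse.
* The pixel-aligned mesh staircases the circular boundary; the free-edge
  hoop stress of a contractile island is nonzero there, so stresses in the
  outermost element ring carry a larger discretization error than the
  interior.
* Translation-only subsets (plus one global warp refinement); no affine
  subset shape functions, no optical flow.
* Trajectories are first-order in time by design (one step per frame).
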