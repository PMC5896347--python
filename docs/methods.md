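# Methods

This note records the models, numerical choices and known limitations of
the package, in the order the pipeline runs.

## Finite-element inclusion phantoms (`phantom_fem`)

**Model.** Plane-strain linear elasticity on a rectangular domain (default
40 × 40 mm) containing a circular inclusion, compressed from the top by a
prescribed fraction of the domain height. Boundary conditions: top surface
axial displacement prescribed (lateral free), bottom surface axial
displacement zero (lateral free, one bottom-center node pinned laterally to
remove the rigid mode), sides traction-free. Poisson's ratio is 0.495
everywhere (soft tissue is nearly incompressible); stiffness contrast is
expressed as the inclusion/background shear-modulus ratio, so the absolute
modulus scale drops out under displacement loading.

**Discretization.** Structured grid of square 4-node quadrilaterals with
*selective reduced integration*: the deviatoric part of the element
stiffness uses 2 × 2 Gauss quadrature, the dilatational (λ) part one-point
quadrature. Fully integrated quads lock volumetrically at ν = 0.495; the
refinement test (coarse vs. halved mesh, inclusion-core strain within 2%)
guards this choice. Elements are assigned to background / inclusion /
sub-inclusion by centroid, so the discrete interface is the closed
staircase of element edges between the regions (geometric error ≤ h/2).
Node snapping onto the circle was considered and rejected: per-node radial
projection leaves gaps in the interface node set, and gridline-intersection
snapping needs ad-hoc conflict resolution near 45° arcs; all reported
quantities are integrated band statistics for which the staircase converges
cleanly under refinement.

**Slip interface.** Frictional contact is approximated by a linear penalty
interface: every node shared by inclusion- and background-side elements is
duplicated, and the pair is coupled by a stiff spring along the local
radial normal, k_n = 10³ μ_bg / h, plus a tangential spring
k_t = f · μ_bg / h capped at k_n, where f is the friction coefficient and h
the element size. f = 0.1 then slides almost freely, f = 1000 reproduces
the bonded response to better than 2%, and the slip-to-bonded transition
sits near f ≈ 1 (where the tangential interface stiffness crosses the
element stiffness scale μ_bg/h). This mapping keeps the model linear and
reproducible; it does not resolve stick–slip zones or enforce a Coulomb
traction bound, so friction-sweep results are trend-level. Note the
tangential stiffness *per unit interface length* scales as f·μ/h², so the
slip response depends on the mesh resolution by construction; production
resolutions are fixed below.

**Heterogeneous lesions.** Five 1.5 mm sub-inclusions, twice as stiff as
the main 10 mm inclusion, are placed by seeded rejection sampling keeping
them ≥ 1 mm apart (edge to edge) and ≥ 1 mm inside the inclusion boundary;
the seed is recorded in the phantom spec so runs are reproducible.

**Field export.** Displacements are sampled onto regular grids through the
element shape functions (element-local bilinear interpolation), which
reproduces nodal values exactly and preserves the displacement jump across
slip interfaces; strains come from shape-function derivatives at the query
point. Out-of-domain queries are masked invalid, never extrapolated.

## RF speckle simulator (`usim_rf`)

Frames are sums over point scatterers of a separable point-spread
function: a Gaussian-envelope cosine along the beam at the pulse-echo
spatial frequency 2 f_c / c, times a lateral Gaussian. Defaults: 7.5 MHz
center frequency, 40 MHz sampling, 0.2 mm beam pitch, 1540 m/s, scatterer
density 40/mm² (≥ 10 per resolution cell, i.e. fully developed speckle —
the envelope-Rayleigh test checks this), amplitudes standard normal.

The axial envelope FWHM is 0.3 mm ≈ 1.5 carrier cycles (≈ 50% fractional
bandwidth, typical of imaging arrays). This width matters: a several-cycle
narrowband burst produces RF correlation sidelobes one carrier cycle from
the true peak that rival it in height and derail correlation tracking;
0.3 mm keeps the sidelobe envelope near 0.7 of the main lobe, which the
envelope-guided peak selection (below) then handles robustly.

Deformation is applied to the *scatterers* (bicubic interpolation of the
displacement grid at each scatterer position), and the frame is re-rendered
analytically — sub-sample motion is therefore exact, with no image
resampling error. Scatterers leaving the valid grid are dropped and
counted. No attenuation, no depth-dependent beam width, no lateral phase:
the tracking operates on generic speckle and none of the tested properties
depend on these effects.

## Speckle tracking (`tracking`)

Exhaustive normalized cross-correlation block matching per grid node
(kernel 1.5 mm lateral × 1.8 mm axial ≈ one beam width × six wavelengths;
search ±1.0 mm axial, ±0.6 mm lateral by default). The integer peak is
selected within ±2 samples of the *envelope* correlation peak — the
envelope surface is unimodal where the RF surface oscillates at the
carrier — and refined per axis by the vertex of a parabola through the
three collinear correlation values, clamped to ±½ sample. Quality is the
peak correlation; nodes fail validity below `min_correlation` (default
0.5), on search borders, or with zero-variance kernels. A 5 × 5 median
consistency pass replaces isolated estimates more than one sample from the
local median (residual cycle hops). Grid defaults: 0.2 mm axially, one
beam laterally.

Multistep accumulation advects material points from the first-frame grid
through each frame-to-frame field, evaluating every step at the current
deformed position by cubic B-spline interpolation and summing; a
trajectory is invalidated when it leaves the grid or lands on an invalid
pixel of any step. For uniform motions this reduces to exact summation;
for successive compressions it reproduces the analytic composition of the
affine maps to the interpolation tolerance.

The tracker is deliberately a plain NCC matcher: its contract here is
displacement accuracy (shift equivariance, sub-sample bias < 0.05 samples,
antisymmetry), not equivalence with any particular published search
strategy. There is no GPU path; problem sizes in this package do not need
one.

## Incompressibility denoising (`denoise`)

The regularized field minimizes

F(u, v) = ∫ (∂u/∂y + ∂v/∂x)² dΩ + λ₁ ∫ (u − ũ)² dΩ + λ₂ ∫ (v − ṽ)² dΩ,

where (ũ, ṽ) is the measured field, u is axial (y axial coordinate) and v
lateral (x lateral). The first term is the squared physical divergence —
the incompressibility penalty. Defaults λ₁ = 100, λ₂ = 1: axial estimates
are trusted ~100× more, so the divergence term corrects mostly the lateral
component (which ultrasound estimates poorly). Both constants are exposed
in the config.

Discretization: central differences in the interior, one-sided at edges
(the natural boundary conditions of the variation); the normal equations
(DᵀD + diag(λw)) z = diag(λw) z̃ are symmetric positive definite and solved
directly up to 40k unknowns, by Jacobi-preconditioned conjugate gradients
(tolerance 1e-8) beyond. Invalid pixels get fidelity weight zero — the
divergence coupling inpaints them — plus a 1e-10·max(λ) diagonal tie-break
that keeps the system positive definite; the perturbation is orders of
magnitude below every tested tolerance. An 8 × 8 dense solve of the same
quadratic serves as an independent oracle in the tests.

## Strain, principal angle, NSDI (`strain_nsdi`)

Each strain component is the slope of a least-squares linear fit over a
1.8 mm moving window along the differentiation axis (Savitzky–Golay,
polynomial order 1, first derivative); border pixels with truncated
windows are masked. The principal angle is
θ_p = ½ atan2(2ε_xy, ε_xx − ε_yy), *folded to the nearest principal axis*:
when |θ_p| > π/4 the orthogonal principal direction is closer to the
lateral axis, so π/2 is subtracted with the sign of θ_p. The fold is the
reading of the method under which the stated range [0, π/4] holds
identically, and it is pinned by a brute-force eigen-decomposition oracle
in the tests. NSDI = |θ_p|/(π/4); the absolute value matches the
non-negative displayed range of the indicator.

**Lesion metrics.** The inside mask rasterizes the lesion contour; the
outside region is the equal-area band of outside pixels nearest the lesion
(selected by distance transform, ties broken deterministically), which
generalizes the hand-drawn equal-area rectangle to arbitrary lesion shapes
and matches the inside area to one pixel by construction. An error is
raised if the band would leave the image. The size ratio defaults to the
polygon-area convention (`method="length"` switches to maximum caliper
length); area was chosen because the area-ratio variant of the metric is
the better standardized of the two in the literature.

## Pipeline, parameter studies and study conditions (`pipeline`)

Synthetic runs solve the phantom, sample ground truth, and either form the
NSDI image directly (truth mode) or push the field through RF simulation,
tracking and denoising (full chain). Per-step compressions are capped at
1% by adding frames — larger inter-frame strains decorrelate the speckle.
Reports embed a config hash, the seed and the package version;
re-running a config byte-reproduces the JSON/CSV outputs.

**Strain source for the parameter sweeps.** The sweeps (compression,
modulus ratio, inclusion diameter, friction) evaluate NSDI from the FE
shape-function strains directly rather than through the 1.8 mm windowed
estimator. The inclusion problem is nearly scale-invariant — the
perturbation field around an inclusion of radius a depends on r/a — so
band statistics are almost independent of inclusion size *unless* a
fixed-width smoothing window is imposed: the window crushes the NSDI halo
of a 4 mm inclusion by several-fold and would turn a mild size effect into
a dominant artifact of the estimator. The windowed chain remains the
image-forming path (and the default for anything tracked from RF data),
selectable per call via `strain_source`.

**Sweep grids.** Case 1: compressions {0.25, 0.5, 1, 2.5, 5}%; Case 3:
modulus ratios {2, 4, 8, 12, 16, 20}; Case 4: diameters {4, 6, 8, 10, 12}
mm; Case 5: friction coefficients {0.1, 1, 10, 100, 1000}; cases 1/3/4 run
bonded and slipping (f = 0.1) interfaces. Lesion contours for the ROI
statistics are the known inclusion boundaries (64-vertex polygons).

**Resolutions.** Default phantom mesh 0.25 mm (≥ 6 elements across a
1.5 mm sub-inclusion). The sweeps use per-case production resolutions from
a refinement study — 0.25 mm (Case 1, whose statistics are
resolution-exact by linearity), 0.2 mm (Case 3), 0.15 mm (Case 4, smallest
inclusion 4 mm), 0.08 mm (Case 5) — with a 0.1 mm sampling grid (the
equal-area band of a 4 mm inclusion is under 1 mm wide). Case 5 needs the
finest mesh because the penalty interface layer is otherwise
under-resolved, which inflates the apparent friction sensitivity of the
band mean severalfold.

**What the sweeps show.** Because the model is linear, displacement scales
exactly with load, θ_p is invariant under uniform scaling of the strain
tensor, and the Case 1 statistics are constant across compression to
machine precision — the compression-stability result is a structural
property of the linear model, not a numerical coincidence. Case 3's
outside-band mean rises monotonically with the modulus ratio; Case 4's
varies by ~9–12% over 4–12 mm diameters; Case 5's by ~7% over the friction
sweep at the production resolution.

## What the synthetic data does and does not establish

The generator reproduces the features the method actually exploits: fully
developed speckle statistics, exact sub-sample motion, anisotropic
displacement quality (lateral ≫ axial error), interface shear
concentrations, near-incompressibility. It omits nonlinear and
viscoelastic tissue behavior, true Coulomb contact, attenuation and
beam-profile depth dependence, 3D motion, and operator-dependent lesion
segmentation. Passing tests therefore demonstrate correctness of the
computational chain and the mechanics-level behavior of the indicator on
idealized phantoms — not clinical performance, which requires in vivo data
outside the scope of this package.

## Known limitations

- The slip interface is a linear spring approximation; its tangential
  stiffness is mesh-dependent by construction and friction-sweep results
  are meaningful only at the stated resolutions.
- Lateral displacement quality after denoising remains far below axial
  quality (lateral strain RMSE ~10× axial in the end-to-end run); NSDI
  images from tracked RF data are correspondingly noisy.
- The half-angle estimator is undefined for exactly isotropic strain;
  such pixels return 0 by convention.
- Plane strain is assumed throughout; out-of-plane motion is not modeled
  and the indicator would need a 3D reformulation for volumetric data.
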