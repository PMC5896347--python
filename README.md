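# nsdielast

Quasi-static ultrasound strain elastography post-processing built around the
**normalized shear deformation indicator (NSDI)** — a dimensionless,
rotation-free measure of local shear deformation used to characterize breast
lesions: malignant masses tend to be stiffer, more heterogeneous and more
firmly bonded to their surroundings than benign ones, and all three traits
leave a shear signature around the lesion boundary.

## The indicator

Under a small quasi-static compression the 2D strain tensor has lateral
normal strain ε<sub>xx</sub>, axial normal strain ε<sub>yy</sub> and shear
strain ε<sub>xy</sub> = ½(∂u/∂x + ∂v/∂y) (u axial displacement, v lateral,
x lateral coordinate, y axial). The principal angle

θ<sub>p</sub> = ½ · atan2(2ε<sub>xy</sub>, ε<sub>xx</sub> − ε<sub>yy</sub>),

folded to the principal axis nearest the lateral direction (subtract ±π/2
when |θ<sub>p</sub>| > π/4), measures how far the principal strain
directions are rotated away from the imaging axes: 0 with no shear, π/4
under pure shear. Normalizing gives

NSDI = |θ<sub>p</sub>| / (π/4) ∈ [0, 1].

Because ε<sub>xy</sub> is the symmetric part of the displacement gradient,
rigid-body rotation cancels exactly — unlike the axial-shear strain
(∂u/∂x alone) used by earlier shear elastography methods.

Computing NSDI needs *both* displacement components at useful quality. The
pipeline therefore chains:

1. **tracking** — normalized-cross-correlation block matching of RF frames
   (1.5 mm × 1.8 mm kernels), envelope-guided peak selection, parabolic
   sub-sample refinement, and B-spline accumulation of frame-to-frame
   fields into the first frame's coordinates;
2. **denoise** — variational regularization that penalizes the divergence
   of the displacement field (soft tissue is nearly incompressible) with
   per-component fidelity weights λ₁ (axial) ≫ λ₂ (lateral), solved via
   its linear Euler–Lagrange system;
3. **strain_nsdi** — Savitzky–Golay strain estimation over 1.8 mm windows,
   the principal angle, the NSDI image, and lesion metrics (mean NSDI
   inside the lesion and in an equal-area band outside it; elastogram /
   B-mode size ratio).

For validation without any external data the package also provides:

- **phantom_fem** — a plane-strain finite-element solver (4-node quads,
  selective reduced integration at ν = 0.495) for circular-inclusion
  phantoms with bonded or slipping (penalty-spring) interfaces and optional
  stiff sub-inclusions;
- **usim_rf** — a convolution-model RF speckle simulator that renders
  pre/post-deformation frames from scatterer fields warped by the FE
  ground truth.

## Worked example

Solve a 40 × 40 mm phantom with a centered 10 mm inclusion four times
stiffer than the background under 1% compression, form the NSDI image from
the ground-truth displacement field, and report mean NSDI inside the
inclusion and in the equal-area outside band:

```yaml
# case1.yaml
schema_version: 1
skip_tracking: true
truth_grid_spacing_mm: 0.2
phantom:
  modulus_ratio: 4.0
  inclusion_diameter_mm: 10.0
  applied_compression: 0.01
  mesh_resolution_mm: 0.25
```

```console
$ nsdi run -c case1.yaml --out run1
{
  "case_id": null,
  "parameter": null,
  "provenance": {
    "config_hash": "cd4c543e289c3098",
    "seed": 0,
    "version": "0.1.0"
  },
  "records": [
    {
      "inside_mean": 0.018874776756883878,
      "outside_mean": 0.04786988737877374
    }
  ]
}
```

The outside mean (0.048) is well above the inside mean (0.019): for a
bonded stiff inclusion the shear concentration spreads *outward* from the
interface while the inclusion interior deforms almost uniformly. Re-running
with `interface: slip` and `friction_coefficient: 0.1` raises the inside
mean several-fold — a loosely coupled lesion shears along its boundary and
the elevated NSDI spreads inward as well. `run1/` holds the HDF5 container
with all intermediate fields, `nsdi.png` / `nsdi.csv` and the JSON report.

Other entry points: `nsdi sweep --case 3` runs the modulus-ratio parameter
study (cases 1, 3, 4, 5 sweep compression, modulus ratio, inclusion
diameter and interface friction); `nsdi phantom -c spec.yaml -o truth.h5`
exports ground-truth fields; the library functions
(`nsdielast.pipeline.end_to_end_recovery` among them) drive the full
FE → RF → tracking → denoise → NSDI chain.

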