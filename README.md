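# dvfcompare

Voxel-by-voxel quality assurance for deformable image registration (DIR).

Validating a DIR algorithm against ground truth requires expert-placed
landmarks or segmentations and so is limited to a handful of image pairs.
`dvfcompare` implements the complementary, fully automated approach:
compare the dense displacement vector fields (DVFs) that two or more
algorithms produce on the *same* anatomy, voxel by voxel. If two
algorithms agree, they are interchangeable for the application at hand
(though both could still be wrong); if they disagree strongly, at least
one of them deviates from the truth. The method scales to long series of
clinical-quality image pairs — for example the peak-exhale/peak-inhale
phases of 4DCT lung studies — with only one segmented image per series.

It is intended for medical-physics and image-registration researchers who
need to screen DIR output for physically impossible behavior, quantify
inter-algorithm discrepancy before trusting dose accumulation, or check
contour propagation.

## What it computes

For a transformation `x -> x + u(x)` given by a DVF `u` on a regular
voxel grid:

- **Jacobian-determinant map** `J(x) = det(I + ∇u)`, the local
  volume-change factor (`J > 1` expansion, `J < 1` contraction, `J < 0`
  physically impossible folding). Derivatives use spacing-normalized
  central differences over the immediate one-voxel neighborhood; the
  boundary shell, where no central difference exists, is set to unity.
  The determinant is kept signed so folding remains visible.
- **Jacobian volume histograms (JVH)** over contoured structures, with
  volume-weighted mean and standard deviation. Under the flow-of-tissue
  interpretation the mean is the structure's total volume-change factor,
  `V_after / V_before = (1/V) Σᵢ vᵢ Jᵢ`.
- **Tail boundaries** `J_X`: the minimum Jacobian inside the top-`X`%
  sub-volume (high tail) or the maximum inside the bottom-`X`% (low
  tail), computed from exact weighted order statistics — plus the
  factor-of-two physicality screen (`J < 0.5` or `J > 2` is not credible
  tissue behavior) and folded-fraction counts.
- **Spatial discrepancy (SD) maps** `|u_A(x) − u_B(x)|` between two
  algorithms' DVFs, in cm — the distance between their dose lookup
  points — and **SD volume histograms (SDVH)** with boundary series
  `(SD)_X` for `X` = 2.5 … 35 %.
- **DICE contour-propagation checks**: `DICE = 2|A∩B| / (|A|+|B|)`
  between structure masks before and after warping through the DVF
  (nearest-neighbor pull-back resampling).
- **Cohort summaries**: per-patient records aggregated to
  mean ± SD / min / max across patients, with two-tailed paired Student
  t-tests. Discrepancy-posture tests claim a difference when
  `p < 0.05`; agreement-posture tests claim agreement when `p > 0.05`.

A synthetic-data module generates analytic deformations (affine, axial
sinusoid, radial folding bumps) with closed-form Jacobians, phantom
sphere structures, and multi-patient cohorts, so every statistic can be
checked against exact ground truth.

## Worked example

```python
import numpy as np
from dvfcompare import (
    GridGeometry, make_axial_sinusoid_field, make_sphere_mask,
    jacobian_map, sample_structure, weighted_mean, weighted_std,
    tail_boundary, sd_map, DisplacementField,
)

# diaphragm-like compression wave: u_z = a sin(k z), Jacobian 1 + a k cos(k z)
geom = GridGeometry(dims=(64, 64, 48), spacing=(1.5, 1.5, 2.5))
field, deform = make_axial_sinusoid_field(a=5.0, k=0.05, axis="z", geom=geom)

lung = make_sphere_mask(center=(48.0, 48.0, 60.0), radius=25.0, geom=geom, label="lung")
samples = sample_structure(jacobian_map(field), lung)
print(f"JVH mean : {weighted_mean(samples):.4f}")
print(f"JVH std  : {weighted_std(samples):.4f}")
print(f"J_2.5 low / high: {tail_boundary(samples, 2.5, 'low').value:.4f}"
      f" / {tail_boundary(samples, 2.5, 'high').value:.4f}")
print(f"truth mean over lung: {deform.truth_jacobian(geom).values[lung.occupancy].mean():.4f}")

# second "algorithm" offset by a constant 3 mm vector -> 0.3 cm discrepancy
other = DisplacementField(geom, field.vectors + np.array([2.0, 1.0, 2.0]))
sds = sample_structure(sd_map(field, other), lung)
print(f"(SD)_2.5 = {tail_boundary(sds, 2.5, 'high').value:.4f} cm")
```

Output:

```
JVH mean : 0.7892
JVH std  : 0.0412
J_2.5 low / high: 0.7507 / 0.8962
truth mean over lung: 0.7887
(SD)_2.5 = 0.3000 cm
```

The phantom "lung" sits where the compression wave contracts tissue: the
mean Jacobian 0.789 says the structure loses ~21 % of its volume, and it
matches the closed-form value 0.7887 to 0.06 %. The 2.5 % tail
boundaries bracket the local volume change; the SD boundary reports the
injected 3 mm inter-algorithm offset exactly, in cm.

## Command line

```bash
dvfcompare synth synth.yaml -o cohort/           # write a synthetic cohort
dvfcompare jacobian field.mha -o jac.mha         # Jacobian map
dvfcompare sdmap fieldA.mha fieldB.mha -o sd.mha # discrepancy map (cm)
dvfcompare dice maskA.mha maskB.mha              # overlap coefficient
dvfcompare warp-mask mask.mha field.mha -o warped.mha
dvfcompare jvh field.mha mask.mha -o lung_jvh    # CSV histogram + JSON stats
dvfcompare sdvh fieldA.mha fieldB.mha mask.mha -o lung_sdvh
dvfcompare analyze --config cohort.yaml -o report/
```

Fields and masks are accepted as NIfTI (`.nii`/`.nii.gz`) or MetaImage
(`.mhd`/`.mha`); vector fields carry 3 components in mm with (x, y, z)
component order matching (column, row, slice). Contours are accepted as
a JSON list of `{"slice": int, "vertices": [[x, y], ...]}` records in mm.

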