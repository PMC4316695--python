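# Methods

## Model

A deformable image registration of a moving image onto a target image is
represented by a dense displacement vector field (DVF) `u` on the target
grid: the transformation is `T(x) = x + u(x)`, with `x` a voxel-center
world coordinate in mm. All analysis is voxel-wise on one shared
axis-aligned lattice; grids with oblique direction cosines are rejected
at the I/O layer because every downstream subtraction and lookup
presumes lattice-aligned world axes. Displacements are stored and
processed in mm with component order (x, y, z) matching array axes
(column, row, slice).

### Jacobian determinant

The local volume-change factor is the determinant of the transformation
gradient, `J(x) = det(I + ∇u)`. The displacement gradient is estimated
from the immediate one-voxel neighborhood by central differences,

    G[c, d] = (u_c(i + e_d) − u_c(i − e_d)) / (2 s_d),

divided per axis by the voxel spacing `s_d`, so anisotropic grids are
first-class. Central differences were chosen over one-sided ones for
second-order accuracy and symmetry; they are exact on affine fields,
which is what the analytic recovery tests exploit. On the one-voxel
boundary shell, where no central difference exists, `J` is set to
exactly 1 (identity). The determinant is kept **signed**: negative
values are the diagnostic of physically impossible folding, and taking
`|J|` would destroy that signal. Reports carry the signed mean and the
negative-value fraction separately.

Two screens quantify non-physical behavior: the folded fraction
(`J < 0`) and the factor-of-two screen (`J < 0.5` or `J > 2`), on the
premise that a genuine local tissue volume change beyond a factor of two
is not credible between breathing phases.

### Spatial discrepancy

For two DVFs `u_A`, `u_B` of the same anatomy, the spatial discrepancy
is the pointwise Euclidean norm `SD(x) = |u_A(x) − u_B(x)|`, reported in
cm (internal storage stays mm) because inter-algorithm differences of
clinical interest are on the centimeter scale. SD is the distance
between the two algorithms' dose lookup points, hence a bound-relevant
quantity for deformable dose accumulation.

### Volume histograms and tail boundaries

A structure is a binary mask on the target grid. Projecting a scalar map
onto a structure yields volume-weighted samples: one `(value, weight)`
pair per set voxel, the value read by trilinear interpolation at the
voxel center (an exact lookup when map and mask share the grid, as they
always do here) and the weight equal to the full voxel volume
`v_i = s_x s_y s_z`. The alternative reading — fractional sub-voxel
weights from partial mask coverage — differs only at structure
boundaries on matched grids; the full-voxel convention was chosen for
exactness and is stated here because it is a genuine free choice.

From the samples:

- weighted mean `(Σ v_i x_i) / (Σ v_i)`; over a Jacobian map this is the
  structure's total volume-change factor `V_after / V_before`;
- weighted **population** standard deviation (the n−1 correction is
  negligible at the >10⁴ voxels of any real structure, and the
  population form keeps small-fixture tests exact);
- tail boundaries `J_X` / `(SD)_X`: sort samples (descending for the
  high tail), accumulate weight until it first reaches ≥ X% of the total
  volume; the boundary is the value of that last included sample — the
  minimum value in the top-X% sub-volume (mirrored for the low tail).
  Boundaries are computed from exact weighted order statistics, not from
  binned histograms, so they carry no binning parameter; the tie rule is
  "first sample whose inclusion reaches the target volume", with no
  interpolation between sample values. Histograms (default 200 bins)
  exist only for reports and plots.

The default `(SD)_X` series is X ∈ {2.5, 5, 10, 15, 20, 25, 30, 35} %.

### Contours, warping, DICE

Per-slice closed polygons are rasterized by the even-odd rule on voxel
centers, with half-open edge handling (left/bottom edges inclusive) so
adjacent polygons tile without double counting; the test is
orientation-free. Mask propagation through a DVF uses **pull-back**
resampling — output voxel at `x` reads the source mask at `x + u(x)`
with nearest-neighbor interpolation — the standard resampling
convention, documented prominently because push-forward would negate the
displacement sign. Lookups outside the grid read background 0, so
structures leaving the field of view vanish rather than clamp. DICE is
plain voxel counting, `2|A∩B| / (|A|+|B|)`.

### Cohort statistics

Per-patient records aggregate to mean ± SD / min / max / n cells;
patients missing a structure reduce that cell's n rather than aborting.
Declared comparisons run a two-tailed paired Student t-test across
patients. Two degenerate cases are resolved explicitly: identically zero
differences give p = 1 (perfect agreement), constant nonzero differences
give p = 0. Two testing postures are supported: *discrepancy* claims a
difference when p < α, *agreement* claims agreement when p > α
(α = 0.05, strict inequalities). The agreement flag reproduces a common
screening procedure; absence of a significant difference is not evidence
of equivalence, and the flag should be read as "no detectable
disagreement at this sample size".

Whether such paired tests should be one- or two-tailed is a genuine
choice; two-tailed was adopted throughout as the conservative default.

## Synthetic data

The generator emulates exhale→inhale lung-like deformation at desk
scale; it produces fields and masks only (never CT intensities, which no
statistic here consumes). Components:

- **affine** `u = A(x − x_c) + t`, Jacobian `det(I + A)` everywhere —
  overall inflation/deflation plus drift;
- **axial sinusoid** `u_axis = a sin(k x_axis)`, Jacobian
  `1 + a k cos(k x_axis)` — nonuniform diaphragm-like compression;
  `|a k| < 1` is enforced so the component alone cannot fold;
- **radial fold bump** `u = −s (x − c) (1 − ρ²)²` for `ρ = |x − c|/R < 1`,
  zero outside: C¹, compactly supported, with center Jacobian
  `(1 − s)³ < 0` for strength `s > 1` — an injectable registration
  defect.

Cohort cases combine a random mild affine (diagonal entries ±0.10,
off-diagonal ±0.02, translations ±3 mm) with 1–3 low-frequency sinusoids
(`a·k` in 0.05–0.25, wavelengths 0.6–1.5 grid extents); the second
algorithm's field adds a band-limited perturbation (sum of ≤ 8
low-frequency sine products) rescaled to an exact peak magnitude — the
`discrepancy` parameter in mm. These levels give per-structure Jacobian
spreads and sub-centimeter to centimeter discrepancies comparable to
what clinical inter-algorithm comparisons report, while keeping all
fields smooth enough for the analytic truth to be meaningful. All
gradients stay analytic, so each case carries exact truth: the pointwise
closed-form Jacobian, the per-structure true volume ratio, and the exact
SD map. The true volume ratio is defined as the mask-mean of the
closed-form Jacobian at voxel centers — the voxel-resolution
discretization of the volume integral — so the 3 % recovery tolerance in
the tests measures only the finite-difference stencil error, not
voxelization of the continuum integral.

Seeding: one master integer seed; patient `p` draws from
`np.random.default_rng([seed, p])`, so cohorts are pure functions of
`(n_patients, seed, discrepancy)` and any patient can be regenerated
independently.

Default grid: 64×64×48 voxels at 1.5×1.5×2.5 mm — anisotropic on
purpose so spacing-normalization bugs cannot cancel; large enough that
phantom structures contain ~10³–10⁴ voxels, small enough that a
13-patient two-algorithm cohort analyzes in seconds. Phantom structures
are voxelized spheres (a large "lung" and a small "gtv"), which have the
right topology for overlap/histogram machinery but none of the sharp
concavities, thin walls, or sliding interfaces of real anatomy.

## What the synthetic validation does and does not show

Passing tests establish that the machinery is correct: derivatives,
weighted order statistics, resampling conventions, and cohort arithmetic
reproduce closed-form truths to their stated tolerances. They do not
certify any real registration algorithm, emulate CT image noise or
artifact-driven DVF errors, or reproduce the clinical magnitudes of any
published cohort — real DVFs are not band-limited analytic fields, and
real organs are not spheres.

## Numerical choices and limitations

- Grid-equality tolerance 1e-3 mm per component (float header
  round-off); dims must match exactly.
- Mask binarization threshold 0.5 for float-stored masks.
- Volumes are written as float64, so round trips are bit-exact in both
  supported formats (NIfTI via nibabel, MetaImage via SimpleITK).
- The Jacobian needs ≥ 3 voxels per axis (an interior must exist).
- Tail boundaries use a relative volume tolerance of 1e-12 when testing
  whether cumulative weight has reached the target, guarding against
  accumulation round-off at exact-hit targets.
- Out of scope: DICOM/RT-STRUCT parsing, resampling between mismatched
  grids, oblique grids, 4-D time-series fields, surface-distance
  metrics, inverse-consistency errors, multiple-testing correction, and
  dose-gradient convolution.
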