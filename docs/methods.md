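# Methods

## Problem and model

Perfusion SPECT of the lung (^99m^Tc-MAA) is acquired over minutes of free
breathing, while the chest CT it is fused with is acquired in a deep-
inspiration breath hold. Averaged over the breathing cycle the diaphragm
sits higher than on the CT, so the caudal lung on SPECT appears compressed
and displaced cranially, and SPECT-derived lung volumes underestimate the
CT volume. `breathsync` corrects this with a deliberately minimal
one-dimensional deformation, estimated without any extra acquisition: only
the four planar images (anterior/posterior at deep intake and at free
breathing) that can be added to a routine protocol.

The deformation has two parameters: a baseline row `X` on the
superior→inferior axis, above which nothing moves, and a magnification
`Y > 0` applied to everything below it,

    r' = X + (r − X)·Y      for r ≥ X,      r' = r      for r < X.

`(X, Y)` is estimated in 2-D and applied in 3-D:

1. **Conjugate-view summation.** Per breathing phase, the posterior planar
   is mirrored left–right into the anterior frame and the two views are
   summed pixelwise (arithmetic sum by default; a geometric-mean mode
   exists for comparison). Counts are conserved exactly.
2. **Rigid alignment.** The SPECT coronal reference is the full
   anterior→posterior sum projection of the volume — a projection, not a
   single slice, because that is what a planar acquisition measures. The
   summed deep-intake planar is resampled to the reference grid (spacing
   and matrix first, a pure scaling resample about the image centre) and
   then rigidly aligned (tx, ty, θ) by minimising mean squared error
   between images normalised to unit total counts; normalisation is needed
   because planar and projected-SPECT count scales differ by acquisition
   duration. Optimisation is a coarse multi-start over integer translations
   (default ±8 px grid) followed by Powell refinement; linear
   interpolation, zero fill outside. The free-breathing planar is resampled
   and moved with the *same* transform, so the pair stays mutually
   registered.
3. **Parameter search.** The free-breathing image D is scaled with
   candidate `(X, Y)` and compared against the deep-intake image C with
   normalised mutual information, NMI = (H(A)+H(B))/H(A,B), computed from a
   joint histogram with 64 equal-width bins per image spanning each image's
   own min–max (range [1, 2]; 2 iff bin-level bijection). The search is an
   exhaustive grid: integer `X` over a caudal band (default rows 30–100 of
   128) × `Y` in [0.8, 1.6] step 0.01. A bounded 2-D grid is cheap
   (~5800 evaluations, seconds), fully reproducible, and immune to the
   local maxima that defeat gradient methods on NMI surfaces. Exact ties
   are broken toward the least deformation: smallest |Y − 1|, then smallest
   X.
4. **Volume deformation.** The winning 1-D row remap is applied identically
   to every (depth, column) line of the SPECT volume, with linear
   interpolation and zero fill. Intensities are interpolated, **not**
   Jacobian-rescaled: the end use is spatial conformity and thresholded
   volume, which count-conservation rescaling would distort. Consequence:
   a stretched impulse carries Y× its input mass — this is intentional and
   tested. `Y = 1` is a bitwise no-op, and because the remap is linear and
   the coronal projection is a sum, deformation and projection commute to
   floating-point accuracy.

## Volumetry

The lung edge on perfusion SPECT is operational, not anatomical: voxels
with counts ≥ a cutoff fraction of the volume's maximum count are lung
(inclusive threshold — the histogram sum runs from the edge count to the
maximum; e.g. a 490-count maximum puts the 10% edge at 49 counts). Lung
volume = supra-threshold voxel count × voxel volume, and is exactly
accounted (volume/voxel-volume is an integer) and non-increasing in the
cutoff. The cutoff is swept over {5, 10, 15, 20}% rather than hard-coded:
the best level depends on reconstruction blur. The maximum is the single
maximum voxel by default; a 99.9th-percentile robust maximum and a
largest-components cleanup are available behind flags but off by default,
matching a pure histogram sum.

The CT lung volume is a simple surrogate for a commercial workstation
segmentation: HU in [−1000, −200] inside the body mask (body = HU > −500,
holes filled), two largest connected components. It is adequate for
phantom CTs with clean HU plateaus and makes no claim of equivalence on
clinical images.

## Synthetic phantoms

Each phantom is one anatomy in two breathing states on a 128³ grid at
4.42 mm isotropic spacing (typical for a 128×128 SPECT matrix):

* **Lungs**: two ellipsoids, default semi-axes (125, 75, 48) mm, i.e.
  ~3.77 L together at deep inspiration — an adult-sized deep-breath lung
  pair. Tracer uptake follows a parabolic profile (1 − r²) falling to zero
  at the pleural surface: perfusion peaks centrally, and this is what
  makes percent-of-maximum thresholds cut at (not outside) the blurred
  edge, reproducing the clinical underestimation of SPECT volumetry.
  A uniform-activity mode exists for geometry tests.
* **Breathing states**: the free-breathing volume is the deep-intake
  activity with rows below the true baseline `X*` compressed by `1/Y*` —
  the exact inverse of the correction model, so recovery is well-posed.
  Deformation is applied to the sharp activity *before* blurring, as in
  reality (anatomy deforms, then the imaging system blurs).
* **Imaging**: isotropic Gaussian blur of σ = 6 mm as a point-spread
  surrogate (≈14 mm FWHM, typical reconstructed SPECT resolution); planars
  are anterior→posterior sum projections (posterior mirrored), scaled to
  ~500 peak counts per view; optional independent Poisson noise per
  acquisition. A single seed drives all randomness through deterministic
  sub-seeds.
* **CT**: same deep-intake anatomy with −800 HU lungs inside a 0 HU
  elliptic-cylinder thorax surrounded by −1000 HU air.
* **Truth**: lung volumes are analytic — full ellipsoid volume at deep
  intake; for free breathing the ellipsoid-cap integral below the baseline
  plane divided by `Y*` plus the untouched part above it.
* A model-mismatch mode adds a lateral drift to the free state to separate
  correctness testing from robustness testing.

What the phantoms do **not** emulate: attenuation, scatter, reconstruction
artefacts, perfusion defects, cardiac motion, hysteresis of the breathing
cycle, or lateral/anterior–posterior components of diaphragm motion.
Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the model's own assumptions, not clinical
accuracy.

## Validation studies and their constructions

Parameter recovery is run in four constructions of increasing realism
(`breathsync.evaluation.recovery_study`):

* **matched** — the moving image is the phantom's summed free-breathing
  planar (Poisson-noised per acquisition if requested) and the reference is
  built by scaling that observed image with the true parameters. The model
  holds exactly on the data, so estimation error is attributable to the
  grid search alone. Noiseless truths on the grid are recovered exactly;
  with ~500-count acquisitions, recovery stays within ±2 rows / ±0.05.
* **independent** — reference and moving images carry independent Poisson
  realizations. This is the physical acquisition model, and it exposes an
  intrinsic information limit: moving `X` by one row displaces content by
  only (Y − 1) voxels, so near Y = 1 the baseline is not identifiable at
  realistic noise (at Y = 1.05, ±2 rows ↔ ±0.1 voxel ≈ 0.4 mm). Joint
  (X, Y) errors then slide along the ridge Y·r + X(1−Y) = const, helped
  along by a second mechanism: scaling interpolates, interpolation smooths
  noise, and NMI with per-image min–max binning mildly rewards smoothing.
  Y itself stays well-estimated; X scatters. This is a property of the
  two-parameter model at planar count levels, not of this implementation.
* **pipeline** — deep and free phantom planars compared directly
  (different anatomies, blur applied after deformation).
* **end_to_end** — the full four-step pipeline. Rigid MSE alignment of a
  deep-inspiration planar to a free-breathing SPECT reference returns a
  small systematic axial shift (a compromise between mismatched breathing
  states, up to ~3 rows at Y* = 1.3); the shift relabels rows, so the
  baseline truth in the aligned frame is X* plus that shift, and recovery
  is scored against it (`aligned_true_X`). The magnification Y is
  frame-invariant and unaffected.

The cohort analogue (`phantom_cohort`, default 20 cases) varies lung size
per case by a semi-axis factor in [0.9, 1.1] (≈ ±30% in volume, comparable
to between-patient spread), draws Y* from {1.05, 1.1, 1.2, 1.3}
(representative diaphragm excursions) and X* from rows 35–70, runs the
full pipeline with Poisson noise, and measures CT, free-breathing SPECT,
and synchronized SPECT volumes over the cutoff sweep. The reproduced
direction: free-breathing SPECT at the 10% cutoff underestimates the true
deep volume (≈ −19%), synchronization recovers roughly a third to a half
of the deficit, and the 5% → 20% sweep brackets the truth from above and
below.

## Statistics

`compare_to_ct` runs Dunnett's many-to-one comparison of every SPECT
method against the CT reference (scipy's implementation). The clinical
design applies Dunnett's test across methods measured on the *same*
patients — i.e., it treats paired columns as independent groups. The
package implements the test as designed rather than silently switching to
a paired procedure, and additionally reports unadjusted paired mean
differences per method so the pairing is visible. Under a simulated null
(every method = reference + iid noise) the family-wise type-I error sits
at the nominal α = 0.05 within Monte-Carlo tolerance (checked over 1000
scaled-down cohorts of 12 cases).

## Numerical choices and degenerate inputs

* NMI raises on constant images (degenerate joint entropy) instead of
  returning 0/0; during the grid search, candidate scalings that produce a
  constant image are skipped, and the search errors only if every grid
  point is degenerate.
* Grid Y values are rounded to 10 decimals so that nominal steps (1.20)
  are representable and comparisons against truth are exact.
* The registration cost accepts the Powell result only if it does not
  worsen the best multi-start cost; θ is normalised to (−180°, 180°].
* Rows remapped from outside the image are zero-filled; content mapped
  past the caudal edge is cropped.
* All algorithm stages are deterministic; randomness exists only in
  phantom generation and is fully seed-driven.
* Problem sizes in the shipped studies (50-case recovery suites, 20-case
  cohort, 1000 null cohorts) were chosen to give stable rates at
  interactive runtimes on a single CPU.

## Known limitations

* The deformation is 1-D; real diaphragm motion has lateral and
  anterior–posterior components and is nonrigid.
* The baseline X is weakly identified near Y = 1 under acquisition noise
  (see above); reported X estimates should be read jointly with Y.
* The CT segmentation surrogate is not a clinical tool.
* Phantom validation shares the model between generator and estimator
  (by design, for well-posedness); the model-mismatch drift mode only
  begins to probe violations.
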