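# Methods

`ventprofile` reconstructs regional lung ventilation from thoracic
electrical impedance tomography (EIT) voltage recordings and quantifies how
much the anatomical content of the reconstruction model — circular (M1),
population-averaged (M2) or individualized (M3) thorax priors, optionally
with lung-pixel masks (M2+, M3+) — changes the accuracy of anteroposterior
ventilation profiles.  Because no public recordings accompany this problem,
a synthetic thorax-phantom simulator stands in for the animal data; every
empirical statement below is produced by the package's own tests or by
`scripts/acceptance.py`.

## Forward model

The forward problem uses the complete electrode model (CEM) on 2.5D
finite-element meshes: the 2D cross-section (thorax, lungs, heart as simple
polygons) is triangulated by a Delaunay triangulation of contour-sampled
boundary nodes plus a hexagonal interior lattice, then extruded symmetrically
about the electrode plane into three slabs of tetrahedra (eight per prism,
around the prism centroid; quad faces split by a smallest-node-index rule so
adjacent prisms tile conformingly).  Meshing is deterministic for identical
inputs.  The default extrusion height is one thorax effective radius, with
electrodes as rectangular mid-plane patches of one tenth that height — the
standard symmetric-slab choice for 2.5D EIT.

* Elements: linear (P1) tetrahedra; per-element relative conductivity.
* Electrodes: 32, equally spaced by arc length, electrode 0 on the anterior
  midline, numbered clockwise viewed from cranial; contact impedance 0.05
  model units per electrode (configurable; difference imaging is insensitive
  to it).
* Grounding: the sum of electrode potentials is constrained to zero through
  a Lagrange multiplier; no measurable voltage depends on this choice.
* Stimulation: skip-4 pattern at 3 mA — drive k injects between electrodes
  k and k+5, measurements use the same pairs; of the 32 x 32 = 1024
  channels, the 96 that share an electrode with their drive are invalid and
  carried as NaN with a validity mask (928 valid channels).  The 195 kHz
  carrier of the hardware this emulates is metadata; the solver is real
  valued.
* Sensitivities: adjoint method.  With the skip-4 pattern the measurement
  fields coincide with the drive fields, so 32 forward solutions give the
  whole Jacobian.  Reciprocity holds to solver precision and Jacobian
  columns match central finite differences to better than 1e-3 (asserted in
  the test suite).

Image grids are 32 x 32 over the tight bounding box of the thorax contour,
row 0 anterior, column 0 the animal's right.  Element-to-pixel projection is
an area-weighted average: vertical columns are sampled at 4 x 4 subpixels per
pixel, elements contribute within their column by volume, and pixels outside
the body mask are zero.

## Reconstruction

Both algorithms produce a linear map R from valid-channel difference
voltages to 32 x 32 images.  Difference voltages are either time differences
(TD, v - v(t_r)) or normalized time differences (NTD, v/v(t_r) - 1); for
NTD the sensitivity matrix is row-normalized by the model's baseline
voltages.

**GREIT.**  Training targets are small conductivity-decrease balls (radius
`ts` x effective radius) centered on every in-body pixel center; the desired
image of a target is a disc of radius `rw` x effective radius (value 1, with
a one-pixel anti-aliasing band, clipped to the body mask).  Ball membership
of mesh elements is fractional (a transition band of one element diameter),
which removes the mesh-quantization noise a hard indicator would inject into
the signatures at desk-scale mesh resolutions.  The matrix solves the
weighted least-squares problem

    R = X W Y^T (Y W Y^T + lambda * Sigma_n)^(-1),   W = diag(1/||y_k||^2),

with identity channel-noise covariance Sigma_n.  The per-sample weights give
every training target equal influence; without them the high-sensitivity
boundary targets dominate (signature norms span two orders of magnitude) and
the achievable noise-figure range collapses.  With unit-norm signatures the
eigenvalues of Y W Y^T are O(1), so lambda is dimensionless.

**One-step Gauss-Newton.**  R = -Pi (J^T J + lambda^2 s P)^(-1) J^T, with
Pi the element-to-pixel projector, P the identity (Tikhonov), the squared
element-adjacency graph Laplacian (Laplace) or diag(J^T J) (NOSER), and
s the mean eigenvalue of J P^(-1) J^T so that lambda is again dimensionless.
The system is evaluated through the Woodbury identity and an
eigendecomposition of the 928 x 928 operator, which makes scanning lambda
cheap.  The global minus sign fixes the convention that ventilation
(inflation lowers lung conductivity) appears positive; GREIT reaches the
same convention by training with contrast -1 targets against positive discs.

**Noise figure.**  The regularization level is always selected by matching a
noise figure

    nf = [ mean|R n| / mean|R y_c| ] / [ mean|n| / mean|y_c| ],

with n i.i.d. unit-variance channel noise (evaluated in closed form from row
norms, not by sampling), y_c the signature of a small central target, image
means over in-body pixels and channel means over valid channels.  nf
decreases monotonically with lambda; calibration bisects log-lambda on
[1e-8, 1e4] until the achieved nf is within 1% of the requested value.
Absolute nf values are convention dependent — a published nf from another
implementation does not transfer numerically, only qualitatively (smaller nf
means stronger smoothing here, since noise amplification shrinks with
regularization).  The Tikhonov prior cannot reach very low noise figures
(its smoothing floor in this convention is around 0.14 on the circular
model); the study pipeline uses GREIT and the Laplace prior, which reach the
whole 0.1–0.5 range.

## Post-processing

Reconstruction of a recording: a provisional reference at frame 0 is used to
detect breath phases on the mean in-body signal (moving average of 0.5 s,
peak separation at least 0.6 nominal breath periods); the series is then
re-referenced at the first detected end-expiration — the conventional EIT
baseline — and reconstructed again.  Tidal images average Z(t_in) - Z(t_ex)
over all complete breaths (each end-inspiration paired with the nearest
following end-expiration; trailing incomplete breaths dropped).  Variants
without anatomical post-processing (vd1, vd2, vd3) zero pixels below 10% of
the image maximum before profiling over the body mask; the masked variants
(vd2+, vd3+) instead keep only the model's own lung-mask pixels, without
thresholding.  Profiles sum masked pixel values in 32 equal horizontal bands
(anterior first) and normalize to 100%.

## Synthetic data

The phantom generator produces three geometry kinds, all area-normalized so
lengths are in units of the thorax effective radius:

* **circular** — the unit disk, no organs (the no-prior analog);
* **averaged** — a fixed smooth pig-like fixture: a thorax deeper than wide
  with a ventral taper, two bean-shaped lungs that are broadest dorsally and
  together cover about a third of the cross-section, and an
  anterior-central heart, matching the gross anatomy of porcine mid-thorax
  CT sections.  It is a synthetic stand-in, not a published shape library;
* **individual** — the averaged fixture warped by a seeded smooth radial
  perturbation (harmonics 2–5, amplitude set so the relative symmetric
  difference Delta-S against the averaged thorax falls in a 3–8% band,
  the scale of inter-animal contour variability this emulates; organs are
  warped consistently; draws violating containment or the band are redrawn,
  up to 10 attempts).

Recordings follow the study protocol conditions: 6 breaths/min, 48 Hz, 30 s
(1,440 frames), lung conductivity sigma(t) = 0.2 (1 - a(y) * dsigma *
(1 - cos 2 pi f t)/2) with peak swing dsigma = 0.2 (small-signal regime),
heart 1.5, background 1.  a(y) is a linear anteroposterior weight with mean
1 over the lung and default gradient 0.3 (posterior-favoring, a plausible
healthy supine distribution; no measured value exists for this parameter).
Voltages depend on time only through the scalar breath amplitude, so each
recording is computed exactly from 13 forward solves interpolated (PCHIP)
along the amplitude axis.  White Gaussian channel noise is added at 50 dB
SNR relative to the RMS breathing signal (electronics-grade noise; cardiac
and movement artifacts are not simulated — a known omission that makes the
synthetic task cleaner than in-vivo data).  The simulation mesh is refined
by a factor of 2 relative to reconstruction meshes (default 40k vs. 20k
elements) and shares no interior nodes with them, avoiding the inverse
crime.  The ground truth is the end-expiration-to-end-inspiration
conductivity-swing image rasterized at 128 x 128 on the same bounding box
(supported exactly on the lung mask), with its 32-band profile as reference.

## Study pipeline and problem sizes

The package follows the two-stage in-vivo protocol.  Stage one sweeps
reconstruction settings (GREIT: nf x reference x background at ts 0.06 /
rw 0.15; Gauss-Newton with the Laplace prior: nf x reference x background)
on three subjects' individualized models, ranking settings by the 2D
correlation between reconstructed and ground-truth tidal images (dense
average ranks per subject, ordered by mean rank).  Stage two applies the
selected GREIT setting to all subjects with the three geometry priors.  In
this implementation's nf convention the sweep selects a sharper setting
(nf 0.5, TD, weighted background) than the published recommendation of
0.15 — expected, since nf scales differ between conventions; the masked
lungs/heart weighting (0.2 / 1.5) is part of the M2/M3 model definition and
is kept for the comparison stage regardless of the background ranking.

Desk-scale defaults keep the full pipeline tractable on one CPU:
reconstruction meshes of ~20k elements (the ~200k of a workstation-scale
study remains a configuration option), simulation meshes ~40k, GREIT
training on every in-body pixel (~600–800 targets), and a reduced sweep grid
(24 settings x 3 subjects).  The eight-subject model comparison runs in a
few minutes at these sizes.

## Statistics

Per-subject agreement is the RMSE between the 32-band EIT and reference
profiles (percentage points).  Variants are compared with a Kruskal-Wallis
test (tie-corrected, chi-square p) followed by Tukey-Kramer multiple
comparisons on rank sums (the Nemenyi procedure, studentized-range
distribution) — a rank-based post-hoc chosen for consistency with the
non-parametric omnibus test.  Descriptive agreement uses pooled Pearson
correlation and a non-parametric Bland-Altman analysis: differences
EIT - reference over band pairs where at least one method reports positive
ventilation, bias as the median, limits of agreement as the 2.5th and 97.5th
percentiles with linear interpolation between order statistics.  The pooled
correlation is also reported without the positivity filter, since published
pooled correlations do not state whether the filter was applied.

## What the synthetic validation does and does not show

Passing tests demonstrate that the pipeline is internally correct (forward
physics, calibration closure, linearity, determinism) and that, under the
simulator's conditions, anatomical priors improve profile accuracy in the
same direction as the in-vivo finding: the circular model is clearly worst,
averaged and individualized models improve on it, and the individualized
model with lung masking is best, with the variant effect significant across
eight phantoms.  The synthetic effect sizes are not comparable to the animal
values: real data add cardiac artifacts, belt-position uncertainty, 3D
current spread beyond the slab, registration error in the reference
modality, and richer inter-animal organ variability than a global contour
warp.  Individual phantoms being smooth warps of the averaged fixture means
the averaged prior is closer to each subject here than a population average
is to a real animal, so the M2-to-M3 margin is conservative.

## Known limitations

* Single excitation frequency, real-valued conductivity; no reactive part.
* No cardiac or perfusion signal; a configuration hook exists but defaults
  off, matching the breath-averaged analysis it would otherwise disturb.
* The Tikhonov prior cannot be calibrated to the sharp end of the noise-
  figure range (see above).
* 2.5D slab models for both simulation and reconstruction; out-of-plane
  anatomy is not represented.
* The noise-figure convention, GREIT sample weighting, and quantile rules
  are documented choices; results are comparable only within them.
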