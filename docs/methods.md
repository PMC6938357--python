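# Methods

## Forward model

Between crossed polarizer and analyser, a retardation OPD transmits the
fraction sin²(Δα) with Δα = π·OPD/λ: zero OPD gives the dark background of a
well-aligned Jamin-Lebedeff system, and the transmittance is periodic in one
wavelength of OPD. Under polychromatic illumination each channel of the
camera records

&nbsp;&nbsp;V_c = Σ_λ S(λ) · Q_c(λ) · sin²(π·OPD/λ) · Δλ,

evaluated with composite trapezoidal weights on a wavelength grid.
Normalization divides each channel by its maximum achievable value
Σ_λ S(λ)Q_c(λ)Δλ, so rendered images live in [0, 1] in *linear* intensity;
all gamma handling is confined to file I/O.

Defaults (all overridable, and loadable from CSV to mimic a measured
sensor): wavelength grid 380–780 nm in 5 nm steps; flat source spectrum;
Gaussian channel sensitivities centered at 610/540/465 nm with 60 nm
standard width. These produce recognizable Michel-Levy order colors with
the characteristic loss of saturation at high order — the physical origin
of the inversion ambiguity.

Two acquisition artifacts are simulated, not corrected: the **ghost image**
(the reference beam also crosses the specimen, adding an attenuated copy
sheared by roughly half the field of view) is modeled as an additive,
zero-padded shifted copy with optional Gaussian pre-blur — no astigmatism
or defocus model; **sensor noise** is i.i.d. additive Gaussian per
pixel/channel, clipped to [0, 1], seeded.

## Phantoms

All geometry is specified in µm, OPD in nm (factor 1000 at map
construction); chord lengths are evaluated at pixel centers without
anti-aliasing, so validation masks erode one pixel at object edges.

- **Fiber** (calibration reference): a cylinder of diameter 38 µm and
  effective index 1.4585 in an index-matched bath (1.4140), giving
  OPD(u) = 2√(r² − u²)·Δn·1000 across the axis and an on-axis maximum of
  1691 nm ≈ 3 interference orders at 546 nm — which is also the dynamic
  range of the calibration. The fiber is modeled at its final uniform
  diameter; a linear-taper option exists but defaults off, and the
  core/cladding structure is ignored (single effective index).
- **Microspheres** (accuracy benchmark): PMMA spheres (n 1.592) in oil
  (n 1.5321); projected OPD(ρ) = 2√(r² − ρ²)·Δn·1000, center value 2rΔn
  (1198 nm for r = 10 µm). Overlapping spheres sum their optical paths; a
  strict mode rejects overlaps for ground-truth use. A seeded
  `random_sphere_field` places non-overlapping spheres by rejection
  sampling.
- **Cell blobs**: sums of random anisotropic Gaussian bumps rescaled to a
  peak OPD (default 500 nm, below one wavelength, as typical for adherent
  cells). These share none of the sharp edges of real organelles; passing
  round-trip tests on them demonstrates calibration + solver consistency,
  not segmentation-grade accuracy on textured specimens.

## Calibration

The look-up table averages the measured RGB per OPD bin of the reference
(default 50 bins over [0, 3·546] nm; half-open bins, last closed). Because
a cylinder samples OPD with density ∝ 1/|dOPD/du|, mid-range bins can be
empty at coarse pixel sizes; empty bins are filled by linear interpolation
between non-empty neighbors and flagged with count 0. An `equal-count`
mode uses quantile edges instead, approximating uniform pixels-per-bin; a
value atom (e.g. a constant background) collapses adjacent quantile edges,
which are resolved by keeping one bin at the atom and spreading the
duplicates to the next distinct edge.

The per-channel polynomial fit (order ≤ 10, power basis on OPD rescaled to
[−1, 1] for conditioning) is **uniformly weighted** across bins, including
the interpolated ones: each bin mean is already an average, the cylinder's
count profile varies by two orders of magnitude across bins, and
count-weighting measurably starves the low-OPD arc of the curve — exactly
where thin specimens live. Count-weighted fitting remains available
(`weighted=True`). Over three full interference orders the blue channel
oscillates ~3.6 times, so an order-10 polynomial tracks the tabulated
curve only to ≈0.05–0.1 RMS per channel; this is an intrinsic limit of the
polynomial parametrization, not of the table.

`ambiguity_report` scans all bin pairs more than two bin-widths apart and
lists those closer in RGB space than a threshold — the OPD pairs a noisy
pixel can be confused between.

## Inversion

**Minimal-norm**: per pixel, the bin whose mean color is nearest in
squared Euclidean RGB distance; ties break toward the smaller OPD. It is
exact up to bin quantization where the color curve is unambiguous, and
fails in isolated pixels near curve self-intersections.

**TV-regularized**: minimizes data + λ_TV·TV over a continuous OPD field,
where the data term evaluates the *unclipped* polynomial (keeping the
analytic gradient exact) and the TV term is the smoothed isotropic total
variation Σ√(gx² + gy² + eps_c²) with forward differences and replicate
boundary. The no-root (squared) variant is available behind
`tv_variant="square"`.

Units: the OPD field is optimized in nm, so the ADAM learning rate of 100
means ~100 nm initial steps over a ~1700 nm range. Inside the objective,
OPD differences are expressed in **interference orders** (OPD/546 nm,
`tv_opd_unit`): a one-order phase jump — the characteristic ambiguity
error — then costs about λ_TV against an O(1) color mismatch, and
eps_c = 0.001 orders ≈ 0.5 nm smooths the penalty at zero gradient. This
is the one scaling under which the default trio (λ_TV = 1.0,
eps_c = 0.001, lr = 100) is mutually consistent; with TV in raw nm the
regularizer's gradient is ~10³ times the data term's and flattens smooth
objects.

The solver initializes at the minimal-norm solution (`init="flat"` starts
at the domain's lower edge) and runs a fixed budget of ADAM steps
(β = 0.9/0.999, ε = 1e-8; default 100 iterations, 400 in the validation
preset; an optional relative-loss stop exists but defaults off). Two
safeguards address the fixed step size: the peak learning rate follows a
linear warmup (min(20, n_iters/5) steps) with cosine decay — ADAM's first
update is otherwise a full ±lr sign step on every pixel, which scatters a
near-optimal initialization — and the returned map is the best-loss
iterate, so the result is never worse than its initialization under the
objective. The output is clamped to the LUT domain. Everything is
deterministic given inputs and config; video frames are reconstructed
independently with no temporal coupling.

## Validation

Spheres are detected by a circle Hough transform on Canny edges
(σ = 1.5) of the normalized input — in the pipeline, the minimal-norm OPD
reconstruction, whose profile is monotone; the raw color image would
contribute concentric false circles from the internal interference rings.
Greedy non-maximum suppression keeps circles whose pairwise disk overlap
is ≤ 25 % of the smaller disk. The analytic projection of ideal spheres at
the detected centers/radii serves as ground truth; the error mask is the
union of detected disks eroded by one pixel (edge pixels are aliased by
construction). Per masked pixel,

&nbsp;&nbsp;Err = (OPD_GT − OPD_rec) / OPD_max · 100,

with OPD_max the calibration reference's full-scale OPD (1691 nm, the
fiber's on-axis value, not the per-sphere maximum). A frame reports the
mean of |Err| and the population standard deviation of signed Err; a
sequence additionally reports the mean ± population std of the per-frame
means.

## Problem sizes and numerical choices

The shipped experiments use 256×256 frames at 0.2 µm/px for
fiber/cell work and 160×160 at 1 µm/px for microsphere sequences; at
these sizes a 400-iteration reconstruction takes ~2 s on one CPU and the
full acceptance run ~15 s. Spectral integration error is < 1 % against
grid refinement (smooth integrand). Finite-difference checks of the
analytic gradient use h = 0.5 nm with instances kept away from sub-nm
neighbor differences, where the smoothed-TV curvature (~1/eps_c) exceeds
what that step can resolve; agreement is then within 1e-4 relative with a
5e-7 absolute floor for the oracle's own truncation.

## Known limitations

- No polarization ray tracing, PSF/diffraction, elliptical-polarization
  compensation, tone mapping or white-balance modeling: the synthetic
  camera is linear and noise-free apart from the additive Gaussian term,
  so real-camera effects (auto white balance, compression, dust) are out
  of model.
- Ghost images are simulated but not detected or corrected; regions where
  a ghost overlaps the object will reconstruct incorrectly.
- The polynomial LUT is a global order-≤10 fit; specimens confined to one
  interference order would be better served by a domain-restricted
  calibration.
- TV regularization trades edge fidelity for ambiguity suppression: sphere
  rims lose 1–2 px of sharpness, and moving objects (motion blur) are not
  handled.
- No phase unwrapping beyond what TV provides, no 3-D (x, y, t) coupling,
  no learned reconstruction.
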