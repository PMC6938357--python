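# jlphase

Quantitative phase recovery from Jamin-Lebedeff color-interference micrographs.

A Jamin-Lebedeff (JL) microscope splits the illumination into an object and a
laterally sheared reference beam between crossed polarizers. A transparent
specimen of thickness *d* and refractive index *n*<sub>O</sub> in a medium of
index *n*<sub>R</sub> delays the object beam by an optical path difference

&nbsp;&nbsp;&nbsp;&nbsp;OPD = *d* · (*n*<sub>O</sub> − *n*<sub>R</sub>),

which white-light interference encodes as a Michel-Levy color: each wavelength
is transmitted with sin²(π·OPD/λ), and the camera integrates the full spectrum
per color channel. `jlphase` turns that single color image back into a
quantitative OPD map (nm) — the quantity proportional to a cell's dry mass per
area — using only a one-shot calibration against a reference object of known
phase profile. It is aimed at users of low-cost/retrofitted JL systems
(e.g. cellphone-camera acquisition) and at anyone who wants a fully synthetic,
end-to-end testable model of color-coded phase imaging.

## What's inside

- **spectral** — the forward model: spectrum-weighted two-beam interference,
  Michel-Levy chart rendering, ghost-image and sensor-noise simulation.
- **phantoms** — analytic ground truth: cylindrical glass fiber (the
  calibration reference, 38 µm, n 1.4585 in a 1.4140 bath → max OPD 3λ₀ at
  λ₀ = 546 nm), PMMA microsphere fields (n 1.592 in 1.5321 oil, OPD = 2rΔn),
  and smooth cell-like blobs.
- **calibration** — RGB↔OPD look-up table (50 bins over 3λ₀ by default),
  per-channel order-≤10 polynomial fit, and an ambiguity report for near
  self-intersections of the 3-D color curve.
- **inversion** — two solvers: the pixel-wise *minimal-norm* lookup
  argmin<sub>opd</sub> Σ<sub>c</sub> (C<sub>c</sub>[opd] − m<sub>c</sub>)², and a
  *TV-regularized* reconstruction that minimizes
  Σ<sub>px</sub> Σ<sub>c</sub> (P<sub>c</sub>(opd) − m<sub>c</sub>)² +
  λ<sub>TV</sub> Σ<sub>px</sub> √(g<sub>x</sub>² + g<sub>y</sub>² + eps<sub>c</sub>²)
  with ADAM through the differentiable polynomial LUT
  (λ<sub>TV</sub> = 1.0, eps<sub>c</sub> = 0.001 orders, lr = 100, 100–400 iterations).
- **validation** — circle-Hough microsphere detection, analytic ground-truth
  projection, and pixel-wise percentage error
  Err = (OPD<sub>GT</sub> − OPD<sub>rec</sub>)/OPD<sub>max</sub>.
- **io / cli** — PNG/TIFF I/O (OPD maps as 32-bit float TIFF in nm), Bayer
  demosaicing, spectral-curve CSVs, and a `jlphase` command with
  `simulate`, `chart`, `calibrate`, `reconstruct`, `validate` subcommands.

## Worked example

```python
import numpy as np
from jlphase import (FiberSpec, fiber_opd_map, cell_phantom, render_rgb,
                     build_lut, fit_poly_lut, minimal_norm_solution,
                     reconstruct_tv, ReconstructionConfig)

spec = FiberSpec()                       # 38 µm fiber, Δn = 0.0445
print(f"fiber max OPD: {spec.max_opd:.0f} nm = {spec.max_opd/546:.2f} orders")

fiber = fiber_opd_map(spec, (256, 256), pixel_size=0.2)
curve = build_lut(render_rgb(fiber), fiber, n_bins=50,
                  opd_range=(0.0, spec.max_opd))
lut = fit_poly_lut(curve, order=10)

cell = cell_phantom((256, 256), 0.2, opd_peak=500.0, seed=1)
image = render_rgb(cell)                 # the "measurement"
mask = cell.values > 50

mn = minimal_norm_solution(image, curve)
tv, trace = reconstruct_tv(image, lut, curve, ReconstructionConfig())
print(f"minimal-norm MAE: {np.abs(mn.values - cell.values)[mask].mean():.1f} nm")
print(f"TV-regularized MAE: {np.abs(tv.values - cell.values)[mask].mean():.1f} nm")
```

Output:

```
fiber max OPD: 1691 nm = 3.10 orders
minimal-norm MAE: 24.5 nm
TV-regularized MAE: 15.4 nm
```

The minimal-norm error is dominated by the 33.8 nm LUT bin quantization plus
scattered color-ambiguity misassignments; the TV solver refines the field
continuously and suppresses the ambiguity flips, recovering the 500 nm-peak
phantom to well under half a bin on average.

The same pipeline from the shell:

```bash
jlphase simulate --phantom fiber --out runs/fiber
jlphase calibrate --image runs/fiber/image.tif --reference runs/fiber/opd_gt.tif --out runs/calib
jlphase simulate --phantom spheres --noise-sigma 0.02 --out runs/spheres
jlphase reconstruct --image runs/spheres/image.tif --lut runs/calib/lut.json \
        --curve runs/calib/curve.csv --out runs/rec --method tv --iters 400
jlphase validate --rec runs/rec/image_opd.tif --out runs/val --opd-max 1691
```

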