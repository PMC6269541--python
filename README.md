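# dxblink

Analysis toolkit for **diffracted X-ray blinking (DXB)** — inferring the
rotational motion of gold-nanocrystal labels (and hence of the protein
molecules they are attached to) from the intensity fluctuations of their
Bragg diffraction under a monochromatic X-ray beam — together with the
classical **diffracted X-ray tracking (DXT)** analysis and a
rotational-Brownian-motion simulator that generates realistic blinking
data, so the whole decay-constant ↔ angular-motion calibration can be
exercised end to end without experimental data.

## The method

A nanocrystal diffracts only while its (111) lattice normal satisfies the
Bragg condition λ = 2d·sinθ to within the rocking-curve acceptance.  As
the crystal tumbles by rotational Brownian motion, its diffraction spot on
the Au(111) Debye ring blinks in and out, and each detector pixel on the
ring records a fluctuating photon-count trajectory *I(t)*.  DXB quantifies
the motion through the normalized intensity autocorrelation

    ACF(τ) = ⟨I(t) I(t+τ)⟩ / ⟨I(t)²⟩,

fitted per pixel over the first 10 % of the observed time to a single
exponential

    ACF(t) = k + A·exp(−Τt),

where Τ (1/s) is the decay constant: faster angular motion decorrelates
the diffracted intensity sooner and yields a larger Τ.  Curves with
k > 0, A > 0, Τ > 0 are averaged and refitted with 1/stderr² weights to
give the reported Τ with its standard error and chi-square.

The classical DXT branch tracks the diffraction spots themselves: spots
are detected and linked frame to frame, angular displacements are pooled
per time interval, their Gaussian width σ(t) gives the mean squared
angular displacement MSD = 2σ², and a zero-offset fit of MSD = 4Dt yields
the angular diffusion constant D (rad²/s).  A zero-intercept regression
of D against Τ — or a goniometer scan at known angular speeds — provides
the calibration line that turns a measured decay constant into physical
angular motion.

## Worked example

Simulate blinking crystals on a compact detector, then run the full DXB
pipeline:

```python
from dxblink import (BraggRing, DetectorGeometry, SimConfig, build_ring_mask,
                     dxb_pipeline, render_frames)

geometry = DetectorGeometry(
    wavelength_nm=0.11, distance_mm=15.0, pixel_size_mm=0.172,
    n_rows=120, n_cols=120, beam_center=(59.5, 59.5),
)
ring = BraggRing.from_geometry(geometry, radial_halfwidth_px=2.0)
mask = build_ring_mask(geometry, ring, background_annulus=(50.0, 56.0))

config = SimConfig(
    n_crystallites=6, D=4e-5, rocking_sigma=5e-3,
    peak_rate=2000.0, background_rate=1.0,
    n_frames=400, exposure=0.4, frame_interval=0.5,
    substeps_per_frame=4, init_spread=2e-2, misorientation_bound=2e-2,
    seed=7,
)
stack = render_frames(config, geometry, ring)
report = dxb_pipeline(stack, mask)
f = report.final_fit
print(f"ring radius: {ring.radius_px:.1f} px, on-ring pixels: {mask.counts['on_ring']}")
print(f"valid pixel fits: {report.counts['valid_fits']} / {report.counts['pixels_analysed']}")
print(f"T = {f.T:.3f} +/- {f.se_T:.3f} 1/s  (k = {f.k:.3f}, A = {f.A:.3f}, chi2 = {f.chi_square:.1f})")
```

This prints:

```
ring radius: 44.5 px, on-ring pixels: 1100
valid pixel fits: 488 / 1100
T = 0.308 +/- 0.012 1/s  (k = 0.240, A = 0.193, chi2 = 164.1)
```

1100 ring pixels were autocorrelated; 488 passed the k, A, Τ > 0
selection, and their error-weighted average decays with
Τ ≈ 0.31 s⁻¹ — the blinking rate set by the chosen diffusion constant
(4×10⁻⁵ rad²/s) crossing the 5 mrad rocking acceptance.

The same steps are available from the shell:

```sh
dxblink simulate --config run.yaml --out stack.tif
dxblink mask     --config run.yaml --out mask.tif
dxblink acf      --stack stack.tif --mask mask.tif --out report/
dxblink track    --stack stack.tif --mask mask.tif --config run.yaml \
                 --min-intensity 50 --max-step 8 --out report/
dxblink calibrate --points points.csv --out cal.json
```

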