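# Methods

## Physical model

A gold nanocrystal carries a (111) plane normal **n** that undergoes
rotational Brownian motion with angular diffusion constant D (rad²/s).
With a monochromatic beam the crystal diffracts only near the Bragg
condition λ = 2d sinθ; we model the diffracted intensity as a Gaussian
rocking curve in the misorientation,

    rate(α) = peak_rate · exp(−α² / 2σ_r²),

where α is the signed departure of the normal's beam-polar angle from the
exactly-diffracting cone and σ_r is the acceptance (mosaic/rocking) width.
The acceptance is treated as one-dimensional: tilting out of the
diffraction condition (rocking) dims the spot, while rotating the normal
about the beam axis moves the spot along the Debye ring at azimuth χ
without dimming it.  This is the geometry of monochromatic powder
diffraction and is what makes blinking (intensity) and tracking (spot
position) two complementary readouts of the same rotational motion.

The Brownian propagator composes small random rotations whose
rotation-vector components are i.i.d. N(0, 2·D·dt) per axis, so the mean
squared excursion of the normal grows as 4·D·t (two transverse axes of
2·D·t each) — the same MSD = 4Dt law the tracking branch fits.

### Simulator

`render_frames` advances each crystallite by `substeps_per_frame`
substeps across the exposure (default 10), averages the rate over the
substeps (intra-exposure averaging is part of real 1-s-exposure data),
draws a Poisson photon total, and spreads it over a 5×5 Gaussian spot
footprint (σ = 0.7 px) centred at the crystallite's ring azimuth;
Poisson background lands on all non-gap pixels.  The detector itself is
noise-free (photon counting).  Dead time (frame_interval − exposure)
advances the dynamics without photons.  Identical config + seed gives a
bit-identical stack.

Timing defaults follow the synchrotron acquisition (1.0 s exposure,
1.85 s interval, 1000-frame records); the default D, 3.78×10⁻³ rad²/s, is
the ligand-free binding-protein value measured by tracking, and the
default rocking width is 2 mrad — the acceptance profile of 40–80 nm
crystals is not published, so σ_r is a configuration value and no test
depends on a specific choice.  The Stokes–Einstein–Debye helper
D = k_B·T/(8πηr³) converts temperature/viscosity/radius triples when a
temperature sweep is wanted.

Free (unbounded) diffusion is the default motion model.  Two optional
features make long records quasi-stationary where an analysis needs them:

* **Bounded mosaic spread** (`misorientation_bound`): the rocking offset
  is reflected at ±bound.  A free walker started at the Bragg condition
  crosses the acceptance once and goes permanently dark, which leaves
  nothing for an autocorrelation to average; surface-tethered crystals
  are in reality confined, and a reflecting bound is the simplest
  confinement that keeps a uniform misorientation ensemble exactly
  stationary without introducing a relaxation time of its own.
* **Goniometer scan** (`scan_speed` > 0): the rocking offset follows a
  deterministic triangle wave across ±`scan_halfwidth` so trajectories
  contain repeated blink events at a known angular speed.

The fast path `simulate_pixel_trajectories` skips imaging and evolves the
rocking offset directly (1-D Gaussian increments of variance 2·D·dt),
treating each synthetic pixel as an independent replicate of
`n_crystallites` crystallites.  It reproduces the blinking statistics of
the rendered stacks at a small fraction of the cost and is what the
calibration property checks use.

What the simulator does **not** emulate: coherent speckle, crystal-shape
transforms, absorption, polarization and solid-angle corrections,
detector point spread beyond the fixed footprint, beam drift, and any
coupling between label motion and protein conformation.  Passing tests
therefore demonstrate that the analysis recovers the motion encoded in an
idealised Poisson blinking process, not that real data are free of those
systematics.

## DXB analysis

The autocorrelation estimator divides each lag's product sum by its own
pair count (N − m) and the denominator by N:

    ACF(m) = [Σ_{t<N−m} I(t)I(t+m)/(N−m)] / [Σ I(t)²/N],

which makes ACF(0) exactly 1 for any nonzero trajectory.  Lag 0 is
excluded from fitting; the default window covers lags 1 …
⌊0.10·N⌋+1 (frames 1–101 of a 1000-frame record), converted to seconds
by the frame *interval* (which, not the exposure, defines the lag
spacing).  An explicit (τ_min, τ_max) window supports overlap refits
between acquisitions at different frame rates.

Per-pixel fits are unweighted; the weighting by standard errors is
described only for the averaged curve, so the per-pixel stage follows the
plain least-squares reading (flagged here deliberately).  The weighted
refit of the averaged curve uses 1/stderr² with
chi² = Σ((data−model)/stderr)²; zero-stderr lags inside the window get
the smallest positive stderr on the window, and frames with zero
background during lab-mode normalisation are imputed with the mean
background — both keep the lag grid uniform and are logged.

Numerical choices: initial guesses k₀ = tail mean of the windowed curve,
A₀ = first-lag value − k₀, T₀ = 3/window span; the optimiser is restarted
from T₀×{0.1, 1, 10, 100} and the lowest-cost converged solution kept,
because the k/A trade-off has a degenerate near-linear local minimum that
a single start can land in.  A fit is valid iff it converged, its
parameter standard errors are finite (a singular Jacobian means the
parameters are not identifiable — e.g. a flat curve), and k, A, T all
exceed 10⁻⁹ (so numerically-zero amplitudes are not accepted).
Non-convergence is reported through `valid=False`, never raised.
Identically-zero pixel trajectories are dropped before the ACF stage with
a logged count.

Background normalisation (I(t)·mean(B)/B(t) with B the summed
background-annulus counts) is off by default and enabled for lab-source
data, where source drift is a real effect; it is invariant under a
uniform rescaling of B.

## DXT analysis

Spots are 8-connected components of above-threshold ring pixels
(connectivity never crosses excluded pixels), with intensity-weighted
centroids.  Linking is greedy smallest-distance-first between consecutive
frames with a hard gate `max_step_px`; there is no gap memory — blinking
makes long gaps ambiguous, and the MSD uses within-track pairs only.
Exact distance ties break by row-major order, making the linker
deterministic.

Displacements pool the azimuthal component Δχ (wrapped to (−π, π]) and
the radial angular component Δ(2θ)/2 into one signed 1-D sample set per
interval; the histogram (Freedman–Diaconis-style bins, minimum 8) is
fitted by a zero-mean Gaussian, and MSD = 2σ² so that per-axis variance
2Dt gives MSD = 4Dt.  The through-origin MSD fit uses the first
min(5, available) intervals.  **Axis caveat:** rendered monochromatic
stacks move their spots only azimuthally (rocking misorientation is
encoded in intensity, not position), so for simulator data the chi-only
mode (`axis_mode="chi"`) is the consistent estimator — pooling the static
radial axis would halve D by construction.  Both modes are exposed; the
end-to-end recovery checks use chi-only for exactly this reason.

## Calibration

The zero-intercept line D = slope·Τ uses slope = Σw·x·y/Σw·x² with
w = 1/y_err²; R² is computed against the weighted mean (and may be
negative for non-proportional data).  Queries outside the calibrated
range are clamped and warned — extrapolation validity is unknown.  The
goniometer route runs the full DXB pipeline per scan stack and pairs each
fitted Τ with its known angular speed; Τ standard errors from the
weighted fit are propagated onto the dependent axis with a first-pass
slope.  The slope of any such line depends on the rocking width and
geometry of the specific sample, so only its linearity and monotonicity
are meaningful across configurations, never a universal numeric value.

## Problem sizes used in the checks

The property checks run on compact scenarios chosen to keep every decay
and displacement well resolved: a 120×120-pixel detector with the full
ring at ≈44 px; 300-frame stacks at 0.1 s/frame with a wide (0.12 rad)
acceptance and bright spots (5×10⁴ photons/s) for tracking recovery at
D ∈ {10⁻⁵, 5×10⁻⁵, 2×10⁻⁴} rad²/s; and 1200-frame, 24-pixel fast-path
ensembles (σ_r = 5 mrad, bounded spread ±4σ_r) for the Τ↔D calibration
across one decade of D.  The published-table ratio computations take the
printed fit parameters as inputs and are deterministic.

## Known limitations

* The exponential is an empirical model: the true ACF of
  diffusion-through-a-Gaussian-acceptance is closer to an algebraic
  (Lorentzian-like) decay, so the fitted Τ depends mildly on the fit
  window.  This mirrors the window sensitivity seen when comparing
  acquisitions at different frame rates.
* The spot azimuth is taken as the azimuth of the plane normal about the
  beam; the exact diffracted-beam azimuth differs by a factor 1/cosθ in
  displacement gain (≈6 % in variance at 2θ ≈ 27°), a bias small against
  the tracking tolerances used here.
* Pixel-to-pixel cross-correlation, multi-exponential models and
  sub-frame (photon-arrival) correlation are out of scope.
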