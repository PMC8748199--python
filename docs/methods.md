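# Methods

This note records the models implemented in flimmux, the defaults chosen
where the experimental description leaves freedom, and what the synthetic
data do and do not establish about real measurements.

## TCSPC forward model

Photon arrival times are the sum of an exponential decay delay (one or more
components, chosen per amplitude fraction) and an IRF jitter term, folded
into the pulse period `T = 1000/rep_rate` ns. Folding is exact: summing the
geometric series of earlier-period emissions gives the wrapped density
`e^(−t/τ) / (τ(1 − e^(−T/τ)))` on `[0, T)`. At the default 80 MHz this wrap
is material — 3.4% of photons for τ = 3.7 ns — so both the simulator and
the fitting model implement it; analyses that ignore it would bias long
lifetimes low by several percent.

Defaults (acquisition): 80 MHz repetition rate, 256 bins over 12.5 ns,
Gaussian IRF with center 1.5 ns and σ = 0.15 ns. The repetition rate is the
stated instrument setting; bin count and IRF shape/width are typical TCSPC
values — the instrument's IRF is not published, so these are declared
choices, not inferences. Bin centers `(k+½)·Δt` are used as photon times
throughout; using edges instead would shift every phasor by half a bin.

Expected (noiseless) histograms come from the same model evaluated on an
8× oversampled grid, circularly convolved by FFT and summed back to the
acquisition bins, so that the discrete model tracks the continuous
convolution; residual sub-bin offsets are absorbed by the fitted IRF shift.

## Scenes, photon budgets, ground truth

Scene geometry (elliptical nuclei, random-walk mitochondria filaments,
Golgi-like blob clusters) is stylized: only the label/lifetime structure
matters for validating separation, not biophysical shape. Foreground pixels
default to 1,000 expected photons (the standard per-pixel collection
budget); the uniform background of 20 photons/pixel is an invented but
plausible level — no background value is published. Per-pixel photon numbers
are Poisson; ground truth records the *expected* per-species photon
fractions, which is the quantity linear unmixing estimates. Relative
brightness defaults to 1 for all species and can be configured.

One integer seed drives each generator call; identical seeds give
bit-identical outputs.

## Phasor analysis

`phasor_transform` computes per-pixel first-harmonic (g, s); zero-photon
pixels carry an explicit invalid flag rather than NaNs and are excluded from
pooling. Pooling is intensity-weighted, which makes the pooled phasor equal
the phasor of the summed histogram exactly; an unweighted mean would not.
Harmonic 1 is the default; higher harmonics are supported but unused.

Calibration derives one complex factor (rotation + modulation scale) mapping
the pooled phasor of a reference of known lifetime onto its theoretical
semicircle position. Because periodic convolution multiplies phasors, this
removes the IRF exactly for all pixels sharing the instrument response; the
transform is stored and must not be re-derived or applied twice.

Background correction exploits the fact that a temporally flat background
has phasor exactly (0, 0): `z_signal = z_total · I/(I − B)` with `B`
estimated as the median intensity of sub-threshold pixels. Without it, even
a 2% background biases the middle species of a three-anchor unmixing by up
to ~0.3, because the anchor triangle of on-circle lifetimes is thin (height
≈ 0.04 for the 1.6/2.6/3.7 ns triple) and amplifies any displacement toward
the origin.

FastFLIM images are count-weighted mean arrival times minus the IRF
centroid, computed on the histogram *as recorded* — the wrap makes this a
bounded underestimate of the lifetime (e.g. 3.26 ns recorded for a 3.7 ns
decay with an ideal IRF). An exact forward map of recorded mean vs lifetime
(including the IRF's own wrapped tail) and its numerical inverse are
provided; the inverse is exact for mono-exponential pixels and approximate
for mixtures, for which the corrected equal-photon G1/S biosensor mixture
lands at the arithmetic mean of the component lifetimes (3.4 ns for
3.7/3.1 ns; 2.7 ns for 2.9/2.5 ns).

## Reconvolution fitting

Pooled decays (≥ 100 photons; per-pixel fitting is deliberately out of
scope — pixel-level analysis goes through phasors) are fitted by bounded
nonlinear least squares with Pearson weights `√max(model, 1)`: model-based
variances are stable in low-count bins where observed-count weights are
not. Parameters: n lifetimes, n amplitudes (photons), a flat background
≥ 0, and an IRF time shift within ±2 ns. Initialization takes τ from the
wrap-corrected FastFLIM mean of the decay, spread ×(0.5, 1, 2) for
multi-component fits. Convergence: relative cost change < 1e-10, bounded
iteration budget; non-convergence is flagged on the result, not raised.
Reduced χ² uses n_bins − n_params degrees of freedom. Model order is
selected by fitting n = 1, 2, 3 and keeping the smallest n with reduced
χ² < 1.2; if none passes, the n = 3 fit is returned flagged.

Both mean-lifetime conventions are reported side by side — amplitude
weighting `Σaτ/Σa` and intensity weighting `Σaτ²/Σaτ` — because commercial
FLIM software does not document which it uses.

## Unmixing

Fractions are *photon-weight* fractions; converting to molecular abundance
would require relative brightness and is offered only as an explicit
post-hoc step. Out-of-simplex pixels are clipped to the nearest point of
the anchor segment/triangle and flagged, keeping images complete while
preserving QC information; a hard "cluster circle" assignment mode (nearest
anchor within radius 0.05, else unassigned) is provided as an alternative,
with no claim about which commercial implementations use. Foreground is
intensity ≥ 100 photons by default, mirroring intensity thresholding of
empty regions. Optional k×k phasor binning (off by default) reduces
per-pixel phasor noise ~k-fold and is the appropriate tool when per-pixel
fraction maps, rather than per-structure summaries, are the goal: at 1,000
photons/pixel the unbinned barycentric noise on the middle species of the
1.6/2.6/3.7 ns triangle is of order 0.5, and no pointwise estimator can
repair that; 3×3 binning brings the per-pixel RMSE to ≈ 0.05–0.07.
Per-structure fractions are computed from the pooled structure phasor,
which is shot-noise limited and accurate to < 0.05 for structures of
≳ 100 pixels at the default budget.

Anchors come either from theoretical lifetime positions (requiring a
calibrated field) or from pooled phasors of single-species calibration
images (≥ 10⁴ photons each); a mixed-species "calibration" image silently
places its anchor at the mixture phasor — a documented misuse the code
cannot detect.

## Fucci biosensor readout

Nuclei are segmented as connected components of thresholded intensity with
a minimum area (touching nuclei can merge — a known limitation; simulator
truth label maps can be passed in instead). Per nucleus the pooled phasor
is projected onto the S→G1 anchor chord; `f` is the G1-species (hCdt-bound)
photon fraction. Phase thresholds 0.25/0.75 are symmetric defaults — the
experimental classification is visual — and are exposed in configuration.
The equal-photon (50:50) interpretation of the G2/M mixture is an
assumption; the published "~3.4 ns" G2/M arrival time is consistent with
it. Time-lapse tracking of nuclei across frames is out of scope; each frame
is classified independently.

## Kinetics and photophysics fits

The two-step labeling scheme `P + S ⇌ PS* → PS` is integrated as an ODE
(LSODA, substrate-normalized states; all traces sharing a time grid are
stacked into one solver call) and fitted globally across concentrations
with rate constants in log₁₀ space; the anisotropy endpoints r_free and
r_bound are shared free parameters. `K_D` and `k_app` are recomputed
properties of the fitted rates, never stored, so the defining identities
cannot drift. The instrument dead time enters as a known input (points
before it are pretrigger and dropped), not an estimated parameter.

Identifiability: with binding rate-limiting (k₁[S]₀ ≪ k₋₁+k₂, the regime of
the 0.125–0.5 µM stopped-flow design), the intermediate stays near quasi-
steady state and the data constrain k_app much more tightly than k₁ and k₋₁
individually. The generator's default stopped-flow conditions therefore
emulate dense multi-timebase sampling (600 log-spaced points, 2 ms–10 s)
and replicate averaging (five replicates per concentration, as recorded
traces are in practice averaged), four concentrations across the stated
range. Under those conditions each rate is recovered with < 10% RMS error
at 1% anisotropy noise; single-concentration data are fitted but flagged
non-identifiable when a Monte-Carlo rate interval spans two orders of
magnitude.

Monte-Carlo intervals resample the base fit (parametric Gaussian redraw
with SD from the residuals by default, residual resampling optionally),
refit N = 1000 times, discard the worst 5% by cost, and take 2.5/97.5
percentiles; Shapiro–Wilk normality of the kept draws is reported. The
residual SD uses n − p degrees of freedom. Discarding the worst fits can
jitter interval widths by ~1–2% in either direction (cost and parameter
extremity are only weakly coupled); it never widens them materially.
Coverage was verified at ≈ 95% on the triplicate titration design; with
single measurements per point (11 observations, 3 parameters) percentile
intervals undercover by ~10%, which is a property of percentile bootstrap
at small n, not of the implementation.

Remaining fits are standard least squares: sigmoid D50 (inflection = D50),
mono-exponential labeling with `k_app = 1/(τ[P]₀)` (x-offset fixed at the
first time point, which is otherwise degenerate with the amplitude),
extinction coefficient from the OLS slope at 1 cm path, Gaussian profile
FWHM `w√(2 ln 2)`. ΔI uses the pooled-variance one-sided t-test (pooled, so
triplicates give the conventional 4 degrees of freedom, not Welch).
Screening selects wells outside control mean ± 3 s.d. (round 1) or ± 2 s.d.
(later rounds) after discarding wells with GFP below 10% of control.

## Numerical choices and degenerate inputs

- Collinearity threshold for anchor triangles is area > 1e-6, small enough
  to admit close-spaced triples such as 3.1/3.4/3.7 ns (area ≈ 5.7e-5)
  while still rejecting true degeneracy; anchor distinctness requires
  pairwise distance > 1e-3.
- The δ-IRF is discretized with sub-bin linear splitting so the fit model
  stays differentiable in the IRF-shift parameter.
- FFT round-off in the periodic convolution is clipped at zero
  (~1e-18-level ringing).
- Zero-photon pixels, empty masks, zero-intensity references, sub-100-photon
  decays, < 2 control wells, and zero t₀ intensities all raise explicit
  errors or flags rather than propagating NaNs.

## What the synthetic data do not show

The generator has no optical blur (species mix only where masks overlap,
not at diffraction-limited edges), no detector afterpulsing or dead time,
no photobleaching within a frame, and mono-exponential species by default,
whereas real tag-dye decays can be mildly multi-exponential. Passing tests
therefore demonstrate the correctness and noise behavior of the estimators
under the stated model, not instrument-specific systematics; on real data
the calibration, background, and IRF-shift steps carry that burden.

## Problem sizes

Test and acceptance computations use desk-scale sizes chosen for statistical
sufficiency: 10⁶-photon pooled decays for lifetime recovery (shot-noise
limit ≈ 0.1%), 96×96 scenes at 1,000 photons/pixel for separation metrics,
10-nucleus fields for phase-call accuracy, 600-point × 4-concentration
stopped-flow designs, and 50-repetition coverage studies.
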