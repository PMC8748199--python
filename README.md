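# flimmux

Fluorescence-lifetime multiplexing analysis for live-cell FLIM: simulate
TCSPC images with known ground truth, separate up to three co-expressed
species per spectral channel by phasor analysis (six across two channels),
determine lifetimes by n-exponential reconvolution fitting, read out a
lifetime-based Fucci cell-cycle biosensor, and fit the surrounding
photophysics and labeling-kinetics models.

## Who this is for

Engineered self-labeling tags (HaloTag variants 7/9/10/11) shift the
fluorescence lifetime that a single rhodamine dye (e.g. MaP555, MaP618)
exhibits when bound — spanning roughly 1.1–2.8 ns (MaP555) and 1.6–3.7 ns
(MaP618) across the four tags. That turns *lifetime* into a multiplexing
axis: several cellular structures labeled with one dye, in one spectral
channel, can be separated by time-correlated single-photon counting (TCSPC)
data alone. This package provides the full analysis chain for that
experiment as tested, scriptable Python, plus a synthetic-data generator so
every stage can be validated without a microscope.

## The math in brief

**Phasor transform.** A per-pixel photon-arrival histogram `c_k` over one
pulse period `T` maps to first-harmonic Fourier coordinates

    g = Σ c_k cos(ω t_k) / Σ c_k ,   s = Σ c_k sin(ω t_k) / Σ c_k ,   ω = 2π/T.

Mono-exponential decays lie on the universal semicircle
`(g − ½)² + s² = ¼` at `g = 1/(1+(ωτ)²)`, `s = ωτ/(1+(ωτ)²)`; photon
mixtures lie on chords, with coordinates equal to the photon-weighted convex
combination of the component phasors. Species fractions therefore follow
from projection onto the anchor chord (2 species) or barycentric coordinates
in the anchor triangle (3 species). A flat temporal background sits exactly
at the origin and is removed by the correction `z → z·I/(I−B)`.

**Reconvolution fitting.** Pooled decays are fitted with the periodic
convolution of `Σ aᵢ e^(−t/τᵢ)` with the instrument response function plus a
flat background, by weighted least squares (Pearson weights from model
counts, floored at one). Model order n = 1, 2, 3 is selected as the smallest
n whose reduced χ² falls below 1.2. At 80 MHz the 12.5 ns period makes the
wrapped tail of slow decays (e.g. e^(−12.5/3.7) ≈ 3.4% of photons for
τ = 3.7 ns) non-negligible; simulator and model both wrap.

**Biosensor readout.** The lifetime-Fucci construct expresses the
long-lifetime tag fused to hCdt (G1) and the short-lifetime tag fused to
hGeminin (S); G2/M shows a mixture. Per nucleus, the pooled phasor is
projected onto the G1–S anchor chord to give the hCdt photon fraction `f`,
classified as G1 (`f > 0.75`), S (`f < 0.25`) or G2/M otherwise.

**Kinetics suite.** Sigmoidal D50 titrations, mono-exponential labeling
kinetics with `k_app = 1/(τ·[P]₀)`, the two-step binding scheme
`P + S ⇌ PS* → PS` fitted globally by ODE least squares with derived
`K_D = k₋₁/k₁` and `k_app = k₁k₂/(k₂+k₋₁)` and Monte-Carlo confidence
intervals (N = 1000, worst 5% discarded), extinction-coefficient regression,
FCS molecular brightness `mB = G(0)·PC`, Gaussian line profiles with
`FWHM = w√(2 ln 2)`, the ΔI screening statistic with a pooled one-sided
t-test, plate-screen selection rules, and photobleaching normalization.

## Worked example

```python
import json
from flimmux import RunConfig
from flimmux.io import run_pipeline

cfg = RunConfig.model_validate({
    "species": {"HaloTag10-MaP618": {"lifetime": 1.6},
                "HaloTag7-MaP618":  {"lifetime": 2.6},
                "HaloTag9-MaP618":  {"lifetime": 3.7}},
    "scene": [
        {"kind": "nucleus",      "count": 1, "size": 12.0, "species": "HaloTag9-MaP618"},
        {"kind": "mitochondria", "count": 2, "size": 8.0,  "species": "HaloTag7-MaP618"},
        {"kind": "golgi",        "count": 1, "size": 7.0,  "species": "HaloTag10-MaP618"}],
    "shape": (96, 96), "seed": 1,
    "unmixing": {"binning": 3}})
report = run_pipeline(cfg, "out_demo")
print(json.dumps(report["metrics"], indent=1))
```

prints

```json
{
 "n_foreground_px": 561,
 "fraction_rmse": 0.03866132244082405,
 "mean_fraction_error": {
  "HaloTag10-MaP618": -0.00822193330060872,
  "HaloTag7-MaP618": -0.05398263378357593,
  "HaloTag9-MaP618": -0.016112524582230447
 }
}
```

i.e. the simulated three-structure scene (one dye, one spectral channel,
1,000 photons per foreground pixel) is unmixed with a per-pixel fraction
RMSE of ≈0.04 against the generator's ground truth, and each structure's
mean photon fraction is attributed to the correct HaloTag species within a
few percent. `out_demo/` holds the rendered TCSPC stack, the phasor field,
one separated intensity image per species, the ground truth and the resolved
configuration. The same stages are scriptable from the shell via the
`flimmux` CLI (`flimmux run --config cfg.json --seed 1 --out out_demo`).

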