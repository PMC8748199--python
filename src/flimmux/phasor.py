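"""Phasor transform, calibration, pooling and FastFLIM mean arrival times.

The phasor of a decay histogram is its first-harmonic Fourier coordinate
(g, s) = (sum c cos(w t) / sum c, sum c sin(w t) / sum c) evaluated at bin
centers. Mono-exponential decays lie on the universal semicircle
(g - 1/2)^2 + s^2 = 1/4; mixtures lie on chords, which is what makes linear
unmixing in phasor space exact in photon weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AcquisitionConfig, TCSPCImage, unwrap_mean_arrival

__all__ = [
    "PhasorField",
    "CalibrationTransform",
    "phasor_transform",
    "theoretical_phasor",
    "calibrate",
    "pooled_phasor",
    "fastflim_mean_arrival",
]


@dataclass
class PhasorField:
    """Per-pixel (g, s) coordinates plus intensity for one harmonic."""

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray  # False where a pixel recorded zero photons
    harmonic: int
    omega: float  # rad/ns
    acq: AcquisitionConfig

    @property
    def shape(self) -> tuple[int, int]:
        return self.g.shape

    def as_complex(self) -> np.ndarray:
        return self.g + 1j * self.s


@dataclass(frozen=True)
class CalibrationTransform:
    """Rotation + scale mapping measured phasors onto theoretical ones.

    Applying the stored transform is the contract; re-deriving or applying it
    twice gives a different (wrong) result, so the transform object is kept
    with the data it calibrated.
    """

    rotation: float  # radians
    scale: float
    reference_lifetime: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    def apply(self, field: PhasorField) -> PhasorField:
        z = field.as_complex() * (self.scale * np.exp(1j * self.rotation))
        return PhasorField(g=z.real, s=z.imag, intensity=field.intensity,
                           valid=field.valid, harmonic=field.harmonic,
                           omega=field.omega, acq=field.acq)


def phasor_transform(img: TCSPCImage, harmonic: int = 1) -> PhasorField:
    """Per-pixel phasor coordinates of a TCSPC image.

    Zero-count pixels are flagged invalid (g = s = 0, valid = False) rather
    than propagating NaNs. Intensity is the exact per-pixel histogram sum.
    """
    omega = img.acq.omega(harmonic)
    t = img.acq.bin_centers
    cosv = np.cos(omega * t)
    sinv = np.sin(omega * t)
    counts = img.counts
    intensity = counts.sum(axis=2)
    num_g = counts @ cosv
    num_s = counts @ sinv
    valid = intensity > 0
    g = np.zeros(intensity.shape, float)
    s = np.zeros(intensity.shape, float)
    g[valid] = num_g[valid] / intensity[valid]
    s[valid] = num_s[valid] / intensity[valid]
    return PhasorField(g=g, s=s, intensity=intensity, valid=valid,
                       harmonic=harmonic, omega=omega, acq=img.acq)


def theoretical_phasor(tau: float, omega: float) -> tuple[float, float]:
    """Phasor of an ideal mono-exponential: lies on the universal semicircle."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    d = 1.0 + (omega * tau) ** 2
    return 1.0 / d, omega * tau / d


def pooled_phasor(field: PhasorField, mask: np.ndarray | None = None
                  ) -> tuple[float, float, float]:
    """Intensity-weighted mean phasor over a mask.

    Equals the phasor of the summed histogram over the mask exactly, because
    each pixel's (g, s) is its histogram's normalized Fourier coordinate.
    """
    if mask is None:
        mask = np.ones(field.shape, bool)
    mask = np.asarray(mask, bool) & field.valid
    w = field.intensity[mask].astype(float)
    total = w.sum()
    if mask.sum() == 0 or total <= 0:
        raise ValueError("pooled_phasor: mask is empty or has zero intensity")
    g = float(np.sum(w * field.g[mask]) / total)
    s = float(np.sum(w * field.s[mask]) / total)
    return g, s, float(total)


def calibrate(field: PhasorField, reference_img: TCSPCImage,
              reference_lifetime: float
              ) -> tuple[PhasorField, CalibrationTransform]:
    """Calibrate a phasor field against a reference of known lifetime.

    The pooled phasor of the reference image is mapped onto the theoretical
    mono-exponential position by one complex factor (rotation + scale); the
    same factor is applied to every pixel. This removes the IRF's phase and
    modulation exactly, since convolution multiplies phasors.
    """
    if reference_img.acq.n_bins != field.acq.n_bins or \
            reference_img.acq.rep_rate != field.acq.rep_rate:
        raise ValueError("reference image acquisition config does not match")
    ref_field = phasor_transform(reference_img, harmonic=field.harmonic)
    if not ref_field.valid.any():
        raise ValueError("reference image has zero intensity")
    g0, s0, _ = pooled_phasor(ref_field)
    z_meas = g0 + 1j * s0
    if abs(z_meas) == 0:
        raise ValueError("reference phasor is at the origin; cannot calibrate")
    gt, st = theoretical_phasor(reference_lifetime, field.omega)
    corr = (gt + 1j * st) / z_meas
    transform = CalibrationTransform(rotation=float(np.angle(corr)),
                                     scale=float(np.abs(corr)),
                                     reference_lifetime=reference_lifetime)
    return transform.apply(field), transform


def estimate_background_rate(field: PhasorField,
                             foreground_threshold: float = 100.0) -> float:
    """Median intensity of below-threshold pixels: the flat background level
    in photons per pixel."""
    bg_px = field.intensity[field.valid & (field.intensity < foreground_threshold)]
    if bg_px.size == 0:
        return 0.0
    return float(np.median(bg_px))


def subtract_background(field: PhasorField, background_rate: float
                        ) -> PhasorField:
    """Remove a flat (uniform-in-time) background from a phasor field.

    Uniform background photons sit exactly at the phasor origin, so the
    signal phasor is z_sig = z_tot * I / (I - B) with B background photons
    per pixel; the returned intensity is the background-free photon count.
    Pixels with I <= B become invalid.
    """
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    if background_rate == 0:
        return field
    signal = field.intensity - background_rate
    ok = field.valid & (signal > 0)
    factor = np.where(ok, field.intensity / np.where(ok, signal, 1.0), 0.0)
    return PhasorField(g=field.g * factor, s=field.s * factor,
                       intensity=np.where(ok, signal, 0.0), valid=ok,
                       harmonic=field.harmonic, omega=field.omega,
                       acq=field.acq)


def bin_phasor(field: PhasorField, k: int = 3) -> PhasorField:
    """k x k box binning of a phasor field (intensity-weighted).

    Equivalent to summing the k x k neighborhood histograms before the
    transform; the standard variance-reduction step before per-pixel
    unmixing. Off by default in the pipeline.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be an odd positive integer")
    if k == 1:
        return field
    from scipy.ndimage import uniform_filter

    w = field.intensity.astype(float)
    num_g = uniform_filter(w * field.g, size=k, mode="constant")
    num_s = uniform_filter(w * field.s, size=k, mode="constant")
    den = uniform_filter(w, size=k, mode="constant")
    valid = den > 0
    g = np.where(valid, num_g / np.where(valid, den, 1.0), 0.0)
    s = np.where(valid, num_s / np.where(valid, den, 1.0), 0.0)
    return PhasorField(g=g, s=s, intensity=field.intensity, valid=valid,
                       harmonic=field.harmonic, omega=field.omega,
                       acq=field.acq)


def fastflim_mean_arrival(img: TCSPCImage, irf_centroid: float = 0.0,
                          wrap_corrected: bool = False) -> np.ndarray:
    """Per-pixel average photon arrival time (FastFLIM), in ns.

    Count-weighted mean bin-center time minus the IRF centroid, computed on
    the histogram as recorded. Because late emission wraps into the next
    period, the recorded mean underestimates the lifetime by a bounded
    amount; with ``wrap_corrected=True`` the mono-exponential wrap bias is
    inverted per pixel (exact for mono-exponential pixels, approximate for
    mixtures). Zero-count pixels return NaN.
    """
    if not 0 <= irf_centroid < img.acq.period:
        raise ValueError("irf_centroid must lie within [0, period)")
    t = img.acq.bin_centers
    intensity = img.counts.sum(axis=2).astype(float)
    num = img.counts @ t
    out = np.full(intensity.shape, np.nan)
    valid = intensity > 0
    out[valid] = num[valid] / intensity[valid] - irf_centroid
    if wrap_corrected:
        period = img.acq.period
        vals = out[valid]
        corrected = np.array([
            unwrap_mean_arrival(v, period) if 0 < v < period / 2 else np.nan
            for v in vals])
        out[valid] = corrected
    return out
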