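"""Shared domain types and the TCSPC decay forward model.

The objects here are used by every stage of the pipeline: the acquisition
geometry (pulse period, time bins), the instrument response function (IRF),
mono/multi-exponential species models, and the raw per-pixel photon-histogram
image. The forward model implements the *periodic* (wrap-around) convolution
of a multi-exponential decay with the IRF: at an 80 MHz pulse rate the period
is only 12.5 ns, so for lifetimes of 3-4 ns a few percent of the emission
wraps into the following excitation period and cannot be neglected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AcquisitionConfig",
    "IRF",
    "SpeciesModel",
    "TCSPCImage",
    "wrapped_exp_bin_masses",
    "expected_decay",
    "decay_model",
    "wrapped_mean_arrival",
    "unwrap_mean_arrival",
    "sample_arrival_times",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """TCSPC acquisition geometry.

    Parameters
    ----------
    rep_rate : float
        Laser repetition rate in MHz (default 80, i.e. a 12.5 ns period).
    n_bins : int
        Number of TCSPC time bins over one period (>= 16).
    seed : int
        Base seed recorded with the acquisition; split per operation.
    """

    rep_rate: float = 80.0
    n_bins: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rep_rate <= 0:
            raise ValueError("rep_rate must be positive (MHz)")
        if self.n_bins < 16:
            raise ValueError("n_bins must be >= 16")

    @property
    def period(self) -> float:
        """Pulse period in ns (1000 / rep_rate[MHz])."""
        return 1000.0 / self.rep_rate

    @property
    def bin_width(self) -> float:
        return self.period / self.n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def omega(self, harmonic: int = 1) -> float:
        """Angular frequency of the given harmonic in rad/ns."""
        if harmonic < 1:
            raise ValueError("harmonic must be >= 1")
        return 2.0 * np.pi * harmonic * self.rep_rate / 1000.0


@dataclass(frozen=True)
class IRF:
    """Instrument response function: Gaussian or measured per-bin curve.

    ``center``/``sigma`` are in ns (Gaussian kind); ``curve`` holds
    nonnegative per-bin weights for a measured IRF (normalized on use).
    """

    kind: str = "gaussian"
    center: float = 1.5
    sigma: float = 0.15
    curve: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "measured", "delta"):
            raise ValueError(f"unknown IRF kind {self.kind!r}")
        if self.kind == "gaussian" and self.sigma <= 0:
            raise ValueError("gaussian IRF requires sigma > 0")
        if self.kind == "measured":
            if self.curve is None:
                raise ValueError("measured IRF requires a curve")
            c = np.asarray(self.curve, dtype=float)
            if np.any(c < 0) or c.sum() <= 0:
                raise ValueError("measured IRF curve must be nonnegative with positive sum")
            object.__setattr__(self, "curve", c / c.sum())

    @property
    def centroid(self) -> float:
        """First moment of the IRF in ns (needs acquisition info for measured)."""
        if self.kind == "gaussian":
            return self.center
        if self.kind == "delta":
            return self.center
        raise ValueError("centroid of a measured IRF depends on the bin grid; "
                         "use centroid_on(acq)")

    def centroid_on(self, acq: AcquisitionConfig) -> float:
        if self.kind in ("gaussian", "delta"):
            return self.center
        t = acq.bin_centers
        return float(np.sum(self.curve * t))

    def discretize(self, acq: AcquisitionConfig, oversample: int = 8,
                   shift: float = 0.0) -> np.ndarray:
        """Per-fine-bin IRF masses over one period, summing to 1.

        The Gaussian is wrapped periodically (it may straddle t=0) and an
        optional time shift in ns is applied.
        """
        m = acq.n_bins * oversample
        delta = acq.period / m
        t = (np.arange(m) + 0.5) * delta
        if self.kind == "delta":
            # sub-bin linear split keeps the model smooth in the shift
            out = np.zeros(m)
            x = ((self.center + shift) % acq.period) / delta - 0.5
            j = int(np.floor(x))
            f = x - j
            out[j % m] += 1.0 - f
            out[(j + 1) % m] += f
            return out
        if self.kind == "gaussian":
            c = self.center + shift
            # wrap the tails across the periodic boundary
            acc = np.zeros(m)
            for k in (-1, 0, 1):
                acc += np.exp(-0.5 * ((t - c + k * acq.period) / self.sigma) ** 2)
            return acc / acc.sum()
        # measured: interpolate the coarse per-bin curve onto the fine grid
        coarse_t = acq.bin_centers
        fine = np.interp(t, coarse_t, self.curve, period=acq.period)
        fine = np.clip(fine, 0, None)
        if shift != 0.0:
            n_roll = shift / delta
            # circular sub-bin shift via linear interpolation
            lo = int(np.floor(n_roll))
            frac = n_roll - lo
            fine = (1 - frac) * np.roll(fine, lo) + frac * np.roll(fine, lo + 1)
        s = fine.sum()
        if s <= 0:
            raise ValueError("discretized IRF has zero mass")
        return fine / s


@dataclass(frozen=True)
class SpeciesModel:
    """A labeled tag-fluorophore species.

    ``components`` is a sequence of (lifetime_ns, amplitude_fraction) pairs;
    amplitude fractions must sum to one. ``relative_brightness`` scales the
    photon budget of structures labeled with this species (HaloTag variants
    change brightness as well as lifetime).
    """

    name: str
    components: tuple[tuple[float, float], ...]
    relative_brightness: float = 1.0

    def __post_init__(self) -> None:
        comps = tuple((float(t), float(a)) for t, a in self.components)
        if not comps:
            raise ValueError("species needs at least one lifetime component")
        for tau, _ in comps:
            if tau <= 0:
                raise ValueError(f"lifetime must be > 0, got {tau}")
        total = sum(a for _, a in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"amplitude fractions must sum to 1, got {total}")
        if self.relative_brightness <= 0:
            raise ValueError("relative_brightness must be > 0")
        object.__setattr__(self, "components", comps)

    @classmethod
    def mono(cls, name: str, tau: float, relative_brightness: float = 1.0) -> "SpeciesModel":
        return cls(name=name, components=((tau, 1.0),),
                   relative_brightness=relative_brightness)

    @property
    def lifetimes(self) -> np.ndarray:
        return np.array([t for t, _ in self.components])

    @property
    def amplitude_fractions(self) -> np.ndarray:
        return np.array([a for _, a in self.components])


@dataclass
class TCSPCImage:
    """Per-pixel photon-count histograms for one spectral channel."""

    counts: np.ndarray  # (rows, cols, n_bins), nonnegative integers
    acq: AcquisitionConfig
    channel: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (rows, cols, n_bins)")
        if self.counts.shape[2] != self.acq.n_bins:
            raise ValueError(
                f"bin axis {self.counts.shape[2]} != acq.n_bins {self.acq.n_bins}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def intensity(self) -> np.ndarray:
        return self.counts.sum(axis=2)

    def pooled(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Summed histogram over a mask (whole image if None)."""
        if mask is None:
            return self.counts.sum(axis=(0, 1))
        return self.counts[np.asarray(mask, bool)].sum(axis=0)


# ---------------------------------------------------------------------------
# Decay forward model
# ---------------------------------------------------------------------------

def wrapped_exp_bin_masses(tau: float, period: float, n: int) -> np.ndarray:
    """Bin masses of the periodically wrapped exponential decay.

    Summing the geometric series of shifted exponentials over all previous
    periods gives, on [0, T), the density e^(-t/tau) / (tau (1 - e^(-T/tau))).
    The integral over bin [j*d, (j+1)*d) is returned; masses sum to 1.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    d = period / n
    edges = np.arange(n + 1) * d
    cdf = -np.expm1(-edges / tau)  # 1 - e^(-t/tau)
    masses = np.diff(cdf) / (-np.expm1(-period / tau))
    return masses


def _periodic_convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    fa = np.fft.rfft(a)
    fb = np.fft.rfft(b)
    return np.fft.irfft(fa * fb, n=a.size)


def decay_model(lifetimes: Sequence[float], amplitudes: Sequence[float],
                background: float, irf: IRF, acq: AcquisitionConfig,
                irf_shift: float = 0.0, oversample: int = 8) -> np.ndarray:
    """Expected per-bin counts: periodic IRF (x) multi-exponential + flat bg.

    ``amplitudes`` are in photons per component (total photons of component i
    over the whole histogram); ``background`` is photons per coarse bin.
    Computed on an oversampled grid and summed back down to the acquisition
    bins so that the discrete convolution tracks the continuous one.
    """
    m = acq.n_bins * oversample
    irf_fine = irf.discretize(acq, oversample=oversample, shift=irf_shift)
    fine = np.zeros(m)
    for tau, a in zip(lifetimes, amplitudes):
        fine += a * wrapped_exp_bin_masses(tau, acq.period, m)
    conv = _periodic_convolve(irf_fine, fine)
    coarse = conv.reshape(acq.n_bins, oversample).sum(axis=1)
    # FFT round-off can leave ~1e-18-level negative ringing
    return np.clip(coarse, 0.0, None) + background


def expected_decay(species: SpeciesModel, n_photons: float, irf: IRF,
                   acq: AcquisitionConfig, background: float = 0.0,
                   oversample: int = 8) -> np.ndarray:
    """Noiseless expected histogram for a species at a given photon budget."""
    amps = n_photons * species.amplitude_fractions
    return decay_model(species.lifetimes, amps, background, irf, acq,
                       oversample=oversample)


def wrapped_mean_arrival(tau: float, period: float) -> float:
    """Mean of the wrapped exponential on [0, T).

    E[t mod T] = tau - T e^(-T/tau) / (1 - e^(-T/tau)); strictly below tau,
    which is the bounded bias a recorded-histogram mean arrival time carries.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    q = np.exp(-period / tau)
    return tau - period * q / (1.0 - q)


def unwrap_mean_arrival(mean_obs: float, period: float) -> float:
    """Invert the wrapped-exponential mean: recover tau from a recorded mean.

    Applies the wrap correction so that a mono-exponential's corrected mean
    arrival time equals its lifetime. For mixtures the correction is only
    approximate (the map is nonlinear) but small at 12.5 ns periods.
    """
    if not 0 < mean_obs < period / 2:
        raise ValueError(
            f"recorded mean {mean_obs} outside invertible range (0, {period / 2})")
    # wrapped mean is strictly increasing in tau, -> period/2 as tau -> inf
    lo, hi = 1e-6, period
    while wrapped_mean_arrival(hi, period) < mean_obs:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("recorded mean too close to period/2 to invert")
    return float(brentq(lambda t: wrapped_mean_arrival(t, period) - mean_obs, lo, hi,
                        xtol=1e-12))


def expected_mean_arrival(tau: float, irf: IRF, acq: AcquisitionConfig,
                          oversample: int = 8) -> float:
    """Expected recorded mean arrival time (ns, IRF-centroid-corrected) of a
    mono-exponential decay, including both the decay's periodic wrap and the
    wrap of the IRF-shifted tail. Strictly increasing in tau."""
    h = decay_model([tau], [1.0], 0.0, irf, acq, oversample=oversample)
    t = acq.bin_centers
    return float(np.sum(h * t) / np.sum(h)) - irf.centroid_on(acq)


def lifetime_from_mean_arrival(mean_obs: float, irf: IRF,
                               acq: AcquisitionConfig) -> float:
    """Invert `expected_mean_arrival`: the lifetime whose recorded mean
    arrival time equals ``mean_obs``. Exact for mono-exponential pixels;
    for mixtures the result is a nonlinearly weighted effective lifetime."""
    f = lambda tau: expected_mean_arrival(tau, irf, acq) - mean_obs
    lo, hi = 1e-4, acq.period
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"recorded mean {mean_obs} ns outside the invertible "
                         f"range ({expected_mean_arrival(lo, irf, acq):.3f}, "
                         f"{expected_mean_arrival(hi, irf, acq):.3f})")
    return float(brentq(f, lo, hi, xtol=1e-10))


def sample_arrival_times(species: SpeciesModel, n_photons: int, irf: IRF,
                         acq: AcquisitionConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw photon arrival times: exponential delay + IRF jitter, mod period."""
    if n_photons < 0:
        raise ValueError("n_photons must be >= 0")
    if n_photons == 0:
        return np.empty(0)
    taus = species.lifetimes
    fracs = species.amplitude_fractions
    if len(taus) == 1:
        t = rng.exponential(taus[0], size=n_photons)
    else:
        comp = rng.choice(len(taus), size=n_photons, p=fracs)
        t = rng.exponential(1.0, size=n_photons) * taus[comp]
    if irf.kind == "gaussian":
        t += rng.normal(irf.center, irf.sigma, size=n_photons)
    elif irf.kind == "delta":
        t += irf.center
    else:  # measured: sample a bin per the curve, uniform within the bin
        bins = rng.choice(acq.n_bins, size=n_photons, p=irf.curve)
        t += (bins + rng.random(n_photons)) * acq.bin_width
    return np.mod(t, acq.period)


def histogram_times(times: np.ndarray, acq: AcquisitionConfig) -> np.ndarray:
    """Bin arrival times into the acquisition's time bins (counts conserve)."""
    idx = np.clip((times / acq.bin_width).astype(np.intp), 0, acq.n_bins - 1)
    return np.bincount(idx, minlength=acq.n_bins).astype(np.int64)
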