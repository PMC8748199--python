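"""n-exponential reconvolution fitting of pooled TCSPC decays.

The model is the periodic convolution of sum_i a_i exp(-t/tau_i) with the
IRF plus a flat background, fitted by weighted (Pearson) least squares with
model-based variances floored at one count. Model order is selected by
increasing n until the reduced chi-square drops below a threshold
(default 1.2, the criterion used for lifetime determination).

Per-pixel fitting is deliberately not offered: pixel-level analysis goes
through the phasor route, fitting is for pooled/ROI decays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import AcquisitionConfig, IRF, decay_model, unwrap_mean_arrival

__all__ = ["DecayFitResult", "fit_reconvolution", "select_model", "mean_lifetime"]

MIN_COUNTS = 100
_TAU_BOUNDS = (0.01, 100.0)
_SHIFT_BOUND = 2.0  # ns


@dataclass
class DecayFitResult:
    n_components: int
    lifetimes: np.ndarray          # ns, sorted ascending
    amplitudes: np.ndarray         # photons per component, matching order
    irf_shift: float               # ns
    background: float              # photons per bin
    chi2_reduced: float
    mean_lifetime_intensity_weighted: float
    mean_lifetime_amplitude_weighted: float
    n_photons: int
    converged: bool
    threshold_met: bool = True     # set by select_model


def _mean_lifetimes(taus: np.ndarray, amps: np.ndarray) -> tuple[float, float]:
    a = np.clip(amps, 0, None)
    if a.sum() <= 0:
        return float("nan"), float("nan")
    amp_w = float(np.sum(a * taus) / np.sum(a))
    int_w = float(np.sum(a * taus ** 2) / np.sum(a * taus))
    return int_w, amp_w


def _initial_guess(decay: np.ndarray, irf: IRF, acq: AcquisitionConfig,
                   n_components: int) -> np.ndarray:
    total = float(decay.sum())
    bg0 = max(float(np.percentile(decay, 5)), 1e-3)
    t = acq.bin_centers
    signal = max(total - bg0 * acq.n_bins, total * 0.1)
    mean_t = float(np.sum(decay * t) / total) - irf.centroid_on(acq)
    try:
        tau0 = unwrap_mean_arrival(mean_t, acq.period)
    except ValueError:
        tau0 = 0.25 * acq.period
    tau0 = float(np.clip(tau0, 0.05, 0.8 * acq.period))
    spread = np.array([0.5, 1.0, 2.0])[:n_components]
    taus = np.clip(tau0 * spread, *_TAU_BOUNDS)
    amps = np.full(n_components, signal / n_components)
    return np.concatenate([taus, amps, [bg0, 0.0]])


def fit_reconvolution(decay: np.ndarray, irf: IRF, acq: AcquisitionConfig,
                      n_components: int = 1,
                      init: np.ndarray | None = None,
                      fit_shift: bool = True,
                      oversample: int = 8) -> DecayFitResult:
    """Weighted least-squares reconvolution fit of a pooled decay.

    Parameters are n lifetimes, n amplitudes (photons), a flat background
    (photons/bin, bounded >= 0) and an IRF time shift. Pearson weights come
    from the model counts, floored at one. Non-convergence is reported via
    the ``converged`` flag, not an exception.
    """
    decay = np.asarray(decay, float)
    if decay.ndim != 1 or decay.size != acq.n_bins:
        raise ValueError("decay must be a 1-D histogram with acq.n_bins bins")
    if not 1 <= n_components <= 3:
        raise ValueError("n_components must be 1, 2 or 3")
    total = float(decay.sum())
    if total < MIN_COUNTS:
        raise ValueError(
            f"refusing to fit {total:.0f} photons; need >= {MIN_COUNTS}")

    n = n_components
    p0 = np.asarray(init, float) if init is not None \
        else _initial_guess(decay, irf, acq, n)
    if p0.size != 2 * n + 2:
        raise ValueError(f"init must have {2 * n + 2} entries "
                         "(taus, amplitudes, background, irf_shift)")

    lo = np.concatenate([np.full(n, _TAU_BOUNDS[0]), np.zeros(n),
                         [0.0], [-_SHIFT_BOUND]])
    hi = np.concatenate([np.full(n, _TAU_BOUNDS[1]), np.full(n, np.inf),
                         [np.inf], [_SHIFT_BOUND]])
    if not fit_shift:
        lo[-1], hi[-1] = -1e-12, 1e-12
    p0 = np.clip(p0, lo + 1e-12, np.where(np.isinf(hi), p0, hi))

    def residuals(p: np.ndarray) -> np.ndarray:
        taus, amps = p[:n], p[n:2 * n]
        bg, shift = p[2 * n], p[2 * n + 1]
        model = decay_model(taus, amps, bg, irf, acq, irf_shift=shift,
                            oversample=oversample)
        w = np.sqrt(np.maximum(model, 1.0))
        return (model - decay) / w

    res = least_squares(residuals, p0, bounds=(lo, hi), method="trf",
                        ftol=1e-10, xtol=1e-12, gtol=1e-10,
                        max_nfev=500 * (p0.size + 1))
    converged = res.status > 0
    p = res.x
    taus, amps = p[:n], p[n:2 * n]
    order = np.argsort(taus)
    taus, amps = taus[order], amps[order]
    dof = acq.n_bins - p0.size
    chi2_red = float(2.0 * res.cost / dof)
    int_w, amp_w = _mean_lifetimes(taus, amps)
    return DecayFitResult(
        n_components=n, lifetimes=taus, amplitudes=amps,
        irf_shift=float(p[2 * n + 1]), background=float(p[2 * n]),
        chi2_reduced=chi2_red,
        mean_lifetime_intensity_weighted=int_w,
        mean_lifetime_amplitude_weighted=amp_w,
        n_photons=int(round(total)), converged=converged)


def select_model(decay: np.ndarray, irf: IRF, acq: AcquisitionConfig,
                 chi2_threshold: float = 1.2, **kwargs) -> DecayFitResult:
    """Fit n = 1, 2, 3 in turn; return the smallest model passing chi2_red
    below the threshold. If none passes, the n=3 fit is returned flagged
    (``threshold_met=False``)."""
    last = None
    for n in (1, 2, 3):
        fit = fit_reconvolution(decay, irf, acq, n_components=n, **kwargs)
        last = fit
        if fit.converged and fit.chi2_reduced < chi2_threshold:
            fit.threshold_met = True
            return fit
    last.threshold_met = False
    return last


def mean_lifetime(fit: DecayFitResult, weighting: str = "intensity") -> float:
    """Mean lifetime of a fit: amplitude weighting sum(a tau)/sum(a) or
    intensity weighting sum(a tau^2)/sum(a tau).

    Both conventions are computed because the weighting used by commercial
    FLIM software is not standardized; intensity weighting is the default.
    """
    if not fit.converged:
        raise ValueError("mean_lifetime requires a converged fit")
    if weighting == "intensity":
        return fit.mean_lifetime_intensity_weighted
    if weighting == "amplitude":
        return fit.mean_lifetime_amplitude_weighted
    raise ValueError("weighting must be 'intensity' or 'amplitude'")
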