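"""Photophysics and labeling-kinetics fits.

Covers the printed analysis suite around the imaging pipeline: the D50
sigmoid of open-closed dye titrations, mono-exponential labeling kinetics
and the apparent second-order rate constant, the two-step stopped-flow
binding scheme P + S <-> PS* -> PS with Monte-Carlo confidence intervals,
extinction-coefficient regression, FCS molecular brightness, Gaussian line
profiles with FWHM, the relative-brightness statistic Delta-I with its
one-sided pooled t-test, plate-screening selection rules, and photobleaching
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "KineticTrace",
    "TwoStepFit",
    "ScreenWell",
    "MonteCarloCI",
    "two_step_progress",
    "fit_sigmoid_d50",
    "fit_monoexp_kapp",
    "fit_two_step",
    "monte_carlo_ci",
    "two_step_monte_carlo",
    "fit_extinction",
    "molecular_brightness",
    "gaussian_fwhm",
    "delta_I",
    "screen_select",
    "bleach_normalize",
]


@dataclass
class KineticTrace:
    """One stopped-flow anisotropy trace (times in s, after dead time)."""

    times: np.ndarray
    values: np.ndarray
    conc_protein: float   # M
    conc_substrate: float  # M
    dead_time: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.conc_protein <= 0 or self.conc_substrate <= 0:
            raise ValueError("concentrations must be positive")


def two_step_progress(times: np.ndarray, k1: float, k_minus1: float,
                      k2: float, P0: float, S0: float
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concentrations ([S], [PS*], [PS]) of P + S <-> PS* -> PS over time.

    Integrated from mixing at t = 0 in substrate-normalized units for
    numerical conditioning; conservation gives [P] = P0 - S0 + [S] + ...
    handled implicitly. Stiff-capable integrator (LSODA).
    """
    times = np.asarray(times, float)
    if S0 <= 0:
        z = np.zeros_like(times)
        return z, z, z

    # scaled states: s = S/S0, ps = PS*/S0; p = P/S0 (free protein)
    p0 = P0 / S0
    a = k1 * S0

    def rhs(t, y):
        s, ps = y
        p = p0 - (1.0 - s)  # bound substrate equals bound protein
        return [-a * p * s + k_minus1 * ps,
                a * p * s - (k_minus1 + k2) * ps]

    t_end = float(times[-1]) if times.size else 0.0
    t_eval = times
    prepend = times.size == 0 or times[0] > 0
    if prepend:
        t_eval = np.concatenate([[0.0], times])
    sol = solve_ivp(rhs, (0.0, max(t_end, 1e-12)), [1.0, 0.0],
                    t_eval=t_eval, method="LSODA", rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    s, ps = sol.y
    if prepend:
        s, ps = s[1:], ps[1:]
    S = np.clip(s, 0, None) * S0
    PSstar = np.clip(ps, 0, None) * S0
    PS = np.clip(S0 - S - PSstar, 0, None)
    return S, PSstar, PS


# ---------------------------------------------------------------------------
# Simple closed-form fits
# ---------------------------------------------------------------------------

@dataclass
class SigmoidFit:
    a: float
    k: float
    x_c: float
    converged: bool
    residual_sd: float

    @property
    def d50(self) -> float:
        return self.x_c


def _sigmoid(x, a, k, x_c):
    return a / (1.0 + np.exp(-k * (x - x_c)))


def fit_sigmoid_d50(x: np.ndarray, y: np.ndarray) -> SigmoidFit:
    """Least-squares sigmoid y = a / (1 + e^(-k(x - x_c))); D50 = x_c."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 5:
        raise ValueError("need >= 5 points spanning the transition")
    a0 = float(y.max() - min(y.min(), 0))
    half = y.min() + 0.5 * (y.max() - y.min())
    x_c0 = float(x[np.argmin(np.abs(y - half))])
    span = max(np.ptp(x), 1e-9)
    k0 = np.sign(np.polyfit(x, y, 1)[0] or 1.0) * 4.0 / span
    try:
        popt, _ = curve_fit(_sigmoid, x, y, p0=[a0, k0, x_c0], maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = [a0, k0, x_c0], False
    resid = y - _sigmoid(x, *popt)
    dof = max(x.size - 3, 1)
    return SigmoidFit(a=float(popt[0]), k=float(popt[1]), x_c=float(popt[2]),
                      converged=converged,
                      residual_sd=float(np.sqrt(np.sum(resid ** 2) / dof)))


@dataclass
class MonoExpFit:
    y0: float
    A: float
    tau: float
    k_app: float
    converged: bool


def fit_monoexp_kapp(times: np.ndarray, values: np.ndarray,
                     conc_protein: float) -> MonoExpFit:
    """Labeling time course y = y0 + A e^(-(x - x0)/tau) with x0 = first
    time point; apparent second-order rate k_app = 1 / (tau [P]0)."""
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if conc_protein <= 0:
        raise ValueError("conc_protein must be > 0")
    x0 = t[0]

    def model(x, y0, A, tau):
        return y0 + A * np.exp(-(x - x0) / tau)

    tau0 = max((t[-1] - t[0]) / 3.0, 1e-9)
    try:
        popt, _ = curve_fit(model, t, y,
                            p0=[y[-1], y[0] - y[-1], tau0], maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = [y[-1], y[0] - y[-1], tau0], False
    y0_, A_, tau_ = (float(v) for v in popt)
    flagged_ok = converged and tau_ > 0
    k_app = 1.0 / (tau_ * conc_protein) if tau_ > 0 else float("nan")
    return MonoExpFit(y0=y0_, A=A_, tau=tau_, k_app=k_app,
                      converged=flagged_ok)


# ---------------------------------------------------------------------------
# Two-step stopped-flow fit
# ---------------------------------------------------------------------------

@dataclass
class TwoStepFit:
    k1: float          # M^-1 s^-1
    k_minus1: float    # s^-1
    k2: float          # s^-1
    r_free: float
    r_bound: float
    converged: bool
    cost: float
    traces: list[KineticTrace] = field(default_factory=list, repr=False)
    ci_95: dict[str, tuple[float, float]] | None = None
    mc_draws: int = 0
    identifiable: bool | None = None

    # K_D and k_app are recomputed from the rates on every access so the
    # dissociation-constant and apparent-rate identities can never drift.
    @property
    def K_D(self) -> float:
        return self.k_minus1 / self.k1

    @property
    def k_app(self) -> float:
        return self.k1 * self.k2 / (self.k2 + self.k_minus1)

    def predict(self, trace: KineticTrace) -> np.ndarray:
        S, PSs, PS = two_step_progress(trace.times, self.k1, self.k_minus1,
                                       self.k2, trace.conc_protein,
                                       trace.conc_substrate)
        return (self.r_free * S + self.r_bound * (PSs + PS)) / trace.conc_substrate


_LOGK_BOUNDS = ((2.0, 9.0), (-4.0, 5.0), (-4.0, 5.0))  # log10 k1, k-1, k2


def _two_step_multi(times: np.ndarray, k1: float, km1: float, k2: float,
                    P0s: np.ndarray, S0s: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Substrate and intermediate fractions for several traces sharing one
    time grid, integrated as a single stacked system (one solver call)."""
    n = S0s.size
    p0 = P0s / S0s
    a = k1 * S0s

    def rhs(t, y):
        s, ps = y[:n], y[n:]
        p = p0 - (1.0 - s)
        flux = a * p * s
        return np.concatenate([-flux + km1 * ps, flux - (km1 + k2) * ps])

    t_eval = times
    prepend = times[0] > 0
    if prepend:
        t_eval = np.concatenate([[0.0], times])
    sol = solve_ivp(rhs, (0.0, float(times[-1])),
                    np.concatenate([np.ones(n), np.zeros(n)]),
                    t_eval=t_eval, method="LSODA", rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = sol.y[:, 1:] if prepend else sol.y
    return y[:n], y[n:]  # s, ps fractions, each (n, n_times)


def _two_step_residuals(p, traces, values_list):
    k1, km1, k2 = 10.0 ** p[0], 10.0 ** p[1], 10.0 ** p[2]
    r_free, r_bound = p[3], p[4]
    shared = all(t.times.size == traces[0].times.size and
                 np.array_equal(t.times, traces[0].times) for t in traces[1:])
    if shared and len(traces) > 1:
        S0s = np.array([t.conc_substrate for t in traces])
        P0s = np.array([t.conc_protein for t in traces])
        s, ps = _two_step_multi(traces[0].times, k1, km1, k2, P0s, S0s)
        s = np.clip(s, 0, None)
        bound = np.clip(1.0 - s, 0, None)
        model = r_free * s + r_bound * bound  # fractions of S0 cancel
        return np.concatenate([m - v for m, v in zip(model, values_list)])
    out = []
    for trace, vals in zip(traces, values_list):
        S, PSs, PS = two_step_progress(trace.times, k1, km1, k2,
                                       trace.conc_protein,
                                       trace.conc_substrate)
        model = (r_free * S + r_bound * (PSs + PS)) / trace.conc_substrate
        out.append(model - vals)
    return np.concatenate(out)


def fit_two_step(traces: list[KineticTrace],
                 init: dict[str, float] | None = None) -> TwoStepFit:
    """Global ODE least-squares fit of the two-step scheme over all traces.

    Rate constants are fitted in log10 space (bounded); the free and bound
    anisotropy endpoints are shared free parameters. Traces at several
    substrate concentrations are needed for identifiability; a single
    concentration still fits but its Monte-Carlo intervals will flag it.
    """
    if not traces:
        raise ValueError("need at least one trace")
    values_list = [t.values for t in traces]
    init = init or {}
    vmin = min(v.min() for v in values_list)
    vmax = max(v.max() for v in values_list)
    p0 = np.array([
        np.log10(init.get("k1", 1e5)),
        np.log10(init.get("k_minus1", 1.0)),
        np.log10(init.get("k2", 1.0)),
        init.get("r_free", vmin),
        init.get("r_bound", vmax),
    ])
    lo = np.array([b[0] for b in _LOGK_BOUNDS] + [-1.0, -1.0])
    hi = np.array([b[1] for b in _LOGK_BOUNDS] + [1.0, 1.0])
    res = least_squares(_two_step_residuals, np.clip(p0, lo, hi),
                        args=(traces, values_list), bounds=(lo, hi),
                        method="trf", ftol=1e-12, xtol=1e-12,
                        max_nfev=3000, x_scale=[1, 1, 1, 0.1, 0.1])
    p = res.x
    return TwoStepFit(k1=10.0 ** p[0], k_minus1=10.0 ** p[1], k2=10.0 ** p[2],
                      r_free=float(p[3]), r_bound=float(p[4]),
                      converged=res.status > 0, cost=float(res.cost),
                      traces=list(traces))


# ---------------------------------------------------------------------------
# Monte-Carlo confidence intervals
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloCI:
    intervals: dict[str, tuple[float, float]]
    draws: pd.DataFrame
    n_kept: int
    n_failed: int
    noise_sd: float
    normality_p: dict[str, float]


def monte_carlo_ci(refit, fitted_y: np.ndarray, residuals: np.ndarray,
                   param_names: list[str], n_draws: int = 1000,
                   discard_frac: float = 0.05, seed: int = 0,
                   mode: str = "parametric",
                   n_fit_params: int | None = None) -> MonteCarloCI:
    """Monte-Carlo parameter intervals for any least-squares fit.

    ``refit(y) -> (params, cost)`` refits the model to perturbed data.
    Parametric mode redraws Gaussian noise with the SD estimated from the
    base-fit residuals; residual mode resamples the residuals themselves.
    The worst ``discard_frac`` of refits by cost are discarded before taking
    2.5/97.5 percentile intervals. Normality of the kept draws is reported
    (Shapiro-Wilk p per parameter).
    """
    if mode not in ("parametric", "residual"):
        raise ValueError("mode must be 'parametric' or 'residual'")
    rng = np.random.default_rng(seed)
    fitted_y = np.asarray(fitted_y, float)
    residuals = np.asarray(residuals, float)
    ddof = n_fit_params if n_fit_params is not None else len(param_names)
    dof = max(residuals.size - ddof, 1)
    sd = float(np.sqrt(np.sum(residuals ** 2) / dof)) if residuals.size > 1 else 0.0
    rows, costs = [], []
    n_failed = 0
    for _ in range(n_draws):
        if mode == "parametric":
            y = fitted_y + rng.normal(0.0, sd, size=fitted_y.shape)
        else:
            y = fitted_y + rng.choice(residuals, size=fitted_y.shape,
                                      replace=True)
        try:
            params, cost = refit(y)
        except Exception:
            n_failed += 1
            continue
        rows.append(np.asarray(params, float))
        costs.append(cost)
    if n_failed > 0.2 * n_draws:
        raise RuntimeError(
            f"{n_failed}/{n_draws} Monte-Carlo refits failed (> 20%)")
    draws = np.array(rows)
    costs = np.array(costs)
    n_keep = max(1, int(np.ceil(len(rows) * (1.0 - discard_frac))))
    keep = np.argsort(costs)[:n_keep]
    kept = draws[keep]
    intervals, normality = {}, {}
    for j, name in enumerate(param_names):
        col = kept[:, j]
        intervals[name] = (float(np.percentile(col, 2.5)),
                           float(np.percentile(col, 97.5)))
        if col.size >= 3 and np.ptp(col) > 0:
            normality[name] = float(stats.shapiro(col).pvalue)
        else:
            normality[name] = float("nan")
    return MonteCarloCI(intervals=intervals,
                        draws=pd.DataFrame(kept, columns=param_names),
                        n_kept=n_keep, n_failed=n_failed, noise_sd=sd,
                        normality_p=normality)


def two_step_monte_carlo(fit: TwoStepFit, n_draws: int = 1000,
                         discard_frac: float = 0.05, seed: int = 0,
                         mode: str = "parametric") -> TwoStepFit:
    """Attach Monte-Carlo 95% intervals (k1, k_minus1, k2, K_D, k_app) to a
    two-step fit; flags non-identifiability when a rate interval spans more
    than two orders of magnitude."""
    traces = fit.traces
    if not traces:
        raise ValueError("fit carries no traces to resample")
    fitted = np.concatenate([fit.predict(t) for t in traces])
    data = np.concatenate([t.values for t in traces])
    residuals = data - fitted
    sizes = [t.times.size for t in traces]
    splits = np.cumsum(sizes)[:-1]

    def refit(y):
        ys = np.split(y, splits)
        new_traces = [KineticTrace(t.times, yv, t.conc_protein,
                                   t.conc_substrate, t.dead_time)
                      for t, yv in zip(traces, ys)]
        f = fit_two_step(new_traces, init={"k1": fit.k1,
                                           "k_minus1": fit.k_minus1,
                                           "k2": fit.k2,
                                           "r_free": fit.r_free,
                                           "r_bound": fit.r_bound})
        return ([f.k1, f.k_minus1, f.k2, f.K_D, f.k_app], f.cost)

    names = ["k1", "k_minus1", "k2", "K_D", "k_app"]
    mc = monte_carlo_ci(refit, fitted, residuals, names, n_draws=n_draws,
                        discard_frac=discard_frac, seed=seed, mode=mode)
    fit.ci_95 = mc.intervals
    fit.mc_draws = mc.n_kept
    spans = []
    for name in ("k1", "k_minus1", "k2"):
        lo, hi = mc.intervals[name]
        spans.append(hi / lo if lo > 0 else np.inf)
    fit.identifiable = bool(max(spans) < 100.0)
    return fit


# ---------------------------------------------------------------------------
# Extinction, brightness, FWHM
# ---------------------------------------------------------------------------

@dataclass
class ExtinctionFit:
    a: float        # intercept
    b: float        # slope, absorbance per M
    epsilon: float  # M^-1 cm^-1


def fit_extinction(conc: np.ndarray, absorbance: np.ndarray,
                   path_cm: float = 1.0) -> ExtinctionFit:
    """OLS line through absorbance vs concentration (M); epsilon from the
    slope assuming the given path length (1 cm default)."""
    x = np.asarray(conc, float)
    y = np.asarray(absorbance, float)
    if x.size < 3:
        raise ValueError("need >= 3 concentrations")
    if np.ptp(x) == 0:
        raise ValueError("concentrations have zero variance")
    lr = stats.linregress(x, y)
    return ExtinctionFit(a=float(lr.intercept), b=float(lr.slope),
                         epsilon=float(lr.slope) / path_cm)


def molecular_brightness(G0: float, photon_counts: float) -> float:
    """FCS molecular brightness mB = G(0) x mean photon counts (Hz/molecule)."""
    if G0 <= 0:
        raise ValueError("G0 must be > 0")
    if photon_counts < 0:
        raise ValueError("photon_counts must be >= 0")
    return G0 * photon_counts


@dataclass
class GaussianProfileFit:
    y0: float
    A: float
    w: float
    x_c: float
    converged: bool

    @property
    def fwhm(self) -> float:
        return self.w * np.sqrt(2.0 * np.log(2.0))


def _gauss_profile(x, y0, A, w, x_c):
    return y0 + A / (w * np.sqrt(np.pi / 2.0)) * np.exp(-2.0 * (x - x_c) ** 2 / w ** 2)


def gaussian_fwhm(positions: np.ndarray, values: np.ndarray
                  ) -> GaussianProfileFit:
    """Gaussian line-profile fit; FWHM = w sqrt(2 ln 2)."""
    x = np.asarray(positions, float)
    y = np.asarray(values, float)
    if x.size < 7:
        raise ValueError("need >= 7 points across the peak")
    y0_0 = float(y.min())
    x_c0 = float(x[np.argmax(y)])
    w0 = max(np.ptp(x) / 6.0, 1e-9)
    A0 = float((y.max() - y0_0) * w0 * np.sqrt(np.pi / 2.0))
    try:
        popt, _ = curve_fit(_gauss_profile, x, y, p0=[y0_0, A0, w0, x_c0],
                            maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = [y0_0, A0, w0, x_c0], False
    return GaussianProfileFit(y0=float(popt[0]), A=float(popt[1]),
                              w=abs(float(popt[2])), x_c=float(popt[3]),
                              converged=converged)


# ---------------------------------------------------------------------------
# Screening statistics
# ---------------------------------------------------------------------------

def delta_I(i_variant: np.ndarray, i_parent: np.ndarray
            ) -> tuple[float, float]:
    """Relative brightness change (I_var - I_par)/I_par and the one-sided
    pooled-variance t-test p value in the direction of the observed change
    (df = n1 + n2 - 2; triplicates give df = 4)."""
    v = np.asarray(i_variant, float)
    p = np.asarray(i_parent, float)
    if v.size < 2 or p.size < 2:
        raise ValueError("need >= 2 replicates per group")
    mp = p.mean()
    if mp == 0:
        raise ValueError("parent mean intensity is zero")
    d_i = (v.mean() - mp) / mp
    df = v.size + p.size - 2
    sp2 = ((v.size - 1) * v.var(ddof=1) + (p.size - 1) * p.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / v.size + 1.0 / p.size))
    if se == 0:
        pval = 0.5 if v.mean() == mp else 0.0
    else:
        tstat = (v.mean() - mp) / se
        pval = float(stats.t.sf(abs(tstat), df))
    return float(d_i), pval


@dataclass(frozen=True)
class ScreenWell:
    well: str
    gfp_intensity: float
    sir_intensity: float
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.gfp_intensity < 0 or self.sir_intensity < 0:
            raise ValueError("intensities must be >= 0")


def screen_select(wells: list[ScreenWell], round: str = "1"
                  ) -> tuple[list[ScreenWell], pd.DataFrame]:
    """Plate-screen selection: wells with GFP below 10% of the control mean
    are discarded (expression too low); remaining wells are selected when
    their SiR intensity falls outside control mean +/- k s.d. (k = 3 in the
    first round, 2 afterwards). Reports the direction of the change."""
    k = 3.0 if str(round) == "1" else 2.0
    controls = [w for w in wells if w.is_control]
    if len(controls) < 2:
        raise ValueError("need >= 2 control wells")
    gfp_mean = float(np.mean([w.gfp_intensity for w in controls]))
    sir = np.array([w.sir_intensity for w in controls])
    sir_mean, sir_sd = float(sir.mean()), float(sir.std(ddof=1))
    rows, selected = [], []
    for w in wells:
        if w.is_control:
            continue
        gfp_ok = w.gfp_intensity >= 0.1 * gfp_mean
        direction = ""
        sel = False
        if gfp_ok:
            if w.sir_intensity > sir_mean + k * sir_sd:
                sel, direction = True, "brighter"
            elif w.sir_intensity < sir_mean - k * sir_sd:
                sel, direction = True, "dimmer"
        if sel:
            selected.append(w)
        rows.append({"well": w.well, "gfp_ok": gfp_ok, "selected": sel,
                     "direction": direction,
                     "sir_intensity": w.sir_intensity})
    report = pd.DataFrame(rows, columns=["well", "gfp_ok", "selected",
                                         "direction", "sir_intensity"])
    return selected, report


def bleach_normalize(roi_means: np.ndarray | pd.DataFrame
                     ) -> np.ndarray | pd.DataFrame:
    """Normalize each ROI time series to its value at t0."""
    if isinstance(roi_means, pd.DataFrame):
        first = roi_means.iloc[0]
        zero = first[first == 0]
        if len(zero):
            raise ValueError(f"ROI(s) {list(zero.index)} have zero t0 intensity")
        return roi_means / first
    arr = np.asarray(roi_means, float)
    series = np.atleast_2d(arr)
    t0 = series[:, 0]
    if np.any(t0 == 0):
        bad = np.flatnonzero(t0 == 0)
        raise ValueError(f"ROI index(es) {bad.tolist()} have zero t0 intensity")
    out = series / t0[:, None]
    return out.reshape(arr.shape)
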