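"""Stochastic Adler dynamics of the interflagellar phase difference.

The phase difference Delta(t) (in beats) between two noisy coupled
oscillators follows Brownian motion in a tilted washboard potential:

    dDelta/dt = delta_nu - 2 pi eps sin(2 pi Delta) + xi(t),
    <xi(t) xi(t')> = 2 T_eff delta(t - t'),

where delta_nu (1/s) is the intrinsic beat-frequency difference, eps (1/s)
the hydrodynamic coupling strength (eps > 0 favours in-phase locking at
Delta0 ~ 0, eps < 0 antiphase at Delta0 ~ 1/2) and T_eff an effective
temperature representing intraflagellar biochemical noise.  The
dimensionless coupling is kappa = eps / omega_bar, and hydrodynamics
predicts |kappa| = k / L with L the flagellum-length-scaled separation.

This module simulates the equation (Euler-Maruyama), predicts the
frequency-difference bifurcation with and without noise, and infers
(eps, delta_nu, T_eff) from a measured Delta(t) via the Ornstein-Uhlenbeck
statistics of locked-state fluctuations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import optimize
from statsmodels.tsa.stattools import acovf

__all__ = [
    "AdlerParams",
    "CouplingFit",
    "simulate_adler",
    "locked_fixed_point",
    "predicted_freq_diff",
    "noisy_freq_diff",
    "autocorrelation",
    "infer_params",
    "fit_coupling_law",
    "teff_from_periods",
]


@dataclass
class AdlerParams:
    """The stochastic-model triple (eps, delta_nu, T_eff) plus mean frequency.

    eps : coupling strength, 1/s (signed: >0 in-phase, <0 antiphase).
    delta_nu : intrinsic frequency difference, 1/s (beats/s).
    T_eff : effective temperature, 1/s (Delta measured in beats).
    omega_bar : mean beat frequency, Hz; used only for nondimensional
        reporting kappa = eps/omega_bar.
    """

    eps: float
    delta_nu: float
    T_eff: float
    omega_bar: float = 33.0

    def __post_init__(self) -> None:
        if self.T_eff < 0:
            raise ValueError("T_eff must be non-negative")
        if not self.omega_bar > 0:
            raise ValueError("omega_bar must be positive")

    @property
    def kappa(self) -> float:
        return self.eps / self.omega_bar

    @property
    def locked(self) -> bool:
        """Whether the noise-free dynamics has a fixed point (2 pi |eps| > |delta_nu|)."""
        return 2 * math.pi * abs(self.eps) > abs(self.delta_nu)


def locked_fixed_point(params: AdlerParams) -> float:
    """Stable zero of the deterministic drift, in beats.

    For eps > 0 the minimum sits near Delta = 0, displaced by the detuning:
    Delta0 = arcsin(delta_nu / 2 pi eps) / 2 pi.  For eps < 0 it sits near
    Delta = 1/2.  Raises if the dynamics is past the bifurcation.
    """
    if not params.locked:
        raise ValueError("no fixed point: 2 pi |eps| <= |delta_nu| (drifting regime)")
    x = params.delta_nu / (2 * math.pi * params.eps)
    base = math.asin(x) / (2 * math.pi)
    if params.eps > 0:
        return base
    return 0.5 - base


@njit(cache=True)
def _em_loop(delta0: float, drift: float, two_pi_eps: float, sqrt2Tdt: float,
             dt: float, n_steps: int, stride: int, noise: np.ndarray,
             out: np.ndarray) -> None:  # pragma: no cover - jitted
    d = delta0
    out[0] = d
    j = 1
    for i in range(n_steps):
        d += (drift - two_pi_eps * math.sin(2 * math.pi * d)) * dt + sqrt2Tdt * noise[i]
        if (i + 1) % stride == 0:
            out[j] = d
            j += 1


def simulate_adler(params: AdlerParams, delta0: float = 0.0, dt: float = 1e-4,
                   duration: float = 10.0, seed: int | np.random.Generator = 0,
                   sample_every: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama integration of the stochastic Adler equation.

    Delta_{n+1} = Delta_n + (delta_nu - 2 pi eps sin 2 pi Delta_n) dt
                  + sqrt(2 T_eff dt) N(0, 1).

    Parameters
    ----------
    delta0 : initial phase difference, beats.
    dt : step, s.  Rejected if it fails the explicit-Euler stability margin
        dt < 0.1 / max(|delta_nu|, 4 pi^2 |eps|).
    sample_every : keep every k-th step (the integration still runs at dt).

    Returns
    -------
    (t, Delta) arrays; Delta unwrapped (winding kept).
    """
    rate = max(abs(params.delta_nu), 4 * math.pi**2 * abs(params.eps), 1e-300)
    if dt > 0.1 / rate:
        raise ValueError(f"dt={dt} unstable; need dt <= {0.1 / rate:.3g} "
                         "(0.1 / max(|delta_nu|, 4 pi^2 |eps|))")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    n_steps -= n_steps % sample_every
    noise = rng.standard_normal(n_steps) if params.T_eff > 0 else np.zeros(n_steps)
    out = np.empty(n_steps // sample_every + 1)
    _em_loop(float(delta0), params.delta_nu, 2 * math.pi * params.eps,
             math.sqrt(2 * params.T_eff * dt), dt, n_steps, sample_every,
             noise, out)
    t = np.arange(len(out)) * (dt * sample_every)
    return t, out


def predicted_freq_diff(eps: float, delta_nu: float) -> float:
    """Noise-free observed-to-intrinsic frequency-difference ratio.

    The deterministic Adler equation runs at the mean rate
    sqrt(delta_nu^2 - (2 pi eps)^2) beyond the bifurcation and locks
    (zero observed difference) inside it:

        dw/dw_far = sqrt(1 - (2 pi eps / delta_nu)^2)   if 2 pi |eps| < |delta_nu|
                  = 0                                    otherwise.
    """
    if delta_nu == 0:
        raise ValueError("delta_nu must be nonzero")
    x = 2 * math.pi * eps / delta_nu
    if abs(x) >= 1:
        return 0.0
    return math.sqrt(1 - x * x)


def noisy_freq_diff(params: AdlerParams, duration: float = 100.0,
                    seeds: range | list[int] = range(10), dt: float = 1e-4,
                    ) -> tuple[float, float]:
    """Observed frequency-difference ratio in the presence of noise.

    Runs seeded simulations and measures the net drift rate
    (Delta(end) - Delta(0)) / duration, normalised by delta_nu.  Noise
    rounds the sharp deterministic bifurcation: phase slips give a nonzero
    ratio even inside the locked regime.

    Returns (mean ratio, standard error over seeds).
    """
    vals = []
    for s in seeds:
        _, d = simulate_adler(params, delta0=0.0, dt=dt, duration=duration,
                              seed=s, sample_every=max(1, int(round(0.01 / dt))))
        vals.append((d[-1] - d[0]) / duration / params.delta_nu)
    vals = np.asarray(vals)
    sem = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
    return float(vals.mean()), float(sem)


def autocorrelation(x: np.ndarray, dt: float, max_lag: float | None = None
                    ) -> dict:
    """Autocovariance of locked-state fluctuations and its exponential fit.

    Computes the biased autocovariance estimator C(tau) and fits
    C(tau) = C0 exp(-tau / tau_r) over an iterated window tau in
    [0, 3 tau_r] (the window is re-chosen from the current tau_r estimate
    until stable).  For an Ornstein-Uhlenbeck process with relaxation rate
    r and <xi xi'> = 2 D delta, C0 = D/r and tau_r = 1/r.

    Returns dict with ``lags``, ``C``, ``C0``, ``tau_r``, ``ok`` (False when
    C(tau) does not decay, e.g. white noise resolves tau_r at the sampling
    interval).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 samples")
    nlag = n - 1 if max_lag is None else min(n - 1, int(max_lag / dt))
    C = acovf(x - x.mean(), adjusted=False, nlag=nlag, fft=True)
    lags = np.arange(len(C)) * dt

    # initial tau_r from the first crossing of C0/e
    C0 = C[0]
    below = np.nonzero(C < C0 / math.e)[0]
    tau_r = lags[below[0]] if len(below) else lags[-1] / 3
    ok = True
    if tau_r <= dt:
        tau_r = dt
        ok = False
    for _ in range(6):
        win = lags <= 3 * tau_r
        if win.sum() < 5:
            win = np.arange(len(lags)) < 5
        try:
            popt, _ = optimize.curve_fit(
                lambda tau, c0, tr: c0 * np.exp(-tau / tr),
                lags[win], C[win], p0=[C0, max(tau_r, dt)],
                maxfev=10000)
        except RuntimeError:
            ok = False
            break
        new_tau = abs(popt[1])
        if abs(new_tau - tau_r) < 0.01 * tau_r:
            tau_r, C0 = new_tau, popt[0]
            break
        tau_r, C0 = new_tau, popt[0]
    if C0 <= 0 or tau_r <= dt:
        ok = False
    return {"lags": lags, "C": C, "C0": float(C0), "tau_r": float(tau_r), "ok": ok}


def infer_params(pair, orientation: str | None = None,
                 hold: float | None = None) -> AdlerParams:
    """Infer (eps, delta_nu, T_eff) from a phase-difference time series.

    Three steps, all restricted to phase-locked segments of Delta(t):

    1. **T_eff from increments.**  The noise term is additive, so the
       one-sample increments of Delta satisfy
       Var(dDelta) = 2 T_eff dt + O(dt^2) regardless of where in the
       potential well the system sits; T_eff = Var(dDelta)/(2 dt), with
       increments taken within segments only (never across a slip).
    2. **(eps, delta_nu) from stationary moments.**  Ito's lemma applied
       to cos(2 pi Delta) and sin(2 pi Delta) in the stationary locked
       state gives two exact linear identities in the unknowns,

           delta_nu E[sin] - 2 pi eps E[sin^2]    = -2 pi T_eff E[cos],
           delta_nu E[cos] - 2 pi eps E[sin cos]  =  2 pi T_eff E[sin],

       (arguments 2 pi Delta throughout) which are solved with the
       empirical moments.  Unlike an Ornstein-Uhlenbeck linearization
       about the well minimum, these identities carry no small-amplitude
       bias from the anharmonicity of the washboard potential; the sign
       of eps (in-phase vs antiphase) comes out of the solve.
    3. A series that never locks cannot resolve eps: the returned params
       carry eps = 0, T_eff = 0 and the raw drift rate as delta_nu.

    Parameters
    ----------
    pair : :class:`flagsync.phase.PhasePairSeries`
    orientation : "IP" or "AP"; defaults to the pair's own tag.  Used only
        as a fallback sign when the moment system is degenerate.
    """
    from .phase import detect_locked

    orientation = orientation or getattr(pair, "orientation", "IP")
    if orientation not in ("IP", "AP"):
        raise ValueError("orientation must be 'IP' or 'AP'")
    omega_bar = 0.5 * (pair.phase1.mean_frequency() + pair.phase2.mean_frequency())
    kwargs = {} if hold is None else {"hold": hold}
    stats = detect_locked(pair, **kwargs)
    # a steadily drifting Delta also produces winding plateaus; its pooled
    # "residuals" are near-uniform on the unit cell (std ~ 0.29), far above
    # any locked state's fluctuation scale
    drifting = stats.locked_residuals.std() > 0.2
    if not stats.segments or stats.n_locked_samples < 200 or drifting:
        drift = (pair.delta[-1] - pair.delta[0]) / (pair.t[-1] - pair.t[0])
        return AdlerParams(eps=0.0, delta_nu=float(drift), T_eff=0.0,
                           omega_bar=omega_bar)
    t = pair.t
    delta = pair.delta
    dt = float(t[1] - t[0])
    incs = []
    segs = []
    for t0, t1 in stats.segments:
        i0 = int(np.searchsorted(t, t0))
        i1 = int(np.searchsorted(t, t1))
        seg = delta[i0:i1 + 1]
        if len(seg) > 1:
            incs.append(np.diff(seg))
            segs.append(seg)
    incs = np.concatenate(incs)
    T_eff = float(incs.var() / (2 * dt))

    theta = 2 * math.pi * np.concatenate(segs)  # sin/cos are winding-blind
    s, c = np.sin(theta), np.cos(theta)
    A = np.array([[s.mean(), -np.mean(s * s)],
                  [c.mean(), -np.mean(s * c)]])
    b = np.array([-2 * math.pi * T_eff * c.mean(),
                  2 * math.pi * T_eff * s.mean()])
    try:
        delta_nu, two_pi_eps = np.linalg.solve(A, b)
        eps = float(two_pi_eps) / (2 * math.pi)
        delta_nu = float(delta_nu)
    except np.linalg.LinAlgError:
        # degenerate moments: fall back to the OU linearization about the
        # pooled lock point
        ac = autocorrelation(stats.locked_residuals, dt,
                             max_lag=min(1.0, 0.25 * stats.n_locked_samples * dt))
        r = 1.0 / ac["tau_r"]
        delta_min = 0.0 if orientation == "IP" else 0.5
        disp = (stats.delta0 - delta_min + 0.5) % 1.0 - 0.5
        cos_term = max(math.cos(2 * math.pi * disp), 0.05)
        eps = r / (4 * math.pi**2 * cos_term)
        delta_nu = 2 * math.pi * eps * math.sin(2 * math.pi * disp)
        if orientation == "AP":
            eps = -eps
    return AdlerParams(eps=eps, delta_nu=delta_nu, T_eff=T_eff,
                       omega_bar=omega_bar)


@dataclass
class CouplingFit:
    """Fit of the separation law |kappa| = k / L."""

    k: float
    loglog_slope: float
    loglog_slope_stderr: float
    L: np.ndarray
    kappa: np.ndarray
    orientation: str = "IP"


def fit_coupling_law(L: np.ndarray, kappa: np.ndarray,
                     orientation: str = "IP") -> CouplingFit:
    """Least-squares fit of |kappa| = k * L^-1 (exponent fixed at -1).

    Also reports the free log-log slope with its standard error as a
    diagnostic of the 1/L hydrodynamic scaling.
    """
    from scipy import stats as sstats

    L = np.asarray(L, dtype=float)
    kap = np.abs(np.asarray(kappa, dtype=float))
    if len(L) < 3 or len(np.unique(L)) < 2:
        raise ValueError("need >= 3 points with distinct separations")
    x = 1.0 / L
    k = float((kap * x).sum() / (x * x).sum())
    res = sstats.linregress(np.log(L), np.log(kap))
    return CouplingFit(k=k, loglog_slope=float(res.slope),
                       loglog_slope_stderr=float(res.stderr),
                       L=L, kappa=kap, orientation=orientation)


def teff_from_periods(periods: np.ndarray) -> float:
    """Single-oscillator phase diffusion from the beat-period distribution.

    For a noisy phase oscillator, the time to advance one beat is a
    first-passage problem of drift-diffusion; its variance obeys
    Var(T) = 2 D / f^3 with f the mean beat frequency and D the phase
    diffusivity in beats^2/s, so

        D = Var(T) f^3 / 2.

    The pair-level effective temperature is the sum of the two cells'
    single-oscillator diffusivities (independent noises add in Delta).
    """
    periods = np.asarray(periods, dtype=float)
    if len(periods) < 100:
        raise ValueError("need at least 100 beat periods")
    f = 1.0 / periods.mean()
    return float(periods.var(ddof=1) * f**3 / 2.0)
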