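"""Phase extraction and phase-difference statistics.

Flagellar phases are reconstructed by Poincare sectioning: a scalar signal
that crosses a threshold exactly once per beat assigns integer beat counts
at the (sub-sample interpolated) crossing times, and the continuous phase
phi(t) grows piecewise-linearly by 2 pi between consecutive crossings.
The phase difference Delta(t) = (phi1 - phi2)/2 pi, in beats, is the
central observable: locked stretches are plateaus of its integer winding
number, phase slips are rapid +-1 jumps between them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "PhaseSeries",
    "PhasePairSeries",
    "LockedStats",
    "poincare_phase",
    "phase_difference",
    "detect_locked",
    "fluctuation_stats",
    "beat_frequencies",
]


@dataclass
class PhaseSeries:
    """Continuous phase of one oscillator from its section passage times.

    crossing_times : strictly increasing times (s) of section passages.
    t : sampling grid (s), restricted to the span of the crossings.
    phi : continuous phase (rad), piecewise linear, gaining exactly 2 pi
        per passage.
    """

    crossing_times: np.ndarray
    t: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        ct = np.asarray(self.crossing_times, dtype=float)
        if len(ct) < 2 or np.any(np.diff(ct) <= 0):
            raise ValueError("need >= 2 strictly increasing crossing times")
        if np.any(np.diff(self.phi) < -1e-12):
            raise ValueError("phase must be non-decreasing")

    @property
    def beat_periods(self) -> np.ndarray:
        return np.diff(self.crossing_times)

    def mean_frequency(self) -> float:
        """Beats per second: (beat count) / (elapsed time)."""
        ct = self.crossing_times
        return (len(ct) - 1) / (ct[-1] - ct[0])


def poincare_phase(t: np.ndarray, signal: np.ndarray, threshold: float = 0.0,
                   direction: str = "up", refractory: float | None = None,
                   ) -> PhaseSeries:
    """Reconstruct a continuous phase from once-per-beat section crossings.

    Crossing times are found where the signal passes ``threshold`` in the
    given direction and refined by linear sub-sample interpolation.  A
    refractory window (default: half the median inter-crossing interval)
    discards spurious re-crossings so that the section is passed precisely
    once per beat; if crossings remain closer than the window after one
    pass, the signal is rejected as ambiguous.

    phi(t) is piecewise linear between crossings (2 pi per beat) and is
    reported on the samples of ``t`` that fall inside the crossing span.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(signal, dtype=float)
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if direction == "down":
        y = -y
        threshold = -threshold
    below = y[:-1] < threshold
    above = y[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if len(idx) < 3:
        raise ValueError("signal crosses the section fewer than 3 times")
    frac = (threshold - y[idx]) / (y[idx + 1] - y[idx])
    times = t[idx] + frac * (t[idx + 1] - t[idx])

    if refractory is None:
        refractory = 0.5 * float(np.median(np.diff(times)))
    if refractory > 0:
        kept = [times[0]]
        for tc in times[1:]:
            if tc - kept[-1] >= refractory:
                kept.append(tc)
        times = np.asarray(kept)
        if len(times) > 1 and np.min(np.diff(times)) < refractory:
            raise ValueError("ambiguous sectioning: crossings persist inside "
                             "the refractory window")
    if len(times) < 2:
        raise ValueError("fewer than 2 crossings after the refractory rule")

    mask = (t >= times[0]) & (t <= times[-1])
    beats = np.interp(t[mask], times, np.arange(len(times), dtype=float))
    return PhaseSeries(crossing_times=times, t=t[mask], phi=2 * np.pi * beats)


@dataclass
class PhasePairSeries:
    """Two phases on a common grid, their difference, and pair metadata.

    delta = (phi1 - phi2) / 2 pi, in beats, unwrapped (winding kept).
    d, l : separation and mean flagellum length (um); L = d/l.
    orientation : "IP" (power strokes parallel) or "AP" (opposed).
    """

    phase1: PhaseSeries
    phase2: PhaseSeries
    t: np.ndarray
    delta: np.ndarray
    d: float = float("nan")
    l: float = float("nan")
    orientation: str = "IP"
    ground_truth: dict | None = None

    @property
    def L(self) -> float:
        return self.d / self.l


def phase_difference(p1: PhaseSeries, p2: PhaseSeries, d: float = float("nan"),
                     l: float = float("nan"), orientation: str = "IP",
                     ) -> PhasePairSeries:
    """Delta(t) = (phi1 - phi2)/2 pi on the common uniform time grid.

    Delta is cumulative (unwrapped): a pair that drifts apart by three
    beats carries Delta ~ 3, not its fractional part.
    """
    t0 = max(p1.t[0], p2.t[0])
    t1 = min(p1.t[-1], p2.t[-1])
    if t1 <= t0:
        raise ValueError("phase series have disjoint time supports")
    dt = min(np.median(np.diff(p1.t)), np.median(np.diff(p2.t)))
    t = np.arange(t0, t1 + 0.5 * dt, dt)
    phi1 = np.interp(t, p1.t, p1.phi)
    phi2 = np.interp(t, p2.t, p2.phi)
    return PhasePairSeries(phase1=p1, phase2=p2, t=t,
                           delta=(phi1 - phi2) / (2 * np.pi),
                           d=d, l=l, orientation=orientation)


@dataclass
class LockedStats:
    """Locked-segment decomposition of a Delta(t) series.

    segments : list of (t_start, t_end) of maximal constant-winding spans.
    slips : list of (time, sign) of sustained winding changes.
    delta0 : pooled mean of Delta - n within segments (beats).
    variance : pooled variance of the locked fluctuations (beats^2).
    tau_sync : mean segment duration (s).
    locked_residuals : concatenated Delta - n - 0 fluctuation samples.
    """

    segments: list
    slips: list
    delta0: float
    variance: float
    tau_sync: float
    locked_residuals: np.ndarray
    n_locked_samples: int = 0
    locked_fraction: float = 0.0


def detect_locked(pair: PhasePairSeries, hold: float | None = None) -> LockedStats:
    """Decompose Delta(t) into locked segments and phase slips.

    The integer winding n(t) = round(Delta - Delta_ref) is tracked with
    Delta_ref the circular mean of Delta mod 1 (so locked plateaus sit at
    integers).  A slip is a change of n sustained for at least ``hold``
    seconds (default: three mean beat periods, which excludes excursions
    that re-trap); maximal constant-n intervals are the locked segments.
    """
    t = pair.t
    delta = pair.delta
    dt = float(np.median(np.diff(t)))
    mean_period = 0.5 * (1 / pair.phase1.mean_frequency() + 1 / pair.phase2.mean_frequency())
    if hold is None:
        hold = 3.0 * mean_period
    if t[-1] - t[0] < hold:
        raise ValueError("series shorter than the hold time")

    ang = 2 * np.pi * delta
    delta_ref = math.atan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * math.pi)
    n = np.round(delta - delta_ref).astype(int)

    # run-length encode, then absorb runs shorter than hold into neighbours
    change = np.nonzero(np.diff(n))[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(n) - 1]])
    runs = [[int(n[s]), s, e] for s, e in zip(starts, ends)]
    min_len = max(1, int(round(hold / dt)))

    def merge_short(runs):
        out = []
        for run in runs:
            if out and out[-1][0] == run[0]:
                out[-1][2] = run[2]
            elif run[2] - run[1] + 1 < min_len and out:
                out[-1][2] = run[2]  # too brief: excursion, stays with previous
            else:
                out.append(run)
        # leading short run: absorb into the following one
        while len(out) > 1 and out[0][2] - out[0][1] + 1 < min_len:
            out[1][1] = out[0][1]
            out[0:2] = [out[1]]
        # re-merge equal neighbours created by absorption
        merged = []
        for run in out:
            if merged and merged[-1][0] == run[0]:
                merged[-1][2] = run[2]
            else:
                merged.append(run)
        return merged

    runs = merge_short(runs)
    segments = [(float(t[s]), float(t[e])) for _, s, e in runs]
    slips = []
    for (n0, _, e0), (n1, s1, _) in zip(runs[:-1], runs[1:]):
        slips.append((float(0.5 * (t[e0] + t[s1])), int(np.sign(n1 - n0))))

    pooled = np.concatenate([delta[s:e + 1] - winding for winding, s, e in runs])
    delta0 = float(pooled.mean())
    variance = float(pooled.var())
    tau_sync = float(np.mean([e - s for s, e in segments]))
    n_locked = int(sum(e - s + 1 for _, s, e in runs))
    return LockedStats(segments=segments, slips=slips, delta0=delta0,
                       variance=variance, tau_sync=tau_sync,
                       locked_residuals=pooled - delta0,
                       n_locked_samples=n_locked,
                       locked_fraction=n_locked / len(n))


def fluctuation_stats(stats: LockedStats, L: float, bins: int = 40) -> dict:
    """Distribution of the rescaled locked fluctuations (Delta - Delta0)/sqrt(L).

    When the coupling scales as eps ~ 1/L the stationary variance of the
    locked fluctuations grows linearly with L, so the rescaled variable has
    an L-independent (Gaussian) distribution.  Returns the histogram, the
    maximum-likelihood Gaussian fit, the variance C0 of the unscaled
    fluctuations, and a normality diagnostic (D'Agostino-Pearson p-value).
    """
    x = stats.locked_residuals
    if len(x) < 100:
        raise ValueError("need >= 100 locked samples")
    z = x / math.sqrt(L)
    hist, edges = np.histogram(z, bins=bins, density=True)
    mu, sigma = float(z.mean()), float(z.std())
    _, p_normal = sstats.normaltest(z)
    return {
        "hist": hist,
        "bin_edges": edges,
        "mean": mu,
        "sigma": sigma,
        "C0": float(x.var()),
        "normality_p": float(p_normal),
        "samples_rescaled": z,
    }


def beat_frequencies(pair: PhasePairSeries, delta_omega_far: float | None = None
                     ) -> dict:
    """Per-flagellum beat frequencies and their difference.

    omega_i = (beat count)/(elapsed time), Hz.  If a far-separation
    reference ``delta_omega_far`` is supplied, the ratio
    delta_omega / delta_omega_far is reported as well (0 for a locked pair).
    """
    for p in (pair.phase1, pair.phase2):
        if len(p.crossing_times) < 11:
            raise ValueError("need >= 10 beats per flagellum")
    w1 = pair.phase1.mean_frequency()
    w2 = pair.phase2.mean_frequency()
    out = {"omega1": w1, "omega2": w2, "delta_omega": w1 - w2}
    if delta_omega_far is not None:
        out["ratio_far"] = (w1 - w2) / delta_omega_far
    return out
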