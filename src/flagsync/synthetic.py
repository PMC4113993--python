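"""Synthetic data with known ground truth for every analysis stage.

The experimental raw inputs of this problem are high-speed video and PIV
velocity fields; this module emulates their *processed* forms — gridded
velocity snapshots, tracked flagellar polylines, interrogation-region
signals and coupled noisy phase pairs — from explicit generative models, so
each downstream stage can be scored against stored ground truth.

Generators and what they emulate
--------------------------------
- :func:`generate_piv_frames` — a moving point force (Stokeslet) of
  sinusoidally modulated magnitude, sampled on a grid with additive
  Gaussian velocity noise: the flow movie around one beating flagellum.
- :func:`generate_waveforms` — an inextensible single-harmonic
  tangent-angle travelling wave: a stand-in beating flagellum (not a fit to
  Volvox beats) with the power/recovery asymmetry that makes the
  beat-averaged propulsive force nonzero.
- :func:`generate_pair_phases` — two phases whose difference obeys the
  stochastic Adler equation with coupling eps = k omega_bar / L.
- :func:`generate_section_signal` — once-per-beat periodic scalar signals
  (the functional role of the interrogation regions) from which Poincare
  sectioning must recover the phases.

Every generator is deterministic given a :class:`SyntheticConfig` seed and
attaches a ground-truth dict that round-trips losslessly through JSON.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .adler import AdlerParams, simulate_adler
from .stokeslet import ForceModulation, VelocityField, evaluate_stokeslet
from .rft import WaveformFrame
from .phase import PhasePairSeries, PhaseSeries

__all__ = [
    "SyntheticConfig",
    "BeatModel",
    "make_grid",
    "generate_piv_frames",
    "generate_waveforms",
    "generate_pair_phases",
    "adler_params_at_separation",
    "generate_section_signal",
]

#: near-field exclusion radius (um) around the Stokeslet for PIV grids; the
#: far-field 1/r form only holds away from the flagellum, and the fits use
#: the far field.
NEAR_FIELD_CUTOFF = 5.0


@dataclass
class SyntheticConfig:
    """Shared configuration of all generators.

    frame_rate : sampling rate, 1/s (default 1000, the high-speed-video
        rate the data emulate).
    duration : generated span, s.
    noise : per-generator dimensionless noise fractions.
    grid_extent / grid_spacing : PIV-like grid geometry, um.
    """

    seed: int = 0
    frame_rate: float = 1000.0
    duration: float = 1.0
    noise: dict = field(default_factory=dict)
    grid_extent: float = 80.0
    grid_spacing: float = 4.0

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Named, independent substream of the root seed (process-stable)."""
        import hashlib

        key = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "little")
        return np.random.default_rng(np.random.SeedSequence(
            self.seed, spawn_key=(key % 2**31,)))

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration * self.frame_rate))
        return np.arange(n) / self.frame_rate


def make_grid(extent: float, spacing: float) -> np.ndarray:
    """Square grid of points in [-extent/2, extent/2]^2, um."""
    axis = np.arange(-extent / 2, extent / 2 + 0.5 * spacing, spacing)
    xx, yy = np.meshgrid(axis, axis)
    return np.column_stack([xx.ravel(), yy.ravel()])


def generate_piv_frames(config: SyntheticConfig,
                        trajectory: Callable[[np.ndarray], np.ndarray] | None = None,
                        force_profile: ForceModulation | None = None,
                        orbit_radius: float = 5.0,
                        ) -> tuple[list[VelocityField], dict]:
    """Movie of a moving, modulated Stokeslet on a grid, plus ground truth.

    trajectory : callable t -> (len(t), 2) positions of the point force
        (um), periodic with the force profile's period.  Default: a
        counterclockwise circle of radius ``orbit_radius`` about the origin.
    force_profile : magnitude modulation |G|(t); default the measured
        single-cell modulation (A0 = 1076 um^2/s, A1 = 0.56, T = 1/33 s).
        The force direction is tangent to the trajectory.

    Each frame is the instantaneous Stokeslet field plus independent
    zero-mean Gaussian noise of fractional amplitude ``config.noise['piv']``
    (fraction of the RMS noise-free speed).  Grid points within
    ``NEAR_FIELD_CUTOFF`` of the instantaneous force position are dropped
    frame-by-frame, which also rejects exact coincidences.
    """
    if force_profile is None:
        force_profile = ForceModulation(A0=1076.0, A1=0.56, T=1.0 / 33.0)
    T = force_profile.T
    if trajectory is None:
        def trajectory(t):
            ang = 2 * np.pi * np.asarray(t) / T
            return orbit_radius * np.column_stack([np.cos(ang), np.sin(ang)])

    times = config.times
    pos = np.atleast_2d(trajectory(times))
    # force direction: tangent of the trajectory (central differences);
    # falls back to +y for a static point
    vel = np.gradient(pos, times, axis=0) if len(times) > 2 else np.zeros_like(pos)
    norms = np.linalg.norm(vel, axis=1)
    tangents = np.where(norms[:, None] > 1e-12, vel / np.maximum(norms, 1e-300)[:, None],
                        np.array([0.0, 1.0]))
    mags = np.asarray(force_profile(times), dtype=float)

    grid = make_grid(config.grid_extent, config.grid_spacing)
    # exclude the near field of the whole force trajectory once, so every
    # frame shares one grid (time averaging needs congruent frames)
    dists = np.linalg.norm(grid[:, None, :] - pos[None, :, :], axis=2)
    grid = grid[dists.min(axis=1) > NEAR_FIELD_CUTOFF]
    frac = float(config.noise.get("piv", 0.0))
    rng = config.rng("piv")
    frames = []
    for i, t in enumerate(times):
        pts = grid
        u = evaluate_stokeslet(mags[i] * tangents[i], pos[i], pts)
        if frac > 0:
            scale = frac * float(np.sqrt(np.mean(np.sum(u**2, axis=1)) / 2))
            u = u + rng.normal(0.0, scale, size=u.shape)
        frames.append(VelocityField(points=pts, velocities=u, t=float(t)))
    truth = {
        "kind": "piv",
        "seed": config.seed,
        "A0": force_profile.A0, "A1": force_profile.A1,
        "T": force_profile.T, "phi0": force_profile.phi0,
        "trajectory_positions": pos.tolist(),
        "force_directions": tangents.tolist(),
        "noise_fraction": frac,
        "near_field_cutoff": NEAR_FIELD_CUTOFF,
    }
    return frames, truth


@dataclass
class BeatModel:
    """Single-harmonic tangent-angle travelling wave.

    psi(s, t) = psi0 + amplitude * (s/length) * sin(2 pi (s/wavelength - t/T))

    The amplitude envelope grows linearly from the (clamped) base to the
    distal tip, which breaks fore-aft symmetry and yields a net
    beat-averaged propulsive force, the functional signature of
    power/recovery asymmetry.  Positions follow by arclength integration of
    (cos psi, sin psi), so frames are inextensible by construction.
    """

    length: float = 19.9          # um
    period: float = 1.0 / 33.0    # s
    wavelength: float = 19.9      # um
    amplitude: float = 1.0        # rad, tip value of the envelope
    psi0: float = 0.0             # rad, mean orientation
    n_nodes: int = 60

    def __post_init__(self) -> None:
        if self.wavelength <= 0 or self.period <= 0:
            raise ValueError("wavelength and period must be positive")

    def tangent_angle(self, s: np.ndarray, t: float) -> np.ndarray:
        env = self.amplitude * np.asarray(s) / self.length
        return self.psi0 + env * np.sin(
            2 * np.pi * (np.asarray(s) / self.wavelength - t / self.period))


def generate_waveforms(config: SyntheticConfig, beat_model: BeatModel | None = None,
                       ) -> tuple[list[WaveformFrame], dict]:
    """Inextensible beating-flagellum polylines, one frame per sample time.

    Node positions are the arclength integral of the unit tangent
    (cos psi, sin psi) on a fine quadrature grid, resampled at the model's
    nodes; per-frame polyline arclength therefore equals the model length
    to high accuracy, and frames are periodic with the beat period.
    """
    if beat_model is None:
        beat_model = BeatModel()
    m = beat_model
    # fine grid for the quadrature, model nodes as a subset
    refine = 8
    s_fine = np.linspace(0.0, m.length, (m.n_nodes - 1) * refine + 1)
    frames = []
    for t in config.times:
        psi = m.tangent_angle(s_fine, float(t))
        tang = np.column_stack([np.cos(psi), np.sin(psi)])
        # cumulative trapezoid of the unit tangent
        ds = np.diff(s_fine)
        steps = 0.5 * (tang[1:] + tang[:-1]) * ds[:, None]
        xy_fine = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        nodes = xy_fine[::refine]
        # a polyline chord-sum always undershoots the smooth arclength
        # (~1e-5 relative at this node count); rescale uniformly so the
        # discrete object itself is exactly inextensible at length l
        chord = np.sum(np.linalg.norm(np.diff(nodes, axis=0), axis=1))
        frames.append(WaveformFrame(nodes=nodes * (m.length / chord), t=float(t)))
    truth = {
        "kind": "waveform", "seed": config.seed,
        "length": m.length, "period": m.period, "wavelength": m.wavelength,
        "amplitude": m.amplitude, "psi0": m.psi0, "n_nodes": m.n_nodes,
    }
    return frames, truth


def adler_params_at_separation(k: float, L: float, omega_bar: float = 33.0,
                               delta_nu_ratio: float = 0.058,
                               teff_ratio: float = 0.005,
                               orientation: str = "IP") -> AdlerParams:
    """Adler triple at scaled separation L under the 1/L coupling law.

    eps = k omega_bar / L (negated for antiphase pairs); delta_nu and
    T_eff are specified as fractions of omega_bar (defaults: the measured
    population means).
    """
    sign = 1.0 if orientation == "IP" else -1.0
    return AdlerParams(eps=sign * k * omega_bar / L,
                       delta_nu=delta_nu_ratio * omega_bar,
                       T_eff=teff_ratio * omega_bar,
                       omega_bar=omega_bar)


def generate_pair_phases(config: SyntheticConfig, params: AdlerParams,
                         L: float = 1.0, l: float = 19.9,
                         delta0: float = 0.0, dt: float = 1e-4,
                         ) -> PhasePairSeries:
    """Coupled noisy phase pair whose difference obeys the Adler equation.

    Delta(t) is integrated by Euler-Maruyama (:func:`~flagsync.adler.
    simulate_adler`) and split symmetrically between the two phases:

        phi1 = 2 pi omega_bar t + pi Delta,   phi2 = 2 pi omega_bar t - pi Delta,

    so (phi1 - phi2)/2 pi reproduces Delta exactly; the common-mode phase
    is irrelevant to all phase-difference statistics.  Sampled at the
    config frame rate; ground truth (the generating triple and the exact
    Delta) rides along on the returned pair.
    """
    if not params.omega_bar > 0:
        raise ValueError("omega_bar must be positive")
    stride = max(1, int(round(1.0 / (config.frame_rate * dt))))
    t, delta = simulate_adler(params, delta0=delta0, dt=dt,
                              duration=config.duration,
                              seed=config.rng("pair_phases"),
                              sample_every=stride)
    common = 2 * np.pi * params.omega_bar * t
    phi1 = common + np.pi * delta
    phi2 = common - np.pi * delta
    p1 = _series_from_phase(t, phi1)
    p2 = _series_from_phase(t, phi2)
    pair = PhasePairSeries(phase1=p1, phase2=p2, t=t, delta=delta,
                           d=L * l, l=l,
                           orientation="IP" if params.eps >= 0 else "AP")
    pair.ground_truth = {
        "kind": "pair_phases", "seed": config.seed,
        "eps": params.eps, "delta_nu": params.delta_nu,
        "T_eff": params.T_eff, "omega_bar": params.omega_bar,
        "L": L, "l": l, "delta0_init": delta0, "dt": dt,
        "delta": delta,
    }
    return pair


def _series_from_phase(t: np.ndarray, phi: np.ndarray) -> PhaseSeries:
    """PhaseSeries from an explicit continuous phase (crossings at 2 pi k).

    Noise can make phi decrease briefly between samples; beat times are the
    *first passages* of the 2 pi k levels, obtained from the running
    maximum, which is what a threshold detector with a refractory rule
    would see.
    """
    run = np.maximum.accumulate(np.asarray(phi, dtype=float))
    k0 = math.ceil(run[0] / (2 * math.pi))
    k1 = math.floor(run[-1] / (2 * math.pi))
    levels = 2 * math.pi * np.arange(k0, k1 + 1)
    crossings = np.interp(levels, run, t)
    return PhaseSeries(crossing_times=crossings, t=t, phi=run - run[0])


def generate_section_signal(pair: PhasePairSeries,
                            waveshape: Callable[[np.ndarray], np.ndarray] = np.sin,
                            noise_fraction: float = 0.0,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scalar interrogation-style signals s_i(t) = waveshape(phi_i(t)).

    ``waveshape`` must be 2 pi-periodic with exactly one upward threshold
    (zero) crossing per period, so that Poincare sectioning of the output
    recovers each input phase once per beat; shapes with multiple upward
    zero crossings per period are rejected.  Optional white noise is added
    as a fraction of the waveshape RMS amplitude.

    Returns (t, signal1, signal2).
    """
    probe = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
    y = np.asarray(waveshape(probe), dtype=float)
    up = int(np.sum((y < 0) & (np.roll(y, -1) >= 0)))  # circular count
    if up != 1:
        raise ValueError("waveshape must cross zero upward exactly once per period")
    amp = float(np.sqrt(np.mean(y**2)))
    sig1 = np.asarray(waveshape(np.interp(pair.t, pair.phase1.t, pair.phase1.phi)))
    sig2 = np.asarray(waveshape(np.interp(pair.t, pair.phase2.t, pair.phase2.phi)))
    if noise_fraction > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        sig1 = sig1 + rng.normal(0, noise_fraction * amp, size=sig1.shape)
        sig2 = sig2 + rng.normal(0, noise_fraction * amp, size=sig2.shape)
    return pair.t, sig1, sig2
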