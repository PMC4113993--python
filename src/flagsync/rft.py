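"""Resistive force theory for slender flagella.

A slender filament moving through viscous fluid experiences a local drag
linear in its local velocity, with distinct normal and tangential
coefficients:

    f(s, t) = C_perp u_perp + C_par u_par            (force per unit length)

with the classical logarithmic coefficients

    C_perp = 4 pi mu / (ln(0.18 lambda/a) + 1/2)
    C_par  = 2 pi mu / (ln(0.18 lambda/a) - 1/2)

at wavelength-to-radius aspect ratio lambda/a (80 for these flagella).
Integrating f over arclength gives the total instantaneous force F(t) the
flagellum exerts on the fluid.  Units: mu in Pa*s, velocities in um/s, so
densities come out in pN/um and integrated forces in pN (1 Pa um^2 = 1 pN).

The local-drag assumption is known to overestimate force production during
the recovery stroke, where neighbouring segments shield each other; this is
documented, not corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DragCoefficients",
    "WaveformFrame",
    "ForceRecord",
    "WaveformAngles",
    "lighthill_coefficients",
    "node_velocities",
    "rft_force_density",
    "integrate_force",
    "force_weighted_com",
    "waveform_angles",
    "EIGHT_PI",
]

EIGHT_PI = 8.0 * math.pi

# fractional arclength stations (proximal, mid, distal) for waveform angles
ANGLE_STATIONS = (1.0 / 6.0, 0.5, 5.0 / 6.0)


@dataclass
class DragCoefficients:
    """Normal/tangential resistance coefficients (Pa*s) of a slender rod."""

    C_perp: float
    C_par: float
    aspect_ratio: float

    def __post_init__(self) -> None:
        if not (self.C_perp > self.C_par > 0):
            raise ValueError("expected C_perp > C_par > 0")


def lighthill_coefficients(mu: float = 1e-3, aspect_ratio: float = 80.0) -> DragCoefficients:
    """Slender-body drag coefficients at wavelength-to-radius ratio lambda/a.

    Valid only where both logarithms keep the coefficients positive, i.e.
    aspect_ratio > e^{1/2}/0.18 (~9.16); below that C_par diverges/changes
    sign and the local theory is meaningless.
    """
    if mu <= 0:
        raise ValueError("viscosity must be positive")
    log = math.log(0.18 * aspect_ratio)
    if log - 0.5 <= 0:
        raise ValueError(
            f"aspect ratio {aspect_ratio} at/below the C_par singularity "
            f"(need lambda/a > {math.exp(0.5)/0.18:.2f})")
    return DragCoefficients(
        C_perp=4 * math.pi * mu / (log + 0.5),
        C_par=2 * math.pi * mu / (log - 0.5),
        aspect_ratio=aspect_ratio,
    )


@dataclass
class WaveformFrame:
    """Ordered flagellar polyline at one instant, basal end first.

    nodes : (N, 2) array, um.  t : s.  Arclengths are computed from the
    nodes on construction.
    """

    nodes: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 2 or len(self.nodes) < 3:
            raise ValueError("need an (N>=3, 2) array of node positions")
        seg = np.linalg.norm(np.diff(self.nodes, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("self-coincident consecutive nodes")
        self.arclengths = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclengths[-1])

    def tangents(self) -> np.ndarray:
        """Unit tangents at nodes, centred differences inside, one-sided at ends."""
        tang = np.gradient(self.nodes, self.arclengths, axis=0)
        norms = np.linalg.norm(tang, axis=1)
        if np.any(norms == 0):
            raise ValueError("degenerate tangent")
        return tang / norms[:, None]


def node_velocities(frames: list[WaveformFrame]) -> np.ndarray:
    """Per-node velocities (um/s) from a uniformly sampled waveform movie.

    Central differences in time at interior frames, one-sided at the ends;
    node correspondence is by index.  Returns (n_frames, n_nodes, 2).
    """
    if len(frames) < 3:
        raise ValueError("need at least 3 frames")
    n_nodes = len(frames[0].nodes)
    if any(len(f.nodes) != n_nodes for f in frames):
        raise ValueError("frame node counts differ")
    ts = np.array([f.t for f in frames])
    dts = np.diff(ts)
    if not np.allclose(dts, dts[0], rtol=1e-6):
        raise ValueError("frames not uniformly spaced in time")
    pos = np.stack([f.nodes for f in frames])
    return np.gradient(pos, ts, axis=0)


def rft_force_density(frame: WaveformFrame, velocities: np.ndarray,
                      coeffs: DragCoefficients) -> np.ndarray:
    """Per-node force density f = C_perp u_perp + C_par u_par, pN/um.

    ``velocities`` is the (N, 2) node-velocity array for this frame; each
    velocity is split along/normal to the local unit tangent.
    """
    velocities = np.asarray(velocities, dtype=float)
    if velocities.shape != frame.nodes.shape:
        raise ValueError("velocity array not congruent with frame nodes")
    that = frame.tangents()
    u_par_mag = np.sum(velocities * that, axis=1)
    u_par = u_par_mag[:, None] * that
    u_perp = velocities - u_par
    return coeffs.C_perp * u_perp + coeffs.C_par * u_par


@dataclass
class ForceRecord:
    """Forces of one frame: densities, integrated force, weighted centroid."""

    frame: WaveformFrame
    density: np.ndarray          # (N, 2) pN/um
    force: np.ndarray            # (2,) pN
    com: np.ndarray              # (2,) um
    profile_normal: np.ndarray   # (N,) pN/um, |f_perp|(s)
    profile_tangential: np.ndarray


def integrate_force(frame: WaveformFrame, density: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trapezoidal arclength quadrature of the force density.

    Returns (F, normal_profile, tangential_profile): the total force (pN)
    and the arclength-resolved magnitudes of the normal and tangential
    density components (pN/um), reported separately.
    """
    s = frame.arclengths
    F = np.trapezoid(density, s, axis=0)
    that = frame.tangents()
    f_par = np.sum(density * that, axis=1)
    f_perp_vec = density - f_par[:, None] * that
    return F, np.linalg.norm(f_perp_vec, axis=1), f_par


def force_weighted_com(frame: WaveformFrame, density: np.ndarray) -> np.ndarray:
    """Force-magnitude-weighted centre of mass x = sum(|f_i| x_i)/sum(|f_i|)."""
    w = np.linalg.norm(np.asarray(density, dtype=float), axis=1)
    total = w.sum()
    if total == 0:
        raise ValueError("all force densities vanish; centre of mass undefined")
    return (w[:, None] * frame.nodes).sum(axis=0) / total


def force_record(frame: WaveformFrame, velocities: np.ndarray,
                 coeffs: DragCoefficients) -> ForceRecord:
    """Full RFT evaluation of one frame (density, force, profiles, centroid)."""
    dens = rft_force_density(frame, velocities, coeffs)
    F, prof_n, prof_t = integrate_force(frame, dens)
    com = force_weighted_com(frame, dens)
    return ForceRecord(frame=frame, density=dens, force=F, com=com,
                       profile_normal=prof_n, profile_tangential=prof_t)


@dataclass
class WaveformAngles:
    """Tangent angles (rad) against the cell-body axis at three stations."""

    x_a: float  # proximal
    x_b: float  # mid
    x_c: float  # distal


def waveform_angles(frame: WaveformFrame, body_axis: np.ndarray) -> WaveformAngles:
    """Signed tangent-vs-body-axis angles at arclength fractions 1/6, 1/2, 5/6.

    The proximal/mid/distal stations are fixed fractions of the total
    arclength so the quantity is reproducible across frames and cells.
    Angles are in (-pi, pi], positive counterclockwise from the axis.
    """
    axis = np.asarray(body_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    that = frame.tangents()
    # interpolate the tangent *vector* in s, then renormalise
    s = frame.arclengths
    out = []
    for frac in ANGLE_STATIONS:
        target = frac * frame.length
        tx = np.interp(target, s, that[:, 0])
        ty = np.interp(target, s, that[:, 1])
        v = np.array([tx, ty])
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("degenerate interpolated tangent")
        v /= n
        cross = axis[0] * v[1] - axis[1] * v[0]
        dot = float(axis @ v)
        out.append(math.atan2(cross, dot))
    return WaveformAngles(*out)
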