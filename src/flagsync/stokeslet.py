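"""Point-force (Stokeslet) flow fields: evaluation, fitting and summaries.

The flow of a point force F applied to a fluid of viscosity mu at x0 is

    u_i(x) = G_j / r * (delta_ij + r_i r_j / r^2),    r = x - x0,

with the *reduced force* G = F / (8 pi mu) in um^2/s.  All printed force
amplitudes in this package are reduced forces; conversion to pN happens
only at reporting time (F[pN] = 8 pi mu[Pa s] G[um^2/s]).

The kernel is the three-dimensional Oseen tensor evaluated in the beating
plane (z = 0); out-of-plane flow is ignored, matching planar PIV data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "VelocityField",
    "StokesletFit",
    "ForceModulation",
    "evaluate_stokeslet",
    "oseen_tensor_apply",
    "fit_stokeslet",
    "time_average_field",
    "radial_decay",
    "fit_force_modulation",
    "rotational_stiffness_bound",
]


@dataclass
class VelocityField:
    """A gridded planar velocity snapshot (the unit of PIV-like data).

    Attributes
    ----------
    points : (N, 2) array, um
    velocities : (N, 2) array, um/s
    t : float, s
    """

    points: np.ndarray
    velocities: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.points.shape != self.velocities.shape or self.points.ndim != 2:
            raise ValueError("points and velocities must be congruent (N, 2) arrays")
        if self.points.shape[1] != 2:
            raise ValueError("planar fields only: expected (N, 2) arrays")
        if not (np.all(np.isfinite(self.points)) and np.all(np.isfinite(self.velocities))):
            raise ValueError("velocity field contains non-finite values")

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.velocities[:, 0], self.velocities[:, 1])


@dataclass
class StokesletFit:
    """Point-force fit of one snapshot: position, reduced force, misfit."""

    x0: np.ndarray
    G: np.ndarray
    residual: float
    success: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=float)
        self.G = np.asarray(self.G, dtype=float)


@dataclass
class ForceModulation:
    """Sinusoidal force-magnitude modulation |G|(t) = A0 (1 + A1 sin(2 pi t/T + phi0)).

    A0 in um^2/s (reduced force), A1 dimensionless in [0, 1), T in s.
    """

    A0: float
    A1: float
    T: float
    phi0: float = 0.0

    def __post_init__(self) -> None:
        if not self.A0 > 0:
            raise ValueError("A0 must be positive")
        if not (0 <= self.A1 < 1):
            raise ValueError("A1 must lie in [0, 1) so the force stays positive")
        if not self.T > 0:
            raise ValueError("period T must be positive")

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.A0 * (1.0 + self.A1 * np.sin(2 * np.pi * np.asarray(t) / self.T + self.phi0))


def evaluate_stokeslet(G: np.ndarray, x0: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Velocities (um/s) of a Stokeslet of reduced force ``G`` at ``x0``.

    ``u(x) = (1/r) (I + rhat rhat) . G`` — linear in G, 1/r decay, factor-two
    parallel/perpendicular anisotropy.

    Raises
    ------
    ValueError
        if any evaluation point coincides with ``x0`` (the kernel is singular).
    """
    G = np.asarray(G, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rvec = pts - x0
    r = np.linalg.norm(rvec, axis=1)
    if np.any(r == 0):
        raise ValueError("evaluation point coincides with the Stokeslet position x0")
    # u = G/r + (G . rhat) rhat / r
    proj = rvec @ G / r**2
    u = G / r[:, None] + proj[:, None] * rvec / r[:, None]
    return u if np.asarray(points).ndim == 2 else u[0]


def oseen_tensor_apply(F_reduced: np.ndarray, r_vec: np.ndarray) -> np.ndarray:
    """Velocity induced at separation ``r_vec`` by a point force, reduced form.

    Identical kernel to :func:`evaluate_stokeslet`; exposed for reuse by the
    bead-spring rower model, where ``F_reduced = F / (8 pi mu)``.
    """
    return evaluate_stokeslet(F_reduced, np.zeros_like(r_vec), np.atleast_2d(r_vec))[0]


def _design_matrix(points: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """(2N, 2) matrix M with u_flat = M @ G for a Stokeslet at x0."""
    rvec = points - x0
    r = np.linalg.norm(rvec, axis=1)
    n = len(points)
    M = np.zeros((2 * n, 2))
    rhat = rvec / r[:, None]
    # row block i: (I + rhat rhat)/r
    M[0::2, 0] = (1.0 + rhat[:, 0] ** 2) / r
    M[0::2, 1] = (rhat[:, 0] * rhat[:, 1]) / r
    M[1::2, 0] = M[0::2, 1]
    M[1::2, 1] = (1.0 + rhat[:, 1] ** 2) / r
    return M

def solve_G(field: VelocityField, x0: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact linear least-squares reduced force for a fixed Stokeslet position.

    Returns (G, rms_residual).  The G-subproblem of the full fit is linear,
    so for any trial x0 this is the global optimum over G.
    """
    x0 = np.asarray(x0, dtype=float)
    r = np.linalg.norm(field.points - x0, axis=1)
    if np.any(r == 0):
        return np.full(2, np.nan), np.inf
    M = _design_matrix(field.points, x0)
    uflat = field.velocities.ravel()
    G, *_ = np.linalg.lstsq(M, uflat, rcond=None)
    resid = (M @ G - uflat).reshape(-1, 2)
    return G, float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def fit_stokeslet(field: VelocityField, init: StokesletFit | None = None) -> StokesletFit:
    """Least-squares Stokeslet fit of one velocity snapshot.

    Local derivative-free search over the point-force position ``x0`` with
    the reduced force solved exactly (linearly) at every trial position;
    multi-start from the grid point of maximum speed (the singularity pulls
    |u| up near x0) and, if given, from ``init``.  Exact-model data is
    recovered to machine precision.
    """
    pts = field.points
    if len(pts) < 10:
        raise ValueError("need at least 10 grid points to fit a Stokeslet")
    # collinearity guard: rank of centred coordinates
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * np.abs(pts).max()) < 2:
        return StokesletFit(np.full(2, np.nan), np.full(2, np.nan), np.inf,
                            success=False, message="degenerate geometry: grid points collinear")

    def objective(x0: np.ndarray) -> float:
        _, rms = solve_G(field, x0)
        return rms

    # multi-start: the singularity pulls |u| up near x0, so the top-speed
    # grid points bracket it; a coarse local scan around the best of them
    # guards against the local minima the excluded near-field disc creates
    span = np.ptp(pts, axis=0).max()
    order = np.argsort(field.speed)[::-1]
    starts = [pts[i] + 1e-3 * span for i in order[:4]]
    if init is not None:
        starts.append(np.asarray(init.x0, dtype=float))
    spacing = max(np.median(np.diff(np.unique(pts[:, 0]))), 1e-3 * span)
    centre = pts[order[0]]
    for dx in (-1.5, -0.5, 0.5, 1.5):
        for dy in (-1.5, -0.5, 0.5, 1.5):
            starts.append(centre + spacing * np.array([dx, dy]))
    scored = sorted(starts, key=objective)[:4]

    best = None
    for s in scored:
        res = optimize.minimize(objective, s, method="Nelder-Mead",
                                options={"xatol": 1e-8 * span, "fatol": 1e-12,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    x0 = best.x
    G, rms = solve_G(field, x0)
    return StokesletFit(x0=x0, G=G, residual=rms, success=bool(np.all(np.isfinite(G))),
                        message=best.message if not best.success else "")


def grid_search_stokeslet(field: VelocityField, x_range, y_range, n: int = 21
                          ) -> StokesletFit:
    """Brute-force oracle: exhaustive x0 grid with exact linear G solve.

    Used to cross-check :func:`fit_stokeslet`'s objective minimum on small
    instances; not meant for production fitting.
    """
    xs = np.linspace(*x_range, n)
    ys = np.linspace(*y_range, n)
    best = None
    for x in xs:
        for y in ys:
            G, rms = solve_G(field, np.array([x, y]))
            if best is None or rms < best[2]:
                best = (np.array([x, y]), G, rms)
    return StokesletFit(x0=best[0], G=best[1], residual=best[2])


def time_average_field(frames: list[VelocityField]) -> tuple[np.ndarray, np.ndarray]:
    """Time averages of a movie: per-point mean speed and mean velocity vector.

    Returns
    -------
    mean_speed : (N,) array, um/s — time mean of |u(x, t)| (the scalar shown
        in time-averaged flow maps).
    mean_velocity : (N, 2) array, um/s — time mean of u(x, t) (for
        streamlines).  The two differ whenever the direction varies in time.
    """
    if not frames:
        raise ValueError("no frames")
    pts0 = frames[0].points
    for f in frames[1:]:
        if f.points.shape != pts0.shape or not np.allclose(f.points, pts0):
            raise ValueError("inconsistent grids across frames")
    speeds = np.stack([f.speed for f in frames])
    vels = np.stack([f.velocities for f in frames])
    return speeds.mean(axis=0), vels.mean(axis=0)


def radial_decay(points: np.ndarray, speed: np.ndarray, origin: np.ndarray,
                 direction: np.ndarray, r_min: float, r_max: float,
                 n_samples: int = 40) -> dict:
    """Radial decay of a scalar speed field along a ray; fitted power law.

    Samples |u| by linear interpolation at radii in [r_min, r_max] along
    ``direction`` from ``origin`` and fits log u = p log r + c.  A Stokeslet
    gives p = -1, a source dipole p = -2.

    Returns a dict with ``r``, ``u``, ``exponent``, ``stderr``.
    """
    from scipy.interpolate import griddata

    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    radii = np.linspace(r_min, r_max, n_samples)
    sample_pts = np.asarray(origin, dtype=float) + radii[:, None] * direction
    u = griddata(points, speed, sample_pts, method="linear")
    ok = np.isfinite(u) & (u > 0)
    if ok.sum() < 5:
        raise ValueError("fewer than 5 usable samples in the fit window; "
                         "does the ray leave the grid?")
    res = stats.linregress(np.log(radii[ok]), np.log(u[ok]))
    return {"r": radii[ok], "u": u[ok],
            "exponent": res.slope, "stderr": res.stderr}


def fit_force_modulation(t: np.ndarray, G_mag: np.ndarray, T: float) -> ForceModulation:
    """Fit |G|(t) = A0 (1 + A1 sin(2 pi t / T + phi0)) at fixed period T.

    The model is linear in (A0, A0 A1 cos phi0, A0 A1 sin phi0), so the fit
    is a single linear least squares; A1 is reported non-negative with phi0
    adjusted accordingly.
    """
    t = np.asarray(t, dtype=float)
    G_mag = np.asarray(G_mag, dtype=float)
    if t[-1] - t[0] < T:
        raise ValueError("series shorter than one modulation period")
    w = 2 * np.pi / T
    X = np.column_stack([np.ones_like(t), np.sin(w * t), np.cos(w * t)])
    c, *_ = np.linalg.lstsq(X, G_mag, rcond=None)
    A0 = c[0]
    amp = float(np.hypot(c[1], c[2]))
    phi0 = float(np.arctan2(c[2], c[1]))
    A1 = amp / A0 if A0 != 0 else 0.0
    return ForceModulation(A0=float(A0), A1=float(A1), T=float(T), phi0=phi0)


@dataclass
class StiffnessBoundInputs:
    """Inputs of the rotational-stiffness estimate for cell-body rocking.

    l : flagellum length, um.  r : distance from the neighbouring force to
    the cell, um.  G : reduced force magnitude F/(8 pi mu), um^2/s.
    aspect_ratio : Lighthill wavelength-to-radius ratio for C_perp.
    alpha_star : upper bound on the observed angular displacement, rad.
    """

    l: float
    r: float
    G: float
    aspect_ratio: float = 80.0
    alpha_star: float = 1.0

    def __post_init__(self) -> None:
        for name in ("l", "r", "G", "aspect_ratio", "alpha_star"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def rotational_stiffness_bound(inp: StiffnessBoundInputs, mu: float = 1e-3) -> float:
    """Lower bound (pN um) on the rotational spring constant of a held cell.

    A neighbouring flagellum exerting reduced force G produces a flow of
    speed u = G/r at distance r; acting on a flagellum of length l it exerts
    a torque ~ C_perp u l^2 / 2.  Balancing against a rotational spring
    k * alpha and bounding alpha by the observed alpha_star gives

        k > C_perp u l^2 / (2 alpha_star).

    If the bound exceeds the torques that residual cell-body rocking could
    supply, rocking cannot explain the observed synchronization.  With
    Pa*s, um and s units the torque comes out directly in pN um.
    """
    from .rft import lighthill_coefficients

    coeffs = lighthill_coefficients(mu=mu, aspect_ratio=inp.aspect_ratio)
    u = inp.G / inp.r                       # um/s
    torque = coeffs.C_perp * u * inp.l**2 / 2.0   # Pa s * um/s * um^2 = pN um
    return torque / inp.alpha_star
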