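"""Rising-drop tensiometry: Young-Laplace shapes, profile fits, decay fits.

A drop of one fluid formed at a needle inside another fluid takes an
axisymmetric shape set by the balance between capillarity and buoyancy.
Writing the meridian in arc-length form (x radial distance from the symmetry
axis, z axial distance from the apex toward the needle, phi the tangent
angle), the Young-Laplace equation becomes the ODE system

    dx/ds = cos(phi)
    dz/ds = sin(phi)
    dphi/ds = 2/b0 - (drho * g / gamma) * z - sin(phi)/x

where b0 is the apex radius of curvature and drho the density difference
driving buoyancy (outer minus inner for a rising drop). The hydrostatic term
reduces the curvature away from the apex, producing the familiar pear shape;
its strength relative to capillarity is the Bond number
Bo = drho * g * b0^2 / gamma. At Bo -> 0 the drop is a sphere and the shape
carries no information about gamma.

Fitting a measured contour with this family of shapes over (gamma, b0, apex
position, tilt) yields the interfacial tension — the standard axisymmetric
drop shape analysis (ADSA) scheme. Surfactant adsorption makes gamma decay in
time; the equilibrium value is extracted by fitting an exponential decay to a
finite plateau, gamma(t) = gamma_eq + (gamma_0 - gamma_eq) * exp(-t/tau).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, least_squares
from scipy.spatial import cKDTree

__all__ = [
    "FluidPair",
    "DropProfile",
    "TensionSeries",
    "DropDetachedError",
    "DegenerateShapeWarning",
    "young_laplace_profile",
    "young_laplace_residual",
    "fit_pendant_drop",
    "fit_tension_decay",
]

STANDARD_GRAVITY = 9.81  # m/s^2


class DropDetachedError(RuntimeError):
    """Integration failed: tension too low to hold a drop of this size."""


class DegenerateShapeWarning(UserWarning):
    """Shape is nearly spherical (or extreme); gamma is ill-constrained."""


@dataclass(frozen=True)
class FluidPair:
    """Densities driving buoyancy in a rising/pendant drop.

    delta_rho is outer minus inner density (kg/m^3); positive for a rising
    drop (light drop in a denser bath).
    """

    delta_rho: float
    g: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if self.delta_rho == 0:
            raise ValueError("delta_rho must be non-zero")
        if self.g <= 0:
            raise ValueError("g must be > 0")


@dataclass(frozen=True)
class DropProfile:
    """One meridian of an axisymmetric drop, apex first.

    Arrays are sampled at uniform arc length s; x >= 0 is the distance from
    the symmetry axis, z >= 0 the axial distance from the apex toward the
    needle, phi the tangent angle.
    """

    s: np.ndarray
    x: np.ndarray
    z: np.ndarray
    phi: np.ndarray
    apex_radius: float
    gamma: float
    fluids: FluidPair
    _interp: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.x[0] > 1e-6 * self.apex_radius or np.any(self.x < -1e-12):
            raise ValueError("profile must start at the symmetry axis with x >= 0")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("arc length must be strictly increasing")

    @property
    def bond_number(self) -> float:
        """Bo = drho * g * b0^2 / gamma."""
        return abs(self.fluids.delta_rho) * self.fluids.g * self.apex_radius**2 / self.gamma

    @property
    def points(self) -> np.ndarray:
        """(N, 2) array of (x, z) coordinates in metres."""
        return np.column_stack([self.x, self.z])

    def volume(self) -> float:
        """Volume of the solid of revolution, pi * integral x^2 dz (m^3)."""
        return float(np.pi * np.trapezoid(self.x**2, self.z))


@dataclass
class TensionSeries:
    """A tension-vs-time series with its exponential-plateau fit."""

    times: np.ndarray
    gammas: np.ndarray
    gamma_eq: float = field(default=np.nan)
    gamma_0: float = field(default=np.nan)
    tau_decay: float = field(default=np.nan)
    ci95: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.gammas = np.asarray(self.gammas, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.gammas <= 0):
            raise ValueError("tensions must be > 0")


# ---------------------------------------------------------------------------
# Forward shape generation
# ---------------------------------------------------------------------------

def _yl_rhs(gamma: float, fluids: FluidPair, b0: float):
    """Right-hand side of the arc-length Young-Laplace system."""
    c = abs(fluids.delta_rho) * fluids.g / gamma

    def rhs(s, y):
        x, z, phi = y
        sphi = np.sin(phi)
        # removable singularity: sin(phi)/x -> 1/b0 at the apex
        azi = sphi / x if x > 1e-12 * b0 else 1.0 / b0
        return [np.cos(phi), sphi, 2.0 / b0 - c * z - azi]

    return rhs


def young_laplace_profile(
    gamma: float,
    fluids: FluidPair,
    apex_radius: float,
    arc_length_max: float,
    n_samples: int = 400,
    rtol: float = 1e-10,
) -> DropProfile:
    """Integrate the Young-Laplace meridian from the apex.

    Parameters
    ----------
    gamma : float
        Interfacial tension (N/m, > 0).
    fluids : FluidPair
        Density difference and gravity.
    apex_radius : float
        Radius of curvature b0 at the apex (m, > 0).
    arc_length_max : float
        Arc length to integrate to (m).
    n_samples : int
        Number of uniform arc-length samples returned.

    Returns
    -------
    DropProfile

    Raises
    ------
    DropDetachedError
        If the integration fails or the profile necks back onto the axis
        (tension too low to hold a drop of this length).
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if apex_radius <= 0:
        raise ValueError("apex_radius must be > 0")
    b0 = apex_radius

    # series start just off the apex: x ~ s, z ~ s^2/(2 b0), phi ~ s/b0
    s0 = 1e-6 * b0
    y0 = [s0, s0**2 / (2.0 * b0), s0 / b0]

    # terminal events bound the physically meaningful meridian: a captive
    # drop keeps its tangent angle phi in (0, pi) from apex to neck and
    # x > 0 until the profile closes. Past either bound the solution folds
    # over or oscillates like a flat meniscus, so the profile is truncated
    # there; if the shape never even developed drop-like curvature, the
    # tension is too low to hold a drop at all.
    def hits_axis(s, y):
        return y[0] - 1e-3 * b0

    hits_axis.terminal = True
    hits_axis.direction = -1

    def folds_over(s, y):
        return (np.pi - y[2]) * (y[2] + 1e-9)

    folds_over.terminal = True
    folds_over.direction = -1

    sol = solve_ivp(
        _yl_rhs(gamma, fluids, b0),
        (s0, arc_length_max),
        y0,
        method="RK45",
        rtol=rtol,
        atol=1e-4 * rtol * b0,
        dense_output=True,
        events=[hits_axis, folds_over],
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise DropDetachedError(
            "Young-Laplace integration failed: drop detaches "
            f"(gamma={gamma:.3g} N/m too low for arc length {arc_length_max:.3g} m)"
        )
    if sol.t_events[1].size and np.max(sol.y[2]) < np.pi / 4:
        raise DropDetachedError(
            f"tension gamma={gamma:.3g} N/m is too low for a drop with apex "
            f"radius {b0:.3g} m: the meridian flattens into a meniscus "
            "instead of a drop (drop detaches)"
        )

    s = np.linspace(s0, sol.t[-1], n_samples)
    x, z, phi = sol.sol(s)
    # prepend the exact apex sample
    s = np.concatenate([[0.0], s])
    x = np.concatenate([[0.0], x])
    z = np.concatenate([[0.0], z])
    phi = np.concatenate([[0.0], phi])
    return DropProfile(
        s=s, x=x, z=z, phi=phi, apex_radius=b0, gamma=gamma, fluids=fluids,
        _interp=sol.sol,
    )


def young_laplace_residual(profile: DropProfile) -> np.ndarray:
    """Nondimensional plug-back residual of the profile at every sample.

    The Young-Laplace ODE has the exact integral form (axial force balance)

        x*sin(phi) = integral_0^s x * (2/b0 - drho*g*z/gamma) * cos(phi) ds'

    equivalent to dphi/ds + sin(phi)/x = 2/b0 - drho*g*z/gamma, because
    (1/x)*d(x*sin(phi))/dx = dphi/ds + sin(phi)/x with dx = cos(phi)*ds.
    The residual is the mismatch of the two sides, nondimensionalized by the
    apex radius; it vanishes identically iff the samples solve the ODE.
    """
    from scipy.integrate import cumulative_simpson

    b0 = profile.apex_radius
    c = abs(profile.fluids.delta_rho) * profile.fluids.g / profile.gamma
    integrand = profile.x * (2.0 / b0 - c * profile.z) * np.cos(profile.phi)
    rhs = cumulative_simpson(integrand, x=profile.s, initial=0.0)
    lhs = profile.x * np.sin(profile.phi)
    return (lhs - rhs) / b0


# ---------------------------------------------------------------------------
# Profile fitting (ADSA)
# ---------------------------------------------------------------------------

def _contour_distance(
    params: np.ndarray,
    contour_m: np.ndarray,
    fluids: FluidPair,
    s_max: float,
    fit_tilt: bool,
) -> np.ndarray:
    """Point-to-curve distances (m) between contour and a model profile."""
    gamma, b0, ax, az = params[:4]
    tilt = params[4] if fit_tilt else 0.0
    if gamma <= 0 or b0 <= 0:
        return np.full(len(contour_m), 1e3 * s_max)
    try:
        prof = young_laplace_profile(gamma, fluids, b0, s_max, n_samples=400,
                                     rtol=1e-8)
    except DropDetachedError:
        return np.full(len(contour_m), 1e3 * s_max)
    # de-tilt the contour about the apex, then fold onto the half meridian
    dx = contour_m[:, 0] - ax
    dz = contour_m[:, 1] - az
    if tilt != 0.0:
        ct, st = np.cos(-tilt), np.sin(-tilt)
        dx, dz = ct * dx - st * dz, st * dx + ct * dz
    folded = np.column_stack([np.abs(dx), dz])
    verts = prof.points
    tree = cKDTree(verts)
    _, idx = tree.query(folded)
    # orthogonal distance to the polyline: project onto the segments
    # adjacent to the nearest vertex (removes vertex-discretization bias)
    d = np.full(len(folded), np.inf)
    for i0, i1 in ((np.maximum(idx - 1, 0), idx), (idx, np.minimum(idx + 1, len(verts) - 1))):
        p0, p1 = verts[i0], verts[i1]
        seg = p1 - p0
        L2 = np.einsum("ij,ij->i", seg, seg)
        t = np.clip(
            np.einsum("ij,ij->i", folded - p0, seg) / np.where(L2 > 0, L2, 1.0), 0, 1
        )
        proj = p0 + t[:, None] * seg
        d = np.minimum(d, np.hypot(*(folded - proj).T))
    return d


def fit_pendant_drop(
    contour: np.ndarray,
    fluids: FluidPair,
    pixel_size: float,
    fit_tilt: bool = False,
    max_restarts: int = 4,
) -> tuple[float, float, float]:
    """Interfacial tension from a rising/pendant drop contour.

    Nonlinear least squares of the Young-Laplace shape family against the
    contour, over (gamma, b0, apex position[, tilt]). The contour is given in
    image pixel coordinates (origin top-left, y down) with the drop apex at
    the smallest y (rising drop imaged apex-up).

    Parameters
    ----------
    contour : (N, 2) array
        Contour points in pixels, >= 50 points spanning apex to neck.
    fluids : FluidPair
    pixel_size : float
        Physical length per pixel (m).
    fit_tilt : bool
        Also fit a rotation of the symmetry axis about the apex.
    max_restarts : int
        Number of Bond-number starts for the coarse scan.

    Returns
    -------
    (gamma, apex_radius, residual) : tuple of float
        Best-fit tension (N/m), apex radius (m) and RMS point-to-curve
        residual in pixels.

    Warns
    -----
    DegenerateShapeWarning
        If the fitted Bond number falls outside [1e-4, 10], where the shape
        barely constrains gamma.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2 or len(contour) < 50:
        raise ValueError("contour must be an (N>=50, 2) array of pixel coordinates")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")

    pts = contour * pixel_size
    g = fluids.g
    drho = abs(fluids.delta_rho)

    # geometric initialization: apex = lowest-z points; b0 from the apex
    # paraboloid z ~ x^2/(2 b0)
    z0 = pts[:, 1].min()
    extent = pts[:, 1].max() - z0
    near_apex = pts[pts[:, 1] <= z0 + 0.15 * extent]
    ax0 = float(np.mean(near_apex[:, 0]))
    az0 = z0
    u = near_apex[:, 0] - ax0
    v = near_apex[:, 1] - az0
    ok = v > 1e-12
    b0_init = float(np.median(u[ok] ** 2 / (2.0 * v[ok]))) if ok.sum() >= 3 else extent / 2
    b0_init = max(b0_init, 1e-2 * extent)

    u_max = np.max(np.abs(pts[:, 0] - ax0))
    s_max = 1.5 * (extent + u_max)

    # coarse Bond-number scan, then polish the best starts
    bond_grid = np.geomspace(0.02, 2.0, max_restarts + 2)
    best = None
    for bond in bond_grid:
        gamma0 = drho * g * b0_init**2 / bond
        p = np.array([gamma0, b0_init, ax0, az0] + ([0.0] if fit_tilt else []))
        r = _contour_distance(p, pts, fluids, s_max, fit_tilt)
        cost = float(np.sum(r**2))
        if best is None or cost < best[1]:
            best = (p, cost)

    scale = np.array(
        [best[0][0], b0_init, max(u_max, b0_init), max(extent, b0_init)]
        + ([1.0] if fit_tilt else [])
    )
    result = least_squares(
        _contour_distance,
        best[0],
        args=(pts, fluids, s_max, fit_tilt),
        x_scale=scale,
        xtol=1e-12,
        ftol=1e-12,
        method="lm" if not fit_tilt else "trf",
        max_nfev=400,
    )
    if not result.success and result.cost > best[1]:
        raise RuntimeError(
            f"pendant-drop fit did not converge (best RMS residual "
            f"{np.sqrt(np.mean(result.fun**2)) / pixel_size:.3g} px)"
        )

    gamma_fit, b0_fit = float(abs(result.x[0])), float(abs(result.x[1]))
    residual_px = float(np.sqrt(np.mean(result.fun**2)) / pixel_size)

    bond_fit = drho * g * b0_fit**2 / gamma_fit
    circle_px = _circle_rms(pts) / pixel_size
    if not (1e-4 <= bond_fit <= 10.0) or circle_px <= 1.05 * residual_px + 0.05:
        warnings.warn(
            f"Bond number {bond_fit:.3g}: drop shape is nearly degenerate "
            f"(a plain circle fits at {circle_px:.3g} px RMS vs "
            f"{residual_px:.3g} px for the Young-Laplace shape) and gamma is "
            "ill-constrained",
            DegenerateShapeWarning,
            stacklevel=2,
        )
    return gamma_fit, b0_fit, residual_px


def _circle_rms(pts: np.ndarray) -> float:
    """RMS radial residual of the best-fit circle (Kasa algebraic fit), in m."""
    x, z = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * z, np.ones_like(x)])
    sol, *_ = np.linalg.lstsq(A, x**2 + z**2, rcond=None)
    cx, cz, c = sol
    r = np.sqrt(c + cx**2 + cz**2)
    return float(np.sqrt(np.mean((np.hypot(x - cx, z - cz) - r) ** 2)))


# ---------------------------------------------------------------------------
# Tension decay fitting
# ---------------------------------------------------------------------------

def fit_tension_decay(times: np.ndarray, gammas: np.ndarray) -> TensionSeries:
    """Fit gamma(t) = gamma_eq + (gamma_0 - gamma_eq) * exp(-t/tau).

    gamma_eq — the plateau the tension relaxes to as surfactant adsorption
    equilibrates — is the reported equilibrium tension. 95% confidence
    intervals come from the fit covariance.

    Raises
    ------
    ValueError
        Fewer than 4 points.
    RuntimeError
        Non-convergence, with diagnostics.
    """
    series = TensionSeries(times=times, gammas=gammas)
    t = series.times - series.times[0]  # plateau invariant under time shifts
    y = series.gammas
    if len(t) < 4:
        raise ValueError(f"need >= 4 points to fit a decay, got {len(t)}")

    span = t[-1]
    if np.ptp(y) < 1e-12 * np.mean(y):
        # constant series: tau unidentifiable, plateau is the mean
        series.gamma_eq = series.gamma_0 = float(np.mean(y))
        series.tau_decay = span if span > 0 else 1.0
        series.ci95 = {"gamma_eq": 0.0, "gamma_0": 0.0, "tau_decay": np.inf}
        return series

    def model(t, g_eq, g_0, tau):
        return g_eq + (g_0 - g_eq) * np.exp(-t / tau)

    p0 = [y[-1], y[0], max(span / 3.0, np.finfo(float).tiny)]
    try:
        popt, pcov = curve_fit(
            model,
            t,
            y,
            p0=p0,
            bounds=([0.0, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10000,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"tension-decay fit did not converge (p0={p0}, n={len(t)}): {exc}"
        ) from exc

    series.gamma_eq, series.gamma_0, series.tau_decay = map(float, popt)
    err95 = 1.96 * np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    series.ci95 = dict(zip(("gamma_eq", "gamma_0", "tau_decay"), map(float, err95)))

    if span < series.tau_decay:
        warnings.warn(
            f"series spans {span:.3g} s but fitted tau is {series.tau_decay:.3g} s; "
            "the plateau is extrapolated",
            UserWarning,
            stacklevel=2,
        )
    return series
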