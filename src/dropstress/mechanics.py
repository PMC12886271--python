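"""Liquid-inclusion mechanics for droplet stress sensors.

A soft oil droplet embedded in an elastic medium deforms under far-field
stress. For an incompressible medium (Poisson ratio nu = 1/2) the Eshelby
framework extended to a liquid inclusion with interfacial tension gives a
closed-form aspect ratio of the deformed droplet:

    b/a = (1 + 10*eps) / (1 - 5*eps),   eps = (sigma_inf/E) / (6 + 15*gamma/(E*R))

where ``sigma_inf`` is the uniaxial stress applied to the medium far from the
droplet, ``E`` the medium's Young modulus, ``gamma`` the droplet/medium
interfacial tension and ``R`` the undeformed droplet radius. The dimensionless
parameter ``eps`` collapses all (E, gamma, R, sigma_inf) combinations onto a
single deformation curve.

Independently of any constitutive law for the medium, the Laplace balance on
an elliptical droplet cross-section gives the local anisotropic stress

    sigma_loc = 2*gamma*(C_b - C_a),  C_b = b/a**2,  C_a = 1/(2a) + a/(2b**2)

with b >= a the long and short semi-axes of the fitted ellipse.

All quantities are SI (m, Pa, N/m) unless noted. Unit conversion for
user-facing interfaces lives in :mod:`dropstress.units`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "MechanicalContext",
    "EllipseFit",
    "StressEstimate",
    "ModelValidityError",
    "EPSILON_STAR_MAX",
    "aspect_ratio_forward",
    "epsilon_star",
    "invert_stress_from_aspect",
    "local_anisotropic_stress",
    "elastocapillary_length",
    "max_tension_for_deformability",
    "stress_from_force",
]

#: The aspect-ratio law diverges as eps -> 1/5 (denominator -> 0).
EPSILON_STAR_MAX = 0.2


class ModelValidityError(ValueError):
    """Raised when parameters fall outside the inclusion model's validity."""


@dataclass(frozen=True)
class MechanicalContext:
    """Physical scalars entering the liquid-inclusion model.

    Parameters
    ----------
    E : float
        Young modulus of the surrounding medium (Pa, > 0).
    gamma : float
        Droplet/medium interfacial tension (N/m, >= 0).
    R : float
        Undeformed droplet radius (m, > 0).
    sigma_inf : float
        Uniaxial far-field stress applied to the medium (Pa).
    nu : float
        Poisson ratio of the medium. The aspect-ratio law used here is
        derived for an incompressible medium; any value other than 1/2
        is rejected.
    """

    E: float
    gamma: float
    R: float
    sigma_inf: float = 0.0
    nu: float = 0.5

    def __post_init__(self) -> None:
        if not (self.E > 0):
            raise ValueError(f"Young modulus must be > 0, got E={self.E}")
        if not (self.R > 0):
            raise ValueError(f"droplet radius must be > 0, got R={self.R}")
        if self.gamma < 0:
            raise ValueError(f"interfacial tension must be >= 0, got gamma={self.gamma}")
        if self.nu != 0.5:
            raise ValueError(
                "the inclusion model is derived for an incompressible medium; "
                f"nu must be exactly 1/2, got nu={self.nu}"
            )


@dataclass(frozen=True)
class EllipseFit:
    """A fitted droplet ellipse; carrier of the semi-axes (b >= a).

    Axes are normalized on construction so that ``b`` is always the long
    semi-axis regardless of argument order. Lengths are in whatever unit the
    caller uses consistently (pixels scaled by ``pixel_size`` give metres).
    """

    a: float
    b: float
    center_xy: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0
    pixel_size: float = 1.0
    axis_uncertainty: float | None = None

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"semi-axes must be > 0, got a={self.a}, b={self.b}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.a > self.b:
            # normalize: b is the long semi-axis; rotate orientation by 90 deg
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)
            object.__setattr__(
                self, "orientation", (self.orientation + math.pi / 2) % math.pi
            )
        if self.axis_uncertainty is None:
            object.__setattr__(self, "axis_uncertainty", self.pixel_size)

    @property
    def aspect_ratio(self) -> float:
        """Long over short semi-axis, >= 1."""
        return self.b / self.a

    @property
    def curvature_max(self) -> float:
        """Maximum curvature C_b = b/a**2 (at the ellipse tips)."""
        return self.b / self.a**2

    @property
    def curvature_min(self) -> float:
        """Minimum meridional curvature C_a = 1/(2a) + a/(2b**2)."""
        return 1.0 / (2.0 * self.a) + self.a / (2.0 * self.b**2)

    @property
    def equivalent_radius(self) -> float:
        """Radius of the area-equivalent circle, sqrt(a*b).

        For an incompressible droplet deforming at constant cross-section
        this is the undeformed radius.
        """
        return math.sqrt(self.a * self.b)


@dataclass(frozen=True)
class StressEstimate:
    """A stress value with its uncertainty and the estimator that produced it."""

    value: float
    uncertainty: float
    method: Literal["local_laplace", "inclusion_inverse", "force_over_area"]

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


# ---------------------------------------------------------------------------
# Forward / inverse deformation model
# ---------------------------------------------------------------------------

def epsilon_star(ctx: MechanicalContext) -> float:
    """Dimensionless collapse parameter of the inclusion deformation law.

    eps = (sigma_inf/E) / (6 + 15*gamma/(E*R)). Two contexts with equal eps
    have identical aspect ratios; plotted against eps, all deformation data
    collapse onto one curve.
    """
    return (ctx.sigma_inf / ctx.E) / (6.0 + 15.0 * ctx.gamma / (ctx.E * ctx.R))


def aspect_ratio_forward(ctx: MechanicalContext) -> float:
    """Aspect ratio b/a of a droplet under uniaxial far-field stress.

    Returns (1 + 10*eps)/(1 - 5*eps) with eps = epsilon_star(ctx). Exactly 1
    at zero stress. The law loses validity as eps -> 1/5 where the predicted
    elongation diverges.

    Raises
    ------
    ModelValidityError
        If eps >= 1/5 (denominator <= 0).
    """
    eps = epsilon_star(ctx)
    denom = 1.0 - 5.0 * eps
    if denom <= 0:
        raise ModelValidityError(
            f"epsilon_star={eps:.4g} is beyond model validity "
            f"(limit epsilon_star = 1/5): aspect ratio diverges"
        )
    return (1.0 + 10.0 * eps) / denom


def invert_stress_from_aspect(
    aspect: float, E: float, gamma: float, R: float
) -> StressEstimate:
    """Far-field stress from a measured aspect ratio (closed-form inverse).

    Solving the forward law for sigma_inf gives

        eps = (r - 1) / (5*r + 10),  sigma_inf = eps * E * (6 + 15*gamma/(E*R))

    with r = b/a >= 1. Round-trips :func:`aspect_ratio_forward` to machine
    precision.

    Parameters
    ----------
    aspect : float
        Measured aspect ratio b/a; must be >= 1 (normalize axes first).
    E, gamma, R : float
        Medium modulus (Pa), interfacial tension (N/m), droplet radius (m).
    """
    if aspect < 1:
        raise ValueError(
            f"aspect ratio must be >= 1 (long over short axis), got {aspect}; "
            "normalize the axes before inverting"
        )
    ctx = MechanicalContext(E=E, gamma=gamma, R=R)  # validates E, gamma, R
    eps = (aspect - 1.0) / (5.0 * aspect + 10.0)
    sigma = eps * ctx.E * (6.0 + 15.0 * ctx.gamma / (ctx.E * ctx.R))
    return StressEstimate(value=sigma, uncertainty=0.0, method="inclusion_inverse")


# ---------------------------------------------------------------------------
# Local Laplace stress
# ---------------------------------------------------------------------------

def _sigma_loc(a: float, b: float, gamma: float) -> float:
    c_b = b / a**2
    c_a = 1.0 / (2.0 * a) + a / (2.0 * b**2)
    return 2.0 * gamma * (c_b - c_a)


def local_anisotropic_stress(fit: EllipseFit, gamma: float) -> StressEstimate:
    """Local anisotropic stress on the droplet from its elliptical shape.

    sigma_loc = 2*gamma*(C_b - C_a) is the difference between the Laplace
    pressures at the points of extreme curvature of the ellipse; it is a
    purely geometric readout that holds regardless of the constitutive law of
    the surrounding medium. Non-negative, zero only for a sphere.

    The uncertainty is propagated from the fit's per-axis length uncertainty
    (one pixel by default) by re-evaluating with the short axis perturbed one
    way and the long axis the opposite way, and reporting half the spread
    between the two perturbed values.
    """
    if gamma < 0:
        raise ValueError("interfacial tension must be >= 0")
    a, b = fit.a, fit.b
    if a <= 0:
        raise ValueError("short semi-axis must be > 0")
    # C_b >= C_a analytically for b >= a; clamp the rounding residue at a ~ b
    value = max(_sigma_loc(a, b, gamma), 0.0)

    delta = fit.axis_uncertainty
    # anti-correlated perturbation: +delta on b / -delta on a maximizes the
    # anisotropy, and vice versa; half-spread estimates the 1-pixel error
    a_lo = max(a - delta, 1e-12 * a)
    hi = _sigma_loc(a_lo, b + delta, gamma)
    lo = _sigma_loc(a + delta, max(b - delta, a + delta), gamma)
    uncertainty = abs(hi - lo) / 2.0
    return StressEstimate(value=value, uncertainty=uncertainty, method="local_laplace")


def local_anisotropic_stress_linearized(fit: EllipseFit, gamma: float) -> float:
    """First-order analytic uncertainty on sigma_loc (cross-check).

    Propagates independent per-axis uncertainties through the gradient of
    sigma_loc(a, b) instead of the finite +/- one-pixel perturbation. Returns
    the 1-sigma uncertainty in the same units as the stress.
    """
    a, b, d = fit.a, fit.b, fit.axis_uncertainty
    dsda = (_sigma_loc(a + 1e-8 * a, b, gamma) - _sigma_loc(a - 1e-8 * a, b, gamma)) / (
        2e-8 * a
    )
    dsdb = (_sigma_loc(a, b + 1e-8 * b, gamma) - _sigma_loc(a, b - 1e-8 * b, gamma)) / (
        2e-8 * b
    )
    return math.hypot(dsda * d, dsdb * d)


# ---------------------------------------------------------------------------
# Elastocapillary design calculators
# ---------------------------------------------------------------------------

def elastocapillary_length(gamma: float, E: float) -> float:
    """Elastocapillary length L_ec = gamma/E (m).

    Droplets much smaller than L_ec are dominated by capillary stress and
    behave as rigid inclusions; droplets of radius comparable to or larger
    than L_ec can be deformed by the elastic stresses of the medium.
    """
    if E <= 0:
        raise ValueError(f"Young modulus must be > 0, got E={E}")
    if gamma < 0:
        raise ValueError("interfacial tension must be >= 0")
    return gamma / E


def max_tension_for_deformability(E: float, R_d: float) -> float:
    """Interfacial-tension scale below which a droplet is deformable.

    A droplet of radius R_d embedded in a medium of modulus E deforms
    observably when R_d >~ gamma/E, i.e. gamma <~ E*R_d. For typical soft
    tissues (E = 100-1000 Pa) and 10-um droplets this gives the 1-10 mN/m
    design window.
    """
    if E <= 0:
        raise ValueError(f"Young modulus must be > 0, got E={E}")
    if R_d < 0:
        raise ValueError("droplet radius must be >= 0")
    return E * R_d


def stress_from_force(F: float, A: float) -> StressEstimate:
    """Uniaxial stress from a measured normal force over a contact area."""
    if A <= 0:
        raise ValueError(f"contact area must be > 0, got A={A}")
    return StressEstimate(value=F / A, uncertainty=0.0, method="force_over_area")
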