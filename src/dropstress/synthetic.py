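"""Ground-truth generators for testing the analysis modules end to end.

Three generators emulate the data the package analyzes, each returning the
rendered data together with a machine-readable truth record so downstream
tests never re-derive ground truth from the rendering:

* :func:`make_emulsion_field` — a fluorescence micrograph of polydisperse
  inner water droplets with lognormal diameters (moment-matched to a target
  arithmetic mean and SD), rendered as anti-aliased bright disks;
* :func:`make_stressed_droplet` — an oil droplet silhouette deformed
  according to the forward inclusion model (aspect ratio from the mechanics
  module, cross-section area preserved, a*b = R^2) with an optional bright
  inner ring of controlled contrast;
* :func:`make_drop_profile` — a rising-drop contour from the Young-Laplace
  integrator with additive normal-direction noise.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mechanics import EllipseFit, MechanicalContext, aspect_ratio_forward
from .imaging import ImageFrame
from .tensiometry import FluidPair, young_laplace_profile

__all__ = [
    "EmulsionFieldSpec",
    "StressedDropletSpec",
    "lognormal_params",
    "sample_diameters",
    "make_emulsion_field",
    "make_stressed_droplet",
    "make_drop_profile",
]

# Reference emulsion statistics: diameter 0.66 +/- 0.37 um (mean +/- SD)
# as obtained with a 5-um-pore membrane; the lognormal family is chosen
# because diameters are positive and right-skewed with only these two
# moments reported.
DEFAULT_MEAN_UM = 0.66
DEFAULT_SD_UM = 0.37


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with given arithmetic mean and SD.

    Moment matching: sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be > 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_diameters(
    n: int, mean: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw n diameters from the moment-matched lognormal law."""
    mu, sigma = lognormal_params(mean, sd)
    return rng.lognormal(mu, sigma, size=n)


@dataclass(frozen=True)
class EmulsionFieldSpec:
    """Recipe for a synthetic emulsion micrograph.

    diameter_law is (arithmetic mean, SD) in um of the lognormal diameter
    distribution; overlap_fraction is the fraction of droplets deliberately
    placed touching a previous droplet (to exercise the watershed split).
    """

    n_droplets: int
    diameter_law: tuple[float, float] = (DEFAULT_MEAN_UM, DEFAULT_SD_UM)
    field_size: tuple[int, int] = (512, 512)
    pixel_size: float = 0.1  # um/px
    background: float = 100.0
    foreground: float = 1000.0
    overlap_fraction: float = 0.0
    noise_sd: float = 0.0
    resolution_um: float = 0.3  # optical resolution: spots render no smaller
    seed: int = 0

    def __post_init__(self) -> None:
        mean, sd = self.diameter_law
        if mean <= 0 or sd <= 0:
            raise ValueError("diameter law mean and sd must be > 0")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.n_droplets < 0:
            raise ValueError("n_droplets must be >= 0")


def _render_disk(img: np.ndarray, cx: float, cy: float, r_px: float, level: float) -> None:
    """Additive anti-aliased disk: coverage ~ clip(r + 0.5 - dist, 0, 1)."""
    h, w = img.shape
    x0, x1 = max(int(cx - r_px - 2), 0), min(int(cx + r_px + 3), w)
    y0, y1 = max(int(cy - r_px - 2), 0), min(int(cy + r_px + 3), h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    cover = np.clip(r_px + 0.5 - dist, 0.0, 1.0)
    img[y0:y1, x0:x1] = np.maximum(img[y0:y1, x0:x1], level * cover)


def make_emulsion_field(spec: EmulsionFieldSpec):
    """Render a synthetic emulsion field with exact ground truth.

    Returns
    -------
    (frame, truth) : (ImageFrame, dict)
        truth holds per-droplet "diameters_um", "centers_px" (x, y) and the
        sampling parameters, and is the only ground-truth channel tests
        should consume.

    Raises
    ------
    RuntimeError
        If the field is too small to place the requested droplets without
        exceeding the allowed overlap fraction.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size
    img = np.zeros((h, w), dtype=float)

    diameters = sample_diameters(spec.n_droplets, *spec.diameter_law, rng)
    # diffraction-limited image formation: a droplet below the optical
    # resolution appears as a spot of the resolution size, never smaller
    apparent = np.maximum(diameters, spec.resolution_um)
    radii_px = apparent / 2.0 / spec.pixel_size

    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    n_overlap_target = int(round(spec.overlap_fraction * spec.n_droplets))
    for i, r in enumerate(radii_px):
        want_overlap = i > 0 and i <= n_overlap_target
        for attempt in range(2000):
            if want_overlap:
                j = rng.integers(0, len(centers))
                # center distance ~ 0.8 * (r_i + r_j): clearly two lobes
                ang = rng.uniform(0, 2 * np.pi)
                dist = 0.8 * (r + placed_r[j])
                cx = centers[j][0] + dist * np.cos(ang)
                cy = centers[j][1] + dist * np.sin(ang)
            else:
                cx = rng.uniform(r + 2, w - r - 2)
                cy = rng.uniform(r + 2, h - r - 2)
            if not (r + 1 <= cx <= w - r - 1 and r + 1 <= cy <= h - r - 1):
                continue
            ok = True
            for (ox, oy), orr in zip(centers, placed_r):
                d = np.hypot(cx - ox, cy - oy)
                if want_overlap and d < 0.99 * (r + orr):
                    # only the deliberate neighbour may touch
                    if d < 0.5 * (r + orr):
                        ok = False
                        break
                elif not want_overlap and d < r + orr + 2:
                    ok = False
                    break
            if ok:
                break
        else:
            raise RuntimeError(
                f"could not place droplet {i} of {spec.n_droplets}: field too "
                "small for the requested density/overlap"
            )
        centers.append((cx, cy))
        placed_r.append(r)
        _render_disk(img, cx, cy, r, spec.foreground - spec.background)

    img += spec.background
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
        img = np.clip(img, 0.0, None)

    frame = ImageFrame(img, spec.pixel_size)
    truth = {
        "diameters_um": np.asarray(diameters),
        "centers_px": np.asarray(centers, dtype=float).reshape(-1, 2),
        "diameter_law": {"family": "lognormal-moment-matched",
                         "mean_um": spec.diameter_law[0],
                         "sd_um": spec.diameter_law[1]},
        "pixel_size_um": spec.pixel_size,
        "seed": spec.seed,
    }
    return frame, truth


@dataclass(frozen=True)
class StressedDropletSpec:
    """Recipe for a single deformed-droplet silhouette.

    The rendered ellipse has aspect ratio given by the forward inclusion
    model for ``context`` and preserves the undeformed cross-section
    (a*b = R^2, incompressibility), with R = ``radius_px`` pixels.
    """

    context: MechanicalContext
    radius_px: float = 60.0
    field_size: tuple[int, int] = (256, 256)
    pixel_size: float = 0.5  # um/px
    orientation: float = 0.0
    background: float = 100.0
    foreground: float = 600.0
    ring_contrast: float = 1.0  # ring level over background; 1 = no ring
    ring_width_px: float = 6.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ring_contrast < 1:
            raise ValueError("ring_contrast must be >= 1")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be > 0")


def make_stressed_droplet(spec: StressedDropletSpec):
    """Render a deformed droplet and its exact EllipseFit ground truth.

    Returns (frame, truth_fit) where truth_fit is the EllipseFit (in pixel
    units) the renderer used: semi-axes b = R*sqrt(r), a = R/sqrt(r) with
    r the forward-model aspect ratio. Validity violations propagate from the
    mechanics module.
    """
    rng = np.random.default_rng(spec.seed)
    ratio = aspect_ratio_forward(spec.context)  # raises beyond validity
    R = spec.radius_px
    b_px = R * math.sqrt(ratio)
    a_px = R / math.sqrt(ratio)

    h, w = spec.field_size
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    ct, st = math.cos(spec.orientation), math.sin(spec.orientation)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct

    # signed "radial" distance surrogate: scaled so 0 on the ellipse,
    # ~pixels near the boundary (gradient of the implicit form ~ 1)
    rho = np.sqrt((u / b_px) ** 2 + (v / a_px) ** 2)
    r_local = np.sqrt((u * a_px / b_px) ** 2 + (v * b_px / a_px) ** 2)
    r_local = np.where(r_local == 0, 1e-9, r_local)
    signed = (rho - 1.0) * r_local / np.maximum(rho, 1e-9)

    img = np.full((h, w), spec.background, dtype=float)
    if spec.ring_contrast > 1.0:
        # fluorescence-style fixture: interior stays at background, only a
        # band of width ring_width_px just inside the contour is bright
        coverage = np.clip(0.5 - signed, 0.0, 1.0) * np.clip(
            signed + spec.ring_width_px + 0.5, 0.0, 1.0
        )
        img += (spec.ring_contrast - 1.0) * spec.background * coverage
    else:
        # brightfield-style silhouette for deformation fixtures
        inside = np.clip(0.5 - signed, 0.0, 1.0)
        img += (spec.foreground - spec.background) * inside

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
        img = np.clip(img, 0.0, None)

    frame = ImageFrame(img, spec.pixel_size)
    truth = EllipseFit(
        a=a_px,
        b=b_px,
        center_xy=(cx, cy),
        orientation=spec.orientation % math.pi,
        pixel_size=spec.pixel_size,
    )
    return frame, truth


def make_drop_profile(
    gamma: float,
    fluids: FluidPair,
    apex_radius: float,
    arc_length_max: float,
    pixel_size: float,
    noise_sd_px: float = 0.0,
    n_points: int = 300,
    seed: int = 0,
    two_sided: bool = True,
):
    """Synthetic rising-drop contour in pixel coordinates, with truth.

    Integrates the Young-Laplace meridian, maps it to image pixels (apex-up,
    origin top-left, y down), optionally mirrors it to a full two-sided
    contour, and perturbs each point by Gaussian noise of ``noise_sd_px``
    pixels along the local normal.

    Returns (contour_px, truth) where truth records gamma, apex radius, Bond
    number, pixel size and the apex pixel position.
    """
    rng = np.random.default_rng(seed)
    prof = young_laplace_profile(gamma, fluids, apex_radius, arc_length_max,
                                 n_samples=n_points)
    x, z, phi = prof.x, prof.z, prof.phi
    if two_sided:
        x = np.concatenate([-x[::-1], x[1:]])
        z = np.concatenate([z[::-1], z[1:]])
        phi = np.concatenate([-phi[::-1], phi[1:]])

    # normals of the meridian: tangent (cos phi, sin phi) -> normal (-sin, cos)
    if noise_sd_px > 0:
        eta = rng.normal(0.0, noise_sd_px * pixel_size, size=x.shape)
        x = x + eta * (-np.sin(phi))
        z = z + eta * np.cos(phi)

    apex_px = (
        1.2 * prof.x.max() / pixel_size + 10.0,
        10.0,
    )
    contour = np.column_stack([x / pixel_size + apex_px[0], z / pixel_size + apex_px[1]])
    truth = {
        "gamma": gamma,
        "apex_radius": apex_radius,
        "bond": prof.bond_number,
        "pixel_size": pixel_size,
        "apex_px": apex_px,
        "noise_sd_px": noise_sd_px,
        "seed": seed,
    }
    return contour, truth
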