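"""Quantification of droplet micrographs.

Four measurements, mirroring a typical inverted-emulsion imaging workflow:

* inner-droplet sizing — intensity threshold, distance-transform watershed to
  split touching droplets, then shape filters (minimum area, minimum
  circularity) and a resolution floor on the diameters;
* time-series preprocessing — histogram matching against a reference frame to
  compensate bleaching, plus saturation of outliers at 10x the background;
* functionalization signal — mean fluorescence in a thin ring just inside the
  droplet contour divided by the mean background intensity, a proxy for how
  much binder has relocated to the droplet surface;
* deformation — least-squares ellipse fit of a droplet contour, feeding the
  local Laplace stress estimator with a +/- one-pixel axis uncertainty.

Image convention: pixel centers, origin top-left, x right / y down. All
physical outputs are scaled by ``pixel_size`` (um per pixel unless stated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import least_squares
from skimage import exposure, measure, segmentation

from .mechanics import EllipseFit, StressEstimate, local_anisotropic_stress

__all__ = [
    "ImageFrame",
    "SizeDistribution",
    "RingMeasurement",
    "preprocess_frames",
    "segment_inner_droplets",
    "surface_weighted_cdf",
    "functionalization_signal",
    "fit_ellipse",
    "track_droplet_stress",
    "select_equatorial_plane",
]

#: Default shape filters and resolution floor for inner-droplet sizing.
MIN_AREA_PX = 6.0  # objects below this area (px^2) are discarded
MIN_CIRCULARITY = 0.5
RESOLUTION_FLOOR_UM = 0.3  # diameters below the optical resolution are floored
SATURATION_FACTOR = 10.0  # cap pixels above this multiple of background


@dataclass(frozen=True)
class ImageFrame:
    """A single grayscale frame with its physical pixel size (um/px)."""

    pixels: np.ndarray
    pixel_size: float
    time_index: int | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "pixels", px)


@dataclass
class SizeDistribution:
    """Per-droplet sizes from a segmented frame (diameters/areas in um)."""

    diameters: np.ndarray
    areas: np.ndarray
    circularities: np.ndarray
    resolution_floor: float = RESOLUTION_FLOOR_UM

    def __post_init__(self) -> None:
        self.diameters = np.atleast_1d(np.asarray(self.diameters, dtype=float))
        self.areas = np.atleast_1d(np.asarray(self.areas, dtype=float))
        self.circularities = np.atleast_1d(np.asarray(self.circularities, dtype=float))

    def __len__(self) -> int:
        return self.diameters.size

    @property
    def mean_diameter(self) -> float:
        return float(np.mean(self.diameters))

    @property
    def sd_diameter(self) -> float:
        return float(np.std(self.diameters))


@dataclass(frozen=True)
class RingMeasurement:
    """Ring-over-background fluorescence ratio of one droplet."""

    ring_mean: float
    background_mean: float
    signal: float
    ring_width: float
    n_ring_pixels: int

    def __post_init__(self) -> None:
        if self.background_mean <= 0:
            raise ValueError("background_mean must be > 0")
        if self.signal < 0:
            raise ValueError("signal must be >= 0")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def estimate_background(
    pixels: np.ndarray, statistic: str = "median"
) -> float:
    """Background level: statistic of pixels outside detected objects.

    Objects are detected with an Otsu threshold; if thresholding finds
    nothing (e.g. a uniform frame) the statistic is taken over all pixels.
    ``statistic`` is "median" (robust default) or "mean".
    """
    from skimage.filters import threshold_otsu

    px = np.asarray(pixels, dtype=float)
    flat = px.ravel()
    if np.ptp(flat) > 0:
        try:
            mask = px > threshold_otsu(px)
        except ValueError:
            mask = np.zeros_like(px, dtype=bool)
        outside = px[~mask]
        if outside.size:
            flat = outside
    if statistic == "median":
        return float(np.median(flat))
    if statistic == "mean":
        return float(np.mean(flat))
    raise ValueError(f"statistic must be 'median' or 'mean', got {statistic!r}")


def preprocess_frames(
    frames: Sequence[ImageFrame],
    reference_index: int = 0,
    saturation_factor: float = SATURATION_FACTOR,
    background_statistic: str = "median",
) -> list[ImageFrame]:
    """Bleaching and saturation compensation for a time series.

    Each frame's histogram is matched to the reference frame (the first by
    default, taken before bleaching has dimmed the signal); then any pixel
    above ``saturation_factor`` times the frame background is set to exactly
    that cap. Frames must share a shape.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    shape = frames[0].pixels.shape
    if any(f.pixels.shape != shape for f in frames):
        raise ValueError("all frames must share the same shape")
    ref = frames[reference_index].pixels

    out: list[ImageFrame] = []
    for f in frames:
        px = f.pixels
        if px is not ref:
            px = exposure.match_histograms(px, ref)
        bg = estimate_background(px, background_statistic)
        cap = saturation_factor * bg
        if bg > 0:
            px = np.minimum(px, cap)
        out.append(ImageFrame(px, f.pixel_size, f.time_index))
    return out


# ---------------------------------------------------------------------------
# Sizing
# ---------------------------------------------------------------------------

def segment_inner_droplets(
    frame: ImageFrame,
    threshold: float | None = None,
    min_area_px: float = MIN_AREA_PX,
    min_circularity: float = MIN_CIRCULARITY,
    resolution_floor: float = RESOLUTION_FLOOR_UM,
) -> SizeDistribution:
    """Size the inner water droplets of an emulsion field.

    Binarize at ``threshold`` (Otsu when None), split touching droplets by a
    watershed on the distance transform, then apply the shape filters: drop
    objects with area < ``min_area_px`` pixels or circularity
    (4*pi*area/perimeter^2) < ``min_circularity``, and floor equivalent
    diameters below ``resolution_floor`` (um) to exactly that floor. Filters
    run before flooring, so flooring never changes the object count.

    An empty image yields an empty distribution, not an error.
    """
    from skimage.filters import threshold_otsu

    px = frame.pixels
    if threshold is None:
        if np.ptp(px) == 0:
            return SizeDistribution(np.empty(0), np.empty(0), np.empty(0),
                                    resolution_floor)
        threshold = threshold_otsu(px)
    binary = px > threshold
    if not binary.any():
        return SizeDistribution(np.empty(0), np.empty(0), np.empty(0),
                                resolution_floor)

    distance = ndi.distance_transform_edt(binary)
    # markers = connected plateaus of local distance maxima: one basin per
    # droplet, and ridge-shaped objects (a single connected plateau) are not
    # fragmented into pieces
    peak_mask = (distance == ndi.maximum_filter(distance, size=5)) & binary
    markers, _ = ndi.label(peak_mask)
    labels = segmentation.watershed(-distance, markers, mask=binary)

    diams, areas, circs = [], [], []
    scale = frame.pixel_size
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        perim = region.perimeter
        if perim <= 0:
            continue
        circ = min(4.0 * np.pi * region.area / perim**2, 1.0)
        if circ < min_circularity:
            continue
        d = region.equivalent_diameter_area * scale
        diams.append(max(d, resolution_floor))
        areas.append(region.area * scale**2)
        circs.append(circ)

    return SizeDistribution(
        np.asarray(diams), np.asarray(areas), np.asarray(circs), resolution_floor
    )


def surface_weighted_cdf(
    dist: SizeDistribution | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Surface-weighted cumulative distribution of droplet diameters.

    Each droplet contributes with weight proportional to its surface area
    (d^2), so the curve answers "what fraction of the total interfacial area
    sits on droplets smaller than d". Returns (sorted diameters, cumulative
    fraction); the final value is exactly 1.
    """
    diameters = np.asarray(getattr(dist, "diameters", dist), dtype=float)
    if diameters.size == 0:
        raise ValueError("size distribution is empty")
    order = np.argsort(diameters)
    d = diameters[order]
    w = d**2
    cdf = np.cumsum(w) / np.sum(w)
    cdf[-1] = 1.0
    return d, cdf


# ---------------------------------------------------------------------------
# Functionalization ring signal
# ---------------------------------------------------------------------------

def _contour_mask(contour: "EllipseFit | np.ndarray", shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels inside a closed contour (ellipse or polygon)."""
    from skimage.draw import polygon2mask

    if isinstance(contour, EllipseFit):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        cx, cy = contour.center_xy
        ct, st = np.cos(contour.orientation), np.sin(contour.orientation)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        return (u / contour.b) ** 2 + (v / contour.a) ** 2 <= 1.0
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("contour must be an EllipseFit or an (N>=3, 2) point list")
    # polygon2mask expects (row, col) = (y, x)
    return polygon2mask(shape, pts[:, ::-1])


def functionalization_signal(
    frame: ImageFrame,
    contour: "EllipseFit | np.ndarray",
    ring_width: float = 3.0,
) -> RingMeasurement:
    """Ring-over-background fluorescence of a droplet surface.

    The ring is the set of pixels inside the contour lying within
    ``ring_width`` (um) of it; the signal is its mean intensity divided by
    the mean intensity outside the contour. Values near 1 mean a bare
    droplet; functionalized droplets in practice reach ~1.9.

    Raises
    ------
    ValueError
        If the contour touches the frame edge, or the droplet is too small
        to contain the ring.
    """
    px = frame.pixels
    mask = _contour_mask(contour, px.shape)
    if not mask.any():
        raise ValueError("contour encloses no pixels")
    edge = np.zeros_like(mask)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    if (mask & edge).any():
        raise ValueError("contour touches the frame edge; ring would be clipped")

    ring_px = ring_width / frame.pixel_size
    depth = ndi.distance_transform_edt(mask)
    ring = mask & (depth <= ring_px)
    interior = mask & (depth > ring_px)
    if not interior.any():
        raise ValueError(
            f"droplet smaller than the {ring_width} um ring width; "
            "ring region is the whole droplet"
        )
    background = px[~mask]
    bg_mean = float(np.mean(background))
    if bg_mean <= 0:
        raise ValueError("background intensity is zero; signal undefined")
    ring_mean = float(np.mean(px[ring]))
    return RingMeasurement(
        ring_mean=ring_mean,
        background_mean=bg_mean,
        signal=ring_mean / bg_mean,
        ring_width=ring_width,
        n_ring_pixels=int(ring.sum()),
    )


# ---------------------------------------------------------------------------
# Ellipse fitting and deformation tracking
# ---------------------------------------------------------------------------

def fit_ellipse(
    contour: np.ndarray,
    pixel_size: float = 1.0,
    refine: bool = True,
) -> EllipseFit:
    """Least-squares ellipse fit of a droplet contour.

    Algebraic (direct conic) fit seeds a geometric refinement that minimizes
    orthogonal point-to-ellipse distances. Axes are normalized so b >= a;
    lengths are returned in the units of ``pixel_size`` per pixel, and the
    per-axis uncertainty is set to one pixel.

    Parameters
    ----------
    contour : (N >= 5, 2) array
        Contour points in pixel coordinates (x, y).
    pixel_size : float
        Physical length per pixel; 1.0 keeps pixel units.
    refine : bool
        Run the geometric refinement after the algebraic fit.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise ValueError("need >= 5 contour points to fit an ellipse")
    model = measure.EllipseModel.from_estimate(pts)
    if not model or not np.all(np.isfinite(np.r_[model.center,
                                                model.axis_lengths,
                                                model.theta])):
        raise ValueError("degenerate contour: ellipse fit failed")
    (xc, yc), (a1, a2), theta = model.center, model.axis_lengths, model.theta

    if refine:
        def resid(p):
            m = measure.EllipseModel((p[0], p[1]), (abs(p[2]), abs(p[3])), p[4])
            return m.residuals(pts)

        res = least_squares(resid, [xc, yc, a1, a2, theta], method="lm", xtol=1e-14)
        if res.success and np.all(np.isfinite(res.x)):
            xc, yc, a1, a2, theta = res.x

    a1, a2 = abs(a1), abs(a2)
    if a1 >= a2:
        b, a, orient = a1, a2, theta
    else:
        b, a, orient = a2, a1, theta + np.pi / 2
    return EllipseFit(
        a=a * pixel_size,
        b=b * pixel_size,
        center_xy=(float(xc), float(yc)),
        orientation=float(orient % np.pi),
        pixel_size=pixel_size,
        axis_uncertainty=pixel_size,
    )


def track_droplet_stress(
    frames: Sequence[ImageFrame],
    contours: Sequence[np.ndarray],
    gamma: float,
) -> list[StressEstimate]:
    """Local anisotropic stress of one droplet followed over time.

    Per frame: fit an ellipse to the droplet contour, then evaluate
    sigma_loc = 2*gamma*(C_b - C_a) with the +/- one-pixel axis uncertainty.
    Lengths are converted by each frame's pixel size (um/px); gamma is in
    N/m and stresses come out in Pa when pixel sizes are given in metres,
    or in Pa with um-lengths if gamma is given per um (use consistent units;
    the CLI converts um -> m before calling).
    """
    if len(frames) != len(contours):
        raise ValueError("need exactly one contour per frame")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    out = []
    for frame, contour in zip(frames, contours):
        fit = fit_ellipse(contour, pixel_size=frame.pixel_size)
        out.append(local_anisotropic_stress(fit, gamma))
    return out


def select_equatorial_plane(
    stack: Sequence[ImageFrame], contours: Sequence[np.ndarray]
) -> int:
    """Index of the z-slice where the fitted droplet ellipse is largest.

    For a convex droplet the equatorial section maximizes the cross-section
    area pi*a*b, so the argmax slice is the equatorial plane.
    """
    if len(stack) != len(contours):
        raise ValueError("need one contour per slice")
    areas = []
    for frame, contour in zip(stack, contours):
        fit = fit_ellipse(contour, pixel_size=frame.pixel_size)
        areas.append(np.pi * fit.a * fit.b)
    return int(np.argmax(areas))
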