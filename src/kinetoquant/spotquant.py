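"""Per-kinetochore recruitment quantification.

Implements the spot-level pipeline used for kinetochore recruitment
assays (e.g. MPS1 relative to CENP-C): a binary kinetochore mask from a
white top-hat of the reference channel thresholded by the iterative
intermeans (isodata) rule; circular 8 px-diameter spot ROIs at the
brightest non-overlapping maxima; a local background ROI accrued
radially from pixels outside both the spot ROI and the kinetochore
mask; channel-by-channel background subtraction with negative values
clipped to zero; and per-kinetochore normalization to the reference
channel, averaged per cell.

Conventions fixed here (and relied on by the tests):

- Even ROI diameters are rasterized about the pixel *corner* nearest
  the detected maximum; pixel centers sit at half-integer offsets from
  that corner, and a diameter-8 disc then contains exactly 52 lattice
  pixels — the same count the background ROI accrues ("an equivalent
  number of pixels"). Odd diameters center on the nearest pixel.
- Background candidates are visited in order of increasing Euclidean
  distance from the ROI center, ties broken in row-major scan order,
  so the accrued set is deterministic across platforms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk, white_tophat

from .errors import (
    ChannelRoleError,
    DegenerateImageError,
    InsufficientBackgroundError,
    RoiOutOfBoundsError,
)
from .imgio import CellCrop, ImageStack, sum_project

DEFAULT_ROI_DIAMETER = 8
DEFAULT_BG_SIZE = 52
DEFAULT_N_SPOTS = 20
DEFAULT_MIN_SEP = 8
DEFAULT_TOPHAT_RADIUS = 5


# ---------------------------------------------------------------------------
# morphology + thresholding primitives
# ---------------------------------------------------------------------------

def tophat_transform(image: np.ndarray, radius_px: int) -> np.ndarray:
    """White top-hat: the image minus its grayscale opening by a disc.

    Retains bright features smaller than the disc (kinetochore spots)
    while removing slowly varying background; the result is
    non-negative and invariant to an additive constant offset.
    """
    if radius_px < 1:
        raise ValueError("structuring-element radius must be >= 1 px")
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("tophat_transform expects a 2D image")
    return white_tophat(img, footprint=disk(radius_px))


def isodata_threshold(values: np.ndarray, *, eps: float | None = None) -> float:
    """Iterative intermeans (isodata) threshold of an intensity sample.

    Starting from the global mean, iterate
    ``t <- (mean(values <= t) + mean(values > t)) / 2``
    to its fixed point. Convergence tolerance: 0.5 intensity units for
    integer data, 1e-6 relative for float (overridable via ``eps``).

    Raises :class:`DegenerateImageError` for a constant sample.
    """
    v = np.asarray(values).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0 or v.min() == v.max():
        raise DegenerateImageError("cannot threshold a constant (or empty) sample")
    if eps is None:
        eps = 0.5 if np.issubdtype(v.dtype, np.integer) else 1e-6 * float(v.max() - v.min())
    v = v.astype(np.float64)
    t = float(v.mean())
    for _ in range(500):
        lo = v[v <= t]
        hi = v[v > t]
        if hi.size == 0:  # t at or above max; nudge to the top interval midpoint
            t_new = (lo.mean() + v.max()) / 2.0
        else:
            t_new = (lo.mean() + hi.mean()) / 2.0
        if abs(t_new - t) < eps:
            return float(t_new)
        t = t_new
    return float(t)


@dataclass
class KinetochoreMask:
    """Binary mask of kinetochore signal in the reference channel."""

    mask: np.ndarray
    source_channel: str
    threshold_value: float
    tophat: np.ndarray | None = None


def build_kinetochore_mask(
    reference_channel: np.ndarray,
    tophat_radius: int = DEFAULT_TOPHAT_RADIUS,
    *,
    source_channel: str = "reference_kt",
) -> KinetochoreMask:
    """Top-hat the reference channel and threshold it by intermeans.

    The mask marks pixels belonging to kinetochore signal; background
    accrual later avoids them. Constant (blank) channels raise."""
    th = tophat_transform(reference_channel, tophat_radius)
    t = isodata_threshold(th)
    return KinetochoreMask(
        mask=th > t, source_channel=source_channel, threshold_value=t, tophat=th
    )


# ---------------------------------------------------------------------------
# maxima detection
# ---------------------------------------------------------------------------

def detect_maxima(
    reference_channel: np.ndarray,
    n_spots: int = DEFAULT_N_SPOTS,
    min_sep_px: float = DEFAULT_MIN_SEP,
    *,
    tophat_radius: int = DEFAULT_TOPHAT_RADIUS,
    exclude_border: int = 0,
) -> list[tuple[int, int]]:
    """Brightest non-overlapping local maxima of the top-hat image.

    Candidate maxima (8-neighborhood, on the top-hat so tilted
    background cannot create false peaks) are visited in descending
    intensity, ties broken row-major, and greedily accepted subject to
    pairwise separation >= ``min_sep_px``. Returns fewer than
    ``n_spots`` centers with a warning when the image cannot supply
    them. ``exclude_border`` drops candidates within that many pixels
    of the edge (so spot and background ROIs fit).
    """
    th = tophat_transform(reference_channel, tophat_radius)
    footprint_max = ndi.maximum_filter(th, size=3, mode="constant", cval=-np.inf)
    is_max = (th >= footprint_max) & (th > 0)
    ys, xs = np.nonzero(is_max)
    if exclude_border > 0:
        H, W = th.shape
        keep = (
            (ys >= exclude_border)
            & (ys < H - exclude_border)
            & (xs >= exclude_border)
            & (xs < W - exclude_border)
        )
        ys, xs = ys[keep], xs[keep]
    vals = th[ys, xs]
    order = np.lexsort((xs, ys, -vals))  # primary: intensity desc; ties row-major

    selected: list[tuple[int, int]] = []
    min_sep2 = float(min_sep_px) ** 2
    for i in order:
        p = (int(ys[i]), int(xs[i]))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep2 for q in selected):
            selected.append(p)
            if len(selected) == n_spots:
                break
    if len(selected) < n_spots:
        warnings.warn(
            f"requested {n_spots} maxima but only {len(selected)} qualify",
            stacklevel=2,
        )
    return selected


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

def _rasterization_center(center: tuple[float, float], diameter_px: int) -> tuple[float, float]:
    """Disc center used for rasterization: nearest pixel corner for even
    diameters, nearest pixel center for odd."""
    cy, cx = center
    if diameter_px % 2 == 0:
        return (math.floor(cy) + 0.5, math.floor(cx) + 0.5)
    return (float(round(cy)), float(round(cx)))


def _disc_pixels(raster_center: tuple[float, float], diameter_px: int) -> list[tuple[int, int]]:
    cy, cx = raster_center
    r2 = (diameter_px / 2.0) ** 2
    ylo, yhi = math.ceil(cy - diameter_px / 2), math.floor(cy + diameter_px / 2)
    out = []
    for y in range(ylo, yhi + 1):
        for x in range(math.ceil(cx - diameter_px / 2), math.floor(cx + diameter_px / 2) + 1):
            if (y - cy) ** 2 + (x - cx) ** 2 < r2:  # strictly inside
                out.append((y, x))
    return out


@dataclass
class SpotROI:
    """Circular spot ROI on the pixel lattice.

    ``raster_center`` is the sub-pixel disc center actually used (a
    pixel corner for even diameters); ``pixel_set`` the lattice pixels
    strictly inside the disc. Diameter 8 yields exactly 52 pixels.
    """

    center: tuple[float, float]
    diameter_px: int = DEFAULT_ROI_DIAMETER
    raster_center: tuple[float, float] = field(init=False)
    pixel_set: list[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        if self.diameter_px < 1:
            raise ValueError("ROI diameter must be >= 1 px")
        self.raster_center = _rasterization_center(self.center, self.diameter_px)
        self.pixel_set = _disc_pixels(self.raster_center, self.diameter_px)


def build_spot_roi(
    center: tuple[float, float],
    diameter_px: int = DEFAULT_ROI_DIAMETER,
    *,
    image_shape: tuple[int, int] | None = None,
) -> SpotROI:
    """Build the circular ROI at a detected maximum.

    If ``image_shape`` is given, an ROI whose pixels fall outside the
    image raises :class:`RoiOutOfBoundsError`.
    """
    roi = SpotROI(center=center, diameter_px=diameter_px)
    if image_shape is not None:
        H, W = image_shape
        for (y, x) in roi.pixel_set:
            if not (0 <= y < H and 0 <= x < W):
                raise RoiOutOfBoundsError(
                    f"spot ROI at {center} extends beyond image of shape {image_shape}"
                )
    return roi


@dataclass
class BackgroundROI:
    """Background pixels accrued radially around a spot ROI."""

    pixel_set: list[tuple[int, int]]
    target_size: int
    spot_center: tuple[float, float]


def accrue_background(
    roi: SpotROI,
    kt_mask: KinetochoreMask | np.ndarray,
    target_size: int = DEFAULT_BG_SIZE,
) -> BackgroundROI:
    """Accrue the local background ROI for a spot.

    Pixels are visited in order of increasing Euclidean distance from
    the ROI's rasterization center (ties row-major); pixels inside the
    spot ROI or under the binary kinetochore mask are skipped; accrual
    stops once ``target_size`` pixels are collected. Raises
    :class:`InsufficientBackgroundError` when the image cannot supply
    enough eligible pixels.
    """
    mask = kt_mask.mask if isinstance(kt_mask, KinetochoreMask) else np.asarray(kt_mask)
    H, W = mask.shape
    cy, cx = roi.raster_center
    roi_set = set(roi.pixel_set)

    # Expanding search: only accept candidates with distance <= R before
    # growing the window, so truncation can never reorder the accrual.
    max_r = math.dist((cy, cx), (0, 0))
    for corner in ((0, W - 1), (H - 1, 0), (H - 1, W - 1)):
        max_r = max(max_r, math.dist((cy, cx), corner))
    R = float(roi.diameter_px + 4)
    while True:
        ylo, yhi = max(0, math.ceil(cy - R)), min(H - 1, math.floor(cy + R))
        xlo, xhi = max(0, math.ceil(cx - R)), min(W - 1, math.floor(cx + R))
        yy, xx = np.mgrid[ylo : yhi + 1, xlo : xhi + 1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        inside = d2 <= R * R
        cand = sorted(
            zip(d2[inside].tolist(), yy[inside].tolist(), xx[inside].tolist())
        )
        collected: list[tuple[int, int]] = []
        for _, y, x in cand:
            p = (int(y), int(x))
            if p in roi_set or mask[p]:
                continue
            collected.append(p)
            if len(collected) == target_size:
                return BackgroundROI(
                    pixel_set=collected, target_size=target_size, spot_center=roi.center
                )
        if R >= max_r:
            raise InsufficientBackgroundError(
                f"only {len(collected)} eligible background pixels "
                f"(need {target_size})"
            )
        R = min(2 * R, max_r)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

@dataclass
class SpotMeasurement:
    """Per-kinetochore, per-channel intensities and reference ratio.

    ``corrected`` is ``max(roi_mean - bg_mean, 0)`` per channel;
    ``ratio`` is corrected(channel) / corrected(reference); the
    measurement is flagged invalid (ratios ``nan``) when the reference
    corrected mean is zero.
    """

    center: tuple[float, float]
    roi_mean: dict[str, float]
    bg_mean: dict[str, float]
    corrected: dict[str, float]
    ratio: dict[str, float]
    valid: bool


def _as_projection(image) -> ImageStack:
    if isinstance(image, CellCrop):
        image = image.stack
    if not isinstance(image, ImageStack):
        raise TypeError("expected an ImageStack or CellCrop")
    if image.n_slices != 1:
        image = sum_project(image)
    return image


def measure_spot(
    projection: ImageStack | CellCrop,
    roi: SpotROI,
    bg: BackgroundROI,
    *,
    reference_role: str = "reference_kt",
) -> SpotMeasurement:
    """Background-corrected, reference-normalized intensities for one spot."""
    stack = _as_projection(projection)
    if reference_role not in stack.channel_roles.values():
        raise ChannelRoleError(f"projection lacks the {reference_role!r} channel")
    ry, rx = np.array([p[0] for p in roi.pixel_set]), np.array([p[1] for p in roi.pixel_set])
    by, bx = np.array([p[0] for p in bg.pixel_set]), np.array([p[1] for p in bg.pixel_set])

    roi_mean: dict[str, float] = {}
    bg_mean: dict[str, float] = {}
    corrected: dict[str, float] = {}
    for idx, role in stack.channel_roles.items():
        plane = stack.pixels[idx, 0].astype(np.float64)
        roi_mean[role] = float(plane[ry, rx].mean())
        bg_mean[role] = float(plane[by, bx].mean())
        corrected[role] = max(roi_mean[role] - bg_mean[role], 0.0)

    ref = corrected[reference_role]
    valid = ref > 0
    ratio = {
        role: (corrected[role] / ref if valid else float("nan"))
        for role in corrected
    }
    return SpotMeasurement(
        center=roi.center,
        roi_mean=roi_mean,
        bg_mean=bg_mean,
        corrected=corrected,
        ratio=ratio,
        valid=valid,
    )


@dataclass
class CellSummary:
    """Per-cell mean reference-normalized ratios over its kinetochores."""

    cell_id: str
    condition_label: str | None
    mean_ratio: dict[str, float]
    n_kinetochores: int
    n_excluded: int
    measurements: list[SpotMeasurement] = field(default_factory=list)


def quantify_cell(
    crop: CellCrop | ImageStack,
    *,
    cell_id: str = "cell",
    n_spots: int = DEFAULT_N_SPOTS,
    roi_diameter: int = DEFAULT_ROI_DIAMETER,
    bg_size: int = DEFAULT_BG_SIZE,
    tophat_radius: int = DEFAULT_TOPHAT_RADIUS,
    min_sep_px: float | None = None,
    reference_role: str = "reference_kt",
) -> CellSummary:
    """Run the full per-cell recruitment pipeline.

    Sum-projects if needed, builds the kinetochore mask from the
    reference channel, picks the ``n_spots`` brightest non-overlapping
    maxima (default 20, the per-cell count used throughout), then for
    each measures ROI and accrued-background means in every channel and
    the ratio to the reference. The per-cell mean is taken over valid
    measurements only; invalid ones (reference corrected to zero) are
    counted in ``n_excluded``.
    """
    stack = _as_projection(crop)
    ref_plane = stack.plane(reference_role)
    kt_mask = build_kinetochore_mask(
        ref_plane, tophat_radius, source_channel=reference_role
    )
    if min_sep_px is None:
        min_sep_px = roi_diameter
    # keep ROIs fully inside the image: half the disc plus rasterization slack
    border = roi_diameter // 2 + 1
    centers = detect_maxima(
        ref_plane,
        n_spots=n_spots,
        min_sep_px=min_sep_px,
        tophat_radius=tophat_radius,
        exclude_border=border,
    )

    measurements: list[SpotMeasurement] = []
    for c in centers:
        roi = build_spot_roi(c, roi_diameter, image_shape=ref_plane.shape)
        bg = accrue_background(roi, kt_mask, target_size=bg_size)
        measurements.append(
            measure_spot(stack, roi, bg, reference_role=reference_role)
        )

    valid = [m for m in measurements if m.valid]
    roles = list(stack.channel_roles.values())
    if valid:
        mean_ratio = {
            role: float(np.mean([m.ratio[role] for m in valid])) for role in roles
        }
    else:
        mean_ratio = {role: float("nan") for role in roles}
    return CellSummary(
        cell_id=cell_id,
        condition_label=stack.condition_label,
        mean_ratio=mean_ratio,
        n_kinetochores=len(measurements),
        n_excluded=len(measurements) - len(valid),
        measurements=measurements,
    )
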