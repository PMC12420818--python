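"""Line-profile analysis for super-resolution (STED-style) images.

Multi-channel intensity profiles between kinetochore pairs, group
normalization and mean ± SEM curves, inter-kinetochore (KT–KT)
distances from sub-pixel spot centers, and intra-kinetochore distances
as the difference of Gaussian-fit peak positions along a shared
profile.

All channels of a profile are sampled at identical coordinates, so
positional offsets between channels are directly comparable. Sampling
uses bilinear interpolation at (at most) unit-pixel spacing:
``ceil(L) + 1`` samples evenly spaced from one endpoint to the other,
where ``L`` is the segment length in pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import curve_fit

from .errors import FitError, RoiOutOfBoundsError
from .imgio import CellCrop, ImageStack, px_to_um
from .spotquant import _as_projection

MAX_FIT_EVALS = 200 * 4  # bounded iterations for the 4-parameter fit


@dataclass
class LineProfile:
    """Multi-channel intensity profile along a segment.

    ``samples`` maps channel role to a 1D intensity sequence;
    ``positions_px`` gives the distance of each sample from ``p0``
    along the line, in pixels (spacing <= 1 px, endpoints included).
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    width_px: int
    samples: dict[str, np.ndarray]
    positions_px: np.ndarray
    pixel_size_um: float

    @property
    def length_px(self) -> float:
        return math.dist(self.p0, self.p1)


def sample_line_profile(
    projection: ImageStack | CellCrop,
    p0: tuple[float, float],
    p1: tuple[float, float],
    width_px: int = 1,
) -> LineProfile:
    """Sample every channel along the segment from ``p0`` to ``p1``.

    ``width_px > 1`` averages ``width_px`` parallel lines at integer
    perpendicular offsets symmetric about the segment. Endpoints
    outside the image raise.
    """
    stack = _as_projection(projection)
    H, W = stack.shape_yx
    for p in (p0, p1):
        if not (0 <= p[0] <= H - 1 and 0 <= p[1] <= W - 1):
            raise RoiOutOfBoundsError(f"profile endpoint {p} outside image {(H, W)}")

    L = math.dist(p0, p1)
    n = int(math.ceil(L)) + 1
    t = np.linspace(0.0, 1.0, n)
    ys = p0[0] + t * (p1[0] - p0[0])
    xs = p0[1] + t * (p1[1] - p0[1])

    if L > 0:
        ny, nx = (p1[1] - p0[1]) / L, -(p1[0] - p0[0]) / L  # unit normal
    else:
        ny, nx = 0.0, 0.0
    offsets = np.arange(width_px) - (width_px - 1) / 2.0

    samples: dict[str, np.ndarray] = {}
    for idx, role in stack.channel_roles.items():
        plane = stack.pixels[idx, 0].astype(np.float64)
        acc = np.zeros(n)
        for o in offsets:
            acc += ndi.map_coordinates(
                plane, [ys + o * ny, xs + o * nx], order=1, mode="nearest"
            )
        samples[role] = acc / len(offsets)

    return LineProfile(
        p0=tuple(p0),
        p1=tuple(p1),
        width_px=width_px,
        samples=samples,
        positions_px=t * L,
        pixel_size_um=stack.pixel_size_um,
    )


# ---------------------------------------------------------------------------
# group alignment and normalization
# ---------------------------------------------------------------------------

def align_profiles(
    profiles: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample single-channel profiles to a common length and average.

    Each profile is linearly resampled to the median length
    (midpoint-registered: all profiles span [0, 1] of their own extent,
    endpoints preserved). Returns ``(stack, mean, sem)`` where
    ``stack`` is (n_profiles, m) and ``sem = sd / sqrt(n)`` per
    position (sample standard deviation, ddof=1).
    """
    if len(profiles) < 2:
        raise ValueError("align_profiles needs at least 2 profiles")
    arrs = [np.asarray(p, dtype=np.float64).ravel() for p in profiles]
    m = int(np.median([a.size for a in arrs]))
    grid = np.linspace(0.0, 1.0, m)
    stack = np.vstack([np.interp(grid, np.linspace(0, 1, a.size), a) for a in arrs])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / math.sqrt(stack.shape[0])
    return stack, mean, sem


def normalize_profile_group(stack: np.ndarray) -> np.ndarray:
    """Normalize an aligned group of single-channel profiles to [0, 100].

    0 is the smallest sample value anywhere in the group and 100 the
    largest value of the group *mean* curve, so the mean curve peaks at
    exactly 100 (individual profiles may exceed it). Constant groups
    raise.
    """
    s = np.atleast_2d(np.asarray(stack, dtype=np.float64))
    lo = s.min()
    peak = s.mean(axis=0).max()
    if peak == lo:
        raise ValueError("cannot normalize a constant profile group")
    return (s - lo) / (peak - lo) * 100.0


# ---------------------------------------------------------------------------
# Gaussian fitting and distances
# ---------------------------------------------------------------------------

@dataclass
class GaussianFit:
    """offset + amplitude * exp(-(x - mean)^2 / (2 sigma^2)) fit."""

    amplitude: float
    mean: float
    sigma: float
    offset: float
    rmse: float
    profile_key: int | None = None  # identity of the source profile


def _gauss(x, amplitude, mean, sigma, offset):
    return offset + amplitude * np.exp(-((x - mean) ** 2) / (2.0 * sigma**2))


def fit_gaussian(
    samples: np.ndarray,
    positions: np.ndarray | None = None,
    *,
    profile_key: int | None = None,
) -> GaussianFit:
    """Least-squares Gaussian fit of a single-channel profile.

    Initialization: amplitude and mean from the sample maximum, offset
    from the minimum, sigma from the second moment of the
    offset-subtracted signal. Iterations are bounded; non-convergence
    raises :class:`FitError` rather than returning silently.
    """
    y = np.asarray(samples, dtype=np.float64).ravel()
    if y.size < 5:
        raise FitError("Gaussian fit needs >= 5 samples")
    if np.ptp(y) == 0:
        raise FitError("cannot fit a Gaussian to a constant profile")
    x = np.arange(y.size, dtype=np.float64) if positions is None else np.asarray(
        positions, dtype=np.float64
    )

    off0 = float(y.min())
    amp0 = float(y.max() - off0)
    mean0 = float(x[int(np.argmax(y))])
    w = np.clip(y - off0, 0, None)
    if w.sum() > 0:
        var = float(np.sum(w * (x - np.average(x, weights=w)) ** 2) / w.sum())
        sig0 = max(math.sqrt(var), (x[1] - x[0]) / 2 if x.size > 1 else 0.5)
    else:  # pragma: no cover - ptp==0 already rejected
        sig0 = 1.0
    try:
        popt, _ = curve_fit(
            _gauss,
            x,
            y,
            p0=[amp0, mean0, sig0, off0],
            bounds=([0, x.min() - 1, 1e-6, -np.inf], [np.inf, x.max() + 1, np.inf, np.inf]),
            maxfev=MAX_FIT_EVALS,
        )
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    amplitude, mean, sigma, offset = map(float, popt)
    rmse = float(np.sqrt(np.mean((_gauss(x, *popt) - y) ** 2)))
    return GaussianFit(
        amplitude=amplitude,
        mean=mean,
        sigma=sigma,
        offset=offset,
        rmse=rmse,
        profile_key=profile_key,
    )


@dataclass
class DistanceMeasurement:
    """A single inter- or intra-kinetochore distance (one replicate)."""

    kind: str  # "kt_kt" | "intra_kt"
    value_um: float
    cell_id: str | None = None


def kt_kt_distance(
    center_a: tuple[float, float],
    center_b: tuple[float, float],
    pixel_size_um: float,
    *,
    cell_id: str | None = None,
) -> DistanceMeasurement:
    """Center-to-center (Euclidean) sister-kinetochore distance in µm."""
    d_px = math.dist(center_a, center_b)
    return DistanceMeasurement(
        kind="kt_kt", value_um=px_to_um(d_px, pixel_size_um), cell_id=cell_id
    )


def intra_kt_distance(
    fit_a: GaussianFit,
    fit_b: GaussianFit,
    pixel_size_um: float,
    *,
    cell_id: str | None = None,
) -> DistanceMeasurement:
    """Distance between two markers within one kinetochore.

    The two fits must come from the same profile coordinates (the same
    line is sampled in both channels); the distance is the absolute
    difference of fitted peak positions, converted to µm.
    """
    if (
        fit_a.profile_key is not None
        and fit_b.profile_key is not None
        and fit_a.profile_key != fit_b.profile_key
    ):
        raise ValueError("intra-kinetochore fits must share profile coordinates")
    return DistanceMeasurement(
        kind="intra_kt",
        value_um=px_to_um(abs(fit_a.mean - fit_b.mean), pixel_size_um),
        cell_id=cell_id,
    )


def refine_pair_centers(
    projection: ImageStack | CellCrop,
    center_a: tuple[float, float],
    center_b: tuple[float, float],
    *,
    role: str = "outer_kt",
    margin_px: float = 8.0,
    window_px: float | None = None,
) -> tuple[tuple[float, float], tuple[float, float], LineProfile]:
    """Sub-pixel spot centers along the inter-spot axis via 1D Gaussian fits.

    A 1 px-wide profile is sampled along the line through the two
    approximate centers, extended ``margin_px`` beyond each (clipped to
    the image); a Gaussian is fitted in a window around each spot's
    projected position and the fitted means are mapped back to 2D
    coordinates. Returns the refined centers and the profile used.
    """
    stack = _as_projection(projection)
    H, W = stack.shape_yx
    a = np.asarray(center_a, dtype=np.float64)
    b = np.asarray(center_b, dtype=np.float64)
    sep = float(np.linalg.norm(b - a))
    if sep == 0:
        return tuple(a), tuple(b), sample_line_profile(stack, tuple(a), tuple(b))
    u = (b - a) / sep

    def _clip_margin(point, direction):
        # largest m <= margin_px keeping point + m*direction inside the image
        m = margin_px
        for coord, d, hi in ((point[0], direction[0], H - 1), (point[1], direction[1], W - 1)):
            if d > 0:
                m = min(m, (hi - coord) / d)
            elif d < 0:
                m = min(m, -coord / d)
        return max(m, 0.0)

    m0 = _clip_margin(a, -u)
    m1 = _clip_margin(b, u)
    p0 = tuple(a - m0 * u)
    p1 = tuple(b + m1 * u)
    prof = sample_line_profile(stack, p0, p1, width_px=1)
    y = prof.samples[role]
    pos = prof.positions_px

    if window_px is None:
        window_px = max(4.0, min(sep / 2.0, 12.0))
    refined = []
    for proj_pos in (m0, m0 + sep):
        sel = np.abs(pos - proj_pos) <= window_px
        if sel.sum() < 5:  # widen degenerate windows near edges
            sel = np.argsort(np.abs(pos - proj_pos))[:5]
        fit = fit_gaussian(y[sel], pos[sel])
        refined.append(tuple(np.asarray(p0) + fit.mean * u))
    return refined[0], refined[1], prof


def measure_pair_in_image(
    projection: ImageStack | CellCrop,
    *,
    role: str = "outer_kt",
    min_sep_px: float = 6.0,
    tophat_radius: int = 6,
    cell_id: str | None = None,
) -> DistanceMeasurement:
    """KT–KT distance of the single brightest pair in an image.

    Detects the two brightest non-overlapping maxima in the given
    channel, refines them to sub-pixel positions along the inter-spot
    axis and returns the Euclidean distance in µm.
    """
    stack = _as_projection(projection)
    from .spotquant import detect_maxima  # local import: avoids cycle at module load

    centers = detect_maxima(
        stack.plane(role), n_spots=2, min_sep_px=min_sep_px, tophat_radius=tophat_radius
    )
    if len(centers) < 2:
        raise FitError("could not locate two kinetochore spots")
    return measure_pair_separation(stack, centers[0], centers[1], role=role, cell_id=cell_id)


def measure_pair_separation(
    projection: ImageStack | CellCrop,
    center_a: tuple[float, float],
    center_b: tuple[float, float],
    *,
    role: str = "outer_kt",
    cell_id: str | None = None,
) -> DistanceMeasurement:
    """KT–KT distance with Gaussian-refined sub-pixel centers."""
    stack = _as_projection(projection)
    ra, rb, _ = refine_pair_centers(stack, center_a, center_b, role=role)
    return kt_kt_distance(ra, rb, stack.pixel_size_um, cell_id=cell_id)
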