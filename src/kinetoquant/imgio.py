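"""Image I/O, projections, cropping and unit conversion.

The in-memory container is :class:`ImageStack`: a ``(channel, z, y, x)``
array in raw detector units plus the physical metadata needed downstream
(pixel size in µm, optional z-step, a mapping of channel index to
biological role). Raw intensities are kept untouched; offset and
background handling happen in the quantification modules.

Coordinate convention: arrays are indexed ``(row=y, col=x)``, 0-based,
with pixel centers at integer coordinates. All distances are
center-to-center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from .errors import ChannelRoleError, RoiOutOfBoundsError

#: Channel roles understood by the quantification modules. ``measure_*``
#: roles are open-ended (measure_1, measure_2, ...).
KNOWN_ROLES = ("dna", "reference_kt", "outer_kt", "inner_kt", "pericentric")


def _validate_roles(channel_roles: dict[int, str], n_channels: int) -> None:
    seen: dict[str, int] = {}
    for idx, role in channel_roles.items():
        if not (0 <= int(idx) < n_channels):
            raise ChannelRoleError(
                f"role map names channel {idx} but image has {n_channels} channel(s)"
            )
        if role in seen:
            raise ChannelRoleError(f"role {role!r} assigned to more than one channel")
        seen[role] = idx


@dataclass
class ImageStack:
    """Multi-channel, optionally z-resolved fluorescence image.

    Parameters
    ----------
    pixels
        Intensity array of shape ``(C, Z, Y, X)`` in detector units.
        ``Z`` may be 1 for a single plane.
    pixel_size_um
        Isotropic x/y pixel size in µm; must be positive.
    channel_roles
        Mapping from channel index to role (e.g. ``{0: "dna",
        1: "reference_kt", 2: "measure_1"}``). Each role at most once.
    z_step_um
        Spacing between z-slices in µm, or ``None`` for 2D data.
    condition_label
        Free-text experimental condition attached to this image.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_roles: dict[int, str] = field(default_factory=dict)
    z_step_um: float | None = None
    condition_label: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:  # single channel, single plane
            self.pixels = self.pixels[np.newaxis, np.newaxis]
        elif self.pixels.ndim == 3:  # (C, Y, X) -> singleton z
            self.pixels = self.pixels[:, np.newaxis]
        if self.pixels.ndim != 4:
            raise ValueError(f"expected (C, Z, Y, X) array, got shape {self.pixels.shape}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        self.channel_roles = {int(k): str(v) for k, v in self.channel_roles.items()}
        _validate_roles(self.channel_roles, self.n_channels)

    # -- basic geometry -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    # -- role access ----------------------------------------------------
    def channel_index(self, role: str) -> int:
        for idx, r in self.channel_roles.items():
            if r == role:
                return idx
        raise ChannelRoleError(f"no channel with role {role!r}")

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(Z, Y, X)`` sub-array for a role."""
        return self.pixels[self.channel_index(role)]

    def plane(self, role: str) -> np.ndarray:
        """Return the 2D image for a role; requires a single z-slice."""
        arr = self.channel(role)
        if arr.shape[0] != 1:
            raise ValueError("plane() requires a z-collapsed stack; project first")
        return arr[0]

    @property
    def roles(self) -> list[str]:
        return sorted(self.channel_roles.values())


@dataclass
class CellCrop:
    """A square single-cell crop of a parent image.

    ``origin`` is the (y, x) of the crop's top-left pixel in the parent;
    regions falling outside the parent are zero-padded and ``padded``
    is set so downstream code can treat edge cells specially.
    """

    stack: ImageStack
    origin: tuple[int, int]
    side_px: int
    padded: bool = False


def read_stack(
    path,
    channel_roles: dict[int, str],
    pixel_size_um: float,
    *,
    n_channels: int | None = None,
    z_step_um: float | None = None,
    condition_label: str | None = None,
    axes: str = "auto",
) -> ImageStack:
    """Read a TIFF into an :class:`ImageStack`.

    Accepts single-page 2D images, ``(C, Y, X)`` / ``(Z, Y, X)`` /
    ``(C, Z, Y, X)`` / ``(Z, C, Y, X)`` stacks. When the file's own axis
    tags are absent the layout is resolved from ``axes``:

    - ``"auto"``: 3D arrays are treated as ``(C, Y, X)`` when
      ``n_channels`` (or the role map) matches the leading axis,
      otherwise as a z-stack of a single channel.
    - ``"CZYX"`` / ``"ZCYX"``: explicit 4D layouts.
    - ``"CYX"`` / ``"ZYX"``: explicit 3D layouts.

    Raises :class:`ChannelRoleError` if the role map references a
    channel the file does not provide.
    """
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    want_c = n_channels
    if want_c is None and channel_roles:
        want_c = max(int(k) for k in channel_roles) + 1

    if arr.ndim == 2:
        pixels = arr[np.newaxis, np.newaxis]
    elif arr.ndim == 3:
        if axes == "CYX" or (axes == "auto" and want_c is not None and arr.shape[0] == want_c):
            pixels = arr[:, np.newaxis]
        else:
            pixels = arr[np.newaxis]  # (1, Z, Y, X)
    elif arr.ndim == 4:
        if axes == "ZCYX":
            pixels = np.moveaxis(arr, 1, 0)
        else:  # CZYX (tifffile writes CZYX for our writer below)
            pixels = arr
    else:
        raise ValueError(f"unsupported TIFF dimensionality: {arr.shape}")

    return ImageStack(
        pixels=pixels,
        pixel_size_um=pixel_size_um,
        channel_roles=channel_roles,
        z_step_um=z_step_um,
        condition_label=condition_label,
    )


def write_stack(path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` as a CZYX TIFF (lossless round-trip
    for integer data)."""
    tifffile.imwrite(
        str(path),
        stack.pixels,
        photometric="minisblack",
        metadata={"axes": "CZYX"},
    )


def sum_project(stack: ImageStack) -> ImageStack:
    """Collapse z by per-pixel sum (the projection used for quantification)."""
    proj = stack.pixels.sum(axis=1, keepdims=True)
    return replace(stack, pixels=proj, z_step_um=None)


def max_project(stack: ImageStack) -> ImageStack:
    """Collapse z by per-pixel maximum (the projection used for display)."""
    proj = stack.pixels.max(axis=1, keepdims=True)
    return replace(stack, pixels=proj, z_step_um=None)


def crop_cell(stack: ImageStack, center: tuple[float, float], side_px: int = 250) -> CellCrop:
    """Crop a ``side_px`` × ``side_px`` window around ``center`` (y, x).

    The window is placed so its top-left corner is
    ``round(center) - side_px // 2``. Out-of-bounds regions are
    zero-padded (flagged on the crop) rather than rejected, so cells at
    the image border remain usable.
    """
    H, W = stack.shape_yx
    cy, cx = int(round(center[0])), int(round(center[1]))
    if not (0 <= cy < H and 0 <= cx < W):
        raise RoiOutOfBoundsError(f"crop center {center} outside image of shape {(H, W)}")
    y0 = cy - side_px // 2
    x0 = cx - side_px // 2
    y1, x1 = y0 + side_px, x0 + side_px

    src_y0, src_x0 = max(y0, 0), max(x0, 0)
    src_y1, src_x1 = min(y1, H), min(x1, W)
    padded = (src_y0, src_x0) != (y0, x0) or (src_y1, src_x1) != (y1, x1)

    out = np.zeros(stack.pixels.shape[:2] + (side_px, side_px), dtype=stack.pixels.dtype)
    out[:, :, src_y0 - y0 : src_y1 - y0, src_x0 - x0 : src_x1 - x0] = stack.pixels[
        :, :, src_y0:src_y1, src_x0:src_x1
    ]
    if padded:
        warnings.warn("cell crop extends beyond the image; zero-padded", stacklevel=2)
    crop_stack = replace(stack, pixels=out)
    return CellCrop(stack=crop_stack, origin=(y0, x0), side_px=side_px, padded=padded)


def px_to_um(d_px: float, pixel_size_um: float) -> float:
    """Convert a pixel distance to µm using the image's acquisition scale."""
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    return float(d_px) * float(pixel_size_um)
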