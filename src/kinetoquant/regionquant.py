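"""Chromatin / pericentromere region-level quantification.

Measures chromatin-associated signals per cell (pericentromeric CPC
subunits, Aurora B, and chromatin-wide H3pS10): a chromatin mask is
derived from the DNA (Hoechst-like) channel by isodata thresholding, a
cytoplasm mask from the remaining cell extent, and each measured
channel is summarized as a chromatin mean — cytoplasm-background
corrected for CPC/Aurora-class channels, uncorrected for H3pS10-class
— normalized by the mean DNA signal and finally scaled to the mean of
the control condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ChannelRoleError, DegenerateImageError
from .imgio import CellCrop, ImageStack
from .spotquant import _as_projection, isodata_threshold

#: Per-channel correction classes.
CORRECTED = "corrected"      # subtract mean cytoplasmic signal (CPC/Aurora B)
UNCORRECTED = "uncorrected"  # chromatin mean as-is (H3pS10)


@dataclass
class RegionMasks:
    """Disjoint chromatin and cytoplasm masks for one cell."""

    chromatin: np.ndarray
    cytoplasm: np.ndarray
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        if (self.chromatin & self.cytoplasm).any():
            raise ValueError("chromatin and cytoplasm masks must be disjoint")


def make_region_masks(
    dna_channel: np.ndarray,
    cell_extent: np.ndarray | None = None,
    *,
    smooth_sigma: float = 1.0,
    dilate_px: int = 2,
    border_margin: int = 5,
    cell_id: str = "cell",
) -> RegionMasks:
    """Segment chromatin and cytoplasm from the DNA channel.

    Chromatin: Gaussian-smoothed DNA channel thresholded by iterative
    intermeans, keeping the largest connected component. Cytoplasm: the
    cell extent (a provided whole-cell mask, or by default the crop
    bounds minus ``border_margin``) minus a ``dilate_px``-pixel dilation
    of the chromatin, so the two masks cannot touch.
    """
    dna = np.asarray(dna_channel, dtype=np.float64)
    if dna.ndim != 2:
        raise ValueError("make_region_masks expects a 2D DNA channel")
    smoothed = ndi.gaussian_filter(dna, sigma=smooth_sigma) if smooth_sigma > 0 else dna
    t = isodata_threshold(smoothed)  # raises DegenerateImageError on blank input
    binary = smoothed > t
    labels, n = ndi.label(binary)
    if n == 0:
        raise DegenerateImageError("empty chromatin mask")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    chromatin = labels == (1 + int(np.argmax(sizes)))

    if cell_extent is None:
        cell_extent = np.zeros_like(chromatin)
        m = border_margin
        cell_extent[m : chromatin.shape[0] - m, m : chromatin.shape[1] - m] = True
    else:
        cell_extent = np.asarray(cell_extent, dtype=bool)

    grown = ndi.binary_dilation(chromatin, iterations=dilate_px)
    cytoplasm = cell_extent & ~grown
    if not cytoplasm.any():
        raise DegenerateImageError("empty cytoplasm mask")
    return RegionMasks(chromatin=chromatin, cytoplasm=cytoplasm, cell_id=cell_id)


@dataclass
class RegionMeasurement:
    """Per-cell region means, corrected and DNA-normalized, per channel."""

    cell_id: str
    condition_label: str | None
    chromatin_mean: dict[str, float]
    cytoplasm_mean: dict[str, float]
    corrected: dict[str, float]
    normalized: dict[str, float]
    dna_mean: float
    valid: bool


def measure_region(
    projection: ImageStack | CellCrop,
    masks: RegionMasks,
    channel_class_map: dict[str, str],
    *,
    dna_role: str = "dna",
) -> RegionMeasurement:
    """Measure region-level signals for the channels in the class map.

    For ``corrected``-class channels (CPC/Aurora B) the chromatin mean
    is background-corrected by the mean cytoplasmic signal, negatives
    clipped to zero; ``uncorrected``-class channels (H3pS10) keep the
    chromatin mean. Every value is then normalized by the mean DNA
    signal over the chromatin mask; a zero DNA mean flags the
    measurement invalid rather than raising.
    """
    stack = _as_projection(projection)
    if dna_role not in stack.channel_roles.values():
        raise ChannelRoleError(f"projection lacks the {dna_role!r} channel")
    for role, cls in channel_class_map.items():
        if cls not in (CORRECTED, UNCORRECTED):
            raise ValueError(f"unknown channel class {cls!r} for role {role!r}")

    chrom = masks.chromatin
    cyto = masks.cytoplasm
    dna_mean = float(stack.plane(dna_role)[chrom].mean())
    valid = dna_mean > 0

    chromatin_mean: dict[str, float] = {}
    cytoplasm_mean: dict[str, float] = {}
    corrected: dict[str, float] = {}
    normalized: dict[str, float] = {}
    for role, cls in channel_class_map.items():
        plane = stack.plane(role).astype(np.float64)
        chromatin_mean[role] = float(plane[chrom].mean())
        cytoplasm_mean[role] = float(plane[cyto].mean())
        if cls == CORRECTED:
            corrected[role] = max(chromatin_mean[role] - cytoplasm_mean[role], 0.0)
        else:
            corrected[role] = chromatin_mean[role]
        normalized[role] = corrected[role] / dna_mean if valid else float("nan")

    return RegionMeasurement(
        cell_id=masks.cell_id,
        condition_label=stack.condition_label,
        chromatin_mean=chromatin_mean,
        cytoplasm_mean=cytoplasm_mean,
        corrected=corrected,
        normalized=normalized,
        dna_mean=dna_mean,
        valid=valid,
    )


def scale_to_control(
    values: pd.DataFrame,
    control_label: str,
    *,
    value_col: str = "value",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Scale per-cell values to the control-condition mean.

    Returns a copy of the table with a ``scaled`` column such that the
    control group's mean maps to exactly 1.0. Raises ``ValueError``
    when the control group is empty or its mean is non-positive.
    """
    df = values.copy()
    ctrl = df.loc[df[condition_col] == control_label, value_col]
    if ctrl.empty:
        raise ValueError(f"control group {control_label!r} is empty")
    ctrl_mean = float(ctrl.mean())
    if not ctrl_mean > 0:
        raise ValueError(f"control group mean must be positive, got {ctrl_mean}")
    df["scaled"] = df[value_col] / ctrl_mean
    return df
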