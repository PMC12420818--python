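"""Synthetic mitotic-cell image generator with full ground truth.

Renders multi-channel fluorescence scenes that emulate the structure
the quantification pipeline assumes: an elliptical chromatin region
(DNA channel) inside a larger cell extent (cytoplasmic background in
every channel), diffraction-limited kinetochore spots — singly, for
recruitment-assay scenes, or as sister pairs at controlled separations
for distance scenes — an inner-centromere marker offset inward of the
outer kinetochore marker, and a broad pericentric band centered
between the members of each pair. Expected intensities are expressed
in photons so Poisson shot noise is meaningful; a gain maps photons to
detector units, and additive zero-mean read noise plus a constant
camera offset complete the noise model.

SNR is defined as peak spot amplitude over the noise standard
deviation at the peak, ``sqrt(amplitude + background + read_sd**2)``.

Defocus across a z-stack uses a simple documented stand-in, not an
optics simulation: per-slice PSF sigma grows as
``sigma0 * sqrt(1 + (z / z_r)**2)`` with the peak scaled by
``(sigma0 / sigma_z)**2`` so the in-plane integral is conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imgio import ImageStack, write_stack

# Study-condition defaults for the widefield recruitment-assay scenes:
# 2 µm stack at 0.2 µm intervals; 0.1075 µm/px (6.45 µm camera pixels
# through a 60x objective); 20 cells per condition; ~30 resolvable
# kinetochores per cell of which 20 are measured.
WIDEFIELD_PIXEL_UM = 0.1075
WIDEFIELD_PSF_SIGMA_UM = 0.1
WIDEFIELD_N_Z = 11
WIDEFIELD_Z_STEP_UM = 0.2
STED_PIXEL_UM = 0.03
STED_PSF_SIGMA_UM = 0.06
DEFAULT_SNR = 10.0


def amplitude_for_snr(snr: float, background_photons: float, read_sd: float) -> float:
    """Peak spot amplitude (photons) giving the requested SNR.

    Solves ``A / sqrt(A + b + r^2) = snr`` for ``A`` with ``b`` the
    local background expectation and ``r`` the read-noise sd.
    """
    c = background_photons + read_sd**2
    return float((snr**2 + snr * math.sqrt(snr**2 + 4 * c)) / 2.0)


@dataclass
class SpotSpec:
    """A single kinetochore: sub-pixel center and per-role peak photons."""

    center_px: tuple[float, float]
    amplitudes: dict[str, float]


@dataclass
class PairSpec:
    """A sister-kinetochore pair: midpoint, axis angle and separation."""

    midpoint_px: tuple[float, float]
    angle_rad: float
    separation_um: float
    amplitudes: dict[str, float]

    def member_centers(self, pixel_size_um: float) -> tuple[tuple[float, float], tuple[float, float]]:
        half = self.separation_um / pixel_size_um / 2.0
        dy, dx = math.sin(self.angle_rad) * half, math.cos(self.angle_rad) * half
        my, mx = self.midpoint_px
        return (my - dy, mx - dx), (my + dy, mx + dx)


@dataclass
class SceneSpec:
    """Everything needed to render one synthetic cell deterministically."""

    shape_px: tuple[int, int] = (250, 250)
    pixel_size_um: float = WIDEFIELD_PIXEL_UM
    n_z: int = 1
    z_step_um: float = WIDEFIELD_Z_STEP_UM
    channel_roles: dict[int, str] = field(
        default_factory=lambda: {0: "dna", 1: "reference_kt", 2: "measure_1", 3: "pericentric"}
    )
    psf_sigma_um: float = WIDEFIELD_PSF_SIGMA_UM
    # chromatin / cell geometry (pixels); None centers on the image
    chromatin_center_px: tuple[float, float] | None = None
    chromatin_axes_px: tuple[float, float] = (55.0, 75.0)
    chromatin_photons: float = 40.0
    cell_axes_px: tuple[float, float] = (100.0, 118.0)
    cytoplasm_photons: float = 8.0
    pericentric_chromatin_photons: float = 25.0
    # spots / pairs
    spots: list[SpotSpec] = field(default_factory=list)
    pairs: list[PairSpec] = field(default_factory=list)
    inner_offset_um: float = 0.12
    pericentric_width_um: float = 0.25
    # per-role multiplicative condition factors (e.g. depletion = 0.2)
    condition_factors: dict[str, float] = field(default_factory=dict)
    condition_label: str | None = None
    # noise model
    read_noise_sd: float = 2.0
    camera_offset: float = 100.0
    gain: float = 1.0
    z_r_um: float = 0.6  # defocus range of the sigma(z) stand-in

    def factor(self, role: str) -> float:
        f = self.condition_factors.get(role, 1.0)
        if f < 0:
            raise ValueError("condition factors must be >= 0")
        return f


@dataclass
class GroundTruth:
    """True scene parameters paired with a rendered image."""

    spots: pd.DataFrame  # columns: role, y, x, amplitude
    pairs: pd.DataFrame  # columns: separation_um, mid_y, mid_x, angle_rad
    chromatin_mask: np.ndarray | None
    cytoplasm_mask: np.ndarray | None
    condition_factors: dict[str, float]
    condition_label: str | None


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _add_gaussian_spot(field: np.ndarray, center: tuple[float, float], amp: float, sigma: float) -> None:
    """Accumulate an isotropic Gaussian onto ``field`` over a local patch."""
    if amp == 0:
        return
    H, W = field.shape
    cy, cx = center
    r = int(math.ceil(6 * sigma)) + 1
    y0, y1 = max(0, int(cy) - r), min(H, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(W, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        raise ValueError(f"spot at {center} lies outside the image")
    yy = np.arange(y0, y1)[:, None] - cy
    xx = np.arange(x0, x1)[None, :] - cx
    field[y0:y1, x0:x1] += amp * np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))


def _add_band(
    field: np.ndarray,
    midpoint: tuple[float, float],
    angle: float,
    length_sigma_px: float,
    width_sigma_px: float,
    amp: float,
) -> None:
    """Accumulate an elongated Gaussian ridge (the pericentric band)."""
    if amp == 0:
        return
    H, W = field.shape
    my, mx = midpoint
    r = int(math.ceil(4 * max(length_sigma_px, width_sigma_px))) + 1
    y0, y1 = max(0, int(my) - r), min(H, int(my) + r + 1)
    x0, x1 = max(0, int(mx) - r), min(W, int(mx) + r + 1)
    yy = np.arange(y0, y1)[:, None] - my
    xx = np.arange(x0, x1)[None, :] - mx
    t = yy * math.sin(angle) + xx * math.cos(angle)  # along the pair axis
    s = yy * math.cos(angle) - xx * math.sin(angle)  # perpendicular
    field[y0:y1, x0:x1] += amp * np.exp(
        -(t**2) / (2 * length_sigma_px**2) - (s**2) / (2 * width_sigma_px**2)
    )


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]) -> np.ndarray:
    yy = np.arange(shape[0])[:, None] - center[0]
    xx = np.arange(shape[1])[None, :] - center[1]
    return (yy / axes[0]) ** 2 + (xx / axes[1]) ** 2 <= 1.0


def _collect_spots(spec: SceneSpec) -> list[tuple[str, tuple[float, float], float]]:
    """Flatten standalone spots and pair members into (role, center, amp)."""
    out: list[tuple[str, tuple[float, float], float]] = []
    for s in spec.spots:
        for role, amp in s.amplitudes.items():
            if role == "pericentric":
                continue
            out.append((role, s.center_px, amp * spec.factor(role)))
    inner_off_px = spec.inner_offset_um / spec.pixel_size_um
    for p in spec.pairs:
        if p.separation_um < 0:
            raise ValueError("pair separation must be >= 0")
        (ay, ax), (by, bx) = p.member_centers(spec.pixel_size_um)
        uy, ux = math.sin(p.angle_rad), math.cos(p.angle_rad)
        for role, amp in p.amplitudes.items():
            if role == "pericentric":
                continue
            a = amp * spec.factor(role)
            if role == "inner_kt":
                # inner-centromere marker sits inward of the outer marker
                out.append((role, (ay + uy * inner_off_px, ax + ux * inner_off_px), a))
                out.append((role, (by - uy * inner_off_px, bx - ux * inner_off_px), a))
            else:
                out.append((role, (ay, ax), a))
                out.append((role, (by, bx), a))
    return out


def expected_field(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Noise-free expected photon field, shape (C, Z, Y, X), plus truth."""
    H, W = spec.shape_px
    C = len(spec.channel_roles)
    Z = spec.n_z
    center = spec.chromatin_center_px or ((H - 1) / 2.0, (W - 1) / 2.0)

    chrom_mask = _ellipse_mask((H, W), center, spec.chromatin_axes_px)
    cell_mask = _ellipse_mask((H, W), center, spec.cell_axes_px)
    chrom_soft = ndi.gaussian_filter(chrom_mask.astype(np.float64), 1.0)
    cell_soft = ndi.gaussian_filter(cell_mask.astype(np.float64), 2.0)
    cyto_truth = cell_mask & ~ndi.binary_dilation(chrom_mask, iterations=2)

    spots = _collect_spots(spec)
    sigma0 = spec.psf_sigma_um / spec.pixel_size_um

    lam = np.zeros((C, Z, H, W), dtype=np.float64)
    z_positions = (np.arange(Z) - (Z - 1) / 2.0) * spec.z_step_um
    for zi, z in enumerate(z_positions):
        sigma_z = sigma0 * math.sqrt(1.0 + (z / spec.z_r_um) ** 2)
        peak_scale = (sigma0 / sigma_z) ** 2
        for ci, role in spec.channel_roles.items():
            f = lam[ci, zi]
            f += spec.cytoplasm_photons * cell_soft
            if role == "dna":
                f += spec.chromatin_photons * chrom_soft
            if role == "pericentric":
                f += (
                    spec.pericentric_chromatin_photons
                    * spec.factor(role)
                    * chrom_soft
                )
                for p in spec.pairs:
                    amp = p.amplitudes.get("pericentric", 0.0) * spec.factor(role)
                    sep_px = p.separation_um / spec.pixel_size_um
                    _add_band(
                        f,
                        p.midpoint_px,
                        p.angle_rad,
                        length_sigma_px=max(sep_px / 4.0, 1.0),
                        width_sigma_px=spec.pericentric_width_um / spec.pixel_size_um,
                        amp=amp * peak_scale,
                    )
            for srole, c, a in spots:
                if srole == role:
                    _add_gaussian_spot(f, c, a * peak_scale, sigma_z)

    truth = GroundTruth(
        spots=pd.DataFrame(
            [(r, c[0], c[1], a) for r, c, a in spots],
            columns=["role", "y", "x", "amplitude"],
        ),
        pairs=pd.DataFrame(
            [
                (p.separation_um, p.midpoint_px[0], p.midpoint_px[1], p.angle_rad)
                for p in spec.pairs
            ],
            columns=["separation_um", "mid_y", "mid_x", "angle_rad"],
        ),
        chromatin_mask=chrom_mask,
        cytoplasm_mask=cyto_truth,
        condition_factors=dict(spec.condition_factors),
        condition_label=spec.condition_label,
    )
    return lam, truth


def render_scene(spec: SceneSpec, seed: int, *, noise: bool = True) -> tuple[ImageStack, GroundTruth]:
    """Render a scene to detector units.

    ``detector = gain * (Poisson(lambda) + N(0, read_sd)) + offset``;
    with ``noise=False`` the expectation itself is returned (plus
    offset), which the oracle tests rely on. A fixed seed gives
    byte-identical output.
    """
    lam, truth = expected_field(spec)
    if noise:
        rng = np.random.default_rng(seed)
        photons = rng.poisson(lam).astype(np.float64)
        photons += rng.normal(0.0, spec.read_noise_sd, size=lam.shape)
        pixels = spec.gain * photons + spec.camera_offset
    else:
        pixels = spec.gain * lam + spec.camera_offset
    stack = ImageStack(
        pixels=pixels,
        pixel_size_um=spec.pixel_size_um,
        channel_roles=dict(spec.channel_roles),
        z_step_um=spec.z_step_um if spec.n_z > 1 else None,
        condition_label=spec.condition_label,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# dataset builders
# ---------------------------------------------------------------------------

def scatter_spots_in_ellipse(
    rng: np.random.Generator,
    center: tuple[float, float],
    axes: tuple[float, float],
    n: int,
    min_sep_px: float,
    shrink: float = 0.85,
) -> list[tuple[float, float]]:
    """Rejection-sample ``n`` centers inside a shrunken ellipse with a
    minimum pairwise separation."""
    placed: list[tuple[float, float]] = []
    for _ in range(20000):
        if len(placed) == n:
            break
        y = center[0] + rng.uniform(-1, 1) * axes[0] * shrink
        x = center[1] + rng.uniform(-1, 1) * axes[1] * shrink
        if ((y - center[0]) / (axes[0] * shrink)) ** 2 + (
            (x - center[1]) / (axes[1] * shrink)
        ) ** 2 > 1:
            continue
        if all((y - py) ** 2 + (x - px) ** 2 >= min_sep_px**2 for py, px in placed):
            placed.append((y, x))
    if len(placed) < n:
        raise RuntimeError(f"could only place {len(placed)}/{n} spots; relax min_sep_px")
    return placed


def make_condition_dataset(
    conditions: dict[str, float],
    n_cells: int = 20,
    seed: int = 0,
    *,
    base_spec: SceneSpec | None = None,
    n_spots_per_cell: int = 30,
    min_sep_px: float = 12.0,
    snr: float = DEFAULT_SNR,
    amp_jitter: float = 0.3,
    out_dir=None,
) -> tuple[list[tuple[ImageStack, GroundTruth]], pd.DataFrame]:
    """Render a control-vs-depletion style dataset.

    One scene per cell per condition; the condition's factor scales the
    measured channel(s) (``measure_1`` spots and the pericentric
    signal) while DNA and the reference kinetochore marker stay at
    control levels — emulating an siRNA-depletion recruitment assay.
    Spot amplitudes are drawn around the SNR-derived level with
    uniform ±``amp_jitter`` relative jitter, independently per channel.

    Returns the rendered scenes and a per-cell ground-truth table; with
    ``out_dir`` the images are also written as TIFFs next to a
    ``ground_truth.csv``.
    """
    if base_spec is None:
        base_spec = SceneSpec(n_z=WIDEFIELD_N_Z)
    rng_root = np.random.default_rng(seed)

    # SNR is defined against the cytoplasmic floor; spots inside chromatin
    # see a slightly higher background, which the local correction removes
    base_amp = amplitude_for_snr(snr, base_spec.cytoplasm_photons, base_spec.read_noise_sd)

    scenes: list[tuple[ImageStack, GroundTruth]] = []
    rows = []
    H, W = base_spec.shape_px
    center = ((H - 1) / 2.0, (W - 1) / 2.0)
    for label, factor in conditions.items():
        if factor < 0:
            raise ValueError("condition factors must be >= 0")
        for i in range(n_cells):
            cell_seed = int(rng_root.integers(0, 2**31 - 1))
            rng = np.random.default_rng(cell_seed)
            jitter_c = tuple(center[k] + rng.normal(0, 3) for k in range(2))
            centers = scatter_spots_in_ellipse(
                rng, jitter_c, base_spec.chromatin_axes_px, n_spots_per_cell, min_sep_px
            )
            # kinetochore-to-kinetochore brightness varies mostly jointly
            # across channels (kinetochore size), with a smaller
            # channel-independent component on top
            spots = []
            for c in centers:
                size_factor = rng.uniform(1 - amp_jitter, 1 + amp_jitter)
                spots.append(
                    SpotSpec(
                        center_px=c,
                        amplitudes={
                            "reference_kt": base_amp * size_factor * rng.uniform(0.9, 1.1),
                            "measure_1": base_amp * size_factor * rng.uniform(0.9, 1.1),
                        },
                    )
                )
            spec = replace(
                base_spec,
                chromatin_center_px=jitter_c,
                spots=spots,
                condition_factors={"measure_1": factor, "pericentric": factor},
                condition_label=label,
            )
            stack, truth = render_scene(spec, cell_seed)
            scenes.append((stack, truth))
            rows.append(
                {
                    "condition": label,
                    "cell_index": i,
                    "factor": factor,
                    "n_spots": len(spots),
                    "seed": cell_seed,
                }
            )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        _write_dataset(out_dir, scenes, table)
    return scenes, table


def make_distance_dataset(
    separation_um: float,
    n_pairs: int = 50,
    sted_like: bool = True,
    seed: int = 0,
    *,
    snr: float = DEFAULT_SNR,
    inner_offset_um: float = 0.12,
    noise: bool = True,
    out_dir=None,
) -> list[tuple[ImageStack, GroundTruth]]:
    """Render single-pair scenes at a fixed true separation.

    STED-like mode uses 30 nm pixels and a 60 nm PSF sigma (single
    optical slice); otherwise widefield sampling is used. Orientation
    is uniform in [0, π) and the midpoint jittered, but the separation
    is fixed so recovery targets are crisp.
    """
    if separation_um < 0:
        raise ValueError("separation must be >= 0")
    pixel = STED_PIXEL_UM if sted_like else WIDEFIELD_PIXEL_UM
    psf = STED_PSF_SIGMA_UM if sted_like else WIDEFIELD_PSF_SIGMA_UM
    sep_px = separation_um / pixel
    side = max(64, int(math.ceil(sep_px)) + 48)
    bg = 20.0
    amp = amplitude_for_snr(snr, bg, 2.0)

    rng_root = np.random.default_rng(seed)
    scenes = []
    for _ in range(n_pairs):
        pair_seed = int(rng_root.integers(0, 2**31 - 1))
        rng = np.random.default_rng(pair_seed)
        mid = (
            (side - 1) / 2.0 + rng.normal(0, 1.5),
            (side - 1) / 2.0 + rng.normal(0, 1.5),
        )
        pair = PairSpec(
            midpoint_px=mid,
            angle_rad=float(rng.uniform(0, math.pi)),
            separation_um=separation_um,
            amplitudes={
                "outer_kt": amp,
                "inner_kt": amp * 0.8,
                "pericentric": amp * 0.5,
            },
        )
        spec = SceneSpec(
            shape_px=(side, side),
            pixel_size_um=pixel,
            n_z=1,
            channel_roles={0: "outer_kt", 1: "inner_kt", 2: "pericentric"},
            psf_sigma_um=psf,
            chromatin_axes_px=(side, side),  # flat field: no chromatin contrast
            chromatin_photons=0.0,
            cell_axes_px=(side * 2.0, side * 2.0),
            cytoplasm_photons=bg,
            pericentric_chromatin_photons=0.0,
            pairs=[pair],
            inner_offset_um=inner_offset_um,
            read_noise_sd=2.0,
        )
        scenes.append(render_scene(spec, pair_seed, noise=noise))
    if out_dir is not None:
        table = pd.DataFrame(
            [
                {
                    "pair_index": i,
                    "separation_um": separation_um,
                    "mid_y": gt.pairs.mid_y[0],
                    "mid_x": gt.pairs.mid_x[0],
                    "angle_rad": gt.pairs.angle_rad[0],
                }
                for i, (_, gt) in enumerate(scenes)
            ]
        )
        _write_dataset(out_dir, scenes, table)
    return scenes


def _write_dataset(out_dir, scenes, table: pd.DataFrame) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, (stack, gt) in enumerate(scenes):
        label = gt.condition_label or "scene"
        write_stack(out / f"{label}_{i:03d}.tif", stack)
    table.to_csv(out / "ground_truth.csv", index=False)
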