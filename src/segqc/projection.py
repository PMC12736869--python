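"""Projection images for visual QC of lung segmentation masks.

Three 2D renderings of a 3D two-lung label volume are supported, each
composed of an axial and a coronal projection side by side:

``colored_mip``
    Each lung's solid mask is depth-colorized slice by slice (pseudo-
    chromadepth: slice index mapped linearly onto a continuous colormap,
    viridis for the right lung and plasma for the left) and collapsed by a
    per-RGB-channel maximum intensity projection.
``colored_outline``
    The mask's surface voxels (foreground voxels with a 6-connected
    background neighbour) are depth-colorized the same way and collapsed by
    a per-channel sample standard-deviation projection (N−1 denominator).
``gray_outline``
    Surface voxels are encoded white, everything else black, and collapsed
    by the same standard-deviation projection; the result is grayscale.

Only slices containing lung voxels (union of both lungs) enter a stack, so
the depth colormap always spans the lungs' own extent. Standard-deviation
panels are min–max rescaled to [0, 1] as a whole before quantization.
Projections are resampled (nearest neighbour) to isotropic pixels, since
the acquisition grid is anisotropic (e.g. 1.4×1.4 mm in-plane, 3.0 mm
slices).

Display conventions: axial images put the anterior side at the top,
coronal images the superior side; the patient's left appears on the right
of the image (anatomical axis 0 runs L→R left-to-right in image columns).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from matplotlib import colormaps
from matplotlib.colors import LinearSegmentedColormap
from PIL import Image

from .volume_io import (
    LEFT_LUNG,
    RIGHT_LUNG,
    BinaryMask,
    LabelVolume,
    extract_binary_mask,
)

METHODS = ("colored_mip", "colored_outline", "gray_outline")

#: anatomical view -> array axis collapsed by the projection
VIEW_AXIS = {"axial": 2, "coronal": 1}


class EmptyVolumeError(ValueError):
    """No foreground voxels — nothing to project."""


# --------------------------------------------------------------------------
# palettes


@dataclass(frozen=True)
class PaletteSpec:
    """Pair of continuous [0,1] -> RGB maps, one per lung."""

    name: str
    right_map: Callable[[np.ndarray], np.ndarray]
    left_map: Callable[[np.ndarray], np.ndarray]


def _cvd_map(bright: tuple[float, float, float]) -> LinearSegmentedColormap:
    dark = tuple(0.25 * c for c in bright)
    return LinearSegmentedColormap.from_list("cvd", [dark, bright])


_PALETTES = {
    "default": lambda: PaletteSpec("default", colormaps["viridis"], colormaps["plasma"]),
    # yellow/cyan pair intended to remain distinguishable under common
    # color-vision deficiencies; not part of the evaluated defaults
    "cvd": lambda: PaletteSpec("cvd", _cvd_map((1.0, 1.0, 0.0)), _cvd_map((0.0, 1.0, 1.0))),
}


def get_palette(name: str = "default") -> PaletteSpec:
    try:
        return _PALETTES[name]()
    except KeyError:
        raise ValueError(f"unknown palette {name!r}; choose from {sorted(_PALETTES)}") from None


# --------------------------------------------------------------------------
# stack construction and projections


@dataclass(eq=False)
class ColorStack:
    """Ordered stack of 2D RGB slices along one anatomical depth axis."""

    slices: np.ndarray  # (N, H, W, 3), values in [0, 1]
    depth_axis: int

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim != 4 or self.slices.shape[-1] != 3:
            raise ValueError(f"expected (N, H, W, 3), got {self.slices.shape}")
        if self.n_slices < 1:
            raise ValueError("a stack needs at least one slice")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


def select_slices(masks: Sequence[BinaryMask], axis: int) -> tuple[int, int]:
    """Smallest half-open slice interval [lo, hi) along ``axis`` covering all
    foreground voxels of all masks."""
    if not masks:
        raise ValueError("need at least one mask")
    union = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        if m.shape != union.shape:
            raise ValueError("masks must share a shape")
        union |= m.voxels
    other = tuple(a for a in range(3) if a != axis)
    occupied = union.any(axis=other)
    idx = np.flatnonzero(occupied)
    if idx.size == 0:
        raise EmptyVolumeError("no foreground voxels in any mask")
    return int(idx[0]), int(idx[-1]) + 1


def surface_voxels(mask: BinaryMask) -> BinaryMask:
    """Boundary shell: foreground voxels with a 6-connected background (or
    out-of-volume) neighbour."""
    from scipy import ndimage

    m = mask.voxels
    struct = ndimage.generate_binary_structure(3, 1)  # face neighbours only
    eroded = ndimage.binary_erosion(m, structure=struct, border_value=0)
    return mask.with_voxels(m & ~eroded)


def depth_colorize(
    mask: BinaryMask,
    axis: int,
    slice_range: tuple[int, int],
    colormap: Callable[[np.ndarray], np.ndarray],
) -> ColorStack:
    """Color every foreground pixel of slice ``lo + i`` with
    ``colormap(i / (N−1))``; background stays black. For a single-slice
    stack the colormap argument is 0."""
    lo, hi = slice_range
    if hi <= lo:
        raise ValueError(f"empty slice range [{lo}, {hi})")
    sub = np.moveaxis(mask.voxels, axis, 0)[lo:hi]
    n = hi - lo
    t = np.arange(n) / (n - 1) if n > 1 else np.zeros(1)
    colors = np.asarray(colormap(t))[:, :3]
    slices = colors[:, None, None, :] * sub[..., None]
    return ColorStack(slices=slices, depth_axis=axis)


def mip_project(stack: ColorStack) -> np.ndarray:
    """Maximum intensity projection, independently per RGB channel."""
    return stack.slices.max(axis=0)


def sd_project(stack: ColorStack) -> np.ndarray:
    """Sample standard deviation (N−1 denominator) along the stack, per
    channel. A single-slice stack has no variation and projects to zero.
    The result is *not* rescaled here; rescaling happens per panel."""
    if stack.n_slices < 2:
        return np.zeros(stack.slices.shape[1:])
    return np.std(stack.slices, axis=0, ddof=1)


def composite_labels(right_img: np.ndarray, left_img: np.ndarray) -> np.ndarray:
    """Combine the two lungs' projections by per-channel maximum."""
    if right_img.shape != left_img.shape:
        raise ValueError(f"shape mismatch: {right_img.shape} vs {left_img.shape}")
    return np.maximum(right_img, left_img)


# --------------------------------------------------------------------------
# panel rendering


@dataclass(eq=False)
class ProjectionPanel:
    """Composed axial+coronal RGB panel for one case and one method."""

    image: np.ndarray  # (H, W, 3) in [0, 1]
    method: str
    case_id: str
    meta: dict = field(default_factory=dict)


def _resample_isotropic(img: np.ndarray, row_mm: float, col_mm: float) -> np.ndarray:
    """Nearest-neighbour rescale so pixels are square in mm (categorical
    colors must not be blended)."""
    target = min(row_mm, col_mm)
    n_rows = max(1, round(img.shape[0] * row_mm / target))
    n_cols = max(1, round(img.shape[1] * col_mm / target))
    ri = np.minimum((np.arange(n_rows) + 0.5) * img.shape[0] // n_rows, img.shape[0] - 1)
    ci = np.minimum((np.arange(n_cols) + 0.5) * img.shape[1] // n_cols, img.shape[1] - 1)
    return img[ri.astype(int)][:, ci.astype(int)]


def _to_display(proj: np.ndarray) -> np.ndarray:
    # projected array keeps the two non-collapsed axes in canonical order:
    # axial -> (L-R, P-A), coronal -> (L-R, I-S). Rows should run A->P
    # (axial) or S->I (coronal), columns L->R.
    return proj.swapaxes(0, 1)[::-1]


_WHITE = lambda t: np.ones((np.size(t), 4))  # noqa: E731 — constant colormap


def render_case(
    vol: LabelVolume,
    method: str,
    palette: PaletteSpec | None = None,
    case_id: str = "",
) -> ProjectionPanel:
    """Render one case into a side-by-side axial+coronal panel.

    ``colored_mip`` uses MIP over depth-colorized solid masks;
    ``colored_outline`` and ``gray_outline`` use the SD projection over
    depth-colorized (resp. white) surface-voxel masks.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    palette = palette or get_palette()
    right = extract_binary_mask(vol, RIGHT_LUNG)
    left = extract_binary_mask(vol, LEFT_LUNG)
    sx, sy, sz = vol.spacing
    view_mm = {"axial": (sy, sx), "coronal": (sz, sx)}  # (row_mm, col_mm) after display

    outline = method in ("colored_outline", "gray_outline")
    if outline:
        right = surface_voxels(right)
        left = surface_voxels(left)

    views: dict[str, np.ndarray] = {}
    depth_ranges: dict[str, tuple[int, int]] = {}
    for view, axis in VIEW_AXIS.items():
        lo, hi = select_slices([right, left], axis)
        depth_ranges[view] = (lo, hi)
        imgs = []
        for mask, cmap in ((right, palette.right_map), (left, palette.left_map)):
            if method == "gray_outline":
                cmap = _WHITE
            stack = depth_colorize(mask, axis, (lo, hi), cmap)
            imgs.append(mip_project(stack) if method == "colored_mip" else sd_project(stack))
        combined = composite_labels(*imgs)
        combined = _to_display(combined)
        views[view] = _resample_isotropic(combined, *view_mm[view])

    panel = _compose_side_by_side(views["axial"], views["coronal"], gap=8)
    if outline:
        lo_v, hi_v = panel.min(), panel.max()
        if hi_v > lo_v:
            panel = (panel - lo_v) / (hi_v - lo_v)
    panel = np.clip(panel, 0.0, 1.0)
    meta = {
        "method": method,
        "palette": palette.name,
        "depth_ranges": {k: list(v) for k, v in depth_ranges.items()},
        "labels": {"right_lung": RIGHT_LUNG, "left_lung": LEFT_LUNG},
        "depth_direction": {"axial": "inferior->superior", "coronal": "posterior->anterior"},
    }
    return ProjectionPanel(image=panel, method=method, case_id=case_id, meta=meta)


def _compose_side_by_side(a: np.ndarray, b: np.ndarray, gap: int = 8) -> np.ndarray:
    h = max(a.shape[0], b.shape[0])
    w = a.shape[1] + gap + b.shape[1]
    out = np.zeros((h, w, 3))
    ya = (h - a.shape[0]) // 2
    yb = (h - b.shape[0]) // 2
    out[ya : ya + a.shape[0], : a.shape[1]] = a
    out[yb : yb + b.shape[0], a.shape[1] + gap :] = b
    return out


def write_panel(panel: ProjectionPanel, path, sidecar: bool = True) -> None:
    """Write the panel as an 8-bit PNG plus a JSON sidecar describing the
    rendering conventions."""
    path = Path(path)
    quantized = np.round(np.clip(panel.image, 0.0, 1.0) * 255).astype(np.uint8)
    Image.fromarray(quantized, mode="RGB").save(path, format="PNG")
    if sidecar:
        meta = {"case_id": panel.case_id, **panel.meta}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
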