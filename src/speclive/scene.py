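"""Synthetic face scenes: ground-truth spectra, region labels, face geometry.

A scene replaces the captured faces a real camera would image: a rectangular
"face" containing a flat forehead strip and cheeks of pure skin, eyebrow and
mouth stripes of non-skin material, a shadowed skin strip (multiplicative
illumination drop, spectral shape preserved), and a distinct background.
Region labels are exact by construction, so selection and classification can
be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grids import Spectrum, WavelengthGrid
from .materials import MaterialSpec, make_material_spectrum
from .region import FaceBox

__all__ = [
    "REGION_LABELS",
    "SceneCube",
    "GradientScene",
    "make_face_scene",
    "make_gradient_scene",
]

#: Region label codes stored per pixel.
REGION_LABELS = {
    "background": 0,
    "flat_skin": 1,
    "eyebrow": 2,
    "mouth": 3,
    "shadow": 4,
}


def _check_dims(height: int, width: int) -> None:
    if height % 4 or width % 4:
        raise ValueError(
            f"scene dims must be multiples of the 4x4 mosaic period, got "
            f"{height}x{width}"
        )


@dataclass
class SceneCube:
    """Palette-indexed scene with per-pixel illumination and region labels."""

    grid: WavelengthGrid
    palette: np.ndarray          # (K, L) reflectance rows
    material_index: np.ndarray   # (H, W) int indices into palette
    illum: np.ndarray            # (H, W) multiplicative illumination
    region_labels: np.ndarray    # (H, W) REGION_LABELS codes
    face_box: Optional[FaceBox]
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        h, w = self.material_index.shape
        _check_dims(h, w)
        if self.material_index.min() < 0 or self.material_index.max() >= len(self.palette):
            raise ValueError("material_index refers outside the palette")
        if self.face_box is not None and (
            self.face_box.bottom > h or self.face_box.right > w
        ):
            raise ValueError(f"face box {self.face_box} exceeds image {h}x{w}")

    @property
    def height(self) -> int:
        return self.material_index.shape[0]

    @property
    def width(self) -> int:
        return self.material_index.shape[1]

    def project(self, response: np.ndarray) -> np.ndarray:
        """Noise-free per-pixel channel responses, shape (H, W, n_channels)."""
        pal = self.palette @ np.asarray(response, float).T  # (K, C)
        return pal[self.material_index] * self.illum[..., None]

    def true_spectra(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Ground-truth spectra (n, L) at the given pixel coordinates."""
        return self.palette[self.material_index[rows, cols]] * \
            self.illum[rows, cols][:, None]


@dataclass
class GradientScene:
    """Smoothly varying scene: pixel spectrum blends two palette endpoints."""

    grid: WavelengthGrid
    endpoints: np.ndarray  # (2, L)
    weight: np.ndarray     # (H, W) blend weight in [0, 1]

    def __post_init__(self) -> None:
        _check_dims(*self.weight.shape)

    @property
    def height(self) -> int:
        return self.weight.shape[0]

    @property
    def width(self) -> int:
        return self.weight.shape[1]

    def project(self, response: np.ndarray) -> np.ndarray:
        ep = self.endpoints @ np.asarray(response, float).T  # (2, C)
        w = self.weight[..., None]
        return (1.0 - w) * ep[0] + w * ep[1]

    def true_spectra(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        w = self.weight[rows, cols][:, None]
        return (1.0 - w) * self.endpoints[0] + w * self.endpoints[1]


#: Minimum mean absolute skin/non-skin reflectance gap over 500-650 nm.
DEFAULT_SEPARATION_MARGIN = 0.02


def _band_mean_abs_gap(grid: WavelengthGrid, a: np.ndarray, b: np.ndarray) -> float:
    lam = grid.wavelengths
    sel = (lam >= 500.0) & (lam <= 650.0)
    an = a / a.max()
    bn = b / b.max()
    return float(np.mean(np.abs(an[sel] - bn[sel])))


def make_face_scene(
    height: int,
    width: int,
    skin: MaterialSpec,
    brow: Optional[MaterialSpec] = None,
    background: Optional[MaterialSpec] = None,
    grid: Optional[WavelengthGrid] = None,
    seed: int = 0,
    shadow_factor: float = 0.55,
    separation_margin: float = DEFAULT_SEPARATION_MARGIN,
) -> SceneCube:
    """Compose a synthetic face scene around one face material.

    `skin` is the face material (any kind: spoof "faces" are scenes whose face
    material is a 2D/3D spoof spectrum). `brow` covers eyebrow/mouth stripes
    and must be non-skin; `background` fills the rest of the frame.
    Raises if the face box is too small to hold all sub-regions, or if a real
    skin face is not spectrally separated from the brow material in the
    500-650 nm band by `separation_margin`.
    """
    from .grids import DEFAULT_GRID

    _check_dims(height, width)
    grid = grid or DEFAULT_GRID
    rng = np.random.default_rng(seed)

    brow = brow or MaterialSpec(
        "print2d", baseline=0.22, dip_depth_542=0.0, dip_depth_577=0.0,
        edge_nm=640.0, random_amp=0.03, seed=int(rng.integers(2**31)),
    )
    background = background or MaterialSpec(
        "resin3d", baseline=0.35, dip_depth_542=0.0, dip_depth_577=0.0,
        random_amp=0.03, seed=int(rng.integers(2**31)),
    )

    skin_refl = make_material_spectrum(skin, grid).values
    brow_refl = make_material_spectrum(brow, grid).values
    bg_refl = make_material_spectrum(background, grid).values

    if skin.kind == "skin":
        gap = _band_mean_abs_gap(grid, skin_refl, brow_refl)
        if gap < separation_margin:
            raise ValueError(
                f"skin/brow 500-650 nm separation {gap:.4f} below margin "
                f"{separation_margin}"
            )

    palette = np.vstack([bg_refl, skin_refl, brow_refl])
    BG, SKIN, BROW = 0, 1, 2

    top, left = height // 8, width // 8
    box_h = (height - 2 * top)
    box_w = (width - 2 * left)
    box = FaceBox(top, left, box_h, box_w)
    if box_h < 16 or box_w < 16:
        raise ValueError(
            f"face box {box_h}x{box_w} too small to contain forehead, "
            f"eyebrow, mouth and shadow sub-regions (needs >= 16x16)"
        )

    material = np.full((height, width), BG, dtype=np.intp)
    labels = np.full((height, width), REGION_LABELS["background"], dtype=np.uint8)
    illum = np.ones((height, width), dtype=float)

    rs, cs = box.slices()
    material[rs, cs] = SKIN
    labels[rs, cs] = REGION_LABELS["flat_skin"]

    # Eyebrows: two stripes just below the forehead quarter of the box.
    brow_h = max(2, box_h // 16)
    brow_w = box_w // 4
    brow_top = top + box_h // 4
    geometry = {"face_box": box, "brow_h": brow_h, "brow_w": brow_w}
    for b_left in (left + box_w // 8, left + box_w - box_w // 8 - brow_w):
        material[brow_top : brow_top + brow_h, b_left : b_left + brow_w] = BROW
        labels[brow_top : brow_top + brow_h, b_left : b_left + brow_w] = \
            REGION_LABELS["eyebrow"]

    # Mouth: one stripe in the lower quarter.
    mouth_h = max(2, box_h // 12)
    mouth_w = box_w // 3
    mouth_top = top + (3 * box_h) // 4
    mouth_left = left + (box_w - mouth_w) // 2
    material[mouth_top : mouth_top + mouth_h, mouth_left : mouth_left + mouth_w] = BROW
    labels[mouth_top : mouth_top + mouth_h, mouth_left : mouth_left + mouth_w] = \
        REGION_LABELS["mouth"]
    geometry.update(mouth_h=mouth_h, mouth_w=mouth_w)

    # Shadow: skin strip along the right edge of the box, scaled illumination.
    shadow_w = max(2, box_w // 10)
    sh_cols = slice(box.right - shadow_w, box.right)
    shadow_rows = slice(brow_top, box.bottom)
    is_skin = material[shadow_rows, sh_cols] == SKIN
    illum_region = illum[shadow_rows, sh_cols]
    illum_region[is_skin] = shadow_factor
    lab_region = labels[shadow_rows, sh_cols]
    lab_region[is_skin] = REGION_LABELS["shadow"]
    geometry.update(shadow_w=shadow_w, shadow_factor=shadow_factor)

    return SceneCube(
        grid=grid,
        palette=palette,
        material_index=material,
        illum=illum,
        region_labels=labels,
        face_box=box,
        geometry=geometry,
    )


def make_gradient_scene(
    height: int,
    width: int,
    spectrum_a: Spectrum,
    spectrum_b: Spectrum,
    diagonal: bool = True,
) -> GradientScene:
    """Scene whose pixel spectra blend linearly between two endpoints."""
    _check_dims(height, width)
    if spectrum_a.grid != spectrum_b.grid:
        raise ValueError("gradient endpoints must share a grid")
    r = np.arange(height)[:, None]
    c = np.arange(width)[None, :]
    if diagonal:
        w = (r + c) / max(height + width - 2, 1)
    else:
        w = np.broadcast_to(c / max(width - 1, 1), (height, width)).copy()
    return GradientScene(
        grid=spectrum_a.grid,
        endpoints=np.vstack([spectrum_a.values, spectrum_b.values]),
        weight=w.astype(float),
    )
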