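"""Demosaicing: one 4x4 mosaic plane -> 16 full-resolution channel planes.

Each channel is sampled on a sparse stride-4 lattice. The intensity-guided
scheme exploits the strong correlation between every channel and the local
panchromatic intensity: estimate a smooth per-pixel intensity from the exact
4x4-period means (every period averages all 16 channels once, so the
estimate mixes channels correctly even at image borders, where a plain box
filter with reflect padding would fold the mosaic onto the wrong channel
sites), then for each channel bilinearly interpolate the sparse
(channel - intensity) difference from its native sites and add the intensity
back. Native-site values are preserved exactly. `period_replicate` is the
no-interpolation baseline: each period's 16 raw values broadcast across the
period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .sensor import MosaicImage, N_CHANNELS, default_mosaic_layout

__all__ = ["ChannelCube", "demosaic_msfa", "period_replicate"]


@dataclass
class ChannelCube:
    """16 full-size channel planes, ordered by channel index."""

    planes: np.ndarray  # (16, H, W)
    layout: np.ndarray = field(default_factory=default_mosaic_layout)

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, float)
        if self.planes.ndim != 3 or self.planes.shape[0] != N_CHANNELS:
            raise ValueError(
                f"planes must be ({N_CHANNELS}, H, W), got {self.planes.shape}"
            )
        if self.planes.min() < -1e-9:
            raise ValueError("channel planes must be nonnegative")

    @property
    def height(self) -> int:
        return self.planes.shape[1]

    @property
    def width(self) -> int:
        return self.planes.shape[2]

    def vectors(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n, 16) channel vectors at the given pixels."""
        return self.planes[:, rows, cols].T


def _site_offsets(layout: np.ndarray) -> list[tuple[int, int]]:
    lay = np.asarray(layout)
    offsets = []
    for ch in range(N_CHANNELS):
        (a,), (b,) = np.nonzero(lay == ch)
        offsets.append((int(a), int(b)))
    return offsets


def _validate_layout(lay: np.ndarray) -> np.ndarray:
    lay = np.asarray(lay)
    if lay.shape != (4, 4) or sorted(lay.ravel()) != list(range(16)):
        raise ValueError(f"unknown mosaic layout:\n{lay}")
    return lay


def _period_mean_intensity(dn: np.ndarray) -> np.ndarray:
    """Smooth intensity field from exact 4x4-period means.

    Period means are residue-correct (each averages all 16 channel sites
    exactly once); they are placed at the period centers and bilinearly
    interpolated (linearly extrapolated at borders) to every pixel.
    """
    h, w = dn.shape
    means = dn.reshape(h // 4, 4, w // 4, 4).mean(axis=(1, 3))
    if means.shape[0] == 1 or means.shape[1] == 1:
        return np.full((h, w), means.mean())
    centers_r = 4.0 * np.arange(h // 4) + 1.5
    centers_c = 4.0 * np.arange(w // 4) + 1.5
    interp = RegularGridInterpolator(
        (centers_r, centers_c), means, method="linear",
        bounds_error=False, fill_value=None,
    )
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    return interp(pts).reshape(h, w)


def demosaic_msfa(m: MosaicImage, layout: Optional[np.ndarray] = None) -> ChannelCube:
    """Intensity-guided demosaicing (pseudo-panchromatic difference scheme)."""
    lay = _validate_layout(m.layout if layout is None else layout)
    dn = np.asarray(m.dn, float)
    h, w = dn.shape
    # Stage 1: per-pixel intensity estimate over full mosaic periods.
    intensity = _period_mean_intensity(dn)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    query = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    planes = np.empty((N_CHANNELS, h, w))
    for ch, (a, b) in enumerate(_site_offsets(lay)):
        rows = np.arange(a, h, 4)
        cols = np.arange(b, w, 4)
        diff = dn[a::4, b::4] - intensity[a::4, b::4]
        if rows.size == 1 or cols.size == 1:
            planes[ch] = intensity + diff.mean()
            continue
        interp = RegularGridInterpolator(
            (rows.astype(float), cols.astype(float)),
            diff,
            method="linear",
            bounds_error=False,
            fill_value=None,  # linear extrapolation at borders
        )
        planes[ch] = intensity + interp(query).reshape(h, w)
    np.clip(planes, 0.0, None, out=planes)
    # Re-anchor native sites to the raw DN (interpolation already passes
    # through them; clipping must not disturb the anchors either).
    for ch, (a, b) in enumerate(_site_offsets(lay)):
        planes[ch, a::4, b::4] = dn[a::4, b::4]
    return ChannelCube(planes=planes, layout=lay)


def period_replicate(m: MosaicImage, layout: Optional[np.ndarray] = None) -> ChannelCube:
    """Baseline: broadcast each period's 16 raw DN values across the period."""
    lay = _validate_layout(m.layout if layout is None else layout)
    dn = np.asarray(m.dn, float)
    planes = np.empty((N_CHANNELS, dn.shape[0], dn.shape[1]))
    for ch, (a, b) in enumerate(_site_offsets(lay)):
        block = dn[a::4, b::4]
        planes[ch] = np.repeat(np.repeat(block, 4, axis=0), 4, axis=1)
    return ChannelCube(planes=planes, layout=lay)
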