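"""Synthetic reflectance spectra for skin and spoof materials.

Live skin reflectance rises monotonically toward the red (melanin) and carries
two narrow oxyhemoglobin absorption dips near 542 and 577 nm; printed/photo
spoofs show a dye-like sigmoidal edge instead, and silicone/resin materials
are smooth and nearly featureless in 500-650 nm. These stand in for the
measured material classes a spectral liveness-detection camera distinguishes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .grids import Spectrum, WavelengthGrid

__all__ = ["MaterialSpec", "make_material_spectrum", "smooth_random_spectrum"]

MATERIAL_KINDS = ("skin", "print2d", "photo2d", "silicone3d", "resin3d")

# Oxyhemoglobin band centers (nm) and Gaussian half-widths used for the dips.
_HB_BANDS = ((542.0, 10.0), (577.0, 9.0))


@dataclass(frozen=True)
class MaterialSpec:
    """Parameters of one synthetic material.

    dip depths are fractions of the local baseline removed at the band center
    (0.2 -> the 542 nm reflectance is 80% of the dip-free level). Non-skin
    kinds must have zero dip depth; that absence is precisely what makes them
    spoofs. `smoothness` is the correlation length (nm) of the random smooth
    perturbation added per instance.
    """

    kind: str
    baseline: float = 0.55
    melanin_slope: float = 0.25
    dip_depth_542: float = 0.20
    dip_depth_577: float = 0.16
    smoothness: float = 60.0
    random_amp: float = 0.04
    edge_nm: float = 590.0  # dye edge position, 2D kinds only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MATERIAL_KINDS:
            raise ValueError(f"unknown material kind {self.kind!r}")
        for name, depth in (("dip_depth_542", self.dip_depth_542),
                            ("dip_depth_577", self.dip_depth_577)):
            if not 0.0 <= depth < 1.0:
                raise ValueError(
                    f"{name}={depth} would drive reflectance nonpositive "
                    f"(baseline {self.baseline}); depths must lie in [0, 1)"
                )
            if self.kind != "skin" and depth != 0.0:
                raise ValueError(
                    f"{self.kind} materials must have zero hemoglobin dip "
                    f"depth, got {name}={depth}"
                )
        if not 0.0 < self.baseline <= 1.0:
            raise ValueError(f"baseline must lie in (0, 1], got {self.baseline}")

    def with_seed(self, seed: int) -> "MaterialSpec":
        return replace(self, seed=seed)


def _smooth_noise(grid: WavelengthGrid, scale_nm: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-ish smooth random curve with correlation `scale_nm`."""
    raw = rng.standard_normal(grid.points)
    sigma = max(scale_nm / grid.step, 1.0)
    sm = gaussian_filter1d(raw, sigma, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_material_spectrum(spec: MaterialSpec, grid: WavelengthGrid) -> Spectrum:
    """Deterministic (given seed) smooth reflectance in (0, 1] for a material."""
    if grid.start > 400.0 or grid.stop < 750.0:
        raise ValueError(f"grid must cover 400-750 nm, got {grid}")
    lam = grid.wavelengths
    rng = np.random.default_rng(spec.seed)
    u = (lam - 400.0) / 350.0  # 0..1 over the working band

    if spec.kind == "skin":
        base = spec.baseline * (0.75 + 0.5 * spec.melanin_slope +
                                spec.melanin_slope * _sigmoid((lam - 590.0) / 40.0))
    elif spec.kind in ("print2d", "photo2d"):
        width = 25.0 if spec.kind == "print2d" else 35.0
        base = spec.baseline * (0.45 + 0.75 * _sigmoid((lam - spec.edge_nm) / width))
    elif spec.kind == "silicone3d":
        base = spec.baseline * (0.95 + 0.1 * u)
    else:  # resin3d
        base = spec.baseline * (0.85 + 0.25 * u * u)

    wiggle = 1.0 + spec.random_amp * _smooth_noise(grid, spec.smoothness, rng)
    refl = base * np.clip(wiggle, 0.2, None)

    dip = np.zeros_like(lam)
    for (center, sigma), depth in zip(_HB_BANDS, (spec.dip_depth_542, spec.dip_depth_577)):
        dip += depth * np.exp(-0.5 * ((lam - center) / sigma) ** 2)
    refl = refl * (1.0 - dip)

    refl = np.clip(refl, 1e-4, None)
    peak = refl.max()
    if peak > 1.0:
        refl = refl / peak
    return Spectrum(grid, refl)


def smooth_random_spectrum(
    grid: WavelengthGrid,
    seed: int,
    scale_nm: float = 60.0,
    level: float = 0.5,
    amplitude: float = 0.3,
) -> Spectrum:
    """A smooth positive random reflectance-like spectrum (test target)."""
    rng = np.random.default_rng(seed)
    v = level * (1.0 + amplitude * _smooth_noise(grid, scale_nm, rng))
    return Spectrum(grid, np.clip(v, 0.02, 1.0))
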