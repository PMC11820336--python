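"""Forward model of the 16-channel 4x4 mosaic snapshot spectral sensor.

Each pixel sits under one of 16 micro-filters tiled periodically in 4x4
units. A channel's DN value is the inner product of the incident spectrum
with the channel's effective response m_i(lambda) = q(lambda) * t_i(lambda)
(quantum efficiency times filter transmission): I = M f. Micro-filters leak
outside their passband, so the synthetic transmissions carry a broadband
crosstalk pedestal that the regularized reconstruction has to overcome.
Pixel DN values carry ~4% multiplicative noise, matching the error level a
real sensor plus calibration chain exhibits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grids import DEFAULT_GRID, Spectrum, WavelengthGrid

__all__ = [
    "SensorModel",
    "MosaicImage",
    "default_mosaic_layout",
    "build_sensor_model",
    "project_spectrum",
    "render_mosaic",
    "simulate_calibration",
]

N_CHANNELS = 16


def default_mosaic_layout() -> np.ndarray:
    """Row-major channel indices 0-15 in the 4x4 tile."""
    return np.arange(16, dtype=np.intp).reshape(4, 4)


def default_qe_curve(grid: WavelengthGrid) -> np.ndarray:
    """Broad silicon-like quantum efficiency peaking mid-band."""
    lam = grid.wavelengths
    return 0.25 + 0.6 * np.exp(-0.5 * ((lam - 560.0) / 160.0) ** 2)


@dataclass
class SensorModel:
    grid: WavelengthGrid
    response: np.ndarray       # (16, L) effective response M, rows m_i = q * t_i
    transmission: np.ndarray   # (16, L) filter transmissions t_i (pre-QE)
    qe: np.ndarray             # (L,) quantum efficiency q
    mosaic_layout: np.ndarray = field(default_factory=default_mosaic_layout)
    dn_noise_cv: float = 0.04
    bit_depth: int = 12

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, float)
        if self.response.shape != (N_CHANNELS, self.grid.points):
            raise ValueError(
                f"response must be {N_CHANNELS}x{self.grid.points}, got "
                f"{self.response.shape}"
            )
        if not np.all(np.isfinite(self.response)) or self.response.min() < 0:
            raise ValueError("response entries must be finite and nonnegative")
        if np.any(self.response.sum(axis=1) <= 0):
            raise ValueError("every channel must have positive total response")
        lay = np.asarray(self.mosaic_layout)
        if lay.shape != (4, 4) or sorted(lay.ravel()) != list(range(16)):
            raise ValueError("mosaic_layout must be a 4x4 bijection onto 0..15")
        if np.linalg.matrix_rank(self.response) < N_CHANNELS:
            raise ValueError("response matrix is rank deficient")

    @property
    def dn_max(self) -> int:
        return 2**self.bit_depth - 1


def build_sensor_model(
    grid: WavelengthGrid = DEFAULT_GRID,
    centers: Optional[np.ndarray] = None,
    fwhms: Optional[np.ndarray] = None,
    crosstalk: float = 0.08,
    qe_curve: Optional[np.ndarray] = None,
    seed: int = 0,
    dn_noise_cv: float = 0.04,
    bit_depth: int = 12,
) -> SensorModel:
    """Synthetic 16-channel sensor: Gaussian filter lobes plus a crosstalk
    pedestal, multiplied by the quantum-efficiency curve.

    Default centers spread evenly over 410-740 nm with ~40 nm FWHM; `seed`
    jitters centers and widths slightly so distinct sensors differ.
    `crosstalk` is the pedestal height as a fraction of each lobe's unit peak.
    """
    if not 0.0 <= crosstalk < 1.0:
        raise ValueError(f"crosstalk must lie in [0, 1), got {crosstalk}")
    rng = np.random.default_rng(seed)
    lam = grid.wavelengths
    if centers is None:
        centers = np.linspace(410.0, 740.0, N_CHANNELS)
        centers = centers + rng.uniform(-3.0, 3.0, N_CHANNELS)
    centers = np.asarray(centers, float)
    if centers.shape != (N_CHANNELS,):
        raise ValueError(f"need {N_CHANNELS} centers, got shape {centers.shape}")
    if centers.min() < grid.start or centers.max() > grid.stop:
        raise ValueError("filter centers must lie within the grid span")
    if fwhms is None:
        fwhms = 40.0 * (1.0 + rng.uniform(-0.1, 0.1, N_CHANNELS))
    fwhms = np.asarray(fwhms, float)
    if np.any(fwhms <= 0):
        raise ValueError("fwhms must be positive")
    if np.any(np.diff(np.sort(centers)) < 1.0):
        warnings.warn("duplicate/near-duplicate filter centers; channels will overlap")

    sigma = fwhms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    lobes = np.exp(-0.5 * ((lam[None, :] - centers[:, None]) / sigma[:, None]) ** 2)
    transmission = (1.0 - crosstalk) * lobes + crosstalk
    qe = default_qe_curve(grid) if qe_curve is None else np.asarray(qe_curve, float)
    if qe.shape != (grid.points,):
        raise ValueError(f"qe_curve must have {grid.points} points")
    return SensorModel(
        grid=grid,
        response=transmission * qe,
        transmission=transmission,
        qe=qe,
        dn_noise_cv=dn_noise_cv,
        bit_depth=bit_depth,
    )


def project_spectrum(model: SensorModel, f) -> np.ndarray:
    """Channel DN vector I_i = sum_lambda f(lambda) m_i(lambda) (linear in f)."""
    if isinstance(f, Spectrum):
        if f.grid != model.grid:
            raise ValueError(f"grid mismatch: {f.grid} vs {model.grid}")
        v = f.values
    else:
        v = np.asarray(f, float)
        if v.shape[-1] != model.grid.points:
            raise ValueError(
                f"spectrum length {v.shape[-1]} != grid points {model.grid.points}"
            )
    return v @ model.response.T


@dataclass
class MosaicImage:
    """Single-plane raw mosaic of DN values."""

    dn: np.ndarray
    layout: np.ndarray
    bit_depth: int = 12
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        h, w = self.dn.shape
        if h % 4 or w % 4:
            raise ValueError(f"mosaic dims must be multiples of 4, got {h}x{w}")
        if self.dn.min() < 0:
            raise ValueError("DN values must be nonnegative")

    @property
    def height(self) -> int:
        return self.dn.shape[0]

    @property
    def width(self) -> int:
        return self.dn.shape[1]


def channel_map(layout: np.ndarray, height: int, width: int) -> np.ndarray:
    """Per-pixel channel index implied by the periodic 4x4 layout."""
    return np.asarray(layout)[
        np.arange(height)[:, None] % 4, np.arange(width)[None, :] % 4
    ]


def render_mosaic(
    model: SensorModel,
    scene,
    exposure: float = 1.0,
    noise_on: bool = True,
    seed: int = 0,
    quantize: bool = True,
) -> MosaicImage:
    """Simulate one snapshot: per pixel, the DN of that pixel's channel.

    Noise is per-pixel independent multiplicative Gaussian with coefficient of
    variation `model.dn_noise_cv`. Quantization (rounding + clipping to the
    bit depth) can be disabled to isolate algebraic reconstruction error.
    """
    proj = scene.project(model.response)  # (H, W, 16)
    h, w = proj.shape[:2]
    ch = channel_map(model.mosaic_layout, h, w)
    dn = exposure * np.take_along_axis(proj, ch[..., None], axis=2)[..., 0]
    if noise_on:
        rng = np.random.default_rng(seed)
        dn = dn * (1.0 + rng.normal(0.0, model.dn_noise_cv, dn.shape))
    dn = np.clip(dn, 0.0, None)
    sat = np.mean(dn > model.dn_max)
    if sat > 0.01:
        warnings.warn(
            f"exposure {exposure} saturates {sat:.1%} of pixels "
            f"(bit depth {model.bit_depth})"
        )
    if quantize:
        dn = np.clip(np.round(dn), 0.0, model.dn_max)
    return MosaicImage(
        dn=dn,
        layout=model.mosaic_layout,
        bit_depth=model.bit_depth,
        meta={"exposure": exposure, "noise_on": noise_on, "seed": seed},
    )


def simulate_calibration(
    model: SensorModel,
    monochromator_step: Optional[float] = None,
    captures_per_step: int = 10,
    noise_on: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Monochromator sweep: measure the response matrix column by column.

    At each grid wavelength a unit monochromatic exposure is captured
    `captures_per_step` times with the sensor's DN noise and averaged,
    emulating the multiple-captures-then-average calibration that suppresses
    sensor noise. Noise off (or captures -> infinity) recovers M exactly.
    """
    step = model.grid.step if monochromator_step is None else float(monochromator_step)
    if abs(step - model.grid.step) > 1e-9:
        raise ValueError(
            f"monochromator step {step} nm must equal the grid step "
            f"{model.grid.step} nm"
        )
    if captures_per_step < 1:
        raise ValueError(f"captures_per_step must be >= 1, got {captures_per_step}")
    true = model.response  # (16, L); column j is the response to e_j
    if not noise_on:
        return true.copy()
    rng = np.random.default_rng(seed)
    eps = rng.normal(
        0.0, model.dn_noise_cv, size=(captures_per_step,) + true.shape
    )
    return (true[None, :, :] * (1.0 + eps)).mean(axis=0)
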