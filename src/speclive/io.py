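"""Plain-text / raster serialization of the pipeline's artifacts.

Formats:
  - spectra CSV: header ``wavelength_nm,value`` (batch files: one column per
    spectrum, ``s0000, s0001, ...``);
  - calibration CSV: ``wavelength_nm,ch00..ch15`` plus a JSON sidecar holding
    the mosaic layout, bit depth and DN noise CV;
  - mosaic raster: 16-bit grayscale PNG plus the same sidecar;
  - channel cube: 16-page 16-bit TIFF;
  - region mask: 0/255 PNG plus a JSON sidecar (box, threshold, count);
  - dataset: one CSV per sample plus a manifest JSON;
  - model checkpoint: ``.npz`` weights plus a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .cnn import ClassifierSpec, SpectralCNN, TrainConfig, TrainedModel
from .dataset import SampleSpectra, SpectraDataset
from .demosaic import ChannelCube
from .grids import WavelengthGrid, make_grid
from .region import RegionMask
from .sensor import MosaicImage, SensorModel

__all__ = [
    "write_spectra_csv", "read_spectra_csv",
    "write_calibration", "read_calibration",
    "write_mosaic", "read_mosaic",
    "write_channel_cube", "read_channel_cube",
    "write_mask", "write_dataset", "read_dataset",
    "write_checkpoint", "read_checkpoint",
]


def _grid_meta(grid: WavelengthGrid) -> dict:
    return {"start_nm": grid.start, "stop_nm": grid.stop, "step_nm": grid.step}


def _grid_from_meta(meta: dict) -> WavelengthGrid:
    return make_grid(meta["start_nm"], meta["stop_nm"], meta["step_nm"])


def write_spectra_csv(path, grid: WavelengthGrid, values: np.ndarray) -> None:
    """One spectrum (L,) or a batch (n, L) to CSV."""
    v = np.atleast_2d(np.asarray(values, float))
    if v.shape[1] != grid.points:
        raise ValueError(f"values have {v.shape[1]} columns, grid has {grid.points}")
    cols = {"wavelength_nm": grid.wavelengths}
    if v.shape[0] == 1:
        cols["value"] = v[0]
    else:
        for i, row in enumerate(v):
            cols[f"s{i:04d}"] = row
    pd.DataFrame(cols).to_csv(path, index=False)


def read_spectra_csv(path) -> tuple[WavelengthGrid, np.ndarray]:
    df = pd.read_csv(path)
    lam = df["wavelength_nm"].to_numpy(float)
    step = lam[1] - lam[0]
    grid = make_grid(lam[0], lam[-1], step)
    vals = df.drop(columns="wavelength_nm").to_numpy(float).T
    return grid, vals[0] if vals.shape[0] == 1 else vals


def write_calibration(path, model: SensorModel) -> None:
    path = Path(path)
    cols = {"wavelength_nm": model.grid.wavelengths}
    for i in range(16):
        cols[f"ch{i:02d}"] = model.response[i]
    pd.DataFrame(cols).to_csv(path, index=False)
    sidecar = {
        "grid": _grid_meta(model.grid),
        "mosaic_layout": np.asarray(model.mosaic_layout).tolist(),
        "bit_depth": model.bit_depth,
        "dn_noise_cv": model.dn_noise_cv,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_calibration(path) -> tuple[np.ndarray, dict]:
    """Measured response matrix (16, L) and the sidecar metadata."""
    path = Path(path)
    df = pd.read_csv(path)
    M = df[[f"ch{i:02d}" for i in range(16)]].to_numpy(float).T
    meta = json.loads(path.with_suffix(".json").read_text())
    meta["grid_obj"] = _grid_from_meta(meta["grid"])
    return M, meta


def write_mosaic(path, m: MosaicImage) -> None:
    path = Path(path)
    iio.imwrite(path, np.clip(np.round(m.dn), 0, 65535).astype(np.uint16))
    sidecar = {
        "mosaic_layout": np.asarray(m.layout).tolist(),
        "bit_depth": m.bit_depth,
        "meta": {k: v for k, v in m.meta.items() if isinstance(v, (int, float, str, bool))},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_mosaic(path) -> MosaicImage:
    path = Path(path)
    dn = np.asarray(iio.imread(path), float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return MosaicImage(dn=dn, layout=np.asarray(meta["mosaic_layout"]),
                       bit_depth=meta["bit_depth"], meta=meta.get("meta", {}))


def write_channel_cube(path, cube: ChannelCube) -> None:
    data = np.clip(np.round(cube.planes), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


def read_channel_cube(path) -> ChannelCube:
    return ChannelCube(planes=np.asarray(tifffile.imread(path), float))


def write_mask(path, mask: RegionMask) -> None:
    path = Path(path)
    iio.imwrite(path, (mask.mask.astype(np.uint8)) * 255)
    b = mask.box
    sidecar = {
        "box": {"top": b.top, "left": b.left, "height": b.height, "width": b.width},
        "threshold": mask.threshold,
        "selected_count": mask.selected_count,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def write_dataset(directory, ds: SpectraDataset) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "grid": _grid_meta(ds.grid),
        "band": list(ds.band),
        "normalize_mode": ds.normalize_mode,
        "target": ds.target,
        "label_names": {str(k): v for k, v in ds.label_names.items()},
        "samples": [],
    }
    for s in ds.samples:
        fname = f"{s.sample_id}.csv"
        write_spectra_csv(directory / fname, ds.grid, s.spectra)
        manifest["samples"].append({"sample_id": s.sample_id, "label": s.label,
                                    "file": fname})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_dataset(directory) -> SpectraDataset:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    grid = _grid_from_meta(manifest["grid"])
    samples = []
    for entry in manifest["samples"]:
        _, vals = read_spectra_csv(directory / entry["file"])
        samples.append(SampleSpectra(entry["sample_id"], entry["label"],
                                     np.atleast_2d(vals)))
    return SpectraDataset(samples=samples, grid=grid,
                          band=tuple(manifest["band"]),
                          normalize_mode=manifest["normalize_mode"],
                          target=manifest["target"])


def write_checkpoint(path, trained: TrainedModel) -> None:
    path = Path(path)
    np.savez(path, **{f"param_{k}": v for k, v in trained.model.params.items()})
    manifest = {
        "spec": {
            "input_length": trained.spec.input_length,
            "conv_blocks": [list(b) for b in trained.spec.conv_blocks],
            "hidden": trained.spec.hidden,
            "classes": trained.spec.classes,
        },
        "cfg": {k: getattr(trained.cfg, k) for k in
                ("batch_size", "epochs", "initial_lr", "lr_half_period",
                 "rho", "eps", "patience", "seed", "lr_absolute")},
        "best_epoch": trained.best_epoch,
        "best_val_loss": trained.best_val_loss,
        "history": trained.history,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def read_checkpoint(path) -> TrainedModel:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    spec = ClassifierSpec(
        input_length=manifest["spec"]["input_length"],
        conv_blocks=tuple(tuple(b) for b in manifest["spec"]["conv_blocks"]),
        hidden=manifest["spec"]["hidden"],
        classes=manifest["spec"]["classes"],
    )
    model = SpectralCNN(spec, seed=0)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        model.load_params({k[len("param_"):]: data[k] for k in data.files})
    cfg = TrainConfig(**manifest["cfg"])
    return TrainedModel(model=model, spec=spec, cfg=cfg,
                        history=manifest["history"],
                        best_epoch=manifest["best_epoch"],
                        best_val_loss=manifest["best_val_loss"],
                        checkpoint=model.copy_params())
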