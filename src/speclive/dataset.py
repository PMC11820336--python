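"""Labeled spectral datasets: normalization, band crop, compression, splits.

Every selected face region yields tens of thousands of reconstructed spectra.
To give every sample equal weight during training (and to cut training time),
each sample's spectra are randomly permuted and mean-filtered down to exactly
2000 rows. Group labels follow the fixed numbering {0: "2D", 1: "Real",
2: "3D"}. The split is two-level: half of the samples in each group build the
model (their spectra split 2/3 train, 1/3 validation) and the other half are
held out entirely for system-level testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import CLASSIFIER_BAND, WavelengthGrid, crop_columns, normalize_rows

__all__ = [
    "LABEL_NAMES",
    "SampleSpectra",
    "SpectraDataset",
    "DatasetSplit",
    "compress_spectra",
    "assemble_dataset",
    "split_dataset",
]

LABEL_NAMES = {0: "2D", 1: "Real", 2: "3D"}
DEFAULT_TARGET = 2000


@dataclass
class SampleSpectra:
    """One physical sample: id, group label, and its (n, L) spectra matrix."""

    sample_id: str
    label: int
    spectra: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in LABEL_NAMES:
            raise ValueError(
                f"unknown label {self.label} for sample {self.sample_id!r}; "
                f"expected one of {sorted(LABEL_NAMES)}"
            )
        self.spectra = np.asarray(self.spectra, float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be an (n, L) matrix")


@dataclass
class SpectraDataset:
    samples: list[SampleSpectra]
    grid: WavelengthGrid
    band: tuple[float, float] = CLASSIFIER_BAND
    normalize_mode: str = "max1"
    target: int = DEFAULT_TARGET
    label_names: dict = field(default_factory=lambda: dict(LABEL_NAMES))

    def __post_init__(self) -> None:
        for s in self.samples:
            if s.spectra.shape != (self.target, self.grid.points):
                raise ValueError(
                    f"sample {s.sample_id!r} has shape {s.spectra.shape}, "
                    f"expected ({self.target}, {self.grid.points})"
                )
            if not np.all(np.isfinite(s.spectra)):
                raise ValueError(f"sample {s.sample_id!r} has non-finite values")

    def by_group(self) -> dict[int, list[SampleSpectra]]:
        groups: dict[int, list[SampleSpectra]] = {}
        for s in self.samples:
            groups.setdefault(s.label, []).append(s)
        return groups


def compress_spectra(
    spectra: np.ndarray, target: int = DEFAULT_TARGET, seed: int = 0
) -> np.ndarray:
    """Randomly arrange n >= target spectra and mean-filter to `target` rows.

    The seeded permutation is partitioned into `target` contiguous groups as
    equal as possible (the first n mod target groups get one extra row); each
    output row is its group's mean. n == target degenerates to a permutation.
    """
    X = np.asarray(spectra, float)
    n = X.shape[0]
    if n < target:
        raise ValueError(
            f"cannot compress {n} spectra to {target}: need n >= target "
            f"(selected face regions are expected to exceed {target} pixels)"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    Xp = X[perm]
    # Group sizes as produced by np.array_split: first (n % target) groups
    # have size n//target + 1.
    q, r = divmod(n, target)
    sizes = np.full(target, q, dtype=np.intp)
    sizes[:r] += 1
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    sums = np.add.reduceat(Xp, starts, axis=0)
    return sums / sizes[:, None]


def assemble_dataset(
    raw_samples: list[tuple[str, int, np.ndarray]],
    grid: WavelengthGrid,
    band: tuple[float, float] = CLASSIFIER_BAND,
    normalize_mode: str = "max1",
    target: int = DEFAULT_TARGET,
    seed: int = 0,
) -> SpectraDataset:
    """normalize -> crop band -> compress, per sample, deterministically.

    `raw_samples` holds (sample_id, group_label, (n, L) spectra on `grid`).
    Per-sample compression seeds are spawned from `seed` so the whole dataset
    is reproducible from (inputs, seed).
    """
    if not raw_samples:
        raise ValueError("cannot assemble a dataset from zero samples")
    child_seeds = np.random.SeedSequence(seed).spawn(len(raw_samples))
    samples = []
    for (sid, label, X), ss in zip(raw_samples, child_seeds):
        if label not in LABEL_NAMES:
            raise ValueError(f"unknown label {label} for sample {sid!r}")
        Xn = normalize_rows(np.clip(np.asarray(X, float), 0.0, None), normalize_mode)
        sub, Xc = crop_columns(grid, Xn, *band)
        comp = compress_spectra(Xc, target=target,
                                seed=int(ss.generate_state(1)[0] % 2**31))
        samples.append(SampleSpectra(sid, label, comp))
    return SpectraDataset(
        samples=samples, grid=sub, band=band,
        normalize_mode=normalize_mode, target=target,
    )


@dataclass
class DatasetSplit:
    train_X: np.ndarray
    train_y: np.ndarray
    val_X: np.ndarray
    val_y: np.ndarray
    test_samples: list[SampleSpectra]
    build_sample_ids: list[str]

    def __post_init__(self) -> None:
        assert self.train_X.shape[0] == self.train_y.shape[0]
        assert self.val_X.shape[0] == self.val_y.shape[0]


def split_dataset(
    ds: SpectraDataset,
    sample_frac: float = 0.5,
    train_frac: float = 2.0 / 3.0,
    seed: int = 0,
) -> DatasetSplit:
    """Two-level stratified split.

    Sample level: `sample_frac` of the samples in each group (floor, at least
    one, never all) build the model; the rest are held-out test samples.
    Spectrum level: within each model-building sample, rows are shuffled and
    floor(train_frac * n) go to training, the remainder to validation.
    """
    rng = np.random.default_rng(seed)
    train_parts, val_parts, test_samples, build_ids = [], [], [], []
    for label, group in sorted(ds.by_group().items()):
        if len(group) < 2:
            raise ValueError(
                f"group {label} ({ds.label_names[label]}) has only "
                f"{len(group)} sample(s); need >= 2 for a sample-level split"
            )
        order = rng.permutation(len(group))
        n_build = min(max(int(len(group) * sample_frac), 1), len(group) - 1)
        for pos, idx in enumerate(order):
            s = group[idx]
            if pos < n_build:
                build_ids.append(s.sample_id)
                row_order = rng.permutation(s.spectra.shape[0])
                n_train = int(np.floor(train_frac * s.spectra.shape[0]))
                train_parts.append((s.spectra[row_order[:n_train]], label))
                val_parts.append((s.spectra[row_order[n_train:]], label))
            else:
                test_samples.append(s)

    def _stack(parts):
        X = np.vstack([p[0] for p in parts])
        y = np.concatenate([np.full(p[0].shape[0], p[1], dtype=np.intp) for p in parts])
        return X, y

    train_X, train_y = _stack(train_parts)
    val_X, val_y = _stack(val_parts)
    return DatasetSplit(train_X, train_y, val_X, val_y, test_samples, build_ids)
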