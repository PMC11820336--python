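"""Face localisation and flat-skin region selection.

The production system locates the face with an off-the-shelf detector, takes
the mean 16-channel DN vector of the forehead strip as a flat-skin reference,
and keeps every facial pixel whose 16-channel DN vector lies within a
Euclidean distance threshold of that reference. Eyebrows, mouth and shadowed
pixels fall outside the threshold and are discarded before reconstruction.

The detector is pluggable: tests and simulations register a ground-truth
detector, production code may wrap any external face detector behind the same
interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np

__all__ = [
    "FaceBox",
    "RegionMask",
    "FaceDetector",
    "GroundTruthDetector",
    "locate_face",
    "reference_vector",
    "select_flat_region",
]


@dataclass(frozen=True)
class FaceBox:
    """Half-open pixel rectangle (0-based, row-major)."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError(f"face box must have positive area, got {self}")
        if self.top < 0 or self.left < 0:
            raise ValueError(f"face box must lie inside the image, got {self}")

    @property
    def bottom(self) -> int:
        return self.top + self.height

    @property
    def right(self) -> int:
        return self.left + self.width

    @property
    def area(self) -> int:
        return self.height * self.width

    def slices(self) -> tuple[slice, slice]:
        return slice(self.top, self.bottom), slice(self.left, self.right)


class FaceDetector(Protocol):
    def detect(self, image: np.ndarray) -> Sequence[FaceBox]: ...


@dataclass
class GroundTruthDetector:
    """Detector stub returning pre-known boxes (synthetic scenes)."""

    boxes: Sequence[FaceBox] = field(default_factory=tuple)

    def detect(self, image: np.ndarray) -> Sequence[FaceBox]:
        return tuple(self.boxes)


def locate_face(image: np.ndarray, detector: FaceDetector) -> Optional[FaceBox]:
    """Largest detected face box, or None when no face is found.

    The no-face outcome is a value, not an exception: a blank frame is a
    normal condition for a liveness camera.
    """
    boxes = list(detector.detect(image))
    if not boxes:
        return None
    h, w = image.shape[:2]
    for b in boxes:
        if b.bottom > h or b.right > w:
            raise ValueError(f"detector returned out-of-image box {b}")
    return max(boxes, key=lambda b: b.area)


def _box_vectors(planes: np.ndarray, box: FaceBox) -> np.ndarray:
    rs, cs = box.slices()
    return planes[:, rs, cs].reshape(planes.shape[0], -1).T  # (n_pixels, 16)


def reference_vector(cube, box: FaceBox, strip_fraction: float = 0.2) -> np.ndarray:
    """Mean 16-channel vector over the top (forehead) strip of the face box."""
    if not 0.0 < strip_fraction <= 1.0:
        raise ValueError(f"strip_fraction must lie in (0, 1], got {strip_fraction}")
    strip_h = int(np.floor(strip_fraction * box.height))
    if strip_h < 1:
        raise ValueError(
            f"forehead strip is empty: strip_fraction {strip_fraction} of box "
            f"height {box.height} rounds to zero rows"
        )
    strip = FaceBox(box.top, box.left, strip_h, box.width)
    return _box_vectors(np.asarray(cube.planes, float), strip).mean(axis=0)


@dataclass
class RegionMask:
    """Boolean selection plane restricted to a face box."""

    mask: np.ndarray
    box: FaceBox
    threshold: float

    @property
    def selected_count(self) -> int:
        return int(self.mask.sum())


def select_flat_region(
    cube,
    box: FaceBox,
    ref: np.ndarray,
    threshold: Optional[float] = None,
    k: float = 0.25,
    normalize: bool = False,
) -> RegionMask:
    """Mask of in-box pixels within Euclidean distance `threshold` of `ref`.

    When `threshold` is None it is taken relative to the reference magnitude,
    ``k * ||ref||``, which makes the selection robust to exposure changes.
    With ``normalize=True`` pixel vectors and the reference are L2-normalized
    before the distance, which makes pure intensity scalings (shadows)
    selectable; the default keeps shadows excluded, matching the behaviour of
    the forehead-referenced selection on real faces.
    """
    planes = np.asarray(cube.planes, float)
    ref = np.asarray(ref, float).reshape(-1)
    if ref.shape[0] != planes.shape[0]:
        raise ValueError(
            f"reference length {ref.shape[0]} does not match {planes.shape[0]} channels"
        )
    vecs = _box_vectors(planes, box)
    if normalize:
        norms = np.linalg.norm(vecs, axis=1)
        vecs = vecs / np.where(norms > 0, norms, 1.0)[:, None]
        ref = ref / np.linalg.norm(ref)
    thr = float(threshold) if threshold is not None else k * float(np.linalg.norm(ref))
    if thr <= 0:
        raise ValueError(f"threshold must be positive, got {thr}")
    dist = np.linalg.norm(vecs - ref, axis=1)
    inbox = dist < thr
    mask = np.zeros(planes.shape[1:], dtype=bool)
    rs, cs = box.slices()
    mask[rs, cs] = inbox.reshape(box.height, box.width)
    return RegionMask(mask=mask, box=box, threshold=thr)
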