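"""Image and mask I/O.

Images are held in memory as float arrays in [0, 1], shape (H, W, 3),
row-major with the origin at the top-left. Binary masks are (H, W) uint8
arrays with values in {0, 1}, where 1 marks nucleus/tumor foreground.
On disk, masks are 8-bit single-channel PNGs encoded 0/255.

A dataset directory pairs ``<id>.png`` (or ``.tif``/``.tiff``) with an
optional ``<id>_mask.png`` ground-truth mask.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, ValidationError

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


@dataclasses.dataclass
class LabeledImage:
    """An RGB image with an optional pixel-exact binary ground-truth mask."""

    image: np.ndarray
    mask: Optional[np.ndarray]
    image_id: str

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValidationError(f"image must be (H, W, 3), got {self.image.shape}")
        if self.mask is not None and self.mask.shape != self.image.shape[:2]:
            raise ValidationError(
                f"mask shape {self.mask.shape} does not match image "
                f"{self.image.shape[:2]} for id {self.image_id!r}"
            )


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    """Scale an integer or float image array to float64 in [0, 1]."""
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr.astype(np.float64), 0.0, 1.0)
    raise FormatError(f"unsupported pixel dtype {arr.dtype}")


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as an (H, W, 3) float array in [0, 1].

    Grayscale inputs are replicated to three channels; an alpha channel,
    if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises various backend errors
        raise FormatError(f"cannot decode {path}: {exc}") from exc
    arr = _to_unit_float(np.asarray(raw))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise FormatError(f"unsupported image shape {arr.shape} in {path}")
    return arr


def read_mask(path, threshold: float = 0.5) -> np.ndarray:
    """Read a mask file; a pixel is foreground iff its scaled intensity > threshold.

    Multi-channel files use the first channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot decode {path}: {exc}") from exc
    arr = _to_unit_float(np.asarray(raw))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (arr > threshold).astype(np.uint8)


def write_image(image: np.ndarray, path) -> None:
    """Write an (H, W, 3) float image in [0, 1] as an 8-bit PNG/TIFF."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255.0 + 0.5).astype(np.uint8))


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit single-channel PNG (0 -> 0, 1 -> 255)."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValidationError("mask values must be 0 or 1")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def load_dataset(directory) -> list[LabeledImage]:
    """Load all image/mask pairs from a directory.

    Files named ``<id>.png|tif|tiff`` are images; ``<id>_mask.png`` is the
    mask for ``<id>``. Images without a mask load with ``mask=None``. An
    empty directory yields an empty list. A mask whose shape disagrees with
    its image raises :class:`ValidationError` naming the id.
    """
    directory = Path(directory)
    items: list[LabeledImage] = []
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in _IMAGE_SUFFIXES:
            continue
        if path.stem.endswith("_mask"):
            continue
        image = read_image(path)
        mask_path = directory / f"{path.stem}_mask.png"
        mask = read_mask(mask_path) if mask_path.exists() else None
        if mask is not None and mask.shape != image.shape[:2]:
            raise ValidationError(
                f"mask shape {mask.shape} does not match image "
                f"{image.shape[:2]} for id {path.stem!r}"
            )
        items.append(LabeledImage(image=image, mask=mask, image_id=path.stem))
    return items


def write_dataset(dataset: list[LabeledImage], directory) -> None:
    """Write each item as ``<id>.png`` plus ``<id>_mask.png`` when a mask exists."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for item in dataset:
        write_image(item.image, directory / f"{item.image_id}.png")
        if item.mask is not None:
            write_mask(item.mask, directory / f"{item.image_id}_mask.png")
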