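"""Patch extraction, labeling, augmentation and mask reassembly.

Both segmentation branches operate on fixed-size square tiles cut from
the input image on a regular grid (default 32x32, non-overlapping).
When the image dimensions are not covered exactly the image is
reflect-padded on the bottom/right to the smallest covering size; grid
coordinates refer to that padded canvas, and reassembly crops the
padding away so the round trip is exact.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence, Union

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, ValidationError
from .image_io import LabeledImage


@dataclasses.dataclass
class PatchGrid:
    """Patches from one image plus the grid geometry needed to reassemble it."""

    patches: np.ndarray  # (n, ps, ps, C) or (n, ps, ps) for masks
    coords: list[tuple[int, int]]  # (row, col) top-left on the padded canvas
    patch_size: int
    stride: int
    source_height: int
    source_width: int
    padded_height: int
    padded_width: int

    def __len__(self) -> int:
        return len(self.patches)


def _padded_extent(dim: int, patch_size: int, stride: int) -> int:
    """Smallest extent >= dim covered exactly by the patch grid."""
    if dim <= patch_size:
        return patch_size
    n_steps = int(np.ceil((dim - patch_size) / stride))
    return patch_size + n_steps * stride


def _check_geometry(patch_size: int, stride: int) -> None:
    if patch_size < 1:
        raise InvalidParameterError("patch_size must be >= 1")
    if stride < 1 or stride > patch_size:
        raise InvalidParameterError("stride must satisfy 1 <= stride <= patch_size")


def _extract(array: np.ndarray, patch_size: int, stride: int) -> PatchGrid:
    h, w = array.shape[:2]
    ph = _padded_extent(h, patch_size, stride)
    pw = _padded_extent(w, patch_size, stride)
    pad = [(0, ph - h), (0, pw - w)] + [(0, 0)] * (array.ndim - 2)
    padded = np.pad(array, pad, mode="reflect") if (ph > h or pw > w) else array
    rows = range(0, ph - patch_size + 1, stride)
    cols = range(0, pw - patch_size + 1, stride)
    coords = [(r, c) for r in rows for c in cols]
    patches = np.stack([padded[r : r + patch_size, c : c + patch_size] for r, c in coords])
    return PatchGrid(
        patches=patches,
        coords=coords,
        patch_size=patch_size,
        stride=stride,
        source_height=h,
        source_width=w,
        padded_height=ph,
        padded_width=pw,
    )


def extract_patches(image: np.ndarray, patch_size: int = 32, stride: int = 32) -> PatchGrid:
    """Cut an (H, W, 3) image into patches left-to-right, top-to-bottom."""
    _check_geometry(patch_size, stride)
    if image.ndim != 3:
        raise ValidationError(f"expected (H, W, C) image, got shape {image.shape}")
    return _extract(image, patch_size, stride)


def extract_mask_patches(mask: np.ndarray, patch_size: int = 32, stride: int = 32) -> PatchGrid:
    """Cut a binary (H, W) mask into patches on the same grid as the image."""
    _check_geometry(patch_size, stride)
    if mask.ndim != 2:
        raise ValidationError(f"expected (H, W) mask, got shape {mask.shape}")
    return _extract(mask, patch_size, stride)


def label_patch(mask_patch: np.ndarray, positive_fraction: float = 0.5) -> int:
    """Binary patch label from ground truth: 1 (cancer) iff the foreground
    fraction reaches ``positive_fraction`` (default: majority)."""
    mask_patch = np.asarray(mask_patch)
    if mask_patch.size == 0:
        raise InvalidParameterError("empty mask patch")
    return int(mask_patch.mean() >= positive_fraction)


def assemble_mask(
    labels: Union[Sequence[int], Sequence[np.ndarray], np.ndarray], grid: PatchGrid
) -> np.ndarray:
    """Reassemble per-patch labels (or per-pixel mask patches) into a full mask.

    Scalar labels are broadcast to every pixel of their patch. With an
    overlapping grid each pixel takes the majority vote over the patches
    covering it; exact ties go to foreground. Padding introduced at
    extraction is cropped, so the output matches the source image size.
    """
    if len(labels) != len(grid.coords):
        raise ValidationError(
            f"{len(labels)} labels for {len(grid.coords)} grid cells"
        )
    ones = np.zeros((grid.padded_height, grid.padded_width), dtype=np.int64)
    cover = np.zeros_like(ones)
    ps = grid.patch_size
    for label, (r, c) in zip(labels, grid.coords):
        patch_vals = np.asarray(label)
        if patch_vals.ndim == 0:
            ones[r : r + ps, c : c + ps] += int(patch_vals)
        else:
            if patch_vals.shape != (ps, ps):
                raise ValidationError(
                    f"mask patch shape {patch_vals.shape} != ({ps}, {ps})"
                )
            ones[r : r + ps, c : c + ps] += patch_vals.astype(np.int64)
        cover[r : r + ps, c : c + ps] += 1
    # majority with ties -> 1: foreground iff ones >= cover/2
    full = (2 * ones >= cover).astype(np.uint8)
    return full[: grid.source_height, : grid.source_width]


def _rotate_pair(
    image: np.ndarray, mask: np.ndarray | None, angle: float
) -> tuple[np.ndarray, np.ndarray | None]:
    angle = angle % 360
    if angle % 90 == 0:
        k = int(angle // 90)
        rot_img = np.rot90(image, k=k, axes=(0, 1))
        rot_mask = None if mask is None else np.rot90(mask, k=k)
        return np.ascontiguousarray(rot_img), (
            None if rot_mask is None else np.ascontiguousarray(rot_mask)
        )
    # Arbitrary angles: bilinear for the image, nearest for the mask so it
    # stays binary; canvas kept at original size with reflect fill.
    rot_img = ndimage.rotate(
        image, angle, axes=(1, 0), reshape=False, order=1, mode="reflect"
    )
    rot_img = np.clip(rot_img, 0.0, 1.0)
    rot_mask = None
    if mask is not None:
        rot_mask = ndimage.rotate(
            mask.astype(np.uint8), angle, axes=(1, 0), reshape=False, order=0, mode="reflect"
        )
    return rot_img, rot_mask


def augment_rotations(
    dataset: Sequence[LabeledImage], angles: Sequence[float] = (0, 90, 180, 270)
) -> list[LabeledImage]:
    """Rotation augmentation: every image/mask pair rotated by every angle.

    Output size is ``len(dataset) * len(angles)``; right-angle rotations are
    lossless. Mask and image are always rotated identically.
    """
    if len(angles) == 0:
        raise InvalidParameterError("angles must be non-empty")
    out: list[LabeledImage] = []
    for item in dataset:
        for angle in angles:
            rot_img, rot_mask = _rotate_pair(item.image, item.mask, angle)
            if angle % 360 == 0:
                new_id = item.image_id  # identity rotation keeps the id
            else:
                tag = int(angle) if float(angle).is_integer() else angle
                new_id = f"{item.image_id}_rot{tag}"
            out.append(LabeledImage(image=rot_img, mask=rot_mask, image_id=new_id))
    return out
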