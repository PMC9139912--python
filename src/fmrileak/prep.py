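"""Slice-to-image preparation for CNN input.

Each 2D slice is min-max normalized to [0, 1] (a constant slice maps to
all zeros), bilinearly resized to a square target, and replicated to three
channels. Normalization is strictly per slice: no dataset-level statistics
are computed, so the preparation step itself cannot carry information
across the train/test boundary.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.transform import resize

from .slices import Slice2D, SliceStack

__all__ = ["PreparedSlice", "enhance_slice", "prepare_stack"]


@dataclasses.dataclass
class PreparedSlice:
    """A 3 x S x S image in [0, 1] with the source slice's provenance."""

    pixels: np.ndarray
    subject_id: str
    class_label: str
    depth_index: int
    time_index: int
    label: int | None = None


def _normalize_resize(pixels: np.ndarray, target_size: int) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2:
        raise ValueError(f"expected a 2D slice, got ndim={pixels.ndim}")
    if not np.all(np.isfinite(pixels)):
        raise ValueError("slice contains non-finite pixel values")
    lo, hi = pixels.min(), pixels.max()
    if hi > lo:
        img = (pixels - lo) / (hi - lo)
    else:
        img = np.zeros_like(pixels)
    if img.shape != (target_size, target_size):
        img = resize(
            img,
            (target_size, target_size),
            order=1,  # bilinear
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
        img = np.clip(img, 0.0, 1.0)
    return np.broadcast_to(img.astype(np.float32), (3, target_size, target_size)).copy()


def enhance_slice(slc: Slice2D, target_size: int = 224) -> PreparedSlice:
    """Prepare one slice: min-max normalize, resize, triplicate channels."""
    return PreparedSlice(
        pixels=_normalize_resize(slc.pixels, target_size),
        subject_id=slc.subject_id,
        class_label=slc.class_label,
        depth_index=slc.depth_index,
        time_index=slc.time_index,
    )


def prepare_stack(stack: SliceStack, target_size: int = 224) -> np.ndarray:
    """Prepare every slice of a stack; returns an (n, 3, S, S) array."""
    out = np.empty((len(stack), 3, target_size, target_size), dtype=np.float32)
    for i in range(len(stack)):
        out[i] = _normalize_resize(stack.pixels[i], target_size)
    return out
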