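"""Depth x time slice extraction, percentile filtering and subsampling.

A 4D BOLD volume of shape (H, W, D, T) is cut into D*T axial 2D slices,
one per (depth, time) index pair. Per subject, only slices whose mean BOLD
signal reaches the chosen percentile of that subject's slice means are
retained (default: 90th percentile, i.e. roughly the brightest ~10%), and
a fixed number of the survivors is sampled uniformly without replacement.
Deduplication keeps only each subject's earliest scan date.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .cohort import Volume4D

__all__ = [
    "Slice2D",
    "SliceStack",
    "n_slices",
    "select_earliest_scan",
    "extract_slices",
    "retained_mask",
    "filter_top_percentile",
    "sample_slices",
    "to_manifest",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class Slice2D:
    """One 2D axial slice with its provenance and mean signal."""

    pixels: np.ndarray
    subject_id: str
    class_label: str
    depth_index: int
    time_index: int
    mean_signal: float


@dataclasses.dataclass
class SliceStack:
    """Ordered set of slices from one subject, stored as a dense array.

    ``pixels`` has shape (n, H, W); ``depth_index``, ``time_index`` and
    ``mean_signal`` are parallel length-n vectors. ``filtered`` and
    ``sample_size`` record whether the percentile filter and the random
    subsample have been applied.
    """

    subject_id: str
    class_label: str
    pixels: np.ndarray
    depth_index: np.ndarray
    time_index: np.ndarray
    mean_signal: np.ndarray
    filtered: bool = False
    sample_size: int | None = None

    def __post_init__(self):
        n = len(self.pixels)
        if not (len(self.depth_index) == len(self.time_index) == len(self.mean_signal) == n):
            raise ValueError("provenance vectors must match the number of slices")

    def __len__(self) -> int:
        return len(self.pixels)

    def __getitem__(self, i: int) -> Slice2D:
        return Slice2D(
            pixels=self.pixels[i],
            subject_id=self.subject_id,
            class_label=self.class_label,
            depth_index=int(self.depth_index[i]),
            time_index=int(self.time_index[i]),
            mean_signal=float(self.mean_signal[i]),
        )

    def take(self, indices: np.ndarray, **updates) -> "SliceStack":
        fields = dict(
            subject_id=self.subject_id,
            class_label=self.class_label,
            pixels=self.pixels[indices],
            depth_index=self.depth_index[indices],
            time_index=self.time_index[indices],
            mean_signal=self.mean_signal[indices],
            filtered=self.filtered,
            sample_size=self.sample_size,
        )
        fields.update(updates)
        return SliceStack(**fields)


def n_slices(volume_shape: Sequence[int]) -> int:
    """Number of depth x time slices a (H, W, D, T) volume yields: D*T.

    Pure arithmetic — no array of that shape is ever allocated, so
    study-scale shapes are instant.
    """
    if len(volume_shape) != 4:
        raise ValueError(f"expected a 4-tuple (H, W, D, T), got {volume_shape}")
    return int(volume_shape[2]) * int(volume_shape[3])


def select_earliest_scan(cohort: pd.DataFrame) -> pd.DataFrame:
    """Keep, per subject, only the row with the earliest scan date.

    The result is sorted by subject_id so it does not depend on the input
    row order. Duplicate (subject, date) rows are rejected.
    """
    dates = pd.to_datetime(cohort["scan_date"], errors="raise")
    if cohort.duplicated(subset=["subject_id", "scan_date"]).any():
        dupes = cohort[cohort.duplicated(subset=["subject_id", "scan_date"], keep=False)]
        raise ValueError(
            f"duplicate (subject_id, scan_date) rows: {sorted(set(dupes['subject_id']))}"
        )
    work = cohort.assign(_date=dates)
    idx = work.groupby("subject_id")["_date"].idxmin()
    out = cohort.loc[idx.sort_index()].sort_values("subject_id", kind="stable")
    return out.reset_index(drop=True)


def extract_slices(volume: Volume4D) -> SliceStack:
    """Cut a 4D volume into all D*T axial slices.

    Slice (d, t) is ``data[:, :, d, t]``; ordering is depth-major
    (d outer loop, t inner). The per-slice mean BOLD signal is computed
    here once and reused by the percentile filter.
    """
    data = volume.data
    h, w, d, t = data.shape
    pixels = np.transpose(data, (2, 3, 0, 1)).reshape(d * t, h, w)
    depth = np.repeat(np.arange(d), t)
    time = np.tile(np.arange(t), d)
    return SliceStack(
        subject_id=volume.subject_id,
        class_label=volume.class_label,
        pixels=pixels,
        depth_index=depth,
        time_index=time,
        mean_signal=pixels.mean(axis=(1, 2)),
    )


def retained_mask(mean_signals: np.ndarray, percentile: float = 90.0) -> np.ndarray:
    """Boolean mask of slices whose mean reaches the given percentile.

    The threshold is the linearly interpolated percentile of all means
    (numpy's default convention); slices with mean >= threshold are kept,
    so ties at the threshold are retained. For N distinct means this keeps
    approximately N * (100 - percentile) / 100 slices.
    """
    means = np.asarray(mean_signals, dtype=float)
    if means.size == 0:
        raise ValueError("cannot filter an empty set of slice means")
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must lie in (0, 100), got {percentile}")
    threshold = np.percentile(means, percentile)
    return means >= threshold


def filter_top_percentile(stack: SliceStack, percentile: float = 90.0) -> SliceStack:
    """Retain the slices in the top (100 - percentile)% by mean signal.

    Original slice ordering is preserved.
    """
    if len(stack) == 0:
        raise ValueError(f"subject {stack.subject_id}: cannot filter an empty slice stack")
    mask = retained_mask(stack.mean_signal, percentile)
    return stack.take(np.flatnonzero(mask), filtered=True)


def sample_slices(
    stack: SliceStack,
    n: int = 700,
    seed: int = 0,
    allow_replacement: bool = False,
) -> SliceStack:
    """Uniform random subsample of ``n`` slices, seeded per subject.

    Without replacement by default; if the stack is smaller than ``n`` and
    ``allow_replacement`` is set, sampling falls back to with-replacement
    and logs the fact. The per-subject stream is derived from
    (seed, subject_id), so subjects are independent of processing order.
    """
    if n < 0:
        raise ValueError("sample size must be nonnegative")
    rng = derive_rng(seed, "sample", stack.subject_id)
    if n > len(stack):
        if not allow_replacement:
            raise ValueError(
                f"subject {stack.subject_id}: requested {n} slices but only "
                f"{len(stack)} available (set allow_replacement to permit resampling)"
            )
        logger.warning(
            "subject %s: sampling %d slices with replacement from %d",
            stack.subject_id, n, len(stack),
        )
        idx = rng.choice(len(stack), size=n, replace=True)
    else:
        idx = rng.choice(len(stack), size=n, replace=False)
    return stack.take(idx, sample_size=n)


def to_manifest(stacks: Iterable[SliceStack]) -> pd.DataFrame:
    """Flatten slice stacks into a tidy manifest of slice identifiers.

    Columns: subject_id, class_label, depth_index, time_index, mean_signal.
    This lightweight table is what the hold-out splitters operate on.
    """
    frames = []
    for stack in stacks:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": stack.subject_id,
                    "class_label": stack.class_label,
                    "depth_index": stack.depth_index.astype(int),
                    "time_index": stack.time_index.astype(int),
                    "mean_signal": stack.mean_signal,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["subject_id", "class_label", "depth_index", "time_index", "mean_signal"]
        )
    return pd.concat(frames, ignore_index=True)
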