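"""The two contrasted hold-out strategies, plus a leakage audit.

*Subject-level* splitting assigns whole subjects (and with them all of
their slices) to either train or test — the valid strategy for a
diagnostic claim, since the model never sees a test subject during
training. *Slice-level* splitting pools all slices of a class and splits
them 70/30 irrespective of subject, so slices of the same brain routinely
land on both sides — the leaky strategy. ``audit_leakage`` detects the
contamination in any split plan by intersecting the subject sets of the
two sides.

Both splitters are stratified per class (each diagnosis split
independently) and operate on a tidy slice manifest with columns
``subject_id, class_label, depth_index, time_index``; collections of
:class:`~fmrileak.slices.SliceStack` are accepted and converted.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .slices import SliceStack, to_manifest

__all__ = [
    "SplitPlan",
    "LeakageAudit",
    "split_by_subject",
    "split_by_slice",
    "audit_leakage",
]

_ID_COLS = ["subject_id", "class_label", "depth_index", "time_index"]


@dataclasses.dataclass
class SplitPlan:
    """Train/test membership of slices under one hold-out mode."""

    mode: str  # "subject" | "slice"
    seed: int
    train: pd.DataFrame
    test: pd.DataFrame
    class_counts: dict  # class_label -> {"train": n, "test": n} (slice counts)

    def __post_init__(self):
        if self.mode not in ("subject", "slice"):
            raise ValueError(f"split mode must be 'subject' or 'slice', got {self.mode!r}")
        train_ids = set(map(tuple, self.train[_ID_COLS[:1] + _ID_COLS[2:]].itertuples(index=False)))
        test_ids = set(map(tuple, self.test[_ID_COLS[:1] + _ID_COLS[2:]].itertuples(index=False)))
        overlap = train_ids & test_ids
        if overlap:
            raise ValueError(f"train and test share {len(overlap)} slice identifiers")

    @property
    def train_subjects(self) -> set:
        return set(self.train["subject_id"])

    @property
    def test_subjects(self) -> set:
        return set(self.test["subject_id"])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mode": self.mode,
            "seed": self.seed,
            "class_counts": self.class_counts,
            "train_ids": self.train[_ID_COLS].to_dict(orient="records"),
            "test_ids": self.test[_ID_COLS].to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SplitPlan":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        payload = json.loads(text)
        return cls(
            mode=payload["mode"],
            seed=payload["seed"],
            train=pd.DataFrame(payload["train_ids"], columns=_ID_COLS),
            test=pd.DataFrame(payload["test_ids"], columns=_ID_COLS),
            class_counts=payload["class_counts"],
        )


@dataclasses.dataclass
class LeakageAudit:
    """Result of checking a split plan for subject contamination."""

    leaky: bool
    shared_subjects: list
    shared_count: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _as_manifest(slices) -> pd.DataFrame:
    if isinstance(slices, pd.DataFrame):
        missing = set(_ID_COLS) - set(slices.columns)
        if missing:
            raise ValueError(f"slice manifest is missing columns {sorted(missing)}")
        return slices.reset_index(drop=True)
    return to_manifest(slices)


def split_by_subject(
    slices: pd.DataFrame | Iterable[SliceStack],
    n_train_subjects: int = 17,
    n_test_subjects: int = 8,
    seed: int = 0,
) -> SplitPlan:
    """Partition each class's subjects into train/test; slices follow.

    Every class must contain exactly ``n_train_subjects + n_test_subjects``
    subjects. The subject partition is uniform at random per class, with a
    per-class stream derived from (seed, class), so the draw for one
    diagnosis is unaffected by adding another.
    """
    manifest = _as_manifest(slices)
    train_parts, test_parts, counts = [], [], {}
    for label, grp in manifest.groupby("class_label", sort=True):
        subjects = np.array(sorted(grp["subject_id"].unique()))
        want = n_train_subjects + n_test_subjects
        if len(subjects) != want:
            raise ValueError(
                f"class {label!r}: need exactly {want} subjects "
                f"({n_train_subjects} train + {n_test_subjects} test), found {len(subjects)}"
            )
        perm = derive_rng(seed, "subject-split", label).permutation(len(subjects))
        train_subj = set(subjects[perm[:n_train_subjects]])
        is_train = grp["subject_id"].isin(train_subj)
        train_parts.append(grp[is_train])
        test_parts.append(grp[~is_train])
        counts[label] = {"train": int(is_train.sum()), "test": int((~is_train).sum())}
    return SplitPlan(
        mode="subject",
        seed=seed,
        train=pd.concat(train_parts, ignore_index=True),
        test=pd.concat(test_parts, ignore_index=True),
        class_counts=counts,
    )


def split_by_slice(
    slices: pd.DataFrame | Iterable[SliceStack],
    train_fraction: float = 0.7,
    seed: int = 0,
) -> SplitPlan:
    """Pool each class's slices and split them train_fraction / rest.

    Subjects are ignored, so with more than one slice per subject the two
    sides almost surely share subjects — the leaky strategy. The train
    count is floor(train_fraction * n); the remainder goes to test.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    manifest = _as_manifest(slices)
    train_parts, test_parts, counts = [], [], {}
    for label, grp in manifest.groupby("class_label", sort=True):
        n = len(grp)
        if n < 2:
            raise ValueError(f"class {label!r}: need at least 2 slices to split, found {n}")
        n_train = math.floor(train_fraction * n)
        perm = derive_rng(seed, "slice-split", label).permutation(n)
        rows = grp.iloc[perm]
        train_parts.append(rows.iloc[:n_train])
        test_parts.append(rows.iloc[n_train:])
        counts[label] = {"train": n_train, "test": n - n_train}
    return SplitPlan(
        mode="slice",
        seed=seed,
        train=pd.concat(train_parts, ignore_index=True),
        test=pd.concat(test_parts, ignore_index=True),
        class_counts=counts,
    )


def audit_leakage(plan: SplitPlan) -> LeakageAudit:
    """Flag a plan as leaky iff some subject has slices on both sides."""
    shared = sorted(plan.train_subjects & plan.test_subjects)
    return LeakageAudit(leaky=bool(shared), shared_subjects=shared, shared_count=len(shared))
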