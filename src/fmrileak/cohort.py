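"""Synthetic multi-subject 4D fMRI cohort generation.

The generator emulates the statistical structure of a resting-state BOLD
cohort drawn from a multi-group Alzheimer's imaging study: per diagnostic
group (CN, MCI, EMCI, LMCI, AD) a fixed number of subjects, each with one
or more 4D scans of shape (H, W, D, T). Every voxel time-series is the sum
of

* a global ``baseline`` intensity,
* a *subject fingerprint* — a smooth 3D spatial random field, fixed per
  subject and constant over time, scaled by ``fingerprint_sd``. This is the
  identity signal a classifier can exploit when slices of one subject leak
  across a train/test split;
* a *class pattern* — a smooth 3D field fixed per diagnosis, scaled by
  ``class_effect_sd``. This is the (optional) genuine diagnostic signal;
* i.i.d. Gaussian acquisition noise with standard deviation ``noise_sd``,
  redrawn per voxel, per time point and per scan.

Fingerprint and class patterns are low-pass filtered white noise rather
than voxelwise white noise, so 2D slices inherit spatially coherent
structure — the kind of anatomy-like signal a convolutional network can
latch onto.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._rng import derive_rng

__all__ = [
    "CohortSpec",
    "Volume4D",
    "generate_subject_volume",
    "generate_cohort",
    "iter_cohort_volumes",
    "load_cohort_table",
    "subject_ids",
]

#: first synthetic scan date; scan k of a subject is BASE_DATE + k days
BASE_DATE = _dt.date(2021, 1, 1)

#: smoothing width (voxels) of the spatial random fields
FIELD_SMOOTHING_SIGMA = 2.0

DEFAULT_CLASS_LABELS = ("CN", "MCI", "EMCI", "LMCI", "AD")


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Parameters defining one synthetic cohort.

    Defaults are desk-scale: 24x28x22 voxels x 10 time points. The
    study-scale shapes (99, 117, 95, 197) and (99, 117, 95, 976) are valid
    values but never required by the test suite.
    """

    n_per_class: int = 25
    class_labels: Sequence[str] = DEFAULT_CLASS_LABELS
    volume_shape: tuple[int, int, int, int] = (24, 28, 22, 10)
    fingerprint_sd: float = 1.0
    class_effect_sd: float = 0.0
    noise_sd: float = 0.1
    baseline: float = 100.0
    scans_per_subject: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be a positive integer")
        if len(self.volume_shape) != 4 or any(s < 1 for s in self.volume_shape):
            raise ValueError(f"volume_shape must be 4 positive integers, got {self.volume_shape}")
        if self.fingerprint_sd < 0 or self.class_effect_sd < 0:
            raise ValueError("fingerprint_sd and class_effect_sd must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.scans_per_subject < 1:
            raise ValueError("scans_per_subject must be >= 1")
        if len(set(self.class_labels)) != len(self.class_labels) or not self.class_labels:
            raise ValueError("class_labels must be a non-empty sequence of distinct names")
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        object.__setattr__(self, "volume_shape", tuple(int(s) for s in self.volume_shape))


@dataclasses.dataclass
class Volume4D:
    """One subject-scan: a 4D BOLD array plus identifying metadata."""

    data: np.ndarray
    subject_id: str
    class_label: str
    scan_date: _dt.date

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"volume must be 4-dimensional, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape


def _smooth_field(rng: np.random.Generator, spatial_shape) -> np.ndarray:
    """Unit-variance smooth Gaussian random field over a 3D grid."""
    field = gaussian_filter(rng.standard_normal(spatial_shape), FIELD_SMOOTHING_SIGMA, mode="nearest")
    sd = field.std()
    if sd > 0:
        field = (field - field.mean()) / sd
    return field.astype(np.float32)


def subject_ids(spec: CohortSpec, class_label: str) -> list[str]:
    """The deterministic subject identifiers of one diagnostic group."""
    if class_label not in spec.class_labels:
        raise ValueError(f"unknown class_label {class_label!r}; expected one of {spec.class_labels}")
    return [f"sub-{class_label}-{i:03d}" for i in range(spec.n_per_class)]


def generate_subject_volume(
    spec: CohortSpec,
    subject_id: str,
    class_label: str,
    seed: int | None = None,
    scan_index: int = 0,
) -> Volume4D:
    """Synthesize one 4D scan: baseline + fingerprint + class pattern + noise.

    Deterministic given ``(spec, subject_id, seed, scan_index)``. The noise
    stream depends on the subject and the scan index but *not* on the class
    label, so with ``class_effect_sd == 0`` relabelled cohorts are
    bit-identical (a proper null).
    """
    if class_label not in spec.class_labels:
        raise ValueError(f"unknown class_label {class_label!r}; expected one of {spec.class_labels}")
    if not (0 <= scan_index < spec.scans_per_subject):
        raise ValueError(f"scan_index {scan_index} outside [0, {spec.scans_per_subject})")
    seed = spec.seed if seed is None else int(seed)
    h, w, d, t = spec.volume_shape

    data = np.full((h, w, d, t), np.float32(spec.baseline), dtype=np.float32)
    if spec.fingerprint_sd > 0:
        fp = _smooth_field(derive_rng(seed, "fingerprint", subject_id), (h, w, d))
        data += np.float32(spec.fingerprint_sd) * fp[..., None]
    if spec.class_effect_sd > 0:
        cp = _smooth_field(derive_rng(seed, "class-pattern", class_label), (h, w, d))
        data += np.float32(spec.class_effect_sd) * cp[..., None]
    noise_rng = derive_rng(seed, "noise", subject_id, scan_index)
    data += np.float32(spec.noise_sd) * noise_rng.standard_normal((h, w, d, t)).astype(np.float32)

    return Volume4D(
        data=data,
        subject_id=subject_id,
        class_label=class_label,
        scan_date=BASE_DATE + _dt.timedelta(days=scan_index),
    )


def iter_cohort_volumes(spec: CohortSpec, scan_index: int = 0) -> Iterator[Volume4D]:
    """Yield one in-memory volume per subject (a single scan date each)."""
    for label in spec.class_labels:
        for sid in subject_ids(spec, label):
            yield generate_subject_volume(spec, sid, label, scan_index=scan_index)


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write the full cohort to ``out_dir`` as NIfTI-1 files plus a manifest.

    Returns the cohort table: one row per (subject, scan date) with columns
    ``subject_id, class_label, scan_date, path``; also written as
    ``cohort.csv`` in ``out_dir``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        if not out_dir.is_dir():
            raise OSError(f"{out_dir} is not a directory")
    except OSError as exc:
        raise OSError(f"cohort output directory {out_dir} is not writable: {exc}") from exc

    rows = []
    for label in spec.class_labels:
        for sid in subject_ids(spec, label):
            for k in range(spec.scans_per_subject):
                vol = generate_subject_volume(spec, sid, label, scan_index=k)
                path = out_dir / f"{sid}_scan-{k}.nii.gz"
                nib.save(nib.Nifti1Image(vol.data, affine=np.eye(4)), str(path))
                rows.append(
                    {
                        "subject_id": sid,
                        "class_label": label,
                        "scan_date": vol.scan_date.isoformat(),
                        "path": str(path),
                    }
                )
    table = pd.DataFrame(rows, columns=["subject_id", "class_label", "scan_date", "path"])
    table.to_csv(out_dir / "cohort.csv", index=False)
    return table


def load_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV written by :func:`generate_cohort`."""
    table = pd.read_csv(path, dtype={"subject_id": str, "class_label": str, "scan_date": str})
    required = {"subject_id", "class_label", "scan_date", "path"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table {path} is missing columns {sorted(missing)}")
    return table


def load_volume(row: pd.Series) -> Volume4D:
    """Load one cohort-table row back into a :class:`Volume4D`."""
    img = nib.load(row["path"])
    return Volume4D(
        data=np.asanyarray(img.dataobj),
        subject_id=row["subject_id"],
        class_label=row["class_label"],
        scan_date=_dt.date.fromisoformat(str(row["scan_date"])),
    )
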