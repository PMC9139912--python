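"""Metrics, median aggregation, the leakage gap, and the full experiment.

The experiment contrasts two hold-out strategies on the same synthetic
cohort: for each binary diagnostic problem the pipeline is

    cohort -> earliest-scan dedup -> depth x time slicing -> percentile
    filter -> per-subject sampling -> image prep -> split (subject-level
    or slice-level) -> CNN training -> per-slice prediction -> confusion
    counts -> accuracy / sensitivity / specificity

Per-problem metrics are reported as percentages per slice; medians are
taken across problems within a hold-out mode, and the leakage report
tabulates the per-problem slice-mode minus subject-mode differences
together with the audits of both split plans.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from ._rng import derive_seed
from .classifier import TinyCNNClassifier
from .cohort import (
    BASE_DATE,
    CohortSpec,
    generate_subject_volume,
    load_cohort_table,
    load_volume,
    subject_ids,
)
from .prep import prepare_stack
from .slices import (
    SliceStack,
    extract_slices,
    filter_top_percentile,
    sample_slices,
    select_earliest_scan,
    to_manifest,
)
from .splits import LeakageAudit, SplitPlan, audit_leakage, split_by_slice, split_by_subject

__all__ = [
    "ConfusionMatrix",
    "MetricsRecord",
    "LeakageReport",
    "ExperimentConfig",
    "confusion",
    "metrics",
    "median_metrics",
    "leakage_gap",
    "run_experiment",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity")


@dataclasses.dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass
class MetricsRecord:
    """Accuracy/sensitivity/specificity (%) for one problem and mode.

    Metrics whose denominator is empty (e.g. sensitivity with no positive
    slices in the test set) are NaN and listed in ``undefined`` rather
    than silently coerced to 0 or 100.
    """

    problem: str
    holdout_mode: str
    accuracy: float
    sensitivity: float
    specificity: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "problem": self.problem,
            "mode": self.holdout_mode,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "undefined": list(self.undefined),
        }


@dataclasses.dataclass
class LeakageReport:
    """Per-problem performance gaps (slice mode minus subject mode)."""

    gaps: pd.DataFrame  # columns: problem, accuracy, sensitivity, specificity
    medians: dict  # mode -> {metric: median}
    audits: dict  # mode -> {problem: audit dict}

    def to_dict(self) -> dict:
        return {
            "gaps": self.gaps.to_dict(orient="records"),
            "medians": self.medians,
            "audits": self.audits,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# metric arithmetic
# ---------------------------------------------------------------------------

def confusion(predictions: Sequence, truths: Sequence, positive_class) -> ConfusionMatrix:
    """Exact confusion counts for one binary problem.

    Any label (predicted or true) outside the problem's two-label pair is
    an error; the negative class is the unique non-positive label.
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must have equal length")
    if len(truths) == 0:
        raise ValueError("cannot build a confusion matrix from zero slices")
    labels = set(np.unique(truths)) | set(np.unique(predictions))
    others = labels - {positive_class}
    if positive_class not in labels and len(others) > 1:
        raise ValueError(f"positive class {positive_class!r} absent and labels {labels} ambiguous")
    if len(others) > 1:
        raise ValueError(
            f"labels {sorted(map(str, labels))} do not form a binary pair "
            f"with positive class {positive_class!r}"
        )
    pos_pred = predictions == positive_class
    pos_true = truths == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(pos_pred & pos_true)),
        fp=int(np.sum(pos_pred & ~pos_true)),
        tn=int(np.sum(~pos_pred & ~pos_true)),
        fn=int(np.sum(~pos_pred & pos_true)),
        positive_class=str(positive_class),
    )


def metrics(
    cm: ConfusionMatrix, problem: str = "", holdout_mode: str = ""
) -> MetricsRecord:
    """Accuracy, sensitivity and specificity (in %) from confusion counts."""
    if cm.total <= 0:
        raise ValueError("confusion matrix has zero total count")
    undefined = []
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fn > 0:
        sensitivity = 100.0 * cm.tp / (cm.tp + cm.fn)
    else:
        sensitivity = math.nan
        undefined.append("sensitivity")
    if cm.tn + cm.fp > 0:
        specificity = 100.0 * cm.tn / (cm.tn + cm.fp)
    else:
        specificity = math.nan
        undefined.append("specificity")
    return MetricsRecord(
        problem=problem,
        holdout_mode=holdout_mode,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        undefined=tuple(undefined),
    )


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
        if "mode" not in frame.columns and "holdout_mode" in frame.columns:
            frame = frame.rename(columns={"holdout_mode": "mode"})
        return frame
    return pd.DataFrame([r.as_dict() for r in records])


def median_metrics(records) -> dict:
    """Per-metric medians over problems (midpoint convention for even n).

    ``records`` may be a list of :class:`MetricsRecord` or a DataFrame
    with columns problem/mode/accuracy/sensitivity/specificity; all rows
    must share one hold-out mode.
    """
    frame = _records_frame(records)
    if len(frame) == 0:
        raise ValueError("need at least one metrics record")
    modes = set(frame["mode"])
    if len(modes) != 1:
        raise ValueError(f"records mix hold-out modes {sorted(modes)}; aggregate one mode at a time")
    return {name: float(np.median(frame[name].to_numpy(dtype=float))) for name in METRIC_NAMES}


def leakage_gap(
    subject_records, slice_records, subject_audits: dict | None = None,
    slice_audits: dict | None = None,
) -> LeakageReport:
    """Per-problem, per-metric differences: slice mode minus subject mode."""
    sub = _records_frame(subject_records).set_index("problem")
    sli = _records_frame(slice_records).set_index("problem")
    if list(sub.index) != list(sli.index):
        raise ValueError(
            f"problem lists differ between modes: {list(sub.index)} vs {list(sli.index)}"
        )
    gaps = pd.DataFrame({"problem": sub.index})
    for name in METRIC_NAMES:
        gaps[name] = (sli[name].to_numpy(dtype=float) - sub[name].to_numpy(dtype=float))
    return LeakageReport(
        gaps=gaps,
        medians={"subject": median_metrics(sub.reset_index().assign(mode="subject")),
                 "slice": median_metrics(sli.reset_index().assign(mode="slice"))},
        audits={"subject": subject_audits or {}, "slice": slice_audits or {}},
    )


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExperimentConfig:
    """Everything needed to run the two-mode experiment deterministically.

    Defaults are the calibrated desk-scale leakage demonstration: 10
    subjects per class, 24x28x22x10 volumes, a pure subject fingerprint
    (no class effect), 40 slices per subject after a 70th-percentile
    filter, a 5/5 subject hold-out versus a 70/30 slice hold-out, and a
    tinycnn trained for 12 epochs at learning rate 1e-3 with batch 32.
    Because all slices of a subject share one fingerprint, the test side
    carries subject-level (not slice-level) information, so the split
    assigns as many subjects to test as to train.
    """

    cohort: CohortSpec = dataclasses.field(
        default_factory=lambda: CohortSpec(
            n_per_class=10,
            class_labels=("CN", "AD"),
            volume_shape=(24, 28, 22, 10),
            fingerprint_sd=1.0,
            class_effect_sd=0.0,
            noise_sd=0.1,
        )
    )
    cohort_dir: str | None = None  # if set, load NIfTI cohort instead of in-memory
    problems: tuple = (("CN", "AD"),)
    percentile: float = 70.0
    n_sample: int = 40
    allow_replacement: bool = False
    n_train_subjects: int = 5
    n_test_subjects: int = 5
    train_fraction: float = 0.7
    target_size: int = 32
    dropout: float = 0.2
    batch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 12
    seed: int = 0
    positive_class: str = "second"  # "second" (default convention) | "first"

    def __post_init__(self):
        self.problems = tuple(tuple(p) for p in self.problems)
        for a, b in self.problems:
            for lab in (a, b):
                if lab not in self.cohort.class_labels:
                    raise ValueError(f"problem label {lab!r} not in cohort classes")
        if self.positive_class not in ("first", "second"):
            raise ValueError("positive_class must be 'first' or 'second'")

    def positive_of(self, problem: tuple[str, str]) -> str:
        return problem[1] if self.positive_class == "second" else problem[0]

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        payload["cohort"] = dataclasses.asdict(self.cohort)
        payload["cohort"]["class_labels"] = list(self.cohort.class_labels)
        payload["cohort"]["volume_shape"] = list(self.cohort.volume_shape)
        payload["problems"] = [list(p) for p in self.problems]
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "cohort" in payload:
            payload["cohort"] = CohortSpec(**payload["cohort"])
        if "problems" in payload:
            payload["problems"] = tuple(tuple(p) for p in payload["problems"])
        return cls(**payload)


@dataclasses.dataclass
class ExperimentResult:
    results: pd.DataFrame  # problem x mode metric rows
    report: LeakageReport
    records: dict  # mode -> list[MetricsRecord]


def _iter_volumes(config: ExperimentConfig):
    """Deduplicated (earliest-scan) volumes for every subject in play."""
    needed = sorted({lab for pair in config.problems for lab in pair})
    spec = config.cohort
    if config.cohort_dir is not None:
        table = load_cohort_table(Path(config.cohort_dir) / "cohort.csv")
        table = table[table["class_label"].isin(needed)]
        table = select_earliest_scan(table)
        volumes = (load_volume(row) for _, row in table.iterrows())
    else:
        # synthesize the scan table (scans_per_subject dates per subject),
        # dedup to the earliest, then generate only the surviving scans
        rows = []
        for lab in needed:
            for sid in subject_ids(spec, lab):
                for k in range(spec.scans_per_subject):
                    rows.append(
                        {
                            "subject_id": sid,
                            "class_label": lab,
                            "scan_date": (BASE_DATE + _dt.timedelta(days=k)).isoformat(),
                            "scan_index": k,
                        }
                    )
        table = select_earliest_scan(pd.DataFrame(rows))
        volumes = (
            generate_subject_volume(
                spec, row["subject_id"], row["class_label"], scan_index=int(row["scan_index"])
            )
            for _, row in table.iterrows()
        )
    yield from volumes


def _build_stacks(config: ExperimentConfig) -> list[SliceStack]:
    """Run dedup -> slice -> filter -> sample for every needed subject."""
    stacks = []
    for vol in _iter_volumes(config):
        stack = extract_slices(vol)
        stack = filter_top_percentile(stack, config.percentile)
        stack = sample_slices(
            stack, config.n_sample, seed=config.seed, allow_replacement=config.allow_replacement
        )
        stacks.append(stack)
    return stacks


def _evaluate_mode(
    config: ExperimentConfig,
    mode: str,
    problem: tuple[str, str],
    manifest: pd.DataFrame,
    X_all: np.ndarray,
) -> tuple[MetricsRecord, LeakageAudit]:
    pair_manifest = manifest[manifest["class_label"].isin(problem)].reset_index(drop=True)
    split_seed = derive_seed(config.seed, "split", mode, *problem) % (2**31)
    if mode == "subject":
        plan = split_by_subject(
            pair_manifest,
            n_train_subjects=config.n_train_subjects,
            n_test_subjects=config.n_test_subjects,
            seed=split_seed,
        )
    else:
        plan = split_by_slice(pair_manifest, train_fraction=config.train_fraction, seed=split_seed)
    audit = audit_leakage(plan)

    model = TinyCNNClassifier(
        dropout=config.dropout,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        seed=derive_seed(config.seed, "train", mode, *problem) % (2**31),
    )
    X_train = X_all[plan.train["row"].to_numpy()]
    y_train = plan.train["class_label"].to_numpy()
    X_test = X_all[plan.test["row"].to_numpy()]
    y_test = plan.test["class_label"].to_numpy()
    model.fit(X_train, y_train)
    preds = model.predict(X_test)

    name = f"{problem[0]} vs. {problem[1]}"
    cm = confusion(preds, y_test, config.positive_of(problem))
    record = metrics(cm, problem=name, holdout_mode=mode)
    logger.info(
        "%s [%s]: accuracy=%.2f sensitivity=%.2f specificity=%.2f (leaky=%s)",
        name, mode, record.accuracy, record.sensitivity, record.specificity, audit.leaky,
    )
    return record, audit


def run_experiment(config: ExperimentConfig, outdir: str | Path | None = None) -> ExperimentResult:
    """Run every problem under both hold-out modes and report the gap.

    Fully deterministic given the config (its seed feeds cohort synthesis,
    sampling, both splitters and training). If ``outdir`` is given, writes
    ``results.csv``, ``leakage_report.json`` and ``results.md``.
    """
    stacks = _build_stacks(config)
    manifest = to_manifest(stacks)
    manifest["row"] = np.arange(len(manifest))
    X_all = np.concatenate([prepare_stack(s, config.target_size) for s in stacks], axis=0)

    records: dict[str, list[MetricsRecord]] = {"subject": [], "slice": []}
    audits: dict[str, dict] = {"subject": {}, "slice": {}}
    for problem in config.problems:
        for mode in ("subject", "slice"):
            record, audit = _evaluate_mode(config, mode, problem, manifest, X_all)
            records[mode].append(record)
            audits[mode][record.problem] = audit.to_dict()

    report = leakage_gap(records["subject"], records["slice"], audits["subject"], audits["slice"])
    results = pd.concat(
        [_records_frame(records["subject"]), _records_frame(records["slice"])],
        ignore_index=True,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rounded = results.copy()
        for name in METRIC_NAMES:
            rounded[name] = rounded[name].round(2)
        rounded.to_csv(outdir / "results.csv", index=False)
        report.to_json(outdir / "leakage_report.json")
        (outdir / "results.md").write_text(_markdown_table(results, report))
    return ExperimentResult(results=results, report=report, records=records)


def _markdown_table(results: pd.DataFrame, report: LeakageReport) -> str:
    """Two-panel markdown summary: per-problem metrics plus median rows."""
    lines = [
        "| Binary classes | Subject hold-out acc/sens/spec (%) | Slice hold-out acc/sens/spec (%) |",
        "| --- | --- | --- |",
    ]
    sub = results[results["mode"] == "subject"].set_index("problem")
    sli = results[results["mode"] == "slice"].set_index("problem")
    for problem in sub.index:
        s, l = sub.loc[problem], sli.loc[problem]
        lines.append(
            f"| {problem} | {s['accuracy']:.2f} / {s['sensitivity']:.2f} / {s['specificity']:.2f} "
            f"| {l['accuracy']:.2f} / {l['sensitivity']:.2f} / {l['specificity']:.2f} |"
        )
    med_s, med_l = report.medians["subject"], report.medians["slice"]
    lines.append(
        f"| **median** | {med_s['accuracy']:.2f} / {med_s['sensitivity']:.2f} / {med_s['specificity']:.2f} "
        f"| {med_l['accuracy']:.2f} / {med_l['sensitivity']:.2f} / {med_l['specificity']:.2f} |"
    )
    return "\n".join(lines) + "\n"
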