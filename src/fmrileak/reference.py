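"""Reported benchmark metrics for the seven binary diagnostic problems.

These are the published test-set results of a ResNet-18 slice classifier
fine-tuned on ADNI-3 resting-state fMRI under the two hold-out strategies
this package contrasts: splitting by subject (brain hold-out, valid) and
splitting by slice (slice hold-out, leaky). They serve as reference input
for the aggregation layer — e.g. checking that median aggregation over the
seven problems reproduces the reported medians — and as the canonical
problem list for experiment configs. They are *data*, not something this
package recomputes: reproducing them would require the access-restricted
cohort and GPU-scale fine-tuning.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["BINARY_PROBLEMS", "REPORTED_METRICS", "reported_metrics"]

#: the seven binary diagnostic problems, as (first, second) label pairs
BINARY_PROBLEMS: tuple[tuple[str, str], ...] = (
    ("EMCI", "LMCI"),
    ("AD", "CN"),
    ("CN", "EMCI"),
    ("CN", "LMCI"),
    ("EMCI", "AD"),
    ("LMCI", "AD"),
    ("MCI", "EMCI"),
)

# (problem, mode) -> accuracy %, sensitivity %, specificity %
_ROWS = [
    ("EMCI vs. LMCI", "subject", 53.08, 23.96, 42.78),
    ("AD vs. CN", "subject", 48.53, 23.20, 33.00),
    ("CN vs. EMCI", "subject", 40.04, 25.14, 20.07),
    ("CN vs. LMCI", "subject", 56.97, 27.17, 40.54),
    ("EMCI vs. AD", "subject", 45.24, 28.00, 24.26),
    ("LMCI vs. AD", "subject", 44.12, 2.62, 52.56),
    ("MCI vs. EMCI", "subject", 46.22, 27.51, 23.76),
    ("EMCI vs. LMCI", "slice", 83.90, 79.39, 88.47),
    ("AD vs. CN", "slice", 73.18, 48.21, 98.16),
    ("CN vs. EMCI", "slice", 86.90, 85.75, 88.00),
    ("CN vs. LMCI", "slice", 84.12, 75.18, 93.07),
    ("EMCI vs. AD", "slice", 79.55, 82.36, 76.74),
    ("LMCI vs. AD", "slice", 84.58, 95.69, 73.48),
    ("MCI vs. EMCI", "slice", 89.86, 86.43, 93.33),
]

REPORTED_METRICS = pd.DataFrame(
    _ROWS, columns=["problem", "mode", "accuracy", "sensitivity", "specificity"]
)


def reported_metrics(mode: str | None = None) -> pd.DataFrame:
    """The reported per-problem metrics, optionally filtered by hold-out mode."""
    if mode is None:
        return REPORTED_METRICS.copy()
    if mode not in ("subject", "slice"):
        raise ValueError(f"mode must be 'subject' or 'slice', got {mode!r}")
    return REPORTED_METRICS[REPORTED_METRICS["mode"] == mode].reset_index(drop=True)
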