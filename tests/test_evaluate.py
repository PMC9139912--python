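"""Metric arithmetic, median aggregation, leakage gap, experiment driver."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmrileak import (
    CohortSpec,
    ExperimentConfig,
    confusion,
    leakage_gap,
    median_metrics,
    metrics,
    reported_metrics,
    run_experiment,
)


def _brute_force_tally(preds, truths, pos):
    tp = fp = tn = fn = 0
    for p, t in zip(preds, truths):
        if p == pos and t == pos:
            tp += 1
        elif p == pos:
            fp += 1
        elif t == pos:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


class TestConfusion:
    def test_perfect_classifier(self):
        cm = confusion(["a"] * 5 + ["b"] * 5, ["a"] * 5 + ["b"] * 5, positive_class="a")
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (5, 5, 0, 0)

    def test_anti_classifier(self):
        cm = confusion(["b"] * 5 + ["a"] * 5, ["a"] * 5 + ["b"] * 5, positive_class="a")
        assert cm.tp == 0 and cm.tn == 0 and cm.fp == 5 and cm.fn == 5

    def test_label_outside_pair_rejected(self):
        with pytest.raises(ValueError, match="binary pair"):
            confusion(["a", "c"], ["a", "b"], positive_class="a")

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from("ab"), st.sampled_from("ab")), min_size=1, max_size=30))
    def test_counts_match_brute_force_tally(self, pairs):
        preds, truths = zip(*pairs)
        cm = confusion(list(preds), list(truths), positive_class="a")
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == _brute_force_tally(preds, truths, "a")
        assert cm.total == len(pairs)


class TestMetrics:
    def test_perfect_case(self):
        cm = confusion(["a"] * 5 + ["b"] * 5, ["a"] * 5 + ["b"] * 5, positive_class="a")
        rec = metrics(cm)
        assert (rec.accuracy, rec.sensitivity, rec.specificity) == (100.0, 100.0, 100.0)

    def test_hand_arithmetic(self):
        # tp=1, fn=3, tn=2, fp=2
        preds = ["a", "b", "b", "b", "a", "a", "b", "b"]
        truths = ["a", "a", "a", "a", "b", "b", "b", "b"]
        rec = metrics(confusion(preds, truths, positive_class="a"))
        assert rec.accuracy == pytest.approx(37.5)
        assert rec.sensitivity == pytest.approx(25.0)
        assert rec.specificity == pytest.approx(50.0)

    def test_degenerate_denominator_flagged_not_coerced(self):
        rec = metrics(confusion(["a", "b"], ["b", "b"], positive_class="a"))
        assert math.isnan(rec.sensitivity)
        assert rec.undefined == ("sensitivity",)
        assert rec.accuracy == pytest.approx(50.0)


class TestMedianMetrics:
    def test_reported_subject_mode_medians_reproduced_exactly(self):
        med = median_metrics(reported_metrics("subject"))
        assert med == {"accuracy": 46.22, "sensitivity": 25.14, "specificity": 33.00}

    def test_reported_slice_mode_medians_reproduced_exactly(self):
        med = median_metrics(reported_metrics("slice"))
        assert med == {"accuracy": 84.12, "sensitivity": 82.36, "specificity": 88.47}

    def test_single_record_is_its_own_median(self):
        one = reported_metrics("subject").iloc[:1]
        med = median_metrics(one)
        assert med["accuracy"] == one["accuracy"].iloc[0]

    def test_even_count_uses_midpoint(self):
        frame = pd.DataFrame(
            {
                "problem": ["p1", "p2"],
                "mode": ["subject", "subject"],
                "accuracy": [40.0, 60.0],
                "sensitivity": [10.0, 30.0],
                "specificity": [0.0, 100.0],
            }
        )
        assert median_metrics(frame) == {
            "accuracy": 50.0,
            "sensitivity": 20.0,
            "specificity": 50.0,
        }

    def test_mixed_modes_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            median_metrics(reported_metrics())


class TestLeakageGap:
    def test_reported_gaps_match_cell_subtraction(self):
        rep = leakage_gap(reported_metrics("subject"), reported_metrics("slice"))
        gaps = rep.gaps.set_index("problem")
        assert gaps.loc["MCI vs. EMCI", "accuracy"] == pytest.approx(89.86 - 46.22)
        assert gaps.loc["LMCI vs. AD", "sensitivity"] == pytest.approx(95.69 - 2.62)

    def test_identical_records_give_zero_gaps(self):
        sub = reported_metrics("subject")
        rep = leakage_gap(sub, sub.assign(mode="slice"))
        assert np.allclose(rep.gaps[["accuracy", "sensitivity", "specificity"]], 0.0)

    def test_mismatched_problem_lists_rejected(self):
        with pytest.raises(ValueError, match="problem lists differ"):
            leakage_gap(reported_metrics("subject").iloc[:3], reported_metrics("slice").iloc[3:])


def _fast_config(**overrides):
    base = dict(
        cohort=CohortSpec(
            n_per_class=6,
            class_labels=("CN", "AD"),
            volume_shape=(16, 16, 8, 5),
            fingerprint_sd=1.0,
            class_effect_sd=0.0,
            noise_sd=0.1,
        ),
        problems=(("CN", "AD"),),
        percentile=50.0,
        n_sample=16,
        n_train_subjects=3,
        n_test_subjects=3,
        target_size=16,
        epochs=8,
        batch_size=16,
        seed=0,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


class TestRunExperiment:
    def test_zero_epoch_smoke_run_emits_full_table(self, tmp_path):
        result = run_experiment(_fast_config(epochs=0), outdir=tmp_path)
        assert len(result.results) == 2  # one problem x two modes
        assert set(result.results["mode"]) == {"subject", "slice"}
        assert (tmp_path / "results.csv").exists()
        assert (tmp_path / "leakage_report.json").exists()
        assert (tmp_path / "results.md").exists()

    def test_subject_plans_clean_slice_plans_leaky(self):
        result = run_experiment(_fast_config(epochs=0))
        audits = result.report.audits
        assert not audits["subject"]["CN vs. AD"]["leaky"]
        assert audits["slice"]["CN vs. AD"]["leaky"]

    def test_deterministic_given_config(self):
        a = run_experiment(_fast_config(epochs=2))
        b = run_experiment(_fast_config(epochs=2))
        pd.testing.assert_frame_equal(a.results, b.results)

    def test_null_cohort_both_modes_near_chance(self):
        """No fingerprint, no class effect: accuracy ~50% in both modes."""
        cfg = _fast_config(
            cohort=CohortSpec(
                n_per_class=6,
                class_labels=("CN", "AD"),
                volume_shape=(16, 16, 8, 5),
                fingerprint_sd=0.0,
                class_effect_sd=0.0,
                noise_sd=1.0,
            ),
            seed=1,
        )
        result = run_experiment(cfg)
        # test-set sizes: subject mode 2x3x16=96 slices; slice mode 2x29=58
        n_test = {"subject": 96, "slice": 58}
        for _, row in result.results.iterrows():
            halfwidth = 100 * 1.96 * np.sqrt(0.25 / n_test[row["mode"]])
            assert abs(row["accuracy"] - 50.0) < halfwidth

    def test_genuine_class_signal_survives_subject_holdout(self):
        """Strong class effect, no fingerprint: both modes succeed."""
        cfg = _fast_config(
            cohort=CohortSpec(
                n_per_class=6,
                class_labels=("CN", "AD"),
                volume_shape=(16, 16, 8, 5),
                fingerprint_sd=0.0,
                class_effect_sd=1.5,
                noise_sd=0.1,
            ),
            epochs=10,
            seed=2,
        )
        result = run_experiment(cfg)
        for _, row in result.results.iterrows():
            assert row["accuracy"] >= 90.0

    def test_leakage_gap_grows_with_fingerprint_strength(self):
        """Mean accuracy gap is monotone over fingerprint levels (trend)."""
        from scipy.stats import spearmanr

        levels = [0.0, 0.5, 2.0]
        pairs = []
        for fp in levels:
            for seed in range(5):
                cfg = _fast_config(
                    cohort=CohortSpec(
                        n_per_class=6,
                        class_labels=("CN", "AD"),
                        volume_shape=(16, 16, 8, 5),
                        fingerprint_sd=fp,
                        class_effect_sd=0.0,
                        noise_sd=0.5,
                    ),
                    seed=seed,
                )
                pairs.append((fp, float(run_experiment(cfg).report.gaps["accuracy"].iloc[0])))
        frame = pd.DataFrame(pairs, columns=["level", "gap"])
        mean_gaps = frame.groupby("level")["gap"].mean()
        assert mean_gaps[levels[0]] < mean_gaps[levels[-1]]
        rho, _ = spearmanr(frame["level"], frame["gap"])
        assert rho > 0
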