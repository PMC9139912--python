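"""Slice extraction, earliest-scan dedup, percentile filter, sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmrileak import (
    SliceStack,
    extract_slices,
    filter_top_percentile,
    n_slices,
    retained_mask,
    sample_slices,
    select_earliest_scan,
)


def _stack_from_means(means):
    """A minimal stack whose slice means are exactly `means`."""
    means = np.asarray(means, dtype=float)
    n = len(means)
    return SliceStack(
        subject_id="s0",
        class_label="CN",
        pixels=np.repeat(means, 4).reshape(n, 2, 2),
        depth_index=np.arange(n),
        time_index=np.zeros(n, dtype=int),
        mean_signal=means,
    )


def _percentile_oracle(means, p):
    """Brute-force sort-and-threshold: linear interpolation of order stats."""
    s = np.sort(np.asarray(means, dtype=float))
    n = len(s)
    pos = p / 100.0 * (n - 1)
    lo = int(np.floor(pos))
    frac = pos - lo
    thr = s[lo] if lo == n - 1 else s[lo] + frac * (s[lo + 1] - s[lo])
    return np.asarray(means) >= thr


class TestSelectEarliestScan:
    def test_minimum_of_two_dates(self):
        t = pd.DataFrame(
            {
                "subject_id": ["A", "A"],
                "class_label": ["CN", "CN"],
                "scan_date": ["2018-01-05", "2017-03-01"],
            }
        )
        out = select_earliest_scan(t)
        assert len(out) == 1 and out.iloc[0]["scan_date"] == "2017-03-01"

    def test_single_scan_identity(self):
        t = pd.DataFrame(
            {
                "subject_id": ["A", "B"],
                "class_label": ["CN", "AD"],
                "scan_date": ["2020-01-01", "2020-06-01"],
            }
        )
        out = select_earliest_scan(t)
        assert out[["subject_id", "scan_date"]].to_dict("records") == t[
            ["subject_id", "scan_date"]
        ].to_dict("records")

    def test_matches_brute_force_minimum_per_subject(self, rng):
        dates = [f"20{10 + d}-0{m}-01" for d in range(3) for m in (1, 5, 9)]
        rows = [
            {"subject_id": s, "class_label": "CN", "scan_date": d}
            for s, ds in zip("ABC", np.array(dates).reshape(3, 3))
            for d in ds
        ]
        shuffled = pd.DataFrame(rows).sample(frac=1, random_state=4)
        out = select_earliest_scan(shuffled)
        expected = {s: min(g["scan_date"]) for s, g in pd.DataFrame(rows).groupby("subject_id")}
        assert dict(zip(out["subject_id"], out["scan_date"])) == expected

    def test_order_independence(self):
        rows = pd.DataFrame(
            {
                "subject_id": ["B", "A", "B", "A"],
                "class_label": ["AD", "CN", "AD", "CN"],
                "scan_date": ["2020-02-01", "2020-03-01", "2020-01-01", "2020-01-15"],
            }
        )
        out1 = select_earliest_scan(rows)
        out2 = select_earliest_scan(rows.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(out1, out2)

    def test_duplicate_subject_date_rejected(self):
        t = pd.DataFrame(
            {
                "subject_id": ["A", "A"],
                "class_label": ["CN", "CN"],
                "scan_date": ["2020-01-01", "2020-01-01"],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            select_earliest_scan(t)


class TestExtractSlices:
    @pytest.mark.parametrize(
        "shape,expected",
        [
            ((99, 117, 95, 197), 18715),
            ((99, 117, 95, 976), 92720),
            ((6, 6, 4, 5), 20),
        ],
    )
    def test_slice_count_arithmetic(self, shape, expected):
        assert n_slices(shape) == expected

    def test_extraction_yields_d_times_t_slices(self, tiny_volume, tiny_stack):
        h, w, d, t = tiny_volume.shape
        assert len(tiny_stack) == d * t
        assert tiny_stack.pixels.shape == (d * t, h, w)

    def test_slice_content_and_mean(self, tiny_volume, tiny_stack):
        s = tiny_stack[7]
        np.testing.assert_array_equal(
            s.pixels, tiny_volume.data[:, :, s.depth_index, s.time_index]
        )
        assert s.mean_signal == pytest.approx(s.pixels.mean())

    def test_reassembly_reconstructs_volume_exactly(self, tiny_volume, tiny_stack):
        h, w, d, t = tiny_volume.shape
        rebuilt = np.empty_like(tiny_volume.data)
        for i in range(len(tiny_stack)):
            rebuilt[:, :, tiny_stack.depth_index[i], tiny_stack.time_index[i]] = (
                tiny_stack.pixels[i]
            )
        np.testing.assert_array_equal(rebuilt, tiny_volume.data)


class TestFilterTopPercentile:
    def test_distinct_means_top_two_of_twenty(self):
        stack = _stack_from_means(np.arange(1, 21))
        kept = filter_top_percentile(stack, 90)
        assert sorted(kept.mean_signal) == [19, 20]

    def test_identical_means_all_tie_and_survive(self):
        stack = _stack_from_means(np.full(15, 3.0))
        assert len(filter_top_percentile(stack, 90)) == 15

    def test_preserves_original_ordering(self, rng):
        stack = _stack_from_means(rng.normal(size=50))
        kept = filter_top_percentile(stack, 60)
        assert list(kept.depth_index) == sorted(kept.depth_index)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            filter_top_percentile(_stack_from_means(np.array([])), 90)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        means=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=1, max_size=80
        ),
        p=st.floats(min_value=1, max_value=99),
    )
    def test_matches_sort_and_threshold_oracle(self, means, p):
        mask = retained_mask(np.array(means), p)
        np.testing.assert_array_equal(mask, _percentile_oracle(means, p))
        # retention bound: at least the nominal fraction survives
        assert mask.sum() >= int(np.floor(len(means) * (100 - p) / 100))
        assert mask.sum() >= 1


class TestSampleSlices:
    def test_exhaustive_sample_is_a_permutation(self, tiny_stack):
        out = sample_slices(tiny_stack, len(tiny_stack), seed=0)
        assert sorted(zip(out.depth_index, out.time_index)) == sorted(
            zip(tiny_stack.depth_index, tiny_stack.time_index)
        )

    def test_deterministic_and_distinct(self, tiny_stack):
        a = sample_slices(tiny_stack, 10, seed=42)
        b = sample_slices(tiny_stack, 10, seed=42)
        ids = list(zip(a.depth_index, a.time_index))
        assert ids == list(zip(b.depth_index, b.time_index))
        assert len(set(ids)) == 10

    def test_empty_sample(self, tiny_stack):
        assert len(sample_slices(tiny_stack, 0, seed=0)) == 0

    def test_oversampling_rejected_without_flag(self, tiny_stack):
        with pytest.raises(ValueError, match="sub-CN-000"):
            sample_slices(tiny_stack, len(tiny_stack) + 1, seed=0)

    def test_oversampling_with_replacement_flag(self, tiny_stack):
        out = sample_slices(tiny_stack, len(tiny_stack) + 5, seed=0, allow_replacement=True)
        assert len(out) == len(tiny_stack) + 5
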