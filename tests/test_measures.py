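"""Fixation-duration measures, filtering protocols, and Eq-style partitioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctdreg.measures import (
    FilterConfig,
    Fixation,
    apply_filters,
    assign_partition,
    assign_partitions,
    first_pass_durations,
    go_past_durations,
    scan_path_durations,
)


def path(*region_dur):
    """Contiguous fixations from (region, duration_ms) pairs."""
    t = 0.0
    out = []
    for region, dur in region_dur:
        out.append(Fixation(region, t, t + dur / 1000.0))
        t += dur / 1000.0
    return out


# ---------------------------------------------------------------------------
# scan path


def assert_visits(got, want):
    assert [r for r, _ in got] == [r for r, _ in want]
    assert [d for _, d in got] == pytest.approx([d for _, d in want])



def test_scan_path_monotone():
    p = path((1, 200), (2, 200), (3, 200))
    assert_visits(scan_path_durations(p), [(1, 200.0), (2, 200.0), (3, 200.0)])


def test_scan_path_regression_yields_three_visits():
    p = path((2, 200), (1, 150), (2, 100))
    assert_visits(scan_path_durations(p), [(2, 200.0), (1, 150.0), (2, 100.0)])


def test_scan_path_merges_same_region_refixations():
    p = path((2, 120), (2, 80), (3, 100))
    assert_visits(scan_path_durations(p), [(2, 200.0), (3, 100.0)])


def test_scan_path_empty():
    assert scan_path_durations([]) == []


# ---------------------------------------------------------------------------
# first pass


def test_first_pass_equals_scan_path_on_monotone_path():
    p = path((1, 200), (2, 150), (3, 100))
    assert first_pass_durations(p) == scan_path_durations(p)


def test_first_pass_excludes_rightward_entry():
    # region 2 is entered from region 3 (the right): no first-pass duration
    p = path((1, 200), (3, 150), (2, 100), (4, 50))
    assert [r for r, _ in first_pass_durations(p)] == [1, 3, 4]


def test_first_pass_excludes_revisits():
    p = path((1, 200), (2, 150), (1, 100), (2, 50))
    assert_visits(first_pass_durations(p), [(1, 200.0), (2, 150.0)])


# ---------------------------------------------------------------------------
# go past


def test_go_past_includes_regression_time():
    # enter 2, regress to 1, then reach 3: go-past(2) spans the regression
    p = path((1, 200), (2, 150), (1, 100), (3, 80))
    gp = dict(go_past_durations(p))
    assert gp[1] == 200.0
    assert gp[2] == pytest.approx(250.0)


def test_go_past_equals_first_pass_on_monotone_path():
    p = path((1, 200), (2, 150), (3, 100))
    # the final region never gets a rightward exit: unresolved
    gp, unresolved = go_past_durations(p, return_unresolved=True)
    assert_visits(gp, [(1, 200.0), (2, 150.0)])
    assert unresolved == [3]
    fp = dict(first_pass_durations(p))
    for region, dur in gp:
        assert dur == fp[region]


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 5), st.integers(50, 400)), min_size=1, max_size=12))
def test_go_past_never_below_first_pass(seq):
    p = path(*seq)
    fp = dict(first_pass_durations(p))
    gp = dict(go_past_durations(p))
    for region, dur in gp.items():
        assert region in fp
        assert dur >= fp[region] - 1e-9


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 6), min_size=1, max_size=10, unique=True))
def test_measures_coincide_without_regressions(regions):
    seq = [(r, 100) for r in sorted(regions)]
    p = path(*seq)
    sp = scan_path_durations(p)
    assert first_pass_durations(p) == sp
    gp = dict(go_past_durations(p))
    for region, dur in sp[:-1]:
        assert gp[region] == pytest.approx(dur)


def test_overlapping_fixations_rejected():
    with pytest.raises(ValueError):
        scan_path_durations([Fixation(1, 0.0, 0.3), Fixation(2, 0.2, 0.4)])
    with pytest.raises(ValueError):
        Fixation(1, 0.5, 0.5)


# ---------------------------------------------------------------------------
# filters


def _responses(durs, participants=None):
    n = len(durs)
    return pd.DataFrame(
        {
            "participant_id": participants if participants is not None else [0] * n,
            "duration_ms": durs,
        }
    )


def test_rt_bounds_keep_middle_value():
    # self-paced-reading bounds: drop < 100 ms and > 3000 ms
    kept, log = apply_filters(_responses([50.0, 500.0, 3500.0]), FilterConfig())
    assert kept["duration_ms"].tolist() == [500.0]
    assert log["counts"] == {"rt_too_short": 1, "rt_too_long": 1}


def test_low_accuracy_excludes_whole_participant():
    df = _responses([500.0] * 4 + [600.0] * 4, [0] * 4 + [1] * 4)
    meta = pd.DataFrame({"accuracy": [4 / 8] * 4 + [8 / 8] * 4})
    cfg = FilterConfig(min_accuracy=5 / 8)
    kept, log = apply_filters(df, cfg, meta)
    assert set(kept["participant_id"]) == {1}
    assert log["counts"]["low_accuracy"] == 4


def test_min_rts_counts_post_item_filters():
    # participant 0 has 3 responses but one fails the RT bound, leaving 2 < 3
    df = _responses([500.0, 50.0, 700.0, 500.0, 600.0, 650.0], [0, 0, 0, 1, 1, 1])
    cfg = FilterConfig(min_rts_per_participant=3)
    kept, log = apply_filters(df, cfg)
    assert set(kept["participant_id"]) == {1}
    assert log["counts"] == {"rt_too_short": 1, "too_few_rts": 2}


def test_disabled_filters_are_identity():
    df = _responses([10.0, 5000.0])
    cfg = FilterConfig(rt_min=None, rt_max=None)
    kept, log = apply_filters(df, cfg)
    assert len(kept) == 2
    assert log["counts"] == {}


def test_missing_metadata_names_the_rule():
    with pytest.raises(ValueError, match="blink"):
        apply_filters(_responses([500.0]), FilterConfig(exclude_blinks=True))


def test_each_exclusion_attributed_to_first_rule():
    # a response that is both blink-interrupted and out of bounds counts as blink
    df = _responses([50.0])
    meta = pd.DataFrame({"blink_flag": [True]})
    kept, log = apply_filters(df, FilterConfig(exclude_blinks=True), meta)
    assert log["counts"] == {"blink": 1}


# ---------------------------------------------------------------------------
# partitioning


@pytest.mark.parametrize(
    "p,s,split",
    [(0, 0, "train"), (1, 0, "train"), (1, 1, "validation"), (3, 0, "test"), (2, 2, "train")],
)
def test_partition_examples(p, s, split):
    label = assign_partition(p, s)
    assert label.value == split
    assert label.split_index == (p + s) % 4


def test_partition_rejects_negative_indices():
    with pytest.raises(ValueError):
        assign_partition(-1, 0)
    with pytest.raises(ValueError):
        assign_partition(0, -2)


def test_partition_fractions_on_complete_grid():
    grid = pd.DataFrame(
        [(p, s) for p in range(8) for s in range(12)],
        columns=["participant_id", "sentence_index"],
    )
    out = assign_partitions(grid)
    frac = out["split"].value_counts(normalize=True)
    assert frac["train"] == 0.5
    assert frac["validation"] == 0.25
    assert frac["test"] == 0.25
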