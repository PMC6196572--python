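"""Coverage filtering and the >=30-point differential-methylation rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methclust.dm_calling import (
    FilterPolicy,
    apply_filter,
    call_dm,
    calls_to_frame,
    frame_to_calls,
    summarize_dm,
)
from methclust.errors import ContractError

from conftest import make_count_table, make_fraction_table, random_count_table


# ---------------------------------------------------------------- filtering

def test_drop_site_removes_low_coverage_site():
    """One sample below 10 reads removes the whole site under drop_site."""
    t = make_count_table(
        ["chr1", "chr1"], [100, 200],
        meth=[[3, 2, 10], [5, 5, 5]],
        total=[[12, 9, 30], [20, 20, 20]],
        groups={"s1": "A", "s2": "A", "s3": "B"},
    )
    out = apply_filter(t, FilterPolicy(mode="drop_site", min_reads=10))
    assert list(out.pos) == [200]


def test_drop_sample_masks_and_keeps():
    """Low-coverage samples are masked; group means use survivors only."""
    t = make_count_table(
        ["chr1"], [100],
        meth=[[6, 3, 10, 10]],
        total=[[12, 9, 15, 20]],
        groups={"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
    )
    out = apply_filter(t, FilterPolicy(mode="drop_sample", min_reads=10))
    assert out.n_sites == 1
    assert np.isnan(out.total[0, 1])  # s2 masked
    calls, _ = call_dm(out, threshold_points=0.0001)
    assert calls[0].n_a == 1  # mean_a from s1 only
    assert calls[0].mean_a == pytest.approx(50.0)  # 6/12, not averaged with s2


def test_drop_sample_requires_group_survivors():
    t = make_count_table(
        ["chr1"], [100],
        meth=[[2, 3, 5, 5]],
        total=[[4, 6, 30, 30]],  # all of group A under 10
        groups={"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
    )
    out = apply_filter(t, FilterPolicy(mode="drop_sample", min_reads=10))
    assert out.n_sites == 0


def test_min_reads_one_is_identity():
    rng = np.random.default_rng(0)
    t = random_count_table(rng, n_sites=20)
    t.total[:] = np.maximum(t.total, 1)
    t.meth[:] = np.minimum(t.meth, t.total)
    out = apply_filter(t, FilterPolicy(mode="drop_site", min_reads=1))
    assert out.equals(t)


def test_fraction_mode_filter_unsupported():
    t = make_fraction_table(["chr1"], [1], [[50.0, 50.0]])
    with pytest.raises(ContractError):
        apply_filter(t, FilterPolicy())


def test_missing_cells_fail_drop_site():
    """drop_site treats a missing cell as insufficient coverage."""
    t = make_count_table(["chr1"], [100], [[np.nan, 5]], [[np.nan, 20]])
    out = apply_filter(t, FilterPolicy(mode="drop_site", min_reads=10))
    assert out.n_sites == 0


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 5000), mode=st.sampled_from(["drop_site", "drop_sample"]))
def test_filter_monotone_in_min_reads(seed, mode):
    """Raising min_reads never recovers sites (or unmasked cells)."""
    rng = np.random.default_rng(seed)
    t = random_count_table(rng, n_sites=25, n_samples=4)
    prev_sites, prev_cells = None, None
    for mr in (1, 5, 10, 20):
        out = apply_filter(t, FilterPolicy(mode=mode, min_reads=mr))
        cells = np.sum(~np.isnan(out.total))
        if prev_sites is not None:
            assert out.n_sites <= prev_sites
            assert cells <= prev_cells
        prev_sites, prev_cells = out.n_sites, cells


# ---------------------------------------------------------------- calling

def test_hand_computed_hypo_call():
    """Group means 80 vs 45 give delta -35 (B-A), direction hypo."""
    t = make_fraction_table(["chr1"], [100], [[80.0, 80.0, 45.0, 45.0]])
    calls, _ = call_dm(t, threshold_points=30)
    assert len(calls) == 1
    assert calls[0].delta == pytest.approx(-35.0)
    assert calls[0].direction == "hypo"


def test_identical_means_never_called():
    t = make_fraction_table(["chr1"], [100], [[40.0, 60.0, 50.0, 50.0]])
    calls, _ = call_dm(t, threshold_points=0.0)
    assert calls == []  # delta 0 is never a call even at threshold 0


def test_boundary_strictness():
    """means 60 vs 30: called at >=30 but not at >30."""
    t = make_fraction_table(["chr1"], [100], [[60.0, 60.0, 30.0, 30.0]])
    loose, _ = call_dm(t, threshold_points=30, strict=False)
    strict, _ = call_dm(t, threshold_points=30, strict=True)
    assert len(loose) == 1 and strict == []


def test_empty_group_site_excluded_not_error():
    t = make_count_table(
        ["chr1", "chr1"], [1, 2],
        meth=[[np.nan, 5], [4, 5]],
        total=[[np.nan, 10], [10, 10]],
    )
    calls, summary = call_dm(t, threshold_points=30)
    assert summary.n_excluded == 1
    assert summary.n_tested == 2


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 5000))
def test_label_swap_antisymmetry(seed):
    """Swapping group labels negates deltas and swaps hyper<->hypo."""
    rng = np.random.default_rng(seed)
    t = random_count_table(rng, n_sites=40, n_samples=4)
    swapped = make_count_table(
        t.chrom, t.pos, t.meth, t.total,
        groups={s: ("B" if g == "A" else "A") for s, g in t.groups.items()},
    )
    a, _ = call_dm(t, threshold_points=20)
    b, _ = call_dm(swapped, threshold_points=20)
    key = lambda c: (c.site.chrom, c.site.pos)
    assert {key(c) for c in a} == {key(c) for c in b}
    bmap = {key(c): c for c in b}
    for c in a:
        m = bmap[key(c)]
        assert m.delta == pytest.approx(-c.delta)
        assert m.direction != c.direction


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 5000))
def test_threshold_monotonicity(seed):
    """The DM set at a higher threshold is a subset of the lower one."""
    rng = np.random.default_rng(seed)
    t = random_count_table(rng, n_sites=40, n_samples=6)
    sets = []
    for thr in (10, 30, 50):
        calls, _ = call_dm(t, threshold_points=thr)
        sets.append({(c.site.chrom, c.site.pos) for c in calls})
    assert sets[2] <= sets[1] <= sets[0]


def test_count_fraction_consistency():
    """Calling on per-sample percents equals calling on raw counts."""
    rng = np.random.default_rng(3)
    t = random_count_table(rng, n_sites=50, n_samples=4)
    t.total[:] = np.maximum(t.total, 1)
    t.meth[:] = np.minimum(t.meth, t.total)
    a, _ = call_dm(t, threshold_points=30)
    b, _ = call_dm(t.to_fraction(), threshold_points=30)
    assert calls_to_frame(a).equals(calls_to_frame(b))


# ---------------------------------------------------------------- summary

def test_summary_counts_small_fixture():
    t = make_fraction_table(
        ["chr1"] * 5, [1, 2, 3, 4, 5],
        [[90, 90, 10, 10], [85, 85, 5, 5], [0, 0, 80, 80],
         [10, 10, 95, 95], [50, 50, 50, 50]],
    )
    calls, summary = call_dm(t, threshold_points=30)
    assert summary.n_dm == 4
    assert summary.n_hypo == 2 and summary.n_hyper == 2
    assert summary.per_chrom.loc["chr1", "pct_dm"] == pytest.approx(80.0)


def test_empty_call_list_all_zero_summary():
    t = make_fraction_table(["chr1"], [1], [[50.0, 55.0]])
    s = summarize_dm([], t)
    assert (s.n_dm, s.n_hyper, s.n_hypo) == (0, 0, 0)


@settings(max_examples=10, deadline=None)
@given(seed=st.integers(0, 5000))
def test_summary_matches_brute_force_recount(seed):
    """Per-chromosome totals equal an independent nested-loop recount."""
    rng = np.random.default_rng(seed)
    t = random_count_table(rng, n_sites=60, n_samples=4)
    calls, summary = call_dm(t, threshold_points=25)
    for chrom in summary.per_chrom.index:
        n_dm = sum(1 for c in calls if c.site.chrom == chrom)
        n_hyper = sum(1 for c in calls if c.site.chrom == chrom and c.delta > 0)
        n_tested = sum(1 for x in t.chrom if x == chrom)
        row = summary.per_chrom.loc[chrom]
        assert row["n_dm"] == n_dm
        assert row["n_hyper"] == n_hyper
        assert row["pct_dm"] == pytest.approx(100.0 * n_dm / n_tested)


def test_calls_frame_round_trip():
    rng = np.random.default_rng(1)
    t = random_count_table(rng, n_sites=40, n_samples=4)
    calls, _ = call_dm(t, threshold_points=10)
    assert frame_to_calls(calls_to_frame(calls)) == calls
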