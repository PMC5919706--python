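"""Trajectory building, daily preferential location, interpolation and
aggregation, checked against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cdrmobility as cm
from cdrmobility.data_io import MISSING, TICKS_PER_DAY
from cdrmobility.itmatrix import _window_mode


# ---------------------------------------------------------------------------
# Independent oracles (pure-python, event-by-event)
# ---------------------------------------------------------------------------

def brute_force_daily_mode(events_df, n_users, n_days):
    """Mode of each user's events per day; ties to the earliest tick."""
    out = np.zeros((n_users, n_days), dtype=int)
    for (u, d), grp in events_df.groupby(
            ["user_id", events_df["tick"] // TICKS_PER_DAY]):
        counts, first = {}, {}
        for t, r in sorted(zip(grp["tick"], grp["region"])):
            counts[r] = counts.get(r, 0) + 1
            first.setdefault(r, t)
        top = max(counts.values())
        winner = min((first[r], r) for r, c in counts.items() if c == top)[1]
        out[u - 1, d] = winner
    return out


def brute_force_window_mode(row, day_bins, n_bins):
    """Per-bin mode of daily labels; ties to the earliest day."""
    out = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        counts, first = {}, {}
        for d in np.flatnonzero(day_bins == b):
            v = row[d]
            if v == MISSING:
                continue
            counts[v] = counts.get(v, 0) + 1
            first.setdefault(v, d)
        if counts:
            top = max(counts.values())
            out[b] = min((first[v], v) for v, c in counts.items()
                         if c == top)[1]
    return out


def _events(calendar, rows):
    df = pd.DataFrame(rows, columns=["user_id", "tick", "region"])
    df = df.sort_values(["user_id", "tick"], ignore_index=True)
    return cm.EventTable(df, calendar)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

class TestBuildTrajectories:
    def test_single_user_two_events(self, calendar):
        ev = _events(calendar, [(1, 5, 1), (1, 9, 2)])
        trajs = cm.build_trajectories(ev)
        assert set(trajs) == {1}
        assert len(trajs[1]) == 2

    def test_two_users_lengths(self, calendar):
        ev = _events(calendar, [(1, 5, 1), (2, 2, 1), (2, 7, 2), (2, 8, 2)])
        trajs = cm.build_trajectories(ev)
        assert len(trajs[1]) == 1 and len(trajs[2]) == 3

    def test_duplicates_collapsed_simultaneous_kept(self, calendar):
        ev = _events(calendar, [(1, 5, 1), (1, 5, 1), (1, 5, 2)])
        trajs = cm.build_trajectories(ev)
        assert len(trajs[1]) == 2          # (5,1) deduped; (5,2) kept

    def test_lengths_match_generator_events(self, conservation_run):
        trajs = cm.build_trajectories(conservation_run.scenario.events)
        dedup = conservation_run.scenario.events.df.drop_duplicates(
            ["user_id", "tick", "region"])
        expected = dedup.groupby("user_id").size()
        assert len(trajs) == len(expected)
        for uid in list(expected.index)[:50]:
            assert len(trajs[uid]) == expected[uid]


# ---------------------------------------------------------------------------
# Daily preferential location
# ---------------------------------------------------------------------------

class TestDailyPreferential:
    def test_majority_wins(self, calendar, toy_partition):
        ev = _events(calendar, [(1, 0, 1), (1, 1, 1), (1, 2, 2)])
        m = cm.daily_preferential(ev, calendar, toy_partition)
        assert m.values[0, 0] == 1

    def test_tie_goes_to_earliest_event(self, calendar, toy_partition):
        ev = _events(calendar, [(1, 5, 2), (1, 6, 1)])
        m = cm.daily_preferential(ev, calendar, toy_partition)
        assert m.values[0, 0] == 2

    def test_day_without_events_is_missing(self, calendar, toy_partition):
        ev = _events(calendar, [(1, 0, 1)])
        m = cm.daily_preferential(ev, calendar, toy_partition)
        assert m.values[0, 1] == MISSING
        assert not m.interpolated

    def test_matches_brute_force_on_random_instances(self, calendar,
                                                     toy_partition):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n_users = int(rng.integers(1, 11))
            n_ev = int(rng.integers(1, 120))
            rows = list(zip(rng.integers(1, n_users + 1, n_ev),
                            rng.integers(0, 31 * TICKS_PER_DAY, n_ev),
                            rng.integers(1, 5, n_ev)))
            ev = _events(calendar, rows)
            got = cm.daily_preferential(ev, calendar, toy_partition)
            expected = brute_force_daily_mode(ev.df, n_users, 365)
            present = np.asarray(sorted(ev.df["user_id"].unique())) - 1
            np.testing.assert_array_equal(got.values, expected[present])


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

def _daily(values, calendar, interpolated=False):
    values = np.asarray(values)
    pad = np.zeros((values.shape[0], 365 - values.shape[1]), dtype=int)
    pad[:, :] = values[:, -1:]          # extend with last value
    full = np.hstack([values, pad])
    return cm.ITMatrix(full, np.arange(1, len(values) + 1), "daily",
                       "region", interpolated, calendar)


class TestInterpolateMissing:
    def test_forward_fill_from_last_active_day(self, calendar):
        m = _daily([[1, MISSING, MISSING, 2]], calendar)
        out = cm.interpolate_missing(m)
        assert list(out.values[0, :4]) == [1, 1, 1, 2]

    def test_leading_gap_backfilled_from_first_active_day(self, calendar):
        m = _daily([[MISSING, MISSING, 1]], calendar)
        m.values[0, 3:] = 1
        out = cm.interpolate_missing(m)
        assert list(out.values[0, :3]) == [1, 1, 1]

    def test_idempotent_and_observed_cells_unchanged(self, calendar):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 5, (20, 365))
        vals[:, 100] = 3                        # every row observed somewhere
        m = cm.ITMatrix(vals, np.arange(20), "daily", "region", False,
                        calendar)
        once = cm.interpolate_missing(m)
        twice = cm.interpolate_missing(once)
        np.testing.assert_array_equal(once.values, twice.values)
        observed = vals != MISSING
        np.testing.assert_array_equal(once.values[observed], vals[observed])

    def test_every_user_everywhere_after_interpolation(self, calendar):
        rng = np.random.default_rng(1)
        vals = rng.integers(0, 4, (30, 365))
        vals[:, 0] = 1
        m = cm.ITMatrix(vals, np.arange(30), "daily", "region", False,
                        calendar)
        out = cm.interpolate_missing(m)
        assert (out.values != MISSING).sum(axis=0).min() == 30

    def test_all_missing_row_rejected(self, calendar):
        m = cm.ITMatrix(np.zeros((1, 365), dtype=int), np.array([9]),
                        "daily", "region", False, calendar)
        with pytest.raises(ValueError, match="no observed location"):
            cm.interpolate_missing(m)

    def test_gap_cap_leaves_distant_cells_missing(self, calendar):
        vals = np.zeros((1, 365), dtype=int)
        vals[0, 0] = 1
        vals[0, 100] = 2
        m = cm.ITMatrix(vals, np.array([1]), "daily", "region", False,
                        calendar)
        out = cm.interpolate_missing(m, max_gap=10)
        assert out.values[0, 10] == 1 and out.values[0, 11] == MISSING
        assert not out.interpolated


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

class TestAggregateTime:
    def test_monthly_majority(self, calendar, toy_partition):
        vals = np.ones((1, 365), dtype=int)
        vals[0, 20:31] = 2                 # January: 20 x A + 11 x B
        m = cm.ITMatrix(vals, np.array([1]), "daily", "region", True,
                        calendar)
        out = cm.aggregate_time(m, "monthly")
        assert out.values[0, 0] == 1

    @pytest.mark.parametrize("resolution,width",
                             [("weekly", 53), ("biweekly", 24),
                              ("monthly", 12)])
    def test_column_counts(self, calendar, resolution, width):
        m = cm.ITMatrix(np.ones((2, 365), dtype=int), np.arange(2), "daily",
                        "region", True, calendar)
        assert cm.aggregate_time(m, resolution).values.shape == (2, width)

    def test_finer_target_rejected(self, calendar):
        m = cm.ITMatrix(np.ones((1, 365), dtype=int), np.array([1]), "daily",
                        "region", True, calendar)
        with pytest.raises(ValueError):
            cm.aggregate_time(m, "daily")
        monthly = cm.aggregate_time(m, "monthly")
        with pytest.raises(ValueError):
            cm.aggregate_time(monthly, "weekly")

    @pytest.mark.parametrize("resolution", ["weekly", "biweekly", "monthly"])
    def test_matches_brute_force_modes_with_ties(self, calendar, resolution):
        rng = np.random.default_rng(7)
        day_bins = calendar.bin_of_day(resolution)
        n_bins = calendar.n_bins(resolution)
        vals = rng.integers(0, 4, (15, 365))    # frequent ties, some missing
        vals[:, 5] = 1
        m = cm.ITMatrix(vals, np.arange(15), "daily", "region", False,
                        calendar)
        got = cm.aggregate_time(m, resolution)
        for i in range(15):
            np.testing.assert_array_equal(
                got.values[i], brute_force_window_mode(vals[i], day_bins,
                                                       n_bins))

    def test_bin_missing_only_if_all_days_missing(self, calendar):
        vals = np.zeros((1, 365), dtype=int)
        vals[0, 40] = 2                        # single observed day in Feb
        vals[0, 300] = 1
        m = cm.ITMatrix(vals, np.array([1]), "daily", "region", False,
                        calendar)
        out = cm.aggregate_time(m, "monthly")
        assert out.values[0, 1] == 2
        assert out.values[0, 0] == MISSING


class TestAggregateSpace:
    def test_region_to_zone_mapping(self, calendar, toy_partition):
        vals = np.zeros((1, 365), dtype=int)
        vals[0, :3] = [1, 3, 2]                # A, C, B
        m = cm.ITMatrix(vals, np.array([1]), "daily", "region", False,
                        calendar)
        out = cm.aggregate_space(m, toy_partition)
        assert list(out.values[0, :3]) == [1, 2, 1]
        assert out.values[0, 3] == MISSING     # missing preserved
        assert out.level == "zone"

    def test_unknown_region_code_rejected(self, calendar, toy_partition):
        vals = np.full((1, 365), 99, dtype=int)
        m = cm.ITMatrix(vals, np.array([1]), "daily", "region", True,
                        calendar)
        with pytest.raises(ValueError, match="outside the partition"):
            cm.aggregate_space(m, toy_partition)

    def test_space_then_time_equals_zone_mode_oracle(self, calendar,
                                                     toy_partition):
        """Zone-mapped dailies reduced per month match the explicit oracle."""
        rng = np.random.default_rng(9)
        vals = rng.integers(0, 5, (10, 365))
        m = cm.ITMatrix(vals, np.arange(10), "daily", "region", False,
                        calendar)
        got = cm.aggregate_time(cm.aggregate_space(m, toy_partition),
                                "monthly")
        zone_vals = toy_partition.zone_of_region_code[vals] * (vals > 0)
        day_bins = calendar.bin_of_day("monthly")
        for i in range(10):
            np.testing.assert_array_equal(
                got.values[i],
                brute_force_window_mode(zone_vals[i], day_bins, 12))


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 3), min_size=10, max_size=40).filter(
    lambda xs: any(x > 0 for x in xs)))
def test_aggregation_never_invents_labels(xs):
    sub = np.asarray([xs])
    mode = _window_mode(sub)[0]
    assert mode in set(x for x in xs if x > 0)


def test_interpolated_matrix_columns_conserve_population(conservation_run):
    m = conservation_run.daily
    n = m.n_users
    assert ((m.values != MISSING).sum(axis=0) == n).all()


def test_itmatrix_csv_roundtrip(tmp_path, calendar):
    rng = np.random.default_rng(3)
    vals = rng.integers(1, 5, (4, 12))
    m = cm.ITMatrix(vals, np.array([10, 20, 30, 40]), "monthly", "zone",
                    True, calendar)
    path = tmp_path / "m.csv"
    cm.write_itmatrix(m, path)
    back = cm.read_itmatrix(path)
    np.testing.assert_array_equal(back.values, m.values)
    np.testing.assert_array_equal(back.user_ids, m.user_ids)
    assert (back.resolution, back.level, back.interpolated) == \
        ("monthly", "zone", True)
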