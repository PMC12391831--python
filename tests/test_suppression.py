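"""Running-mean suppression flags and host/non-host corrected-index events."""

import numpy as np
import pytest

from ghostforest import (
    Chronology,
    GsiSeries,
    IndexSeries,
    RingWidthSeries,
    SeriesSet,
    correct_host,
    detect_site_events,
    detect_tree_events,
    flag_suppression,
    merge_cores,
    running_mean,
    site_events,
    site_suppression,
    widespread_years,
)
from ghostforest.suppression import SuppressionFlags


def _series(widths, first_year=1900, sid="S"):
    return RingWidthSeries(sid, first_year, np.asarray(widths, dtype=float), tree_id=sid)


class TestRunningMean:
    def test_constant_series(self, constant_series):
        rm, defined = running_mean(constant_series)
        np.testing.assert_allclose(rm, 1.2)
        assert defined.all()

    def test_step_series_hand_oracle(self):
        """20x1.0 then 20x2.0; window offsets -10..+9 around the step."""
        s = _series([1.0] * 20 + [2.0] * 20)
        rm, _ = running_mean(s)
        # i=20: years 10..29 -> ten 1.0 and ten 2.0
        assert rm[20] == pytest.approx(1.5)
        # i=15: years 5..24 -> fifteen 1.0, five 2.0
        assert rm[15] == pytest.approx((15 * 1.0 + 5 * 2.0) / 20)
        # i=25: years 15..34 -> five 1.0, fifteen 2.0
        assert rm[25] == pytest.approx((5 * 1.0 + 15 * 2.0) / 20)

    def test_window_longer_than_series_gives_global_mean(self):
        w = np.linspace(1.0, 2.0, 14)
        rm, _ = running_mean(_series(w))
        np.testing.assert_allclose(rm, w.mean())

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            running_mean(_series(np.ones(8)))

    def test_matches_bruteforce_oracle(self, rng):
        w = np.exp(rng.normal(0, 0.3, 60))
        s = _series(w)
        rm, _ = running_mean(s, window=20)
        for i in [0, 5, 10, 30, 55, 59]:
            start, end = i - 10, i + 9
            if start < 0:
                end, start = end - start, 0
            if end > 59:
                start, end = max(0, start - (end - 59)), 59
            assert rm[i] == pytest.approx(w[start : end + 1].mean(), abs=1e-12)


class TestFlagSuppression:
    def test_constant_series_no_flags(self, constant_series):
        assert not flag_suppression(constant_series).any()

    def test_single_deep_dip_is_flagged(self):
        """Width 0.10 vs centered mean ~0.955: 0.10 < 0.25 * 0.955."""
        w = np.ones(40)
        w[20] = 0.10
        flags = flag_suppression(_series(w))
        assert flags[20]
        assert flags.sum() == 1

    def test_moderate_dip_not_flagged_under_quarter_rule(self):
        w = np.ones(40)
        w[20] = 0.50
        assert not flag_suppression(_series(w)).any()

    def test_threshold_monotonicity(self, rng):
        """Flag percentage is monotone non-decreasing in threshold_frac."""
        w = np.exp(rng.normal(0, 0.5, 80))
        s = _series(w)
        counts = [flag_suppression(s, threshold_frac=f).sum() for f in (0.25, 0.5, 0.75, 0.9)]
        assert counts == sorted(counts)


class TestWidespreadYears:
    def _flags(self, matrix, first_year=2000):
        matrix = np.asarray(matrix, dtype=bool)
        n_trees, n_years = matrix.shape
        return SuppressionFlags(
            tree_ids=[f"T{i}" for i in range(n_trees)],
            years=np.arange(first_year, first_year + n_years),
            flags=matrix,
            defined=np.ones_like(matrix, dtype=bool),
        )

    def test_all_trees_flagged_is_widespread(self):
        f = self._flags(np.ones((6, 3)))
        assert widespread_years(f) == [2000, 2001, 2002]

    def test_exactly_75_percent_is_not_widespread(self):
        """Strictly 'over 75%': 6 of 8 trees = 75% exactly -> excluded."""
        m = np.zeros((8, 1))
        m[:6, 0] = 1
        assert widespread_years(self._flags(m)) == []

    def test_seven_of_ten_not_widespread(self):
        m = np.zeros((10, 1))
        m[:7, 0] = 1
        assert widespread_years(self._flags(m)) == []

    def test_low_depth_years_excluded(self):
        m = np.ones((3, 2), dtype=bool)
        f = self._flags(m)
        assert widespread_years(f, min_depth=5) == []
        assert widespread_years(f, min_depth=3) == [2000, 2001]


class TestMergeCores:
    def test_two_cores_averaged_per_year(self):
        a = RingWidthSeries("T1a", 2000, np.array([1.0, 2.0, 3.0]), tree_id="T1")
        b = RingWidthSeries("T1b", 2001, np.array([4.0, 5.0]), tree_id="T1")
        (tree,) = merge_cores(SeriesSet("X", [a, b]))
        assert tree.first_year == 2000
        np.testing.assert_allclose(tree.widths, [1.0, 3.0, 4.0])

    def test_site_suppression_counts_trees_not_cores(self, rng):
        series = []
        for t in range(6):
            w = np.exp(rng.normal(0, 0.1, 40))
            for c in "ab":
                series.append(RingWidthSeries(f"T{t}{c}", 1960, w, tree_id=f"T{t}"))
        flags = site_suppression(SeriesSet("X", series))
        assert len(flags.tree_ids) == 6


class TestCorrectHost:
    def _chron(self, values, first_year=1950):
        values = np.asarray(values, dtype=float)
        years = np.arange(first_year, first_year + len(values))
        return Chronology("NH", years, values, np.full(len(values), 8))

    def test_host_identical_to_nonhost_is_degenerate(self, rng):
        vals = 1 + 0.2 * rng.random(50)
        host = IndexSeries("H", 1950, vals, tree_id="H")
        g = correct_host(host, self._chron(vals))
        assert g.degenerate
        assert detect_tree_events(g) == []

    def test_implanted_depression_drives_ngsi_below_onset(self, rng):
        vals = 1 + 0.1 * rng.standard_normal(80)
        depressed = vals.copy()
        depressed[40:52] -= 2.0 * vals.std(ddof=1)  # 12-year, -2 index-sd depression
        host = IndexSeries("H", 1950, np.clip(depressed, 0, None), tree_id="H")
        g = correct_host(host, self._chron(vals))
        assert (g.ngsi[40:52] < -1.28).all()

    def test_invariant_to_nonhost_constant_shift(self, rng):
        h = IndexSeries("H", 1950, 1 + 0.2 * rng.random(60), tree_id="H")
        c = 1 + 0.2 * rng.random(60)
        g1 = correct_host(h, self._chron(c))
        g2 = correct_host(h, self._chron(c + 5.0))
        np.testing.assert_allclose(g1.gsi, g2.gsi, atol=1e-12)

    def test_equivariant_to_nonhost_rescaling(self, rng):
        h = IndexSeries("H", 1950, 1 + 0.2 * rng.random(60), tree_id="H")
        c = 1 + 0.2 * rng.random(60)
        g1 = correct_host(h, self._chron(c))
        g2 = correct_host(h, self._chron(3.0 * c))
        np.testing.assert_allclose(g1.gsi, g2.gsi, atol=1e-12)
        np.testing.assert_allclose(g1.ngsi, g2.ngsi, atol=1e-10)

    def test_zero_variance_nonhost_raises(self, rng):
        h = IndexSeries("H", 1950, 1 + 0.2 * rng.random(60), tree_id="H")
        with pytest.raises(ValueError, match="variance"):
            correct_host(h, self._chron(np.ones(60)))

    def test_short_overlap_raises(self, rng):
        h = IndexSeries("H", 1950, 1 + 0.2 * rng.random(20), tree_id="H")
        with pytest.raises(ValueError, match="overlap"):
            correct_host(h, self._chron(1 + 0.2 * rng.random(20)))


def _gsi(ngsi, first_year=1950, tree_id="T"):
    ngsi = np.asarray(ngsi, dtype=float)
    return GsiSeries(tree_id=tree_id, first_year=first_year, gsi=ngsi.copy(), ngsi=ngsi)


class TestDetectTreeEvents:
    def test_no_excursion_no_periods(self):
        assert detect_tree_events(_gsi(np.zeros(30))) == []

    def test_six_years_at_minus_2_5_is_one_moderate_period(self):
        x = np.zeros(30)
        x[10:16] = -2.5
        (p,) = detect_tree_events(_gsi(x))
        assert (p.start_year, p.end_year) == (1960, 1965)
        assert p.severity == "moderate"

    def test_three_year_excursion_rejected_by_min_duration(self):
        x = np.zeros(30)
        x[10:13] = -2.5
        assert detect_tree_events(_gsi(x)) == []

    def test_single_year_interruption_bridged(self):
        x = np.zeros(30)
        x[10:20] = -1.5
        x[14] = 0.0  # 1-year recovery inside the run
        (p,) = detect_tree_events(_gsi(x))
        assert (p.start_year, p.end_year) == (1960, 1969)

    def test_two_year_interruption_splits(self):
        x = np.zeros(40)
        x[10:16] = -1.5
        x[18:24] = -1.5
        periods = detect_tree_events(_gsi(x))
        assert len(periods) == 2

    @pytest.mark.parametrize("depth, severity", [(-1.5, "minor"), (-2.5, "moderate"), (-3.5, "severe")])
    def test_severity_classes(self, depth, severity):
        x = np.zeros(30)
        x[10:16] = depth
        (p,) = detect_tree_events(_gsi(x))
        assert p.severity == severity


class TestSiteEvents:
    def test_no_tree_periods_gives_no_events(self):
        spans = {f"T{i}": (1950, 2000) for i in range(5)}
        assert site_events([], spans) == []

    def test_proportion_threshold(self):
        """1 of 5 trees active -> 0.2 < 0.25 -> no event; 2 of 5 -> event."""
        spans = {f"T{i}": (1950, 2000) for i in range(5)}
        one = detect_tree_events(_gsi(np.where(np.arange(51) < 10, -2.0, 0.0), tree_id="T0"))
        assert site_events(one, spans) == []
        two = one + detect_tree_events(
            _gsi(np.where(np.arange(51) < 10, -2.0, 0.0), tree_id="T1")
        )
        events = site_events(two, spans)
        assert len(events) == 1
        assert events[0].max_proportion == pytest.approx(0.4)

    def test_two_events_separated_by_normal_year(self):
        spans = {f"T{i}": (1950, 2010) for i in range(4)}
        x = np.zeros(61)
        x[10:20] = -2.0
        x[21:31] = -2.0  # 1 normal year (1970) between runs, no site-level bridging
        periods = []
        for t in range(3):
            periods += detect_tree_events(_gsi(x, tree_id=f"T{t}"), bridge_gap=0)
        events = site_events(periods, spans)
        assert [(e.start_year, e.end_year) for e in events] == [(1960, 1969), (1971, 1980)]

    def test_too_few_trees_raises(self):
        with pytest.raises(ValueError, match="trees"):
            site_events([], {"T0": (1950, 2000)})

    def test_event_reports_trees_and_severities(self):
        spans = {f"T{i}": (1950, 2000) for i in range(4)}
        periods = []
        for t, depth in enumerate((-1.5, -2.5, -3.5)):
            x = np.zeros(51)
            x[5:15] = depth
            periods += detect_tree_events(_gsi(x, tree_id=f"T{t}"))
        (e,) = site_events(periods, spans)
        assert e.trees_involved == ["T0", "T1", "T2"]
        assert e.severities == {"T0": "minor", "T1": "moderate", "T2": "severe"}


def test_detect_site_events_pipeline(rng):
    """Implanted depression in most trees is recovered as one site event."""
    gsis = []
    for t in range(8):
        x = rng.normal(0, 0.5, 70)
        if t < 7:
            x[30:45] -= 3.0
        x = (x - x.mean()) / x.std(ddof=1)
        gsis.append(GsiSeries(tree_id=f"T{t}", first_year=1950, gsi=x.copy(), ngsi=x))
    periods, events = detect_site_events(gsis)
    assert len(events) == 1
    assert abs(events[0].start_year - 1980) <= 2
    assert abs(events[0].end_year - 1994) <= 2
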