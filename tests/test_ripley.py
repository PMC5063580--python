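import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from outbreaksync.records import StudyPeriod
from outbreaksync.ripley import (
    EventSeries,
    circular_envelope,
    cross_k,
    events_from_record,
    l_transform,
    multivariate_k,
)
from conftest import make_binary


def ev(years, region="A", event_type="outbreak_years"):
    return EventSeries(region_id=region, event_years=np.asarray(years), event_type=event_type)


def brute_force_cross_k(a, b, t_max, n):
    """Independent oracle: explicit double loop over event pairs."""
    out = np.zeros(t_max + 1)
    for t in range(t_max + 1):
        c = sum(1 for u in a for v in b if abs(u - v) <= t)
        out[t] = n / (len(a) * len(b)) * c
    return out


def brute_force_multivariate_k(series, t_max, n):
    """Oracle over all ordered pairs of series."""
    out = np.zeros(t_max + 1)
    denom = sum(
        len(a) * len(b) for i, a in enumerate(series) for j, b in enumerate(series) if i != j
    )
    for t in range(t_max + 1):
        c = sum(
            1
            for i, a in enumerate(series)
            for j, b in enumerate(series)
            if i != j
            for u in a
            for v in b
            if abs(u - v) <= t
        )
        out[t] = n * c / denom
    return out


class TestEventsFromRecord:
    def test_episode_endpoints(self, period):
        vals = np.zeros(period.n, dtype=int)
        vals[1715 - 1700 : 1733 - 1700 + 1] = 1
        s = make_binary("NM", 1700, vals)
        assert events_from_record(s, "initiations", period).event_years.tolist() == [1715]
        assert events_from_record(s, "cessations", period).event_years.tolist() == [1733]

    def test_all_zero(self, period10):
        s = make_binary("A", 1700, np.zeros(10))
        assert events_from_record(s, "outbreak_years", period10).n_events == 0

    def test_two_episodes(self):
        s = make_binary("A", 1700, [1, 1, 0, 1, 0, 0])
        period = StudyPeriod(1700, 1705)
        assert events_from_record(s, "initiations", period).event_years.tolist() == [1700, 1703]
        assert events_from_record(s, "cessations", period).event_years.tolist() == [1701, 1703]
        assert events_from_record(s, "outbreak_years", period).event_years.tolist() == [
            1700, 1701, 1703,
        ]


class TestCrossK:
    def test_coincident_single_events(self):
        period = StudyPeriod(1700, 1990)
        k = cross_k(ev([1800]), ev([1800], "B"), 0, period)
        assert k[0] == 291

    def test_separated_single_events(self):
        period = StudyPeriod(1700, 1990)
        k = cross_k(ev([1800]), ev([1810], "B"), 15, period)
        assert np.all(k[:10] == 0)
        assert np.all(k[10:] == 291)

    def test_saturated_partner(self):
        period = StudyPeriod(1700, 1729)
        n = period.n
        b_years = list(range(1700, 1730))
        a_years = [1705, 1714]
        k = cross_k(ev(a_years), ev(b_years, "B"), 5, period)
        oracle = brute_force_cross_k(a_years, b_years, 5, n)
        np.testing.assert_allclose(k, oracle)

    def test_empty_series_error(self):
        period = StudyPeriod(1700, 1790)
        with pytest.raises(ValueError, match="'B'"):
            cross_k(ev([1700]), ev([], "B"), 5, period)

    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 301))
        period = StudyPeriod(1700, 1700 + n - 1)
        t_max = int(rng.integers(0, min(26, n - 1)))
        years = period.years
        a = sorted(rng.choice(years, size=int(rng.integers(1, 21)), replace=False))
        b = sorted(rng.choice(years, size=int(rng.integers(1, 21)), replace=False))
        k_ab = cross_k(ev(a), ev(b, "B"), t_max, period)
        np.testing.assert_allclose(k_ab, brute_force_cross_k(a, b, t_max, n))
        # symmetry
        np.testing.assert_allclose(k_ab, cross_k(ev(b, "B"), ev(a), t_max, period))
        # monotone in window size
        assert np.all(np.diff(k_ab) >= -1e-12)


class TestMultivariateK:
    def test_identical_series_saturate_at_zero_window(self):
        # single coincident event per region: every event matches across
        # every pair, so K(0) attains its maximum n
        period = StudyPeriod(1700, 1990)
        series = [ev([1750], f"R{i}") for i in range(7)]
        k = multivariate_k(series, 0, period)
        assert k[0] == period.n

    def test_disjoint_distant_events(self):
        period = StudyPeriod(1700, 1990)
        series = [ev([1700 + 50 * i], f"R{i}") for i in range(4)]
        k = multivariate_k(series, 10, period)
        assert np.all(k == 0)

    @given(st.integers(0, 10_000))
    def test_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 150))
        period = StudyPeriod(1700, 1700 + n - 1)
        t_max = int(rng.integers(0, 15))
        series = []
        for i in range(int(rng.integers(2, 6))):
            m = int(rng.integers(1, 11))
            series.append(
                sorted(rng.choice(period.years, size=m, replace=False).tolist())
            )
        k = multivariate_k([ev(s, f"R{i}") for i, s in enumerate(series)], t_max, period)
        np.testing.assert_allclose(k, brute_force_multivariate_k(series, t_max, n))

    def test_all_empty_error(self):
        period = StudyPeriod(1700, 1790)
        with pytest.raises(ValueError, match="non-empty"):
            multivariate_k([ev([], "A"), ev([], "B")], 5, period)


class TestLTransform:
    def test_zero_expectation_values(self):
        assert l_transform(np.array([1.0]))[0] == 0
        # K(5) = 11 = 2*5+1 is the independence expectation
        assert l_transform(np.array([1.0, 3, 5, 7, 9, 11]))[5] == 0

    def test_saturated_zero_window(self):
        assert l_transform(np.array([291.0]))[0] == 145


class TestCircularEnvelope:
    def test_full_rotation_identity(self):
        v = np.array([0, 1, 1, 0, 0, 1, 0, 0, 1, 1])
        np.testing.assert_array_equal(np.roll(v, len(v)), v)

    def test_duplicated_records_flagged_synchronous(self):
        rng = np.random.default_rng(5)
        period = StudyPeriod(1700, 1899)
        vals = np.zeros(200, dtype=int)
        for start in rng.choice(190, size=8, replace=False):
            vals[start : start + 6] = 1
        recs = [make_binary(f"R{i}", 1700, vals) for i in range(5)]
        res = circular_envelope(recs, "outbreak_years", t_max=10, period=period,
                                n_sim=199, seed=11)
        assert res.l[0] > res.envelope_high[0]
        assert res.significant[0]

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(6)
        period = StudyPeriod(1700, 1799)
        recs = [
            make_binary(f"R{i}", 1700, rng.integers(0, 2, 100)) for i in range(4)
        ]
        a = circular_envelope(recs, "initiations", 10, period, n_sim=50, seed=42)
        b = circular_envelope(recs, "initiations", 10, period, n_sim=50, seed=42)
        np.testing.assert_array_equal(a.l, b.l)
        np.testing.assert_array_equal(a.envelope_low, b.envelope_low)
        np.testing.assert_array_equal(a.envelope_high, b.envelope_high)
        np.testing.assert_array_equal(a.significant, b.significant)

    def test_rotation_preserves_episode_mass(self):
        # total outbreak years (and hence event counts up to a seam split)
        # are invariant under rotation
        rng = np.random.default_rng(7)
        v = rng.integers(0, 2, 60)
        for off in (1, 13, 59):
            assert np.roll(v, off).sum() == v.sum()
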