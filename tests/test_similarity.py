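import itertools

import numpy as np
import pytest

from outbreaksync.records import RegionSet, StudyPeriod
from outbreaksync.similarity import (
    PairwiseMatrix,
    centroid_distances,
    climate_similarity,
    distance_decay_regression,
    mantel,
    outbreak_similarity,
    pair_agreement_counts,
    partial_mantel,
)
from conftest import make_binary, make_climate


def pm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"R{i}" for i in range(len(values))]
    return PairwiseMatrix(region_ids=list(ids), values=values)


def random_pm(rng, n=4):
    m = rng.standard_normal((n, n))
    m = (m + m.T) / 2
    return pm(m)


def exhaustive_mantel_p(A, B, alternative="two-sided"):
    """Exact p by enumeration of all simultaneous relabelings of B."""
    n = A.n
    iu = np.triu_indices(n, k=1)
    a = A.values[iu]
    bmat = B.values.copy()
    np.fill_diagonal(bmat, 0.0)
    r_obs = np.corrcoef(a, bmat[iu])[0, 1]
    count = total = 0
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        r = np.corrcoef(a, bmat[np.ix_(p, p)][iu])[0, 1]
        if alternative == "two-sided":
            count += abs(r) >= abs(r_obs) - 1e-12
        else:
            count += r >= r_obs - 1e-12
        total += 1
    return count / total


class TestSimilarityIndices:
    def test_identical_binary_records(self, period10):
        a = make_binary("A", 1700, [1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
        assert outbreak_similarity(a, a, period10) == 1.0

    def test_complementary_binary_records(self, period10):
        a = make_binary("A", 1700, [1, 0] * 5)
        b = make_binary("B", 1700, [0, 1] * 5)
        assert outbreak_similarity(a, b, period10) == 0.0

    def test_hand_counted_agreement(self, period10):
        a = make_binary("A", 1700, [1, 1, 1, 0, 0, 0, 0, 1, 1, 0])
        b = make_binary("B", 1700, [1, 1, 0, 0, 0, 1, 0, 1, 0, 0])
        counts = pair_agreement_counts(a, b, period10)
        assert (counts.a, counts.b, counts.c, counts.d) == (3, 4, 2, 1)
        assert outbreak_similarity(a, b, period10) == pytest.approx(0.7)

    def test_symmetry_and_relabel_invariance(self, period10):
        rng = np.random.default_rng(3)
        av, bv = rng.integers(0, 2, 10), rng.integers(0, 2, 10)
        a, b = make_binary("A", 1700, av), make_binary("B", 1700, bv)
        flipped_a = make_binary("A", 1700, 1 - av)
        flipped_b = make_binary("B", 1700, 1 - bv)
        s = outbreak_similarity(a, b, period10)
        assert s == outbreak_similarity(b, a, period10)
        assert s == outbreak_similarity(flipped_a, flipped_b, period10)

    def test_climate_identical(self, period10):
        x = make_climate("A", 1700, np.arange(10.0))
        assert climate_similarity(x, x, period10) == 0.0

    def test_climate_constant_offset(self, period10):
        x = make_climate("A", 1700, np.zeros(10))
        y = make_climate("B", 1700, np.ones(10))
        assert climate_similarity(x, y, period10) == -1.0

    def test_climate_hand_case(self):
        period = StudyPeriod(1700, 1701)
        x = make_climate("A", 1700, [0.0, 2.0])
        y = make_climate("B", 1700, [1.0, 0.0])
        assert climate_similarity(x, y, period) == -1.5

    def test_climate_similarity_nonpositive(self, period10):
        rng = np.random.default_rng(4)
        x = make_climate("A", 1700, rng.standard_normal(10))
        y = make_climate("B", 1700, rng.standard_normal(10))
        assert climate_similarity(x, y, period10) <= 0


class TestCentroidDistances:
    def test_three_four_five(self):
        rs = RegionSet(region_ids=["A", "B"], coordinates=[[0, 0], [3, 4]])
        d = centroid_distances(rs)
        assert d.values[0, 1] == 5.0

    def test_duplicate_coordinates_warn(self):
        rs = RegionSet(region_ids=["A", "B"], coordinates=[[1, 1], [1, 1]])
        with pytest.warns(UserWarning, match="duplicate"):
            d = centroid_distances(rs)
        assert d.values[0, 1] == 0.0

    def test_hand_computed_layout(self):
        coords = np.array([[0, 0], [1, 0], [0, 2], [3, 4], [5, 5], [2, 2], [4, 1]])
        rs = RegionSet(region_ids=[f"R{i}" for i in range(7)], coordinates=coords)
        d = centroid_distances(rs)
        for i in range(7):
            for j in range(i + 1, 7):
                expected = np.hypot(*(coords[i] - coords[j]))
                assert d.values[i, j] == pytest.approx(expected)


class TestDistanceDecayRegression:
    def test_collinear(self):
        dist = pm([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0]])
        sim = pm(1 - 0.1 * dist.values)
        res = distance_decay_regression(sim, dist)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(-0.1)

    def test_constant_similarity(self):
        rng = np.random.default_rng(5)
        dist = random_pm(rng)
        sim = pm(np.full((4, 4), 0.5))
        assert distance_decay_regression(sim, dist).r_squared == pytest.approx(0.0)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(6)
        dist = random_pm(rng, 6)
        sim = pm(0.5 - 0.02 * dist.values + 0.1 * random_pm(rng, 6).values)
        res = distance_decay_regression(sim, dist)
        x, y = dist.upper_triangle(), sim.upper_triangle()
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert res.slope == pytest.approx(slope, abs=1e-12)
        assert res.intercept == pytest.approx(intercept, abs=1e-12)
        assert res.r_squared == pytest.approx(r2, abs=1e-12)


class TestMantel:
    def test_self_correlation(self):
        rng = np.random.default_rng(7)
        A = random_pm(rng)
        res = mantel(A, A, n_perm=100, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_anti_correlation(self):
        rng = np.random.default_rng(8)
        A = random_pm(rng)
        B = pm(-A.values)
        assert mantel(A, B, n_perm=100, seed=1).r == pytest.approx(-1.0)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater"])
    def test_permutation_p_matches_exhaustive_enumeration(self, alternative):
        rng = np.random.default_rng(9)
        A, B = random_pm(rng), random_pm(rng)
        exact = exhaustive_mantel_p(A, B, alternative)
        res = mantel(A, B, n_perm=10000, seed=2, alternative=alternative)
        # (1 + hits) / (n_perm + 1) estimates the enumeration p; binomial MC error
        mc_err = 4 * np.sqrt(exact * (1 - exact) / 10000)
        assert res.p == pytest.approx(exact, abs=max(mc_err, 2e-3))

    def test_p_within_bounds(self):
        rng = np.random.default_rng(10)
        res = mantel(random_pm(rng), random_pm(rng), n_perm=99, seed=3)
        assert 1 / 100 <= res.p <= 1

    def test_invariant_under_common_reordering(self):
        rng = np.random.default_rng(11)
        A, B = random_pm(rng, 5), random_pm(rng, 5)
        perm = [3, 1, 4, 0, 2]
        A2 = pm(A.values[np.ix_(perm, perm)], ids=[A.region_ids[i] for i in perm])
        B2 = pm(B.values[np.ix_(perm, perm)], ids=[B.region_ids[i] for i in perm])
        assert mantel(A, B, 10, seed=1).r == pytest.approx(mantel(A2, B2, 10, seed=1).r)

    def test_zero_variance_error(self):
        rng = np.random.default_rng(12)
        flat = pm(np.ones((4, 4)))
        with pytest.raises(ValueError, match="variance"):
            mantel(flat, random_pm(rng), n_perm=10, seed=1)


class TestPartialMantel:
    def test_b_equals_c_gives_zero(self):
        rng = np.random.default_rng(13)
        A, C = random_pm(rng), random_pm(rng)
        res = partial_mantel(A, C, C, n_perm=100, seed=1)
        assert abs(res.r) < 1e-10

    def test_uncorrelated_confounder_preserves_r(self):
        # with C independent of A and B, partial r approximates simple r
        rng = np.random.default_rng(14)
        diffs = []
        for _ in range(40):
            n = 8
            base = rng.standard_normal((n, n))
            A = pm((base + base.T) / 2)
            noise = rng.standard_normal((n, n)) * 0.6
            B = pm(A.values + (noise + noise.T) / 2)
            C = random_pm(rng, n)
            simple = mantel(A, B, n_perm=10, seed=1).r
            partial = partial_mantel(A, B, C, n_perm=10, seed=1).r
            diffs.append(partial - simple)
        assert abs(np.mean(diffs)) < 0.05

    def test_permutation_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(15)
        A, B, C = random_pm(rng), random_pm(rng), random_pm(rng)
        iu = np.triu_indices(4, k=1)

        def residualize(y, x):
            X = np.column_stack([np.ones_like(x), x])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return y - X @ beta

        a = residualize(A.values[iu], C.values[iu])
        b = residualize(B.values[iu], C.values[iu])
        amat = np.zeros((4, 4))
        amat[iu] = a
        amat += amat.T
        r_obs = np.corrcoef(a, b)[0, 1]
        count = total = 0
        for perm in itertools.permutations(range(4)):
            p = np.array(perm)
            r = np.corrcoef(amat[np.ix_(p, p)][iu], b)[0, 1]
            count += abs(r) >= abs(r_obs) - 1e-12
            total += 1
        exact = count / total
        res = partial_mantel(A, B, C, n_perm=10000, seed=4)
        mc_err = 4 * np.sqrt(exact * (1 - exact) / 10000)
        assert res.p == pytest.approx(exact, abs=max(mc_err, 2e-3))
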