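"""Pairwise similarity indices, distance decay, and Mantel tests.

Outbreak similarity between two regions is the simple matching fraction of
common-period years with identical outbreak status, (a + b) / (a + b + c + d)
with a = joint outbreak years, b = joint non-outbreak years, c and d the
disagreements.  (The compilation literature labels this a "Jaccard" index,
but the printed formula includes joint absences, i.e. the simple matching
coefficient; the formula is what is implemented.)

Climate similarity is the negated mean annual absolute drought-index
difference, -(1/n) * sum_t |x_t - y_t| <= 0 — the inverse of the mean annual
Euclidean distance in one-dimensional climate space.

Association between pairwise matrices is tested with Mantel and partial
Mantel permutation tests over simultaneous row/column relabelings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .records import AnnualBinarySeries, ClimateSeries, RegionSet, StudyPeriod

__all__ = [
    "PairAgreementCounts",
    "PairwiseMatrix",
    "pair_agreement_counts",
    "outbreak_similarity",
    "climate_similarity",
    "outbreak_similarity_matrix",
    "climate_similarity_matrix",
    "centroid_distances",
    "distance_decay_regression",
    "mantel",
    "partial_mantel",
    "MantelResult",
    "RegressionResult",
]


class PairAgreementCounts(NamedTuple):
    a: int  # both regions in outbreak
    b: int  # both in non-outbreak
    c: int  # only the first in outbreak
    d: int  # only the second in outbreak


@dataclass
class PairwiseMatrix:
    """Symmetric region-by-region matrix; the diagonal is undefined (NaN)."""

    region_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.region_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match region count")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(
            self.values[off], self.values.T[off], equal_nan=True
        ):
            raise ValueError("matrix must be symmetric")
        np.fill_diagonal(self.values, np.nan)

    @property
    def n(self) -> int:
        return len(self.region_ids)

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle entries in row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def pair_agreement_counts(
    x: AnnualBinarySeries, y: AnnualBinarySeries, period: StudyPeriod
) -> PairAgreementCounts:
    xv, yv = x.window(period), y.window(period)
    return PairAgreementCounts(
        a=int(np.sum((xv == 1) & (yv == 1))),
        b=int(np.sum((xv == 0) & (yv == 0))),
        c=int(np.sum((xv == 1) & (yv == 0))),
        d=int(np.sum((xv == 0) & (yv == 1))),
    )


def outbreak_similarity(
    x: AnnualBinarySeries, y: AnnualBinarySeries, period: StudyPeriod
) -> float:
    """Fraction of period years on which the two records agree, in [0, 1]."""
    a, b, c, d = pair_agreement_counts(x, y, period)
    return (a + b) / (a + b + c + d)


def climate_similarity(
    x: ClimateSeries, y: ClimateSeries, period: StudyPeriod
) -> float:
    """Negated mean annual absolute difference, <= 0 (0 iff identical)."""
    return -float(np.mean(np.abs(x.window(period) - y.window(period))))


def _pairwise(series, period, fn) -> PairwiseMatrix:
    ids = [s.region_id for s in series]
    n = len(series)
    vals = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = fn(series[i], series[j], period)
    return PairwiseMatrix(region_ids=ids, values=vals)


def outbreak_similarity_matrix(
    records: Sequence[AnnualBinarySeries], period: StudyPeriod
) -> PairwiseMatrix:
    return _pairwise(records, period, outbreak_similarity)


def climate_similarity_matrix(
    climate: Sequence[ClimateSeries], period: StudyPeriod
) -> PairwiseMatrix:
    return _pairwise(climate, period, climate_similarity)


def centroid_distances(regions: RegionSet) -> PairwiseMatrix:
    """Euclidean centroid-to-centroid distances (km) on the projected plane."""
    if regions.n < 2:
        raise ValueError("need at least two regions")
    diff = regions.coordinates[:, None, :] - regions.coordinates[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    off = ~np.eye(regions.n, dtype=bool)
    if np.any(d[off] == 0):
        warnings.warn("duplicate region coordinates (zero pairwise distance)")
    return PairwiseMatrix(region_ids=list(regions.region_ids), values=d)


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


def distance_decay_regression(
    similarity: PairwiseMatrix, distance: PairwiseMatrix
) -> RegressionResult:
    """OLS of pairwise similarity on pairwise distance (upper-triangle pairs)."""
    if similarity.region_ids != distance.region_ids:
        raise ValueError("matrices must share the same region set")
    y = similarity.upper_triangle()
    x = distance.upper_triangle()
    if len(x) < 3:
        raise ValueError("need at least three region pairs")
    if np.var(y) == 0:
        # constant similarity: distance explains nothing
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


class MantelResult(NamedTuple):
    r: float
    p: float
    n_perm: int


def _check_pair(A: PairwiseMatrix, B: PairwiseMatrix) -> None:
    if A.region_ids != B.region_ids:
        raise ValueError("matrices must share the same region set")
    if A.n < 4:
        raise ValueError("need at least four regions for a permutation null")


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    if np.std(u) == 0 or np.std(v) == 0:
        raise ValueError("zero variance in upper-triangle entries")
    return float(np.corrcoef(u, v)[0, 1])


def _count_extreme(r_obs: float, r_perm: np.ndarray, alternative: str) -> int:
    if alternative == "two-sided":
        return int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    if alternative == "greater":
        return int(np.sum(r_perm >= r_obs - 1e-12))
    if alternative == "less":
        return int(np.sum(r_perm <= r_obs + 1e-12))
    raise ValueError(f"unknown alternative {alternative!r}")


def mantel(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    n_perm: int = 10000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> MantelResult:
    """Mantel test: Pearson r over upper triangles, permutation p-value.

    Permutations relabel B's rows and columns simultaneously; the identity
    permutation is included in both the numerator and denominator, so
    p is in [1/(n_perm+1), 1].  Two-tailed on |r| by default.
    """
    _check_pair(A, B)
    a = A.upper_triangle()
    bmat = B.values.copy()
    np.fill_diagonal(bmat, 0.0)
    iu = np.triu_indices(A.n, k=1)
    r_obs = _pearson(a, bmat[iu])
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        p = rng.permutation(A.n)
        r_perm[k] = _pearson(a, bmat[np.ix_(p, p)][iu])
    p_val = (1 + _count_extreme(r_obs, r_perm, alternative)) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p_val, n_perm=n_perm)


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of y on [1, x] by least squares."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_mantel(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    C: PairwiseMatrix,
    n_perm: int = 10000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> MantelResult:
    """Partial Mantel test of A vs B controlling for C.

    Both A and B are residualized on C over the upper triangles; r is the
    Pearson correlation of the residuals.  The permutation null relabels the
    residualized-A matrix (rows and columns together).
    """
    _check_pair(A, B)
    _check_pair(A, C)
    iu = np.triu_indices(A.n, k=1)
    a, b, c = A.upper_triangle(), B.upper_triangle(), C.upper_triangle()
    res_a = _residualize(a, c)
    res_b = _residualize(b, c)
    if np.std(res_b) <= 1e-12 * max(1.0, float(np.std(b))):
        # B is an (numerically) exact affine function of C: nothing left
        return MantelResult(r=0.0, p=1.0, n_perm=n_perm)
    r_obs = _pearson(res_a, res_b)
    # symmetric matrix of residualized A for relabeling
    amat = np.zeros((A.n, A.n))
    amat[iu] = res_a
    amat += amat.T
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        p = rng.permutation(A.n)
        r_perm[k] = _pearson(amat[np.ix_(p, p)][iu], res_b)
    p_val = (1 + _count_extreme(r_obs, r_perm, alternative)) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p_val, n_perm=n_perm)
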