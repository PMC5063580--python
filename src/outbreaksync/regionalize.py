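"""Stand-to-region conversion of percent-of-trees outbreak series.

Stand-level reconstructions report, per year, the fraction of sampled trees
recording outbreak conditions.  A year belongs to a regional outbreak when it
lies in a run of at least ``min_run`` consecutive years in which at least
``threshold`` of the region's trees record an outbreak (defaults 40% and two
years).  Pooling across sites is tree-weighted: summed outbreak trees over
summed sampled trees, not a mean of site fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .records import AnnualBinarySeries, _read_matrix, _runs_of_ones

__all__ = ["PercentSeries", "read_percent_matrix", "regionalize", "pool_sites"]


@dataclass
class PercentSeries:
    """Fraction of trees recording outbreak per year, on contiguous years."""

    region_id: str
    first_year: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)) or not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError(f"series {self.region_id!r}: fractions must be in [0, 1]")


def read_percent_matrix(path) -> list[PercentSeries]:
    """Read a ``year,<region>,...`` CSV of fractions in [0, 1]."""
    return [
        PercentSeries(region_id=s.region_id, first_year=s.first_year, values=s.values)
        for s in _read_matrix(path, binary=False)
    ]


def regionalize(
    percent: PercentSeries, threshold: float = 0.40, min_run: int = 2
) -> AnnualBinarySeries:
    """Binary regional outbreak record from a pooled percent series.

    A year is an outbreak year iff it belongs to a maximal run of at least
    ``min_run`` consecutive years with fraction >= ``threshold`` (weak
    inequality, no rounding).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    above = (percent.values >= threshold).astype(np.int8)
    out = np.zeros_like(above)
    for i, j in _runs_of_ones(above):
        if j - i + 1 >= min_run:
            out[i : j + 1] = 1
    return AnnualBinarySeries(
        region_id=percent.region_id, first_year=percent.first_year, values=out
    )


def pool_sites(
    per_site_tree_counts: Mapping[str, tuple[Sequence[int], Sequence[int]]],
    region_id: str,
    first_year: int,
) -> PercentSeries:
    """Tree-weighted pooled outbreak fraction across sites.

    ``per_site_tree_counts`` maps site id to an ``(outbreak, total)`` pair of
    equal-length per-year tree counts.  The pooled fraction for a year is the
    sum of outbreak trees over the sum of sampled trees across sites; a year
    with zero sampled trees anywhere in the pool is an error.
    """
    if not per_site_tree_counts:
        raise ValueError("no sites given")
    outbreak = None
    total = None
    for site, (o, t) in per_site_tree_counts.items():
        o = np.asarray(o, dtype=float)
        t = np.asarray(t, dtype=float)
        if o.shape != t.shape:
            raise ValueError(f"site {site!r}: outbreak/total length mismatch")
        if np.any(o < 0) or np.any(t < o):
            raise ValueError(f"site {site!r}: need 0 <= outbreak <= total")
        outbreak = o if outbreak is None else outbreak + o
        total = t if total is None else total + t
    if np.any(total <= 0):
        year = first_year + int(np.flatnonzero(total <= 0)[0])
        raise ValueError(f"no trees sampled in year {year}")
    return PercentSeries(region_id=region_id, first_year=first_year, values=outbreak / total)
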