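"""Annual outbreak and climate records: data model, CSV I/O, episodes.

The analysis operates on three kinds of inputs, all defined on contiguous
calendar years:

* binary outbreak-status series (one per region, values in {0, 1}),
* real-valued drought-index series (e.g. summer PDSI, one per region),
* region centroid coordinates on a common projected plane, in km.

Matrices are exchanged as CSV with a leading ``year`` column and one column
per region.  Leading/trailing missing cells are allowed (records of unequal
length) and are trimmed per region; internal gaps are rejected because every
downstream statistic assumes contiguous annual coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyPeriod",
    "AnnualBinarySeries",
    "ClimateSeries",
    "RegionSet",
    "Episode",
    "EpisodeSummary",
    "FormatError",
    "read_binary_matrix",
    "read_climate_matrix",
    "write_binary_matrix",
    "write_climate_matrix",
    "read_region_set",
    "write_region_set",
    "common_period",
    "extract_episodes",
    "episodes_to_series",
    "summarize_episodes",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected matrix layout."""


@dataclass(frozen=True)
class StudyPeriod:
    """A closed interval of calendar years, ``[start_year, end_year]``.

    ``n`` is the inclusive year count; the seven-region compilation shares
    a 291-year common period (1700-1990).
    """

    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError(
                f"start_year {self.start_year} exceeds end_year {self.end_year}"
            )

    @property
    def n(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def __contains__(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year


@dataclass
class _AnnualSeries:
    """One region's annual record on contiguous calendar years."""

    region_id: str
    first_year: int
    values: np.ndarray

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.values) - 1

    @property
    def period(self) -> StudyPeriod:
        return StudyPeriod(self.first_year, self.last_year)

    def covers(self, period: StudyPeriod) -> bool:
        return self.first_year <= period.start_year and self.last_year >= period.end_year

    def window(self, period: StudyPeriod) -> np.ndarray:
        """Values restricted to ``period`` (which the series must cover)."""
        if not self.covers(period):
            raise ValueError(
                f"series {self.region_id!r} ({self.first_year}-{self.last_year}) "
                f"does not cover {period.start_year}-{period.end_year}"
            )
        i = period.start_year - self.first_year
        return self.values[i : i + period.n]


@dataclass
class AnnualBinarySeries(_AnnualSeries):
    """Binary outbreak status per year (1 = outbreak conditions recorded)."""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            raise ValueError(
                f"series {self.region_id!r}: non-binary value at year "
                f"{self.first_year + int(np.flatnonzero(bad)[0])}"
            )


@dataclass
class ClimateSeries(_AnnualSeries):
    """Real-valued annual drought index (negative = warmer/drier)."""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"series {self.region_id!r}: non-finite values")


@dataclass
class RegionSet:
    """Region labels with projected centroid coordinates in km."""

    region_ids: list[str]
    coordinates: np.ndarray  # shape (n_regions, 2): (east_km, north_km)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("duplicate region ids")
        if self.coordinates.shape != (len(self.region_ids), 2):
            raise ValueError("coordinates must be (n_regions, 2)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")

    @property
    def n(self) -> int:
        return len(self.region_ids)


@dataclass(frozen=True)
class Episode:
    """A maximal run of consecutive outbreak years, inclusive on both ends."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"episode start {self.start} exceeds end {self.end}")

    @property
    def duration(self) -> int:
        """Inclusive duration in years (``end - start + 1``)."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class EpisodeSummary:
    """Count and duration/gap means for an episode list.

    ``mean_quiescent`` averages the gaps strictly *between* consecutive
    episodes (``next.start - prev.end - 1``); margins before the first and
    after the last episode are not counted.  It is NaN for fewer than two
    episodes, as is ``mean_duration`` for an empty list.
    """

    n_episodes: int
    mean_duration: float
    mean_quiescent: float


# ---------------------------------------------------------------------------
# CSV I/O


def _read_matrix(path, *, binary: bool) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2 or df.columns[0] != "year":
        raise FormatError(f"{path}: expected header 'year,<region_id>,...'")
    years = df["year"].to_numpy()
    if not np.issubdtype(years.dtype, np.integer):
        raise FormatError(f"{path}: year column must be integer")
    if len(years) == 0:
        raise FormatError(f"{path}: no data rows")
    if np.any(np.diff(years) != 1):
        i = int(np.flatnonzero(np.diff(years) != 1)[0])
        raise FormatError(
            f"{path}: years must be consecutive ascending; gap after {years[i]}"
        )
    out = []
    cls = AnnualBinarySeries if binary else ClimateSeries
    for col in df.columns[1:]:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        raw_na = df[col].isna().to_numpy()
        bad_parse = np.isnan(vals) & ~raw_na
        if bad_parse.any():
            i = int(np.flatnonzero(bad_parse)[0])
            raise FormatError(
                f"{path}: non-numeric cell at year {years[i]}, column {col!r}"
            )
        present = ~np.isnan(vals)
        if not present.any():
            raise FormatError(f"{path}: column {col!r} is entirely empty")
        lo, hi = int(np.argmax(present)), len(vals) - int(np.argmax(present[::-1]))
        if np.isnan(vals[lo:hi]).any():
            i = lo + int(np.flatnonzero(np.isnan(vals[lo:hi]))[0])
            raise FormatError(
                f"{path}: internal gap at year {years[i]}, column {col!r} "
                "(only leading/trailing years may be missing)"
            )
        trimmed = vals[lo:hi]
        if binary and not np.isin(trimmed, (0.0, 1.0)).all():
            i = lo + int(np.flatnonzero(~np.isin(trimmed, (0.0, 1.0)))[0])
            raise FormatError(
                f"{path}: non-binary cell {df[col].iloc[i]!r} at year {years[i]}, "
                f"column {col!r}"
            )
        out.append(cls(region_id=str(col), first_year=int(years[lo]), values=trimmed))
    return out


def read_binary_matrix(path) -> list[AnnualBinarySeries]:
    """Read a ``year,<region>,...`` CSV of {0,1} cells into binary series.

    Leading/trailing empty cells per region are trimmed; internal gaps or
    non-binary cells raise :class:`FormatError` naming the offending cell.
    """
    return _read_matrix(path, binary=True)


def read_climate_matrix(path) -> list[ClimateSeries]:
    """Read a ``year,<region>,...`` CSV of real-valued cells."""
    return _read_matrix(path, binary=False)


def _write_matrix(series: Sequence[_AnnualSeries], path, fmt) -> None:
    start = min(s.first_year for s in series)
    end = max(s.last_year for s in series)
    years = np.arange(start, end + 1)
    df = pd.DataFrame({"year": years})
    for s in series:
        col = np.full(len(years), np.nan)
        col[s.first_year - start : s.first_year - start + len(s.values)] = s.values
        df[s.region_id] = col
    with open(path, "w") as fh:
        fh.write(",".join(df.columns) + "\n")
        for _, row in df.iterrows():
            cells = [str(int(row["year"]))]
            for s in series:
                v = row[s.region_id]
                cells.append("" if np.isnan(v) else fmt(v))
            fh.write(",".join(cells) + "\n")


def write_binary_matrix(series: Sequence[AnnualBinarySeries], path) -> None:
    _write_matrix(series, path, lambda v: str(int(v)))


def write_climate_matrix(series: Sequence[ClimateSeries], path) -> None:
    _write_matrix(series, path, lambda v: repr(float(v)))


def read_region_set(path) -> RegionSet:
    """Read ``region_id,east_km,north_km`` CSV into a :class:`RegionSet`."""
    df = pd.read_csv(path)
    expected = ["region_id", "east_km", "north_km"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected header {','.join(expected)}")
    return RegionSet(
        region_ids=[str(r) for r in df["region_id"]],
        coordinates=df[["east_km", "north_km"]].to_numpy(dtype=float),
    )


def write_region_set(regions: RegionSet, path) -> None:
    pd.DataFrame(
        {
            "region_id": regions.region_ids,
            "east_km": regions.coordinates[:, 0],
            "north_km": regions.coordinates[:, 1],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Periods and episodes


def common_period(series: Iterable[_AnnualSeries]) -> StudyPeriod:
    """Largest period covered by every series (intersection of spans)."""
    series = list(series)
    if not series:
        raise ValueError("no series given")
    start = max(s.first_year for s in series)
    end = min(s.last_year for s in series)
    if start > end:
        raise ValueError(f"series share no common period ({start} > {end})")
    return StudyPeriod(start, end)


def _runs_of_ones(values: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of 1s as (start_index, end_index) inclusive pairs."""
    padded = np.concatenate(([0], np.asarray(values, dtype=np.int8), [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def extract_episodes(series: AnnualBinarySeries, period: StudyPeriod) -> list[Episode]:
    """Maximal runs of outbreak years within ``period``, as inclusive episodes."""
    vals = series.window(period)
    return [
        Episode(period.start_year + i, period.start_year + j)
        for i, j in _runs_of_ones(vals)
    ]


def episodes_to_series(
    episodes: Sequence[Episode], period: StudyPeriod, region_id: str = "episodes"
) -> AnnualBinarySeries:
    """Inverse of :func:`extract_episodes`: paint episodes onto a binary series."""
    vals = np.zeros(period.n, dtype=np.int8)
    for ep in episodes:
        if ep.start < period.start_year or ep.end > period.end_year:
            raise ValueError(f"episode {ep.start}-{ep.end} outside period")
        vals[ep.start - period.start_year : ep.end - period.start_year + 1] = 1
    return AnnualBinarySeries(region_id=region_id, first_year=period.start_year, values=vals)


def summarize_episodes(episodes: Sequence[Episode]) -> EpisodeSummary:
    """Episode count, mean inclusive duration, and mean internal quiescent gap."""
    eps = sorted(episodes, key=lambda e: e.start)
    n = len(eps)
    if n == 0:
        return EpisodeSummary(0, float("nan"), float("nan"))
    mean_dur = float(np.mean([e.duration for e in eps]))
    if n < 2:
        return EpisodeSummary(n, mean_dur, float("nan"))
    gaps = [nxt.start - prev.end - 1 for prev, nxt in zip(eps, eps[1:])]
    return EpisodeSummary(n, mean_dur, float(np.mean(gaps)))
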