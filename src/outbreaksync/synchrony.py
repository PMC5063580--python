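"""Detection of synchronous outbreak periods across regions.

A synchronous period is a span in which at least ``min_regions`` regions are
simultaneously in outbreak for at least ``min_run`` consecutive years (the
compilation used 3 of 7 regions and 2 years).  Periods separated by at most
``max_bridge`` sub-threshold years can optionally be merged; by default no
merging is done.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .records import AnnualBinarySeries, StudyPeriod, _runs_of_ones

__all__ = [
    "SynchronyCounts",
    "SynchronousPeriod",
    "count_regions",
    "detect_synchronous_periods",
    "period_table",
    "fraction_years_with_at_least",
]


@dataclass
class SynchronyCounts:
    """Per-year count of regions in outbreak over a study period."""

    period: StudyPeriod
    counts: np.ndarray  # shape (period.n,)
    n_regions: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.period.n:
            raise ValueError("counts length must equal period length")
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.n_regions:
            raise ValueError("counts must lie in [0, n_regions]")


@dataclass(frozen=True)
class SynchronousPeriod:
    """An inclusive span of region-synchronous outbreak years.

    ``participants`` are the regions recording an outbreak in at least one
    year of the span.  ``truncated`` flags periods cut off by the study
    period boundary (still in progress at a record's end).
    """

    start: int
    end: int
    participants: frozenset[str]
    truncated: bool = False

    @property
    def duration(self) -> int:
        return self.end - self.start + 1


def count_regions(
    records: Sequence[AnnualBinarySeries], period: StudyPeriod
) -> SynchronyCounts:
    """Number of regions in outbreak status per year of ``period``."""
    if not records:
        raise ValueError("no records given")
    mat = np.stack([r.window(period) for r in records])
    return SynchronyCounts(period=period, counts=mat.sum(axis=0), n_regions=len(records))


def detect_synchronous_periods(
    counts: SynchronyCounts,
    records: Sequence[AnnualBinarySeries],
    min_regions: int = 3,
    min_run: int = 2,
    max_bridge: int = 0,
) -> list[SynchronousPeriod]:
    """Maximal runs of years with at least ``min_regions`` regions in outbreak.

    Runs separated by at most ``max_bridge`` sub-threshold years are merged
    (bridge years count toward the merged span); merged runs shorter than
    ``min_run`` are discarded.  Participants are computed over the merged
    span.  Periods touching the study-period boundary are flagged truncated.
    """
    if min_regions < 1 or min_run < 1 or max_bridge < 0:
        raise ValueError("min_regions, min_run >= 1 and max_bridge >= 0 required")
    period = counts.period
    above = (counts.counts >= min_regions).astype(np.int8)
    runs = _runs_of_ones(above)
    # merge runs separated by <= max_bridge below-threshold years
    merged: list[list[int]] = []
    for i, j in runs:
        if merged and i - merged[-1][1] - 1 <= max_bridge:
            merged[-1][1] = j
        else:
            merged.append([i, j])
    out = []
    for i, j in merged:
        if j - i + 1 < min_run:
            continue
        start = period.start_year + i
        end = period.start_year + j
        members = frozenset(
            r.region_id
            for r in records
            if r.window(StudyPeriod(start, end)).any()
        )
        out.append(
            SynchronousPeriod(
                start=start,
                end=end,
                participants=members,
                truncated=(start == period.start_year or end == period.end_year),
            )
        )
    return out


def period_table(periods: Sequence[SynchronousPeriod]) -> pd.DataFrame:
    """Tabulate periods (sorted by start) with semicolon-joined participants."""
    rows = [
        {
            "start": p.start,
            "end": p.end,
            "duration": p.duration,
            "participants": ";".join(sorted(p.participants)),
            "truncated": p.truncated,
        }
        for p in sorted(periods, key=lambda p: p.start)
    ]
    return pd.DataFrame(
        rows, columns=["start", "end", "duration", "participants", "truncated"]
    )


def fraction_years_with_at_least(counts: SynchronyCounts, k: int) -> tuple[int, float]:
    """Count and fraction of period years with at least ``k`` regions in outbreak."""
    if not 1 <= k <= counts.n_regions:
        raise ValueError(f"k must be in [1, {counts.n_regions}]")
    n_years = int((counts.counts >= k).sum())
    return n_years, n_years / counts.period.n
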