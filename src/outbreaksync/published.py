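"""Published western spruce budworm synchrony reference data.

The compilation study printed its full table of 13 synchronous outbreak
periods (1700-1990 common period, seven regions) and per-region summary
statistics of the underlying reconstructions.  The regional annual records
themselves were not deposited, so the period table and the per-region
summaries are the reproducible published inputs; they are encoded here
verbatim for use as worked-example inputs and calibration anchors.

Region codes: BC = central British Columbia, WA = northern Washington,
MT = western Montana / eastern Idaho, ID = western Idaho / northeastern
Oregon, OR = north-central Oregon, CO = southern Colorado, NM = northern
New Mexico.
"""

from __future__ import annotations

from .records import Episode, StudyPeriod
from .synchrony import SynchronousPeriod

__all__ = [
    "REGIONS",
    "NORTHWEST_REGIONS",
    "SOUTHWEST_REGIONS",
    "COMMON_PERIOD",
    "SYNCHRONOUS_PERIODS",
    "REGIONAL_SUMMARIES",
]

REGIONS = ("BC", "WA", "MT", "ID", "OR", "CO", "NM")
NORTHWEST_REGIONS = ("BC", "WA", "MT", "ID", "OR")
SOUTHWEST_REGIONS = ("CO", "NM")

#: Common period shared by all seven regional reconstructions.
COMMON_PERIOD = StudyPeriod(1700, 1990)

#: The 13 published synchronous outbreak periods: (start, end, participants).
#: A synchronous period is one in which at least three of the seven regions
#: were in outbreak for at least two consecutive years; participants are the
#: regions recording an outbreak in at least one year of the period.  The
#: last period is truncated by the end of the New Mexico record in 1990.
_TABLE = [
    (1702, 1703, ("BC", "MT", "CO")),
    (1715, 1733, ("BC", "WA", "MT", "ID", "OR", "CO", "NM")),
    (1743, 1776, ("BC", "WA", "MT", "ID", "OR", "CO", "NM")),
    (1785, 1805, ("BC", "WA", "MT", "ID", "OR", "CO", "NM")),
    (1810, 1820, ("BC", "WA", "MT", "CO", "NM")),
    (1824, 1838, ("WA", "MT", "OR", "CO", "NM")),
    (1844, 1845, ("ID", "OR", "CO")),
    (1849, 1855, ("MT", "ID", "OR", "CO")),
    (1871, 1878, ("WA", "MT", "ID", "OR", "CO", "NM")),
    (1891, 1934, ("BC", "WA", "MT", "ID", "OR", "CO", "NM")),
    (1938, 1955, ("BC", "WA", "MT", "ID", "OR", "NM")),
    (1960, 1963, ("WA", "MT", "OR", "CO")),
    (1975, 1990, ("BC", "WA", "MT", "ID", "OR", "CO", "NM")),
]

SYNCHRONOUS_PERIODS = [
    SynchronousPeriod(
        start=s,
        end=e,
        participants=frozenset(p),
        truncated=(e == COMMON_PERIOD.end_year),
    )
    for s, e, p in _TABLE
]

#: Published per-region reconstruction summaries over 1700-1990:
#: (number of outbreaks, mean duration in years, mean quiescent gap in years).
#: Reference values only -- the underlying annual records are not deposited,
#: so these cannot be recomputed here; they calibrate the synthetic scenarios.
REGIONAL_SUMMARIES = {
    "BC": (8, 12.6, 28.3),
    "WA": (14, 8.1, 13.1),
    "MT": (14, 12.0, 8.8),
    "ID": (11, 10.3, 15.7),
    "OR": (15, 7.8, 11.0),
    "CO": (8, 28.7, 9.7),
    "NM": (11, 13.8, 13.5),
}


def synchronous_episodes() -> list[Episode]:
    """The published synchronous periods as plain episodes."""
    return [Episode(p.start, p.end) for p in SYNCHRONOUS_PERIODS]
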