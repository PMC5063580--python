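"""Superposed epoch analysis of drought indices around outbreak events.

Compositing a climate-anomaly series across a set of event years at fixed
lags (default -5..+5 years) reveals the average pre-/post-event moisture
anomaly; significance of each lag's composite is assessed against Monte
Carlo draws of equally many random event years.  Complemented by Welch
t-tests comparing index values between year groups (synchronous-outbreak
years vs others; the five pre-initiation years vs others).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import ClimateSeries, StudyPeriod
from .synchrony import SynchronousPeriod

__all__ = [
    "ClimateIndex",
    "SEAComposite",
    "build_index",
    "compute_anomalies",
    "sea",
    "pre_event_years",
    "welch_t",
    "WelchResult",
    "group_comparisons",
]


@dataclass
class ClimateIndex:
    """Unweighted per-year mean drought index over member regions."""

    label: str
    members: list[str]
    first_year: int
    values: np.ndarray

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.values) - 1

    def window(self, period: StudyPeriod) -> np.ndarray:
        if self.first_year > period.start_year or self.last_year < period.end_year:
            raise ValueError(f"index {self.label!r} does not cover the period")
        i = period.start_year - self.first_year
        return self.values[i : i + period.n]


@dataclass
class SEAComposite:
    """Mean anomaly per lag with Monte-Carlo confidence band."""

    lags: np.ndarray
    composite: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray
    n_events: int
    n_boot: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lags,
                "composite": self.composite,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "significant": self.significant,
            }
        )


def build_index(
    climate: Sequence[ClimateSeries], members: Sequence[str], label: str = "index"
) -> ClimateIndex:
    """Average the member regions' series over their shared year span."""
    if not members:
        raise ValueError("empty member list")
    by_id = {s.region_id: s for s in climate}
    missing = [m for m in members if m not in by_id]
    if missing:
        raise ValueError(f"unknown member regions: {missing}")
    chosen = [by_id[m] for m in members]
    start = max(s.first_year for s in chosen)
    end = min(s.last_year for s in chosen)
    if start > end:
        raise ValueError("member series share no common years")
    span = StudyPeriod(start, end)
    vals = np.mean([s.window(span) for s in chosen], axis=0)
    return ClimateIndex(label=label, members=list(members), first_year=start, values=vals)


def compute_anomalies(index: ClimateIndex, period: StudyPeriod) -> np.ndarray:
    """Index values over ``period`` minus the full-period mean (no detrending)."""
    vals = index.window(period)
    return vals - vals.mean()


def _composite(
    anom: np.ndarray, event_idx: np.ndarray, lags: np.ndarray, require_full: bool
) -> np.ndarray:
    """Mean anomaly per lag over events; lags outside the record are skipped.

    ``event_idx`` may be 2-D (draws x events); returns (draws x lags) then.
    """
    idx = np.atleast_2d(event_idx)
    n = len(anom)
    if require_full:
        ok = (idx.min(axis=1) + lags.min() >= 0) & (idx.max(axis=1) + lags.max() < n)
        if not ok.all():
            raise ValueError("an event window crosses the period boundary")
    out = np.empty((idx.shape[0], len(lags)))
    for j, lag in enumerate(lags):
        pos = idx + lag
        valid = (pos >= 0) & (pos < n)
        vals = np.where(valid, anom[np.clip(pos, 0, n - 1)], 0.0)
        cnt = valid.sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[:, j] = np.where(cnt > 0, vals.sum(axis=1) / np.maximum(cnt, 1), np.nan)
    return out if event_idx.ndim == 2 else out[0]


def sea(
    anomalies: np.ndarray,
    events: Sequence[int],
    period: StudyPeriod,
    lags: Sequence[int] = range(-5, 6),
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    require_full_window: bool = False,
) -> SEAComposite:
    """Superposed epoch composite with Monte-Carlo confidence intervals.

    The null distribution per lag comes from ``n_boot`` draws of
    ``len(events)`` years sampled uniformly without replacement from all
    period years, composited identically; a lag is significant when the
    observed composite falls outside the (alpha/2, 1-alpha/2) percentiles.
    Event lags that fall outside the period are skipped unless
    ``require_full_window`` is set, in which case they are an error.
    """
    events = np.asarray(sorted(events), dtype=np.int64)
    if len(events) == 0:
        raise ValueError("no events given")
    if events[0] < period.start_year or events[-1] > period.end_year:
        raise ValueError("events must fall inside the study period")
    anom = np.asarray(anomalies, dtype=float)
    if len(anom) != period.n:
        raise ValueError("anomaly series length must equal the period length")
    lags = np.asarray(list(lags), dtype=np.int64)
    idx = events - period.start_year
    obs = _composite(anom, idx, lags, require_full_window)

    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, len(events)), dtype=np.int64)
    for b in range(n_boot):
        draws[b] = rng.choice(period.n, size=len(events), replace=False)
    null = _composite(anom, draws, lags, require_full=False)
    lo, hi = np.nanpercentile(null, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    return SEAComposite(
        lags=lags,
        composite=obs,
        ci_low=lo,
        ci_high=hi,
        significant=(obs < lo) | (obs > hi),
        n_events=len(events),
        n_boot=n_boot,
    )


def pre_event_years(
    periods: Sequence[SynchronousPeriod], period: StudyPeriod, k: int = 5
) -> np.ndarray:
    """Deduplicated union of the k years preceding each period start."""
    if k < 1:
        raise ValueError("k must be >= 1")
    years: set[int] = set()
    for p in periods:
        years.update(
            y for y in range(p.start - k, p.start) if period.start_year <= y <= period.end_year
        )
    return np.array(sorted(years), dtype=np.int64)


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t-test, two-tailed.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(len(a) + len(b) - 2), p=1.0)
        raise ValueError("both samples degenerate (zero variance)")
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def group_comparisons(
    index: ClimateIndex,
    periods: Sequence[SynchronousPeriod],
    period: StudyPeriod,
    k: int = 5,
    exclude_pre_years_in_periods: bool = False,
) -> pd.DataFrame:
    """The two published contrasts as Welch t-tests on index values.

    Contrast ``synchronous_vs_other``: years inside synchronous periods vs
    all other period years.  Contrast ``pre_initiation_vs_other``: the k
    years preceding each period start vs all other years.  Pre-initiation
    years falling inside another synchronous period are kept by default
    (``exclude_pre_years_in_periods`` drops them).
    """
    vals = index.window(period)
    years = period.years
    in_period = np.zeros(period.n, dtype=bool)
    for p in periods:
        in_period[(years >= p.start) & (years <= p.end)] = True
    pre = np.isin(years, pre_event_years(periods, period, k=k))
    if exclude_pre_years_in_periods:
        pre &= ~in_period

    rows = []
    for name, mask in [
        ("synchronous_vs_other", in_period),
        ("pre_initiation_vs_other", pre),
    ]:
        g1, g2 = vals[mask], vals[~mask]
        if len(g1) == 0 or len(g2) == 0:
            raise ValueError(f"contrast {name!r}: empty group")
        res = welch_t(g1, g2)
        rows.append(
            {
                "contrast": name,
                "n_group": len(g1),
                "n_other": len(g2),
                "mean_group": g1.mean(),
                "sd_group": g1.std(ddof=1),
                "mean_other": g2.mean(),
                "sd_other": g2.std(ddof=1),
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
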