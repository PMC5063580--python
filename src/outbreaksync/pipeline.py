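"""End-to-end orchestration of the synchrony analysis.

``run_all`` sequences the full analysis on a set of input CSVs: synchronous
period detection, the three Ripley's-K event analyses with circular-shift
envelopes, similarity/distance matrices with decay regressions and Mantel
tests, and superposed epoch analyses of the regional drought indices around
period initiations and cessations, plus the two Welch-t group contrasts.
All randomness flows from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import epoch, published, ripley, similarity, synchrony
from .records import (
    StudyPeriod,
    common_period,
    read_binary_matrix,
    read_climate_matrix,
    read_region_set,
)

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("outbreaksync")


@dataclass
class RunConfig:
    """Inputs and parameters for a full pipeline run."""

    binary_path: str
    climate_path: str
    geometry_path: str
    out_dir: str
    start_year: int | None = None
    end_year: int | None = None
    min_regions: int = 3
    min_run: int = 2
    max_bridge: int = 0
    t_max: int = 25
    n_sim: int = 1000
    n_perm: int = 10000
    n_boot: int = 1000
    alpha: float = 0.05
    seed: int = 0
    northwest: list[str] = field(default_factory=list)
    southwest: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("min_regions", "min_run", "t_max", "n_sim", "n_perm", "n_boot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.max_bridge < 0:
            raise ValueError("max_bridge must be >= 0")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")


def _write_matrix_csv(m: similarity.PairwiseMatrix, path: Path) -> None:
    df = pd.DataFrame(m.values, index=m.region_ids, columns=m.region_ids)
    df.to_csv(path, index_label="region_id")


def _stage(name: str):
    log.info("stage: %s", name)


def run_all(config: RunConfig) -> dict:
    """Run every analysis stage; returns the machine-readable summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("run parameters: %s", dataclasses.asdict(config))
    rng = np.random.default_rng(config.seed)

    def stage_seed() -> int:
        return int(rng.integers(2**31))

    try:
        _stage("read inputs")
        records = read_binary_matrix(config.binary_path)
        climate = read_climate_matrix(config.climate_path)
        regions = read_region_set(config.geometry_path)
        period = common_period(list(records) + list(climate))
        if config.start_year is not None or config.end_year is not None:
            period = StudyPeriod(
                config.start_year or period.start_year,
                config.end_year or period.end_year,
            )
        log.info("study period %d-%d (%d yr)", period.start_year, period.end_year, period.n)

        _stage("synchronous period detection")
        counts = synchrony.count_regions(records, period)
        periods = synchrony.detect_synchronous_periods(
            counts,
            records,
            min_regions=config.min_regions,
            min_run=config.min_run,
            max_bridge=config.max_bridge,
        )
        table = synchrony.period_table(periods)
        table.to_csv(out / "periods.csv", index=False)
        n_at_least, frac = synchrony.fraction_years_with_at_least(counts, config.min_regions)

        _stage("Ripley K analyses")
        ripley_significant = {}
        for event_type in ripley.EVENT_TYPES:
            res = ripley.circular_envelope(
                records,
                event_type,
                t_max=config.t_max,
                period=period,
                n_sim=config.n_sim,
                alpha=config.alpha,
                seed=stage_seed(),
            )
            pd.DataFrame(
                {
                    "t": res.t,
                    "K": res.k,
                    "L": res.l,
                    "env_low": res.envelope_low,
                    "env_high": res.envelope_high,
                    "significant": res.significant,
                }
            ).to_csv(out / f"ripley_{event_type}.csv", index=False)
            ripley_significant[event_type] = res.t[res.significant].tolist()

        _stage("similarity and Mantel analyses")
        sim_ob = similarity.outbreak_similarity_matrix(records, period)
        sim_cl = similarity.climate_similarity_matrix(climate, period)
        dist = similarity.centroid_distances(regions)
        # align every matrix to the outbreak-record region order
        for name, m in [("climate", sim_cl), ("geometry", dist)]:
            if sorted(m.region_ids) != sorted(sim_ob.region_ids):
                raise ValueError(f"{name} and outbreak region sets differ")
        def _reorder(m: similarity.PairwiseMatrix) -> similarity.PairwiseMatrix:
            if m.region_ids == sim_ob.region_ids:
                return m
            perm = [m.region_ids.index(r) for r in sim_ob.region_ids]
            return similarity.PairwiseMatrix(
                region_ids=list(sim_ob.region_ids),
                values=m.values[np.ix_(perm, perm)],
            )
        sim_cl = _reorder(sim_cl)
        dist = _reorder(dist)
        _write_matrix_csv(sim_ob, out / "outbreak_similarity.csv")
        _write_matrix_csv(sim_cl, out / "climate_similarity.csv")
        _write_matrix_csv(dist, out / "distance_km.csv")

        reg_ob = similarity.distance_decay_regression(sim_ob, dist)
        reg_cl = similarity.distance_decay_regression(sim_cl, dist)
        tests = {
            "outbreak_vs_distance": similarity.mantel(
                sim_ob, dist, n_perm=config.n_perm, seed=stage_seed()
            ),
            "climate_vs_distance": similarity.mantel(
                sim_cl, dist, n_perm=config.n_perm, seed=stage_seed()
            ),
            "outbreak_vs_climate": similarity.mantel(
                sim_ob, sim_cl, n_perm=config.n_perm, seed=stage_seed()
            ),
            "outbreak_vs_climate_given_distance": similarity.partial_mantel(
                sim_ob, sim_cl, dist, n_perm=config.n_perm, seed=stage_seed()
            ),
            "outbreak_vs_distance_given_climate": similarity.partial_mantel(
                sim_ob, dist, sim_cl, n_perm=config.n_perm, seed=stage_seed()
            ),
        }
        pd.DataFrame(
            [
                {"test": k, "r": v.r, "p": v.p, "n_perm": v.n_perm}
                for k, v in tests.items()
            ]
        ).to_csv(out / "mantel_tests.csv", index=False)

        _stage("superposed epoch analyses")
        available = {c.region_id for c in climate}
        nw = config.northwest or [r for r in published.NORTHWEST_REGIONS if r in available]
        sw = config.southwest or [r for r in published.SOUTHWEST_REGIONS if r in available]
        indices = {"all": epoch.build_index(climate, sorted(available), label="all")}
        if nw:
            indices["northwest"] = epoch.build_index(climate, nw, label="northwest")
        if sw:
            indices["southwest"] = epoch.build_index(climate, sw, label="southwest")
        initiations = [p.start for p in periods]
        cessations = [p.end for p in periods]
        sea_summary = {}
        comparisons = []
        for label, index in indices.items():
            anom = epoch.compute_anomalies(index, period)
            for ev_name, events in [("initiations", initiations), ("cessations", cessations)]:
                comp = epoch.sea(
                    anom,
                    events,
                    period,
                    n_boot=config.n_boot,
                    alpha=config.alpha,
                    seed=stage_seed(),
                )
                comp.to_frame().to_csv(out / f"sea_{ev_name}_{label}.csv", index=False)
                sea_summary[f"{ev_name}_{label}"] = comp.lags[comp.significant].tolist()
            gc = epoch.group_comparisons(index, periods, period)
            gc.insert(0, "index", label)
            comparisons.append(gc)
        pd.concat(comparisons).to_csv(out / "group_comparisons.csv", index=False)

        summary = {
            "period": [period.start_year, period.end_year],
            "n_regions": len(records),
            "n_synchronous_periods": len(periods),
            "mean_synchronous_duration": (
                float(table["duration"].mean()) if len(table) else None
            ),
            "years_with_min_regions": n_at_least,
            "fraction_years_with_min_regions": frac,
            "ripley_significant_windows": ripley_significant,
            "distance_decay": {
                "outbreak_r_squared": reg_ob.r_squared,
                "climate_r_squared": reg_cl.r_squared,
            },
            "mantel": {k: {"r": v.r, "p": v.p} for k, v in tests.items()},
            "sea_significant_lags": sea_summary,
            "seed": config.seed,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        return summary
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
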