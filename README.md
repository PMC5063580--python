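# outbreaksync

Spatial-synchrony analysis of multi-century, annually resolved binary
outbreak records — built around the western spruce budworm (*Choristoneura
occidentalis*), a defoliator whose outbreaks have been reconstructed from
host/non-host tree-ring comparisons in seven regions of western North
America over the 1700–1990 common period.  The package is for
dendroecologists and population ecologists who want to ask, for this or any
comparable multi-region binary disturbance record: *do outbreaks cluster in
time across regions, does that synchrony decay with distance, and is it
driven by spatially autocorrelated climate (the Moran effect)?*

## What it computes

Given per-region annual binary outbreak series `x_i(t) ∈ {0,1}`, drought
index series (e.g. summer PDSI) and region centroids:

- **Synchronous periods** — maximal runs of ≥ `min_run` (default 2)
  consecutive years in which at least `min_regions` (default 3) regions are
  simultaneously in outbreak, with participant sets and Table-style
  summaries (episode durations are inclusive, `end − start + 1`; quiescent
  gaps are counted strictly between episodes).
- **1-D multivariate Ripley's K** for discrete outbreak events (outbreak
  years, episode initiations, cessations):
  `K̂_ab(t) = n/(n_a n_b) · #{(u,v) : |u−v| ≤ t}`, pooled over all region
  pairs, with the L-transform `L(t) = (K̂(t) − (2t+1))/2` so that `E[L] ≈ 0`
  under independence.  Significance comes from circular-shift surrogates:
  each region's record is rotated by a random offset with wraparound,
  preserving within-region temporal structure while destroying cross-region
  alignment.
- **Similarity / distance-decay / Mantel** — outbreak similarity
  `(a+b)/(a+b+c+d)` (fraction of years with matching status), climate
  similarity `−(1/n) Σ_t |x_t − y_t|`, centroid distances, OLS distance-decay
  regressions, and Mantel / partial Mantel permutation tests over
  simultaneous row/column relabelings (10,000 permutations by default).
- **Superposed epoch analysis (SEA)** — drought-index anomalies composited
  over lags −5..+5 around synchronous-period initiations and cessations,
  with Monte-Carlo confidence bands from random event-year draws, plus
  Welch t contrasts (synchronous vs other years; the five pre-initiation
  years vs other years).
- **A calibrated synthetic-data generator** — spatially correlated Gaussian
  climate (exponential distance decay, optional northwest/southwest
  anticorrelated "dipole", optional AR(1) persistence) driving per-region
  two-state renewal outbreak processes whose initiation probability is
  concentrated in drought-then-release years by a tunable forcing strength
  β; β = 0 gives climate-independent, mutually independent regions.

## Worked example

```python
import outbreaksync as ob
from outbreaksync.synchrony import period_table

cfg = ob.paper_layout(seed=11)          # 7 regions, 1700-1990, strong forcing
climate = ob.gen_climate(cfg)
records = ob.gen_outbreaks(climate, cfg, seed=12)
period = cfg.period

counts = ob.count_regions(records, period)
periods = ob.detect_synchronous_periods(counts, records)
print(period_table(periods).head(5).to_string(index=False))

res = ob.circular_envelope(records, "initiations", t_max=25, period=period,
                           n_sim=1000, seed=13)
print("significant windows (initiations):", res.t[res.significant].tolist())

sim_ob = ob.outbreak_similarity_matrix(records, period)
sim_cl = ob.climate_similarity_matrix(climate, period)
dist = ob.centroid_distances(cfg.region_set())
pm = ob.partial_mantel(sim_ob, sim_cl, dist, n_perm=10000, seed=14,
                       alternative="greater")
print(f"partial Mantel (outbreak ~ climate | distance): r = {pm.r:.2f}, p = {pm.p:.4f}")
```

prints

```
 start  end  duration         participants  truncated
  1700 1718        19 BC;CO;ID;MT;NM;OR;WA       True
  1723 1743        21 BC;CO;ID;MT;NM;OR;WA      False
  1749 1750         2             CO;NM;WA      False
  1752 1756         5             CO;NM;WA      False
  1766 1776        11    CO;ID;MT;NM;OR;WA      False
significant windows (initiations): [0, 1, 2, 9]
partial Mantel (outbreak ~ climate | distance): r = 0.71, p = 0.0004
```

Reading this: the synthetic seven-region record contains multi-decadal
periods in which three or more regions are simultaneously in outbreak (the
first is truncated by the 1700 boundary).  Outbreak initiations co-occur
across regions far more often than the circular-shift null allows at
windows of 0–2 years — synchrony is concentrated at the annual scale — and
pairwise outbreak similarity tracks pairwise climate similarity even after
geographic distance is held constant, the signature of climate-driven
(Moran) synchronization rather than dispersal.

The same analyses run from the shell:

```bash
outbreaksync simulate --seed 11 --out-dir data/
outbreaksync detect   --binary data/outbreaks.csv --out periods.csv
outbreaksync ripley   --binary data/outbreaks.csv --events initiations \
                      --tmax 25 --nsim 1000 --seed 13 --out ripley.csv
outbreaksync run-all  --binary data/outbreaks.csv --climate data/climate.csv \
                      --geometry data/regions.csv --out-dir out/ --seed 1
```

## Input formats

Binary and climate matrices are CSV with header `year,<region_id>,...`, one
row per consecutive year; cells may be empty only at the leading/trailing
margins of a column.  Region geometry is `region_id,east_km,north_km` on a
common projection.

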