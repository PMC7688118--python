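# runcontingent

Discovery and classification of **spawning-run contingents** — co-occurring
groups within one population that run to different river reaches on
different schedules — from fixed-station acoustic-telemetry detections.

Anadromous fish such as striped bass ascend long estuaries each spring in
runs that can hide more than one behavioral unit: a lower-reach contingent
and an upper-reach contingent whose phenologies overlap in time but differ
in destination, timing, and — because they depart into coastal fisheries at
different moments — mortality. This package turns a raw detection log
(timestamp, tag, receiver) into that contingent structure and its
demographic consequences, and ships a synthetic telemetry generator with
ground-truth labels so the entire analysis is runnable and testable without
field data.

## Method

1. **Daily phenologies.** Each fish-day position is the mean river km of
   that day's detections. Interior gaps are filled with a two-sided 4-day
   exponential-weighted moving average (weight 2⁻ᵈ at day-distance *d*);
   the run is the span between the outermost days at or above the
   entry/exit threshold (river km 43). All runs of a cohort-year are padded
   to a common date axis with a constant anchor (river km 35), so that runs
   far apart in calendar time stay dissimilar.
2. **Clustering.** Pairwise dissimilarity is dynamic time warping
   (symmetric2 step pattern, L1 local cost, unnormalised), which matches
   run shapes that are offset in time — the property lockstep Euclidean
   distance lacks. *k*-medoids (PAM, deterministic multi-start BUILD +
   SWAP) partitions the cohort; each cluster's medoid phenology is its
   centroid, and later-year tracks are labelled by nearest-centroid DTW
   distance. Year-to-year label contingency is tested by chi-square and
   summarised as a persistence (concordance) fraction.
3. **Timing.** Per contingent-year: first/median/last entry and exit dates,
   the 50%-incidence date (first day half the eventual entrants have
   crossed the threshold), and the monitored water temperature on that day.
4. **Mortality.** Last detection separates time at large from assumed loss.
   Instantaneous daily loss rate *Z* = −slope of OLS on ln(extant count);
   survival *Ŝ(t)* = Π(1 − dᵢ/nᵢ) with Greenwood variance; contingents are
   contrasted with the Peto & Peto modified Gehan–Wilcoxon (weighted
   log-rank) test, wⱼ = Π(1 − dᵢ/(nᵢ+1)).

## Worked example

```sh
python examples/02_simulate_and_cluster.py
```

```
year 2017: clustered 60 fish into 2 contingents; medoid tags ['L029', 'U012']; total within-cluster DTW cost 13264.8
cluster sizes: {'lower': 30, 'upper': 30}
agreement with simulated truth: 100.0%
```

Sixty simulated fish (30 targeting river km 90–100, 30 targeting
160–200) are clustered from their detection logs alone; the recovered
labels match the generator's ground truth fish for fish. The other
examples show DTW vs lockstep matching, the timing table, the survival
stack, and the full pipeline written to CSV. The same analysis runs from
the shell:

```sh
runcontingent simulate --seed 42 --out data/
runcontingent analyze --detections data/detections.csv \
    --receivers data/receivers.csv --fish data/fish.csv \
    --environment data/environment.csv --out results_dir/
runcontingent report results_dir/
```

## Layout

- `src/runcontingent/` — `io`/`config` (CSV formats, shared settings),
  `preprocess`, `dtw`, `cluster`, `phenology`, `survival`, `synthetic`,
  `pipeline`, `cli`.
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  details, and limitations.
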