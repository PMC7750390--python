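# herdnet

Proximity interaction networks of housed dairy cattle from indoor
positioning data.

Commercial dairy herds are increasingly tracked with collar-mounted
local-positioning sensors that record every cow's planar position at
~0.1 Hz.  From such trajectories one can ask who associates with whom: a
**proximity interaction** is a sustained event in which a dyad (pair of
cows) stays within a radius *r* for a duration *t* — by default within
3 m for 60 s, i.e. 6 consecutive samples at 0.1 Hz.  Counting these
events per day and barn zone yields symmetric weighted networks whose
structure can be tested for social differentiation, temporal stability,
and assortment by individual attributes (lameness, parity, days in
milk).  `herdnet` implements that full pipeline for researchers in
animal social network analysis and precision livestock farming:

1. **synthetic herd generation** (`herdnet.synthdata`) — barn-confined
   semi-Markov movement with milking absences, planted dyadic preference
   structure, sensor noise at a configurable CEP50 (default 1.90 m) and
   stuck/out-of-barn artifacts, with a ground-truth contact log;
2. **trajectory cleaning** (`herdnet.preprocess`) — region filter with
   3 m buffer, stuck-run removal, 15-point moving-average smoothing,
   stationary-day removal, with per-stage removal accounting;
3. **interaction detection** (`herdnet.proximity`) — the strict/lenient,
   tumbling/sliding sustained-proximity protocol per dyad, day and
   functional zone (full barn, feeding, non-feeding);
4. **network measures** (`herdnet.netmetrics`) — edge density,
   components, degree, local clustering, block averaging, mean-weight
   display filtering;
5. **permutation inference** (`herdnet.permstats`) — the shared
   permutation p-value rule `p = #(t_p >= t_o)/q` with the 1/(q+1)
   biased-zero correction, social differentiation
   `S = sum_dyads (O_ij - E_ij)^2 / n_dyads` against a uniform
   multinomial null, permuted Kruskal–Wallis and Wilcoxon rank tests,
   Mantel–Spearman matrix correlation, attribute-difference assortment,
   mobility-score lameness classification, Bonferroni correction;
6. **orchestration** (`herdnet.pipeline`, `herdnet` CLI) — a single
   config drives simulate → clean → detect → networks → stats with
   deterministic seeding and file-based handoffs.

## Worked example

```python
from herdnet import (
    BarnGeometry, ProximityProtocol, SimConfig,
    simulate_herd, inject_artifacts, clean_pipeline,
    daily_interaction_matrix, edge_density, social_differentiation,
)

cfg = SimConfig(n_cows=20, n_days=1, seed=1)
geometry = BarnGeometry()
clean, truth = simulate_herd(cfg, geometry)      # noise-free planted tracks
observed, artifacts = inject_artifacts(clean, cfg, geometry)

result = clean_pipeline(observed, geometry)
for stage, frac in result.stage_removed_fraction.items():
    print(f"{stage}: {100 * frac:.2f}% removed")

m = daily_interaction_matrix(
    result.cleaned, geometry, "full_barn", ProximityProtocol(), day_index=0
)
print(f"edge density: {edge_density(m):.2f}")
diff = social_differentiation(m, q=1000, seed=1)
print(f"S = {diff.S:.1f}, p = {diff.p:.4g}, "
      f"differentiated dyads: {100 * diff.differentiated_fraction:.1f}%")
```

prints

```
region_filter: 0.53% removed
stuck_removal: 0.10% removed
smoothing: 7.34% removed
stationary_day_removal: 0.00% removed
edge density: 0.95
S = 4450.0, p = 0.000999, differentiated dyads: 84.7%
```

Every cleaning stage reports its share of the original records (here the
dominant loss is the 7 samples clipped from each end of every smoothed
segment).  The day's network is almost fully connected — at 3 m in a
crowded barn nearly every dyad meets at least once — and the
differentiation statistic rejects the uniform-association null
decisively: interactions concentrate on preferred dyads rather than
spreading evenly, with ~85 % of dyads deviating beyond the null's 95th
percentile.

The same flow as a shell session:

```sh
herdnet simulate --seed 1 --out run/
herdnet clean --positions run/positions_raw.csv --out run/clean.csv
herdnet detect --positions run/clean.csv --zone feeding --day 0 --out run/m.csv
herdnet networks --matrix run/m.csv
herdnet run --seed 1 --out run_all/          # everything end to end
```

The `analysis/` directory holds the numbered study scripts
(`01_simulate_herd.py` … `06_calibration_power.py`) that generate the
demo herd (30 cows, 3 days), clean it, build the 3 × 3 day-zone matrices,
compute network measures, run the full inference battery, and perform
the calibration/power simulation studies, writing tables under
`results/`.

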