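# farmabm

An agent-based simulation of farm land-use decision-making under
climate-change-related extreme weather events, for researchers studying
agro-structural change, policy scenarios and climate adaptation in
European-style mixed farming regions.

## The model

Farms are bounded-rational agents that pursue a satisfying balance between
income and workload rather than profit maximization. Each simulated year a
farm evaluates three satisfaction criteria:

1. agricultural income per full-time worker equivalent (fte) must reach a
   farm-type-specific minimum;
2. annual workload must stay at or below 1800 h per fte;
3. hourly income must reach a peer floor, the farming-type mean minus one
   standard deviation, recomputed over active farms every year.

A farm satisfied with both income and workload does nothing. Otherwise it
samples one of ten actions — do nothing, hire labor, intensify, extensify,
convert to organic production, switch crop cycles, afforest grassland,
expand via a land rental market, shed land, or terminate — from a
likelihood vector conditioned on its satisfaction state, farming type and
farming style (innovative, yield optimizer, support optimizer, idealist,
traditionalist). Terminated farms pass their parcels to the rental market;
parcels that stay unclaimed convert to forest.

Extreme weather events are region-wide stochastic shocks: each year an
event probability is drawn from a truncated normal (scenario mean μ, SD σ)
and an event, if it occurs, cuts that year's yields by a scenario-specific
fraction. Events also drive learning. With x the cumulative regional event
count, the willingness to adapt of inertia type *i* is

        α_i(x) = (x / 37)^{z_i},    capped at 1,

where the exponent z_i encodes inertia (z_1 < z_2 < z_3 < z_4, mapped from
the farming styles). In adaptive runs α scales the likelihood of the four
adaptation actions — extensification, organic conversion, land-use change,
expansion — by (1 + α_i), so at α = 1 their weight doubles before the
vector is renormalized.

Three scenario presets (each with a learning-enabled `A` variant) span
policy futures: `BAU` (constant subsidies, μ = 10 %/a, 40 % event yield
loss), `HS` (high subsidy: +50 %/+75 % conventional/organic subsidies by
2030, rising prices, μ = 7.5 %/a, 30 % loss) and `FM` (free market:
subsidies abolished by 2030, μ = 15 %/a, 60 % loss, organic farms may
revert to conventional).

Because the underlying parcel-level administrative data are not public, a
synthetic region initializer reproduces the study region's 2015 aggregate
structure: 2,990 farms on 76,220 parcels and 87,545 ha, log-normal farm
sizes pinned to the regional mean and the 44 % share of farms above 20 ha,
five farming styles assigned uniformly, 18 % organic farms, cropland in
three rotation cycles plus meadow/pasture grassland, and cattle herds
computed from grassland forage.

## Worked example

```bash
$ farmabm synth --seed 1 --out region/
wrote 2990 farms, 76220 patches, 87545.0 ha to region/

$ farmabm simulate --config BAU --seed 1 --out out/
BAU: 2163 active farms, 59453 ha agricultural area in 2052
```

The run starts from the synthetic 2015 snapshot (2,990 active farms) and
simulates 37 annual decision rounds; under business-as-usual conditions
with this seed, 2,163 farms (−28 %) remain active and the cultivated area
shrinks from 87,545 to 59,453 ha, the remainder having moved through the
rental market into forest. `out/metrics.csv` holds the full per-year
indicator series (active farms by type, areas by land use, extensive-area
share, organic share, crop-cycle shares, satisfaction shares), and
`out/events.csv` the drawn extreme-event sequence, which can be replayed
into another run with `farmabm replay` for common-random-number
comparisons — the same pairing that `farmabm mc --paired` automates for
adaptive-versus-plain experiments.

The same functionality is available as a library:

```python
from farmabm import preset, run_monte_carlo, summarize, synthesize_region

region = synthesize_region(seed=1)
results = run_monte_carlo(preset("BAU"), region, n_runs=100, base_seed=0,
                          paired=True)
summary = summarize(results)          # MC means/quantiles, paired deltas
```

## Documentation

`docs/methods.md` describes the model assumptions, the default
calibration, numerical conventions and known limitations in detail.
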