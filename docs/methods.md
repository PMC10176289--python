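# Methods

## Model overview and assumptions

The simulation is a discrete-time, spatially implicit agent-based model of
a mixed agricultural region. State consists of farms (agents) and patches
(land parcels); one step is one year. Per year the model applies, in
order: deterministic scenario multipliers; the extreme-event draw (or
replay); the update of the cumulative event counter and the learning
functions; cattle-herd recomputation from forage; farm accounts and
peer statistics; the three-criteria satisfaction evaluation; one sampled
action per unsatisfied active farm, processed in randomized order; the
rental-market step; and the capture of the regional indicators.

Key structural assumptions:

* **Satisficing, not optimizing.** Farms act only when unsatisfied, and
  they choose probabilistically from a fixed action repertoire; there is
  no forward-looking optimization.
* **Region-wide events.** An extreme event hits all farms in the same
  year with the same fractional yield loss. Events are not typed
  (drought vs. flood) and have no spatial footprint.
* **Individual, persistent learning.** Learning is driven solely by the
  cumulative regional event count through α_i(x) = (x/37)^z_i; there is
  no social-network imitation and no forgetting. α saturates at 1 only if
  an event occurred in every one of the 37 simulated years.
* **No farm entry, no off-farm income, no debt dynamics.** The active
  farm population can only shrink; income is agricultural income only.
* **Land conservation.** Cropland + grassland + rental pool + forest area
  is constant; agricultural area leaves production only via afforestation
  (chosen or by pool timeout) and can return only from the rental pool.

## Horizon bookkeeping

The simulation runs 37 annual decision/event steps after the 2015
initialization snapshot, matching the denominator of the learning
function; reported series span the 38 labels 2015–2052. Calendar labels
are cosmetic — the step count is authoritative — and both the start year
and the horizon are configurable.

## Scenario drivers

Trend quantities (class-specific yield decline, producer prices, per-ha
labor demand) interpolate linearly from 1.0 at the start year to their
scenario endpoint in the final year; linearity between the two printed
anchors is the simplest defensible choice. Subsidy multipliers follow a
stepwise schedule — three equal steps in 2020/2025/2030 reaching +50 %
(conventional) / +75 % (organic) in the high-subsidy scenario and 0 in the
free-market scenario, constant thereafter. Yield-decline ranges are mapped
to land-use classes with cropland at the upper bound and grassland at the
lower (e.g. business-as-usual "5–25 %" becomes 25 % for cropland, 5 % for
grassland); every endpoint is configurable. Events multiply the land-based
yield factor only: area subsidies and livestock margins are unaffected
(direct payments are area-based).

## Synthetic region

The initializer emulates the aggregate 2015 structure of the study region
(2,990 farms, 76,220 parcels, 87,545 ha). Where marginal distributions are
published they are pinned exactly:

* **Farm sizes** are log-normal with (μ, σ) solved in closed form from the
  regional mean size (87,545/2,990 ≈ 29.3 ha) and P(size > 20 ha) = 0.44;
  sampled sizes are rescaled to the exact regional total, and patch areas
  are a Dirichlet split (concentration 3) of each farm's size, so patch
  sums reproduce farm sizes exactly.
* **Patch counts** per farm are proportional to size (largest-remainder
  rounding, minimum one patch).

Unpublished proportions are free parameters with documented defaults,
overridable from the `init` config section: farm-type shares (cash crop
0.45, pig/suckler processing 0.09/0.06, meat/milk cattle 0.22/0.18),
per-type cropland probability (0.95 down to 0.20, giving ≈ 60 % cropland
area overall), grassland split (meadow 0.50 / pasture 0.35 / mountain
pasture 0.15), equal crop-cycle shares, 18 % organic farms, whole-farm
initial intensity drawn uniformly from {2, 3, 4}, and pig herds of 20–80
livestock units on pig-processing farms. Cattle herds are not drawn: they
are recomputed every year as forage provision — meadow/pasture area ×
intensity × 0.3 lu — so extensification shrinks herds endogenously.

The labor endowment is `max(0.5, 0.8 + 0.02·size + N(0, 0.25))` fte. The
mild size dependence reflects that larger farms employ more (family and
permanent) labor; with a size-independent endowment the small-farm
majority would start far below any plausible income threshold, which is
not a defensible initial condition.

What the generator does **not** emulate: spatial adjacency and geometry,
within-farm heterogeneity of initial intensity, correlations between farm
type and size, and the region's true (unpublished) type/intensity/organic
proportions. Passing tests on this synthetic region therefore demonstrate
the mechanics and directional behaviour of the model, not calibrated
predictions for the real region.

## Economy defaults

The per-ha gross margin, labor and subsidy tables the published record
does not include are shipped as synthetic defaults (EUR and hours per ha
and year): conventional cropland margins rise linearly from 300 (intensity
1) to 900 (intensity 5) with labor 35–75 h; grassland classes are cheaper
and lighter; organic production earns ≈ 10 % higher margins and an area
premium (450 vs. 250 EUR/ha subsidy) at ≈ 35 % higher labor. Rotation
cycles modify cropland economics (root-crop cycle cr1: margin ×1.25,
labor ×1.30; soy cr2: neutral; rapeseed cr3: ×0.95 / ×0.90), so
income-stressed farms switching land use move to cr1 and workload-stressed
farms to cr3. Cattle earn 500 EUR and take 60 h per livestock unit; pigs
300 EUR and 15 h. Type-specific minimum incomes per fte (6,000–18,000 EUR)
sit near the lower quintile of the initial income distribution, giving
≈ 30 % initial income dissatisfaction and ≈ 22 % workload excess, and a
business-as-usual farm decline of ≈ −28 % over 37 years — levels a
regional scientist would call realistic. All values are config-overridable;
the tables enforce that organic labor is never below conventional and that
conventional margins and labor are non-decreasing in intensity.

## Decision matrix

The per-style action probability tables are not published; the shipped
matrix encodes the documented qualitative structure. Base vectors per
satisfaction quadrant load income-stressed states on intensification,
land-use change, expansion and (weakly) termination; workload-stressed
states on hiring, extensification and reduction; doubly unsatisfied
states spread wider with more exit mass. Styles tilt multiplicatively
(innovative ×1.5 on change actions, traditionalists ×1.8 on inaction and
×0.5 on change, optimizers toward yield/subsidy actions, idealists toward
organic and afforestation), followed by renormalization. The matrix
serializes to a flat CSV (quadrant, farm type, style, act1..act10) so real
tables can be substituted without code changes.

Structural masking zeroes impossible actions before sampling:
intensification at the ceiling, extensification at the floor, the one-shot
organic switch (reversal allowed only in the free-market scenario),
land-use change without cropland, afforestation without grassland, and
reduction below two patches (so only termination empties a farm). The
suffer counter increments each year a farm is unsatisfied on both
criteria, decrements on afforestation (floor 0), and at the threshold
(default 5) restricts the farm to reduction/termination — giving the
counter the termination-pressure role its name implies; the threshold is
configurable because the published semantics are incomplete.

Renormalization after the (1 + α) learning boost is a deliberate choice:
the multiplication alone does not yield a proper distribution, and
renormalizing preserves the stated relative boost — the odds of each
adaptive action against any non-adaptive action exactly double at α = 1.

## Numerical and RNG conventions

* All randomness derives from one base seed through named
  `numpy.random.SeedSequence` substreams (events, decisions), so replaying
  a stored event log perturbs nothing else; paired experiments reuse the
  non-adaptive run's event log in the adaptive variant.
* The event probability uses exact truncation to [0, 1] (scipy
  `truncnorm`), with σ = 0 as the deterministic limit. At the shipped
  parameters the truncation bias is < 1e-4.
* Peer floors use the population SD (the floor is a population
  descriptor, not an estimate); a farming type with a single farm gets SD
  0, so its floor is that farm's own value. The floor comparison carries a
  1e-9 relative tolerance so summation round-off cannot tip a farm
  exactly at its floor.
* Thresholds are inclusive: workload ≤ 1800 h/fte and income ≥ minimum
  both satisfy.
* Effective labor supply is fte + hired_hours/1800, so hiring lowers
  per-fte workload — its evident purpose.
* Hourly income is income/workload with workload > 0; farms with neither
  patches nor livestock are flagged degenerate.
* Snapshots and event logs round-trip bit-exactly through CSV
  (`%.17g` writing, round-trip float parsing).
* At α = 0 the likelihood adaptation returns the input vector unchanged
  (exact identity), which makes a zero-event adaptive run byte-identical
  to its non-adaptive twin.

## Problem sizes used in the shipped tests

Unit and property tests run on hand-built micro-regions and on a 200-farm
/ 1,600-patch synthetic region; the invariant sweep uses thirty 100-farm
runs across all six scenario variants; tendency checks use 30 paired runs
per scenario at 200 farms; event statistics use 100–10,000 sequences; the
initializer checks run at the full 2,990-farm scale. These sizes were
chosen so the full suite completes in well under a minute of simulation
time while keeping Monte-Carlo standard errors small relative to the
asserted tolerances.

## Tendency checks and their tolerances

Headline outcome levels depend on the unpublished calibration tables, so
the suite asserts directions, not points: final active farms order
HS ≥ BAU ≥ FM in the Monte-Carlo mean (tolerance two farms on the close
HS/BAU comparison); paired adaptive-minus-plain deltas preserve farms
(pooled over BAU and FM) and agricultural area (tolerance 0.5 % of the
initial area); and the extensive-area share rises under adaptation in the
free-market scenario, where events are frequent enough for α to move. In
the low-event scenarios α stays below ≈ 0.1 for all but the most
responsive type, so the adaptation signal there is small relative to
common-random-number residual noise at test scale — matching the model's
own logic that rare events provide little learning stimulus.

## Known limitations

* No spatial structure: parcels have no location, so spatial heterogeneity
  of events, land markets or conversion cannot be studied.
* The free-market event-frequency parameterization (μ = 0.15) implies
  ≈ 5.6 events per run in expectation; reported historical-style summaries
  around 4.3 would require a mechanism (e.g. capping) the model does not
  include.
* Prices and markets are exogenous multipliers; there is no market
  clearing, no succession/demography, and no irrigation option (rejected
  as infeasible for the study region).
* The synthetic calibration reproduces plausible aggregate levels, not
  the real region's bookkeeping data; quantitative outputs should be read
  comparatively (across scenarios and variants), not predictively.
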