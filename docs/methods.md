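# Methods

## Model

`scanwatch` implements the discrete Poisson space–time scan statistic for
prospective cluster surveillance. The study region is partitioned into
areas at three nested levels of census-style geography; each area carries a
population for two strata (all ages, under 25, with "under 25" meaning age
at death strictly below 25). Under the null hypothesis of spatially and
temporally homogeneous risk, the count in any set of area-months is Poisson
with mean proportional to its person-months, so the expected count of a
window is `mu = C * (zone_pop * months) / (total_pop * T)` — indirect
standardisation with the population held constant over the study (a
single-census assumption). The test statistic for a window is the Poisson
log-likelihood ratio `c*ln(c/mu) + (C-c)*ln((C-c)/(C-mu))`, taken as zero
unless `c > mu`: the system hunts excess-risk clusters only (a deficit of
suicides is not a surveillance signal; the low-rate branch can be enabled
via `high_rate_only=False`).

Candidate spatial windows are circular: for each area centroid, the zones
are the distance-ordered prefixes of areas, grown one area at a time until
the next addition would exceed the radius cap or the population-fraction
cap, whichever binds first. The singleton zone is always retained even
when the center's own population exceeds the cap, so a single hot area can
still be flagged. Distance ties are broken by ascending area id, making
zone enumeration fully deterministic. Temporal windows are all closed
month intervals up to the duration cap anywhere in the epoch (retrospective
enumeration — clusters may end mid-epoch). Centroids are stratum-specific:
population-weighted means of child centroids at the two upper levels
(computed separately for the under-25 and all-ages populations, whose
spatial distributions differ), and geometric polygon centroids at
mesh-block level where no finer population exists.

Inference is by Monte Carlo rank: each replicate redistributes the grand
total `C` multinomially over area-months with probabilities proportional to
the null expectations (the standard conditional form of the discrete
Poisson scan), the replicate statistic is that dataset's maximum window
LLR, and `p = rank/(R+1)` with `rank = 1 + #{replicate maxima >= candidate
LLR}`. All reported clusters — the most likely and the non-overlapping
secondaries — are ranked against the same null-maximum distribution, so
the p-value floor is `1/(R+1)`. Secondary clusters are reported in
decreasing LLR subject to sharing no area with any higher-ranked reported
cluster, the conventional no-geographic-overlap rule; within one scan only
the best interval per zone is reported, since any further interval of the
same zone is dominated and excluded by the overlap rule anyway.

## Surveillance design

The rolling sweep replays a monthly data feed: epochs of `epoch_len`
months (default 24) advance by `step` months (default 1) from the study's
first month until the final epoch ends at the study's last month; each
epoch is scanned once per level and age stratum. A 90-month study thus
yields 67 epochs and 402 runs. Because overlapping epochs and nested
levels rediscover the same deaths, significant results are grouped by the
Jaccard similarity of their enclosed event-id sets (default threshold 0.5,
transitive closure, never across age strata); each group's representative
is its highest-LLR member, and its detection date is the end month of the
earliest flagging epoch — the moment that month's data would just have
arrived. Grouping applies across both epochs and levels; the threshold is
configurable because any equivalence rule here is a judgment call made
quantitative. Runs are seeded independently from one root seed
(`numpy.random.SeedSequence` spawn keys), are isolated against per-run
failure, and are cached by `(epoch, level, stratum, params hash)` so
appending one month of data and re-running recomputes only new epochs.

Significance is two-tiered: clusters at `p <= alpha` (default .01) are
detections; everything up to a configurable `report_ceiling` is retained
and tagged, reflecting surveillance practice where near-threshold clusters
(up to p ≈ .1) still warrant file review.

## Synthetic data

The generator emulates the structure of a confidential state suicide
register and its geography, not any real pattern of deaths. Geography is a
planar grid in kilometres: rectangular mesh blocks tile the plane and are
grouped into contiguous SA1 and SA2 blocks with exact nested population
sums. Mesh-block populations are `round(dwellings * 2.5)` with dwellings
uniform on 30–60 (mesh blocks are defined by dwelling count), rescaled so
SA2s average the configured ~10,000 people; the under-25 population is
binomial per mesh block, giving realistic stratum heterogeneity. Default
SA1/SA2 composition (4 mesh blocks per SA1, 25 SA1s per SA2) reproduces the
~400 / ~10,000 person targets of the real hierarchy.

Baseline events are Poisson per mesh-block-month with rate
`annual_total/12 * pop/total_pop` (defaults: 700 events/year over 90
months, the scale of the register the design targets), placed uniformly
inside their mesh block, with ages drawn to match the under-25 fraction in
expectation and a configurable fraction (~2.5%) flagged as lacking valid
residential coordinates — these records carry no usable location, mirroring
register records for people without a fixed address, and are excluded by
the preparation step. Injected clusters add exactly `excess` events
uniformly over the mesh blocks within a radius of a chosen center and
uniformly over a month interval, recording the ground truth for recovery
testing.

What the synthetic mode does **not** emulate: irregular real boundaries and
coastline effects, population change over time, spatial autocorrelation of
risk, seasonality, or any contagion mechanism. Passing tests therefore
demonstrate the statistical machinery (calibration, power against localized
excess, conservation, determinism) — not that real clusters of any
particular aetiology will be found. Real-data use replaces the grid with
lon/lat GeoJSON boundaries; distances then use the haversine great-circle
formula.

## Numerical and design choices

- **Boundary tie-breaks.** On the synthetic grid, cells are half-open so a
  point on a shared edge belongs to the cell whose minimum corner it
  touches; with polygon geometries, point-in-polygon uses covered-by
  semantics with ties resolved to the smallest area id. Joins are
  idempotent and never silently drop events: unmatched and out-of-range
  records are returned to the caller.
- **Month indexing.** Months are integers from 0 at the study's first
  calendar month; intervals are closed, so a 24-month epoch spans exactly
  24 indices.
- **LLR conventions.** `0*log(0) = 0`; a window with `mu = 0` and `c > 0`
  scores +inf (it can only arise from a zero-population area holding
  cases, which the preparation step surfaces); `c = mu` scores 0.
- **Replicate kernel.** The Monte Carlo path uses a numba-compiled loop
  kernel for the replicate maximum; a vectorised numpy path computes the
  observed scan and serves as an exact cross-check of the kernel in the
  test suite (they agree to 1e-9).
- **Determinism.** Every stochastic step takes an explicit seed; fixed
  seeds give byte-identical events, geographies, p-values and report
  bundles.
- **Disclosure control.** Summary tables suppress observed counts below a
  threshold (default 5, configurable): the count prints as `nr`, the
  p-value as an upper bound on a coarse grid (.01/.05/.1/...), and the zone
  population rounded up to the nearest 50 — common statistical-disclosure
  practice where the true threshold of the reporting authority is unknown.

## Validation studies and problem sizes

The package validates itself at desk scale (`scanwatch.evaluation`):

- **Exhaustiveness.** On random instances up to 8 areas × 8 months the
  engine's most likely cluster (members, interval, observed, expected,
  LLR) must equal a plain-Python exhaustive enumeration exactly.
- **Null calibration.** 200 null case series (120 cases multinomial over a
  100-area geography, 24 months) scanned at 199 replicates; the share of
  most-likely clusters with `p <= .05` must fall in the exact binomial 99%
  interval around .05. The rank construction makes this hold by
  exchangeability, so the check guards the implementation, not the theory.
- **Recovery power.** 20 synthetic datasets (144 mesh blocks, ~18,000
  people, 40 baseline events/year over 30 months), each with one injected
  cluster of 10 excess events over 6 months within 1 km of a random mesh
  block — an observed-far-above-expected configuration typical of genuine
  clusters at this population scale. The full sweep (every epoch × level ×
  stratum, 199 replicates, alpha .01) must detect a significant cluster
  containing the truth center with an overlapping interval in at least 80%
  of datasets, no later than 3 months after the truth window ends. The
  study sizes here are deliberate scale models of the full design; the
  run-count arithmetic (67 epochs, 402 runs) is checked at full scale,
  where it is pure arithmetic.

## Limitations

Only circular windows are scanned; elongated clusters along coasts or
corridors are better served by elliptic or irregular windows. The
space–time permutation variant (which needs no population denominators) is
not implemented. P-values are retrospective: no adjustment is made for the
multiplicity of repeated monthly analyses, so over a long surveillance
horizon the family-wise false-alarm rate exceeds alpha (the operational
posture is that an occasional false positive triggers only a file review).
Populations are static between censuses, and age is the only covariate
handled, by stratification.
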