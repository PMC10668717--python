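# Methods and design notes

This note documents the models, rules and numerical choices behind
`wolfalps`, the assumptions they rest on, and what the synthetic-data
tests do and do not demonstrate about real monitoring data.

## Sign validation

Classification is a deterministic decision table over the record's
evidence type and attributes. Expert judgment (a checked scat, a verified
howl) is always an *input flag*, never computed: the package encodes the
agreed interpretation of evidence, not image or audio analysis.

Two rules need table-level context and are applied as passes over the
full table rather than per record:

* **Kill corroboration.** A depredation with typical bites counts as C2
  only "combined with other C2 data". The linkage rule is: another C2
  sign within 10 km and 14 days. An explicit `combined_with_c2` flag
  short-cuts the search (for data exported from systems that already
  resolved it).
* **Indirect DNA certification.** A track on which a DNA-confirmed sample
  was collected (shared `track_id`) is hard evidence, so a C2/C3 track is
  upgraded to C1 in a post-pass.

Track length exactly 100 m is C2 (the threshold is inclusive). A howl
with pups checked by an expert is stand-alone C2; no simultaneous other
evidence is required. Screening discards records lacking minimum
technical documentation (`technically_documented` false) or flagged for
possible deception; the flag records an explicit screening failure, so an
absent flag means "documented".

Classification satisfies an evidence-monotonicity property — weakening
any single attribute (shorter track, no expert check, bad photo, DNA not
confirmed) can never raise a category — which the suite fuzzes.

## Monitoring year

The biological wolf year runs from reproduction to reproduction: 1 May of
calendar year Y through 30 April of Y+1, labelled "Y–Y+1". The boundary
matters (30 April and 1 May of one calendar year belong to different
monitoring years) and is tested explicitly.

## Occurrence grid

Cells are 10 km half-open squares indexed by floor division of planar
coordinates (EEA-grid style); boundary points belong to the cell whose
lower-left corner they touch. A cell is confirmed by ≥ 1 C1 sign or ≥ 2
*mutually independent* C2 signs within the monitoring year; C3 never
contributes. Dispersers' signs confirm cells like any other — occurrence
tracks the species' presence, not territory membership.

"Independent" is not defined by the standard, so a concrete rule is
fixed here: two C2 signs are independent iff they are dated on different
calendar days, or lie more than 1 km apart without sharing a track
identifier. The area of occurrence is 100 km² × the number of confirmed
cells whose *center* lies in the Alpine-range polygon — a deterministic
in/out rule chosen over partial-intersection area bookkeeping so results
are exactly reproducible. A sign (including a track) is located at its
recorded point.

Real-world coordinates with a declared projected CRS pass through
unchanged; no reprojection is performed.

## Reproductive units

The population index counts packs and pairs only; dispersers and solitary
animals are reported separately and never enter totals.

**Clustering.** Signs sharing a genotype label are always linked
(genetics overrides distance); remaining signs link within 15 km in the
same monitoring year (about twice the 7.98 km representation-circle
radius); connected components become candidate territories. A singleton
component with neither hard evidence nor a genotype is dropped.

**Adjacent packs.** Proximity can merge neighbouring territories, and the
standard requires positive evidence to count two adjacent packs as two
units. Merged components are partitioned by pedigree label — pedigree
identity is an input from the genetics laboratory, not reconstructed
here — with non-genotyped signs joining the nearest pedigree nucleus;
components without distinguishing evidence stay merged (the conservative
direction: a minimum count).

**Pack/pair rules.** Pack: reproduction confirmed (pup DNA or another
C1 pup record, or an expert-checked howl with pups), or ≥ 3 individuals
confirmed by C1 (distinct genotypes or animals counted on good
photo/video), or ≥ 2 independent C2 tracks each showing ≥ 3 animals
traveling together (the animal count on a track is an input attribute).
Pair: exactly one male + one female among the adult C1 genotypes plus C1
bonding evidence — a good photo/video of the two, or genetic proof of the
couple on one track or joint same-day sampling within 2 km. When both
rules fire, reproduction dominates: the unit is a pack (a pair is by
definition a couple that has not yet reproduced).

**Transboundary resolution.** Units of one year sharing genotype labels
(the same animals in two national datasets) are merged and counted once.
A unit genetically documented in two countries is TR; a unit whose 200 km²
representation circle crosses a border, with signs within 10 km of that
border on both sides in the same year but no cross-border genetic match,
is LTR (the "likely transboundary" call from the spatio-temporal sign
distribution, given a concrete rule here). A genotype claimed from more
than two countries raises an integrity error. Resolution is idempotent
and invariant to the order in which national lists are processed.

## Growth model

Process: `N_{t+1} = λ N_t ε_t`, `log ε_t ~ Normal(0, σ_p²)` — abundance
is positive and growth multiplicative, so the process error is lognormal.
Observation: `y_t ~ Poisson(θ_t)` with `θ_t ~ Gamma(mean N_t, dispersion
φ)`; marginally `y_t` is negative-binomial with variance `N_t + φ N_t²`.
Missing monitoring years contribute no observation term; their latent
abundance is imputed through the process model.

Priors (proper, weak, overridable via `GrowthModelSpec`):
λ ~ Uniform(0.1, 4), σ_p ~ half-Normal(1), φ ~ half-Normal(1),
N₀ ~ Lognormal(0, 2).

**Sampler.** Adaptive Metropolis-within-Gibbs on the log-abundance chain:
single-site random-walk updates in an odd/even checkerboard (each parity
vectorizes because a site's full conditional touches only its
neighbours), scalar updates for log λ, log σ_p and log φ, plus three
joint moves that break the strong posterior correlations of state-space
models — a *drift* move proposing λ together with the matching rotation
of the whole trajectory, a *level* move shifting the trajectory, and an
interweaved σ_p move rescaling the innovations around the trend (the
process density and the transform Jacobian cancel exactly, leaving only
observation and prior terms). Proposal scales adapt toward standard
acceptance targets (0.44 single-site, 0.3 joint) during warm-up and are
then frozen, so the post-adaptation chain is a valid fixed-kernel MCMC.
All chains (and, in recovery experiments, all replicates) advance
together as rows of numpy arrays.

Defaults mirror the published analysis — 8 chains, 100,000 iterations
thinned by 10 after 10,000 adaptation iterations — and a reduced test
preset (4 chains × 10,000 iterations thinned by 2, i.e. 5,000 kept draws
per chain) is used in the suite and the acceptance script; the suite
checks that posterior summaries are stable across chain counts within
Monte-Carlo error. Convergence is monitored with the classic split-R̂;
`fit_growth_model` raises when any scalar parameter exceeds 1.05 (the
estimator is cross-checked against arviz in the suite).

Two analytic limits anchor the tests: with σ_p, φ → 0 a noise-free
geometric series forces the λ posterior onto the implied geometric rate
`(N_end/N_start)^(1/years)`, and a constant series forces it onto 1.
Simulation-based calibration (`recovery_experiment`) at λ = 1.22,
σ_p = 0.05, φ = 0.1, N₀ = 2, 25 years × 100 replicates gives ≈ nominal
95% CI coverage and |bias| < 0.02 for λ.

On the published sparse series (totals observed in only four monitoring
years out of 28) the λ posterior mean is ≈ 1.25 with sd ≈ 0.19: with four
observations the error scales σ_p and φ are largely prior-dominated,
which widens and right-skews λ. The posterior median ≈ 1.22 coincides
with the published point estimate; exact replication is impossible
because the full yearly series behind the published fit is not printed.

## Synthetic recolonization generator

The generator emulates the data-generating process the standard assumes,
on an abstract planar study region (kilometre coordinates, four-country
quadrant layout, Alpine-range polygon inset from the region edge — no
real GIS layers).

* **Demography.** Each unit survives a year with probability 0.95 and
  founds one new pair with probability `growth_rate − survival`, so the
  expected yearly multiplier of the unit count is exactly `growth_rate`
  (default 1.22, the Alpine estimate). The paper-level standard gives no
  demographic rates; these are free parameters with documented defaults.
* **Settlement.** New pairs settle at an exponential dispersal distance
  (scale 40 km) from a parent territory, with a 5% long-range uniform
  component producing the stepping-stone settlements seen in real
  recolonizations; centers keep ≥ 2× the territory radius apart, so
  territories never overlap. A region too small for the initial units
  raises a capacity error; later saturation silently skips a founding
  (mild density dependence at the margins).
* **Pairs vs packs.** Pairs convert to packs on first reproduction
  (probability 0.9 per year after the founding year; the founding-year
  probability is solved so the stationary pair share equals
  `pair_fraction`, default 0.15 — consistent with 80–85% of wolves living
  in packs and with the observed pair fractions near 15%).
* **Detection.** Signs per unit-year are Poisson at per-class rates
  (DNA 6, photo 2.5, track 3, scat 2, howl 1.5, kill 1 — generous,
  deliberately on the well-monitored end), placed uniformly in the
  territory circle. DNA samples carry the member's genotype label, sex,
  age class and pedigree (= social unit) with probability
  `genotyping_success` (0.9). Pair tracks sometimes carry couple DNA;
  howls with pups occur mainly in reproducing units.
* **Dispersers and noise.** Solitary dispersers leave tracks and DNA
  outside territories; noise signs (rate 0.2 per 100 km² per year) are
  attribute-poor by construction — unchecked scats, short tracks, single
  howls, sightings — so they can never be classified C1 and ground truth
  stays interpretable.

Everything is driven by one seeded generator: identical config + seed
gives bit-identical CSV output.

**What passing tests show — and don't.** On this generator the full
pipeline recovers ≥ 90% (typically ≈ 98%) of true unit-years with correct
pack/pair status and zero genotype double-assignments. That validates the
*logic* of the pipeline under the standard's own assumptions. It does not
calibrate real-world detectability: real genotyping success varies by
matrix and season, pedigree assignment is itself uncertain, territories
deform around terrain, and national effort differs — none of which the
generator represents. Detection rates here are illustrative, not
estimated from field data.

## Problem sizes and determinism

The suite's reference dataset is 8 monitoring years from 4 founding units
(≈ 5,000 signs); recovery experiments use 100 replicates of 25-year
series; sparse-series fits use the 28-year published window. These sizes
were chosen to exercise every code path at desk scale. All randomness
flows from explicit seeds (numpy `default_rng` / `SeedSequence`), and the
pipeline report is byte-identical across reruns of the same config.

## Known limitations

* Pack/pair rules depend on input attributes (animal counts on tracks,
  expert flags, pedigree labels); the package never infers them.
* The LTR rule and the C2-independence rule are concrete operational
  choices where the standard leaves interpretation to experts; both are
  surfaced as config thresholds.
* The growth model assumes density-independent exponential growth — the
  right description of a recolonization front, wrong near saturation.
* No capture–recapture abundance estimation and no conversion from
  reproductive units to individual counts: the index is units, by design.
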