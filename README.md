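# wolfalps

Tools for population-level monitoring of a transboundary wolf
(*Canis lupus*) population, built around the harmonized standards used to
assess the Alpine population across national borders. The package is aimed
at wildlife biologists and analysts who need to turn heterogeneous
national sign-of-presence records into comparable, additive population
indices: where wolves occur, how many reproductive units (packs and
pairs) exist — each counted exactly once even when a territory straddles
a border — and how fast the population is growing.

## What it does

1. **Sign validation** (`wolfalps.classification`). Every field record —
   DNA sample, photo/video, track, scat, depredation, howl, telemetry,
   sighting — is screened for genuineness and classified into the
   SCALP-style categories: **C1** hard evidence, **C2** confirmed
   observation, **C3** unconfirmed observation. Records without minimum
   technical documentation are discarded. Dates are mapped to the
   biological monitoring year (1 May – 30 April).

2. **Occurrence grid** (`wolfalps.grid`). Wolf occurrence is the set of
   10 × 10 km reference-grid cells confirmed within a monitoring year by
   ≥ 1 C1 sign or ≥ 2 mutually independent C2 signs. The area of
   occurrence is 100 km² per confirmed cell, restricted to the Alpine-range
   polygon for trend reporting.

3. **Reproductive units** (`wolfalps.units`). C1–C2 signs are clustered
   into candidate territories (shared genotypes first, then spatial
   proximity); the pack/pair decision rules are applied (reproduction
   confirmed, ≥ 3 individuals together, or a bonded male–female couple);
   adjacent packs are split only with distinguishing evidence; and
   cross-border duplicates are merged into single transboundary (TR/LTR)
   units before national and population totals are computed. Each
   territory is represented by a 200 km² circle centred on the centroid of
   the minimum convex polygon of its signs.

4. **Growth model** (`wolfalps.growth`). The yearly total of reproductive
   units is fitted with a Bayesian hierarchical state-space model:
   exponential growth `N_{t+1} = λ N_t ε_t` with lognormal process error
   `log ε_t ~ Normal(0, σ_p²)`, and a gamma-Poisson observation model
   `y_t ~ Poisson(θ_t)`, `θ_t ~ Gamma(mean N_t, dispersion φ)` — i.e. a
   negative-binomial count with variance `N_t + φ N_t²`. Years without an
   evaluation are imputed as latent states. Inference is by an adaptive
   Metropolis-within-Gibbs sampler with split-R̂ convergence checks;
   `recovery_experiment` runs simulate–fit–score validation at scale.

5. **Synthetic data** (`wolfalps.synthetic`). A spatially explicit
   recolonization simulator — branching growth of territorial units,
   dispersal-kernel founding with long-range stepping stones, imperfect
   detection and genotyping, dispersers and noise signs — generates
   ground-truthed multi-country datasets so the entire pipeline can be
   scored against known truth.

6. **Pipeline / CLI** (`wolfalps.pipeline`, `wolfalps` command).
   `simulate`, `classify`, `grid`, `units`, `trend` and `all` subcommands
   orchestrate the stages with a JSON config, deterministic seeding and a
   provenance-carrying report bundle.

## Worked example

```sh
printf '{"n_years": 8, "initial_units": 4}' > cfg.json
wolfalps all --config cfg.json --seed 11 --out-dir demo
```

simulates 8 monitoring years of recolonization in a four-country study
region, classifies the 4,876 generated signs (592 C1, 250 C2, 2,873 C3,
1,161 discarded), and prints the report. Unit totals grow from 4 in
2005–2006 to 13 in 2012–2013, the in-range area of occurrence grows from
1,200 km² to 4,300 km², and the growth-model posterior for λ is

```
mean 1.257  median 1.227  sd 0.232  95% CI [0.920, 1.810]  R̂ 1.003
```

consistent with the configured yearly growth rate of 1.22 for this short,
small-count series. `demo/` holds the full bundle: classified signs,
per-cell occurrence (CSV + GeoJSON), resolved units with transboundary
status, per-country summaries, the count series, latent-abundance
estimates for every year, and `report.json` echoing every threshold used.

The same objects are available as a library:

```python
from wolfalps import CountSeries, fit_growth_model, TEST_MCMC

series = CountSeries.from_dict(
    {"1993–1994": 1, "1996–1997": 5, "2015–2016": 77, "2020–2021": 243},
    1993, 2020,
)
post = fit_growth_model(series, mcmc=TEST_MCMC)
print(post.summary().loc["lambda"])        # posterior mean ≈ 1.25
print(post.latent_summary().tail())        # imputed abundances per year
```

## Layout

```
src/wolfalps/      classification, grid, units, growth, synthetic,
                   regions, pipeline, cli
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance.py
docs/methods.md    model and design notes
```
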