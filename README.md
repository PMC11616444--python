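# batforage

Colony-level analysis of long-distance central-place foraging in
GPS-tracked bats.

Greater spear-nosed bats (*Phyllostomus hastatus*) roosting on an island
commute 15–25 km each night to colony-specific foraging areas on the
mainland, far beyond the closest available food. Quantifying that
behaviour from raw GPS tracks takes a chain of standard but fiddly
steps, each of which this package implements as a tested, reusable
module:

1. **Track I/O and cleaning** (`data_io`, `preprocessing`) — Movebank-dialect
   CSV reading, splitting into bat-nights (18:00–06:00 local), projection to
   a local metric CRS, removal of speed spikes (> 15 m s⁻¹) and far
   over-water fixes, downsampling to a 2-min grid with explicit `NA` slots.
2. **Behavioural segmentation** (`hmm`) — a two-state hidden Markov model on
   step lengths (gamma) and turning angles (wrapped Cauchy), separating
   *foraging* (short, tortuous moves) from *commuting* (long, straight
   flight). Fitting is direct numerical maximum likelihood pooled across
   nights; decoding is Viterbi plus forward–backward smoothing.
3. **Foraging metrics** (`metrics`) — commute straightness index, foraging
   bout anchors with distance and bearing to the roost (0 rad = due south,
   clockwise positive; compass degrees = rad·180/π + 180), on/off-island
   time budgets with binomial GLMs, and the balsa-tree energetics
   back-of-envelope.
4. **Null-track simulation** (`nullsim`) — resource-blind trajectories from
   the fitted movement kernel, constrained so bats never settle into
   foraging over open water and return to the roost by morning. These show
   where the colony *could* have foraged given how it moves.
5. **Hierarchical Bayesian inference** (`hier`) — per colony × season ×
   provenance, distances d_ij ~ Normal(μ_d + b_i, σ_d) and bearings
   θ_ij ~ von Mises(μ_θ + a_i, κ) with individual random intercepts
   b_i ~ N(0, τ_d), a_i ~ N(0, τ_θ) and weakly regularizing priors.
   Reported per group: population mean, effective SD (spread of the
   marginal predictive: √(σ_d² + τ_d²) for distance, √(−2 ln A(κ) + τ_θ²)
   for angle), and individual-level variability τ, each with 95%
   credibility intervals, plus draw-wise contrasts between groups.
6. **Foraging-area overlap** (`overlap`) — the scaled product of the
   distance and angle predictive densities on a metric raster, its 95%
   highest-density contour, and asymmetric pairwise overlap percentages
   clipped to land.

A synthetic-data generator (`synthetic`) reproduces the statistical
structure this pipeline assumes — island roost, two-mode movement,
colony-specific commute corridors, seasonal variance differences, GPS
dropout and outliers — with full ground truth, so every stage is testable
without access to tracking data.

## Worked example

```python
from batforage import synthetic, preprocessing, hmm, metrics, hier

land, cfg = synthetic.make_landscape(seed=1)
scenarios = synthetic.default_scenarios(n_individuals=4, nights_per_individual=3)
ds = synthetic.simulate_dataset(scenarios, seed=1, landscape=land, config=cfg)

clean, series, log = preprocessing.preprocess_tracks(ds.tracks, land)
model = hmm.fit(series, n_states=2, n_restarts=2, seed=1)
seqs = [hmm.decode(model, s) for s in series]

locs = []
for s, q in zip(series, seqs):
    locs.extend(metrics.extract_foraging_locations(s, q, land))
table = metrics.locations_to_frame(locs)
fit = hier.fit_hier(table[(table.colony_id == "colony1") & ~table.on_home_island],
                    seed=1)
print(fit.summary())
```

prints (numbers from this exact run):

```
      parameter        mean        q2.5       q97.5
0          mu_d   23.339903   20.069866   26.279303
1       sigma_d    1.116458    0.994165    1.257324
2         tau_d    2.557231    0.917483    7.236300
3      eff_sd_d    2.846717    1.452708    7.328182
4         kappa   65.809633   53.392944   79.061024
5     tau_theta    0.208544    0.119061    0.288710
6   eff_circ_sd    0.244411    0.172383    0.315311
7      mu_theta    1.422544    1.179412    1.671419
8  mu_theta_deg  261.505774  247.575321  275.765244
```

Read: colony 1 forages a posterior-mean 23.3 km from the roost
(95% interval 20.1–26.3 km) at a mean bearing of 1.42 rad ≈ 262°
compass (west-south-west), with an effective circular spread of
0.24 rad — a narrow, colony-specific corridor. The generator's truth for
this colony is 23.5 km at 1.54 rad (268°). With only four tracked
individuals the random-intercept SD τ_d is wide and partly
prior-driven, which the interval reports honestly.

The same stages are available as a CLI for file-based workflows:

```bash
batforage simulate-data --seed 1 --out data/
batforage preprocess --tracks data/tracks.csv --metadata data/metadata.csv \
    --landscape data/coast.geojson --config data/config.json --out clean/
batforage segment --tracks data/tracks.csv --metadata data/metadata.csv --out hmm/
```

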