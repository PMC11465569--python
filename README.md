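# temposelect

Temporal-grid step-selection analysis of animal habitat selection, with a
synthetic landscape + movement simulator for validating every stage by
parameter recovery.

## The problem

Habitat selection by large herbivores is not static: the cost–benefit
balance of a forest stand, a wetland, or an arable field changes with the
hour of the day and the season.  Classic analyses average selection over
coarse blocks (day/night, summer/winter) and can miss or dilute these
dynamics.  `temposelect` implements a fine-grained alternative for hourly
GPS telemetry:

1. **Step-selection function (SSF).**  Each observed movement step is
   matched with one random step drawn from the animal's own movement
   kernel — step length ~ Gamma(k, θ), turning angle ~ von Mises(μ, κ),
   both fitted to the observed steps.  Habitat covariates are measured at
   the step endpoints and the selection coefficient β for a covariate x is
   estimated by matched conditional logistic regression, whose 1:1 form
   reduces to

   ```
   ℓ(β) = Σ_pairs −log(1 + exp(−β · (x_obs − x_rand)))
   ```

   solved by Newton–Raphson.  exp(β) is the relative selection strength
   (RSS): how many times more likely the habitat is chosen over the
   alternative at equal availability.

2. **Temporal grid.**  Step pairs are split into 26 fourteen-day periods ×
   24 clock hours = 624 temporal subsets; each subset is standardized to
   863 pairs (1,726 locations) by sampling whole pairs, and seven
   single-covariate models are fitted per subset (five habitat dummies:
   deciduous forest, coniferous forest, wetland, grassland, arable land;
   plus z-scored distance to roads and to settlements) — 4,368 fits in
   total.

3. **Cyclic smoothing.**  The 624 per-cell β̂ for each model are smoothed
   with a Gaussian additive model `β̂ = α + f_hour + f_year + f_int` built
   from cyclic cubic B-splines (basis dimension 5 for hour, 10 for year,
   tensor interaction, second-difference penalties, GCV-selected smoothing
   parameters), yielding a continuous 365-day × 24-hour selection surface
   per habitat.

4. **Selectivity metrics.**  Preference shares (% of day-hour cells with
   β > 0) and median RSS, the cumulative selectivity index Σ|β̂| over the
   five habitat models with its own smooth, diel/seasonal fold differences
   (marginal max/min ratios), and temporal repeatability (Pearson r of the
   7-model selection profile between all 194,376 unordered pairs of
   subsets).

A forward simulator (`synthetic_data`) generates patchy Voronoi landscapes
with road/settlement distance fields and moves agents by the same
gamma/von Mises kernel, choosing among M candidate endpoints with
probability ∝ exp(Σ_h β_h(day, hour)·x_h) for known, cyclically
time-varying β surfaces — so the whole pipeline is testable against ground
truth.

## Worked example

Simulate five individual-years of hourly fixes under a seasonal preference
for deciduous forest and a diel avoidance of arable land, then run the
full analysis:

```python
import warnings
from temposelect.pipeline import RunConfig, SimulateBlock, run_pipeline

config = RunConfig(
    seed=42,
    out_dir="moose_demo",
    simulate=SimulateBlock(
        n_individuals=5,
        true_beta={
            "deciduous_forest": {"a0": 0.3, "a_year": 1.0},
            "arable": {"a0": -0.3, "a_hour": 1.0},
        },
    ),
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")   # sparse-cell subsampling warnings
    result = run_pipeline(config, write=False)
```

Printing the headline numbers:

```text
fixes: 43800  steps: 43795  pairs: 43790
cells: 624  clogit fits: 4368
gamma kernel: shape=1.910 scale=128.6 m
         model_id  share_positive  median_rss_positive
 deciduous_forest           0.612                2.187
coniferous_forest           0.444                1.094
          wetland           0.291                1.089
        grassland           0.414                1.112
           arable           0.373                1.463
        dist_road           0.373                1.048
  dist_settlement           0.679                1.071
cumulative folds: diel=1.95 seasonal=2.58
repeatability: 194376 pairwise r, 43.9% negative
```

The grid bookkeeping is exact (624 subsets, 4,368 fits, 194,376 pairwise
correlations).  Deciduous forest — simulated with a positive baseline —
shows the highest preference share and median RSS; the habitats simulated
as neutral hover near share 0.5 and RSS 1.  With only five
individual-years the per-cell fits are noisy, which is why the neutral
shares are not exactly 0.5; the recovery tests in `tests/test_acceptance.py`
run the same experiment at 20 individual-years, where the smoothed
surfaces correlate > 0.95 with the injected truth.

The same pipeline runs from files (`gps_csv` + `landscape_ascii` in the
config) and from the command line:

```bash
temposelect run --config cfg.yml
temposelect simulate --config cfg.yml --tracks-out tracks.csv
temposelect metrics --fits fits.csv
temposelect validate --gps tracks.csv --landscape landscape.txt
```

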