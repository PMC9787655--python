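# scrmove

Integrated spatial capture–recapture (SCR) + movement modelling for
populations of highly mobile animals — motivated by aerial
capture–recapture and telemetry studies of polar bears on spring sea ice,
where individuals routinely traverse areas larger than the survey region
and the classic "static activity center" assumption of SCR fails.

The package jointly estimates, in one Bayesian state-space model:

1. **Movement** — each individual's latent daily trajectory s_{i,1:T},
   following either a bivariate normal random walk
   `s_{t+1} ~ N(s_t + δ∇c(s_t), σ²_sex I)` or a correlated random walk
   `s_{t+1} ~ N(s_t + γ_sex(s_t − s_{t−1}) + δ∇c(s_t), σ²_sex I)`, where
   c(s) is the distance-to-sea-ice potential whose gradient attracts
   individuals to ice (δ > 0);
2. **Detection** — search–encounter sampling over J trap cells with a
   multinomial logit of survey effort, an immediate behavioural response,
   and a half-normal distance kernel
   `η_j = α₀ + α₁ log x_{tj} + α₂ B_{it} − d²_{itj}/(2σ²_det)`, plus
   telemetry fixes `u ~ N(s_t, σ²_det I)` (GPS) or
   `N(s_t, σ²_det I + Σ_ellipse)` (Argos error ellipses, marginalized
   analytically);
3. **Abundance** — data augmentation with per-reproductive-state strata
   (z_i ~ Bern(ψ_r)), latent litter sizes n_i ~ Cat(ω), and derived
   spatiotemporal quantities: daily abundance N_At = Σ z_i 1{s_it ∈ A} in
   the surveyed region A, the cumulative superpopulation N*_At, total
   bears including dependent offspring, and per-trap-cell density
   surfaces.

Inference is a custom Metropolis-within-Gibbs sampler (conjugate updates
for ψ, ω and litters; single-site and full-trajectory block updates for
latent paths; adaptive random-walk Metropolis for the remaining
parameters), with Gelman–Rubin and effective-sample-size diagnostics. A
synthetic-data module generates complete studies (landscape, trajectories,
helicopter-transect effort, encounters, telemetry) and a simulation-study
harness measures percent relative bias and credible-interval coverage
across replicates. See `docs/methods.md` for the full model account and
the design decisions behind the sampler.

## Worked example

Simulate a desk-scale study (40 bears on a 300 × 300 km state space whose
central 200 × 200 km is ice, a 3 × 3 grid of 25-km trap cells surveyed
daily for 10 days, up to 10 GPS-tagged individuals) and refit it:

```python
import pandas as pd
from scrmove import micro_scenario, generate_dataset, SCRMovementModel
from scrmove.simstudy import _fit_config

sc = micro_scenario()                      # truths: sigma=15, gamma=0.5,
ds = generate_dataset(sc, seed=11)         # alpha0=-8, alpha1=2.5,
                                           # sigma_det=5, delta=50
print("captured:", ds.encounters.n_individuals,
      "| telemetry fixes:", ds.telemetry.n_fixes,
      "| true mean daily abundance in A:", round(float(ds.truth.n_daily.mean()), 2))
model = SCRMovementModel.from_simulation(ds, config=_fit_config(sc))
res = model.fit(iterations=2400, burn=1200, thin=3, chains=2, seed=5)
print(res.summary().round(2))
```

which prints (abridged):

```
captured: 11 | telemetry fixes: 400 | true mean daily abundance in A: 5.9
            median   q2.5  q97.5  rhat     ess
parameter
sigma_all    14.78  13.10  16.54  1.00   88.28
gamma_all     0.55   0.42   0.68  1.00   61.69
sigma_det     4.88   4.61   5.15  1.00  265.97
alpha1        0.99  -1.89   3.56  1.00  800.00
N_M          67.00  32.98  99.00  1.07   47.63
mean_N_At    10.75   5.60  17.50  1.10   52.76
N_superpop   37.00  18.00  59.02  1.07   52.70
```

Reading this: the movement parameters are sharply recovered
(σ = 14.8 km/day against a generating value of 15; persistence γ = 0.55
against 0.5; within-occasion scale σ_det = 4.9 km against 5) because ~400
telemetry fixes pin the tagged bears' trajectories. With only 11 captured
individuals the detection slope and abundance are weakly identified — their
wide 95% intervals (which cover the truths: mean daily abundance 5.9 bears,
effort slope 2.5) are the honest answer at this sample size, exactly the
sparse-data regime the model is designed to report faithfully.
`res.abundance_summary()` gives the daily and cumulative abundance series
with credible bands, and `res.density_surface()` the mean bears per trap
cell per day.

A command-line interface wraps the same workflow:

```bash
scrmove simulate --scenario scenario.yaml --out data/ --seed 3
scrmove fit --data data/ --config config.yaml --out posterior/ --seed 1
scrmove experiment --scenario scenario.yaml --replicates 10 --out exp/
scrmove summarize --posterior posterior/
scrmove plot-density --posterior posterior/ --out density.png
```

Scenario and config files are YAML mappings of the `Scenario` and
`ModelConfig`/`Priors` dataclass fields (`preset: micro` or
`preset: reference` select the built-in designs).

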