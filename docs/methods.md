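# Methods

`scrmove` implements an integrated spatial capture–recapture (SCR) movement
model: a state-space model whose latent process is the daily trajectory of
every individual in a population, observed through search–encounter
detections and telemetry, with population size estimated by Bayesian data
augmentation. This note records the model as implemented, the numerical and
design choices that were genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## Model

**State space and initial distribution.** The study region is a rectangle in
projected km coordinates discretized into square habitat cells (1 km in the
motivating polar bear analysis), each flagged as sea ice or not. Individual
*i*'s first-occasion cell is categorical over the cells with probabilities
π₁:G, uniform on ice cells and zero elsewhere; the location s_{i1} is uniform
within the drawn cell.

**Movement.** Two daily kernels are available:

- bivariate normal random walk: s_{i,t+1} ~ N(s_{it} + δ∇c(s_{it}), σ²_sex I)
- correlated random walk: s_{i,t+1} ~ N(s_{it} + γ_sex (s_{it} − s_{i,t−1})
  + δ∇c(s_{it}), σ²_sex I), with 0 ≤ γ ≤ 1.

c(s) is the distance (km) from s to the nearest ice-cell centroid (an exact
Euclidean distance transform), and ∇c is its finite-difference gradient
(central in the interior, one-sided at borders), stored per cell and looked
up piecewise-constant at continuous locations using half-open cell
membership. The sign convention is chosen so that δ > 0 attracts individuals
toward ice. With γ = 0 the correlated walk reduces *exactly* (same code
path) to the plain walk; the first transition of a correlated walk, which
has no previous displacement, uses the plain-walk mean.

Step densities are unbounded bivariate normals; locations outside the
state-space extent receive −∞ log-density, and simulation keeps locations
inside the extent by exact inverse-CDF truncated-normal draws per
coordinate. No truncation normalizer is applied: the state space is meant to
extend far beyond the data, where the distinction is numerically invisible,
and including the state-dependent normalizer turns boundary-hugging
trajectories whose step means lie outside the extent into degenerate
posterior attractors (we observed a chain finding one). The residual
incoherence between the simulated and evaluated law is confined to steps
whose Gaussian mass crosses the boundary; the synthetic designs below keep
that event rare by surrounding the ice with open water so the potential, not
the boundary, confines movement.

**Detection.** Each of J surveyed grid cells (25 km in the case study) acts
as an effective trap. On occasion t an individual at s is recorded in cell j
or not at all, categorically with multinomial-logit probabilities

    η_j = α₀ + α₁ log x_{tj} + α₂ B_{it} − d_{itj}²/(2σ_det²),

where x_{tj} is km searched, B_{it} flags the first survey strictly after an
individual's first capture, and d is the distance to the trap-cell centroid.
Cells with zero effort get η = −∞ (detection probability exactly zero):
unsurveyed cells cannot detect. Effort enters as the natural log of km with
no offset; α₀ absorbs the scale.

**Telemetry.** Up to four fixes per individual-day are normal around the
daily location with the same σ_det that scales the detection kernel —
σ_det measures within-occasion movement and is identified jointly by both
data streams. Satellite (Argos-type) fixes add an error-ellipse covariance
R diag((ca)², (cb)²) Rᵀ; because every layer is Gaussian the latent true
fix location is marginalized analytically, giving u ~ N(s, σ_det² I + Σ_e).
The axis-to-SD factor c defaults to 1/√2 (the half-normal error-ellipse
convention) and is configurable, since tags report error ellipses rather
than 1-SD ellipses.

**Abundance.** Data augmentation with a fixed reproductive state per
augmented individual (1 male, 2 female without offspring, 3 female with
offspring) and stratum-specific augmentation totals M_r (defaults
803/480/317) and inclusion probabilities ψ_r with Beta(1,1) priors. Litter
sizes n_i ∈ {1,2,3} are categorical with Dirichlet(1,1,1)-prior
probabilities ω, observed for captured females and latent otherwise. Derived
per retained draw: N_M = Σ z_i; daily abundance in the surveyed region A,
N_At = Σ z_i 1{s_it ∈ A}; the cumulative count N*_At = Σ z_i max(w_{i,1:t});
total-bear versions adding z_i 1{r_i=3} n_i; and per-trap-cell density
surfaces (bears per 625 km² cell per day, with a per-km² convenience
column). Dependent offspring are included in reported totals by default,
with a flag to exclude them.

## Priors and defaults

Vague by default: N(0, sd 10) for α₀, α₁, α₂; Gamma(0.01, rate 0.01) for
σ_sex and σ_det; Beta(1,1) for γ_sex and ψ_r; Dirichlet(1) for ω; and
N(50, sd 1) for δ. δ is *fixed* at 50 by default (case-study mode): it is
not estimable when few individuals approach the habitat edge; set
`ModelConfig(delta=None)` to sample it under its informative prior. All
hyperparameters live in `Priors` and are configurable.

## Inference

Metropolis-within-Gibbs with a fixed, documented sweep order:

1. **Parameter block** (repeated `param_repeats` = 5 times per sweep — the
   scalars are far cheaper than the trajectory updates, so repetitions buy
   effective samples almost for free): conjugate Gibbs draws for ψ_r | z
   (Beta) and ω | n (Dirichlet) and a Gibbs refresh of latent litter sizes;
   adaptive random-walk Metropolis for σ_sex (log scale), γ_sex (natural
   scale, proposals outside [0,1] rejected), δ (if sampled), α's and σ_det
   (log scale).

   Two non-obvious proposals matter here. (a) Movement parameters are
   proposed *jointly with fresh prior trajectories for the z = 0 phantom
   individuals*: retained phantom trajectories are prior draws at the
   current parameter and otherwise dominate the conditional, freezing the
   chain; because phantoms carry no likelihood, their terms cancel exactly
   in the acceptance ratio (equivalent to integrating them out), and the
   replacement draw can be deferred until acceptance. (b) A joint
   (α₀, α₁) move along the direction that leaves the logit at mean log
   effort unchanged; the posterior is wide along this ridge and
   coordinate-wise proposals crawl.

2. **Locations of detected individuals**: single-site Metropolis on each
   s_it. The local target includes the transitions t−1→t and t→t+1 *and*,
   under the correlated walk, t+1→t+2 (whose mean contains s_t through the
   persistence term), the initial-distribution factor at t = 1, the
   encounter term, and any telemetry fixes at t. Occasions are scanned in
   three interleaved passes (sites ≥ 3 apart share no factor), so each pass
   decides all its sites from two whole-path density evaluations.

3. **Initial cells**: an independence proposal from the initial law itself
   (cell from π, uniform within), so the initial terms cancel and the ratio
   involves only the outgoing transitions and occasion-1 observation terms.

4. **Trajectory blocks** for never-detected individuals: propose a complete
   trajectory from the movement prior; the prior proposal cancels all
   movement terms, leaving exactly the ratio of non-detection likelihoods
   (acceptance 1 when z = 0 or no effort was expended).

5. **Inclusion indicators**: exact two-point Gibbs,
   odds(z=1) = ψ_r P(no detections | s_i)/(1 − ψ_r).

Proposal scales adapt by Robbins–Monro (target acceptance 0.35) during
burn-in only and are frozen afterwards, so retained draws come from fixed
kernels. Chains initialize detected individuals' trajectories by linear
interpolation through their detections and fixes (snapped to ice at
occasion 1), augmented individuals from the movement prior, and parameters
from fixed moderate values (σ = 10 km, γ = 0.5, α₀ = −5, α₁ = 1,
σ_det = 5 km, ψ = 0.3); prior medians are unusable as starting values under
Gamma(0.01, 0.01) scale priors. A non-finite joint density at
initialization raises immediately with component attribution.

Convergence is summarized by the classic between/within-chain potential
scale reduction factor (flagged above 1.1) and an initial-positive-sequence
effective sample size; posterior tables report medians with 2.5/97.5
percentiles computed by linear-interpolation (type 7) quantiles.

### Correctness checks

Three independent audits back the sampler, all in the test suite:

- every Metropolis kernel's acceptance ratio is compared against the
  difference of the full joint log-density (plus explicit proposal terms)
  on recorded random proposals — no kernel uses a private likelihood;
- single-kernel stationarity: the location kernel reproduces the
  closed-form Gaussian bridge; the initial-cell kernel reproduces π by a
  chi-square test; conjugate updates match their Beta/Dirichlet closed
  forms by moment tests;
- a successive-conditional (Geweke) experiment on a micro model (T = 3, ten
  augmented individuals, four ice cells) alternates data re-simulation with
  posterior sweeps and KS-tests the ψ, σ, γ marginals against fresh prior
  draws. This experiment uses proper, moderately informative priors
  (σ ~ Gamma(16, 8), γ, ψ ~ Beta(2,2), α ~ N(0, 1.5), σ_det ~ Gamma(100,
  10)): kernel correctness does not depend on the prior, and scale-free
  vague priors make the two-sample comparison numerically meaningless. The
  micro landscape places its four ice cells ≥ 25 km from the extent
  boundary so the truncated simulation law and the unbounded density are
  exactly the same law during the check.

## Synthetic data

The generator reproduces the structure of the reference simulation design:
N = 500 individuals over K = 25 daily occasions on a case-study-sized
landscape (600 × 700 km at 1-km cells, ~420,000 cells, a coastal no-ice
band), a 5 × 9 grid of 25-km trap cells, 20 surveyed occasions, truths
σ = 15 km, γ = 0.5 (or 0 for the plain-walk variant), α₀ = −8, α₁ = 2.5,
σ_det = 5 km, δ = 50, and telemetry on the first 15 captured individuals
(ties broken by index) with four GPS fixes per occasion on every occasion.
Survey effort is generated as seeded helicopter transects — a rook-move walk
across the trap grid visiting ~14 cells per occasion with 10–35 km searched
per visited cell (roughly a 300-km flight day) — because the original
resampled real flight tracks that are not bundled here; real effort can be
supplied as CSV. Litter sizes for simulated mothers use the renormalized
reported medians.

What the generator does *not* emulate: real sea-ice geometry and its
within-season change, spatial autocorrelation of effort between days,
heterogeneous per-individual detectability, and Argos fix-rate patterns
(simulated tags fix on a regular schedule; an Argos-noise option exists to
exercise the ellipse likelihood). Passing recovery tests therefore
demonstrates self-consistency of estimator and generative model at realistic
sample sizes, not robustness to these real-data features.

**Desk-scale recovery design.** Full-scale replication (100 replicates,
multi-day chains each) is out of desk range, so recovery is demonstrated on
a reduced version of the same design chosen a priori: N = 40 individuals on
a 300 × 300 km state space (5-km cells) whose central 200 × 200 km is ice —
the 50-km open-water margins mean the attraction potential, not the extent
boundary, confines movement — with a 3 × 3 grid of 25-km trap cells at the
center, all nine cells surveyed on each of T = 10 occasions at 20–45
km/cell/day (a single helicopter can cover most of such a grid daily), up
to 10 tagged individuals, truths as above with δ fixed at 50 in the fit,
and a single male stratum with M = 100. This yields roughly one detection
per day and a dozen captured individuals per replicate — the same sparse
encounter regime as the full design at one-twelfth scale. Ten seeded
replicates are each fit with two chains of 2,400 iterations (1,200 burn-in,
thin 3); percent relative bias is reported both as mean-of-medians and
mean-of-means (the former is the headline number), and 95% CRI coverage is
judged within three binomial standard errors. Replicates with any R̂ > 1.1
are flagged, never dropped. At this scale the detection intercept/slope and
total abundance are weakly identified (a dozen detections); their wide
intervals are the honest answer, and coverage — not point accuracy — is the
criterion for abundance.

## Numerical choices and edge cases

- Half-open cell membership [lo, hi) everywhere (habitat cells, trap cells,
  region A), so seam points are unambiguous and the top/right extent edge is
  outside.
- Distances are Euclidean centroid-to-centroid km in one projected CRS; no
  geodesy.
- Zero-effort cells contribute exactly zero detection probability; a
  recorded detection in a zero-effort cell-day is rejected at validation,
  and its log-likelihood is −∞ if constructed directly.
- An encounter history pointing at trap j uses 0-based indices internally
  with J meaning "not detected"; interchange CSVs carry trap-cell ids with
  blanks for non-detection.
- The innermost encounter-likelihood and path-density loops have optional
  numba-compiled fast paths; the numpy implementations remain as the
  reference and fallback, and both satisfy the same oracle tests.
- Posterior CSVs round-trip losslessly (full-precision floats on write,
  round-trip parsing on read).

## Known limitations

- Single season, closed population, no transitions between reproductive
  states, no survival/recruitment.
- One movement class per reproductive state mapping (male/female by
  default); behavioural switching and velocity-process models are out of
  scope.
- The gradient lookup is piecewise-constant per habitat cell; at 1-km
  resolution the effect of interpolation choices is negligible, at coarse
  test resolutions it is visible in the drift field.
- The boundary incoherence discussed above means the package should be used
  as intended — with a state space extending well beyond the data — rather
  than with movements comparable to the domain size.
- Detection-side quantities (α₀, α₁, N) are weakly identified in very
  sparse designs; the sampler mixes across the (α₀, N) ridge but posterior
  intervals are honest about the uncertainty.
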