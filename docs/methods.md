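# Methods

## The behavioural model

Each trial presents a sensorimotor conflict of ordinal magnitude level
L ∈ {0, 1, 2, 3} (level 0 = unaltered), in one of two aspects — temporal
delay (100/200/300 ms) or spatial deviation (6/10/14°). The magnitude
coding is shared across aspects: analyses treat "alteration magnitude" as a
single ordinal predictor, which is the only way to span both physical units.
The 25% unaltered trials form one pool with aspect `none`; every per-aspect
analysis (psychometric slopes, per-aspect d′/γ) reuses that pool as its
level-0 point.

### Observer model (synthetic cohort)

The generator implements an equal-variance Gaussian signal-detection
observer. On a trial at level L the latent evidence is x ~ N(δ_L, 1) with
δ_0 = 0; the participant answers "identical" when x < κ. Confidence is the
evidence margin passed through a gain and offset plus metacognitive noise,

    confidence = clip(g·|x − κ| + b + ε, −3, 3),   ε ~ N(0, σ_meta),

so a single parameter σ_meta moves a participant continuously from
confidence tightly coupled to evidence quality (high γ) to fully decoupled
confidence (γ ≈ 0). Between-participant heterogeneity: κ_i ~ N(κ, κ_sd); a
shared additive shift u_i ~ N(0, δ_sd) applied to all three increments and
clipped at zero (preserving δ₁ ≤ δ₂ ≤ δ₃); σ_meta,i truncated-normal at
zero. Trial missingness (the pre-registered exclusion categories: no
movement, camera malfunction, no response) is injected uniformly at a
group rate ρ — 1.9% for controls, 8.4% for patients.

Block structure: conditions are balanced across the 5 blocks (6 trials per
altered cell and 12 unaltered per 48-trial block) and shuffled within
block. This makes first-block analyses well-defined — with a fully uniform
shuffle a 48-trial block can miss an (aspect × level) cell entirely. The
generator models no learning, reaction times, or kinematics.

### Calibration

Defaults (`src/soameta/config/default_params.yaml`) are produced by
`scripts/calibrate.py`, a staged search against the published group
statistics of the paradigm: d′ = 1.8 / 0.76, c = −0.43 / −0.73,
γ = 0.26 / 0.00 (control / psychosis), with the slope classifier in its
published ~80–95% accuracy band.

1. An analytic inversion of the homogeneous observer gives κ = d′/2 − c and
   the per-level slope s solving mean_L Φ(κ − sL) = Φ(−d′/2 − c).
2. The between-participant SDs are chosen on a coarse grid so the
   classifier lands mid-band while the d′ effect size stays near the
   published Cohen's d ≈ 1.9 (chosen: δ_sd = 0.65, κ_sd = 0.5). These two
   constraints are tightly coupled: Cohen's d = 1.9 over a 1.04 d′ gap
   *forces* a pooled between-participant SD near 0.55.
3. κ and s are re-centred by damped fixed-point iteration on simulated
   group means (participant heterogeneity shifts the group mean of the
   nonlinear z-transformed rates).
4. σ_meta is grid-searched per group for the γ targets (1.1 control, 3.5
   psychosis).

Clinical scores use truncated-normal marginals with means/SDs matching the
published cohort table (PANSS Positive 15.1 ± 3.2, Negative 15.2 ± 5.2,
Total ≈ 62.8). PANSS Positive is generated as a linear function of the
participant's *realized* γ plus noise with correlation ρ = −0.47, making
the generative coupling target exact; coupling to the latent σ_meta instead
would leave the realized correlation an unknown attenuated quantity. Other
scales are uncoupled. This is a phenomenological stand-in: it reproduces
the correlation structure the analyses probe, not a mechanism.

### What the generator does and does not show

Passing tests on synthetic cohorts demonstrate that the analysis stack
recovers known generative structure (rates, d′, γ, slopes, model signs,
couplings) at the study's design size. They do not validate the observer
model against real behaviour: real data have learning and fatigue effects,
non-Gaussian evidence, serial dependencies, and response-scale
idiosyncrasies (confidence clumping at slider landmarks) that the
generator deliberately omits.

## Analysis choices

* **Extreme-rate correction**: log-linear, (count + 0.5)/(n + 1), applied
  to every participant uniformly (avoids the conditional bias of
  correcting only extreme cases). Which correction the original analysis
  used is not documented; this is the package's default and only the
  corrected path is exposed.
* **Signal convention**: the unaltered trial is the signal, so negative c
  = bias toward self-attribution. This is the convention under which the
  published group criteria (−0.43 vs −0.73) line up with patients
  over-attributing.
* **γ**: binary accuracy from the judgment's correctness; confidence
  treated as fully ordered; tied pairs excluded (γ is defined on
  concordant/discordant pairs only). Counting is O(n log n) by sorting the
  two accuracy classes; the test suite pins it to an O(n²) enumeration
  oracle. Participants with undefined γ (no accuracy contrast or constant
  confidence) are dropped from group tests with a warning.
* **Classifier**: features are the two slopes only (intercepts recorded
  for diagnostics, unused); centroids are means of per-participant slope
  vectors of the retained set, always computed from full retained trials.
  Trial subsampling applies to held-out participants only — the intended
  use-case is classifying a new individual from few trials against
  established group norms; a `subsample_retained` switch inverts this.
  Draws that leave an (aspect × level) cell empty are rejected and redrawn
  (≤100 attempts). Exact distance ties go to `control` (with a warning);
  measure-zero in practice but kept deterministic. Participant sampling
  and trial sampling use independent seeded RNG streams so grid cells
  share their participant splits.
* **Permutation null**: labels permuted every iteration (group sizes
  preserved) before centroid computation; unbiased at 50%. Note that the
  *real-label* classifier on two groups drawn from one distribution is at
  chance only in expectation across cohorts: within a fixed cohort the
  held-out members share their group's realized mean-shift with the
  centroids, biasing accuracy upward. The permutation null is therefore
  the correct chance reference, and the chance-level test averages across
  cohorts.
* **Mixed models**: magnitude enters as the centered ordinal level; its
  quadratic term is Gram-Schmidt orthogonalized against the linear term
  (the confidence profile is U-shaped: high when clearly-own or clearly
  altered). Group is sum-coded control = +1 / psychosis = −1 — under this
  coding the magnitude main effect is the mean of the group slopes and the
  interaction is half their difference, both negative, matching the
  published sign pattern; treatment coding would flip the interaction
  sign. Aspect: spatial +0.5 / temporal −0.5 / unaltered 0. Accuracy:
  correct +1 / incorrect −1. Random effects: per-participant intercept and
  magnitude slope. BIC = −2 logL + k log(n_obs) with k counting fixed
  effects plus the three random-effect (co)variance parameters (plus the
  residual variance in the linear case) — the same counting lme4 uses, so
  BICs are comparable across backends. No installed Python package fits ML
  logistic mixed models, so the package includes a Laplace-approximation
  fitter (vectorized per-participant Newton mode-finding inside an L-BFGS-B
  outer loop); it matches lme4::glmer (same approximation) to ~1e-3 on
  log-likelihood and coefficients in the test suite. Wald z tests
  condition on the variance parameters, as glmer's do. Linear fits run
  statsmodels MixedLM under ML with both lbfgs and powell, keeping the
  better likelihood — lbfgs alone occasionally stalls in a local optimum,
  which would corrupt a BIC comparison between nested models. Fits with
  near-zero random-effect SD or |correlation| > 0.999 are flagged
  singular but retained, and non-converged candidates are reported and
  skipped in the comparison.
* **Correlations**: uncorrected two-sided Pearson p-values (mirroring the
  exploratory report this table receives), with a Holm-adjusted column
  emitted alongside. Cells with < 3 pairs or a constant vector are flagged,
  not dropped.
* **Participant-level exclusion** is list-based (IDs supplied in config),
  since the criteria live in a pre-registration rather than in published
  text; the synthetic generator produces no participant-level exclusions.

## Problem sizes and tolerances

Defaults chosen as desk-scale analysis settings: classifier checks run at
2,000 iterations (10,000 remains the production default and a config
option); the robustness grid at 400 iterations per cell; sign-recovery
Monte-Carlo at 100 cohorts of the full study size; calibration checks
average group statistics over 8 cohorts (a single 30-participant group
mean has sampling SD ≈ 0.13 for d′ — a direct consequence of the
realistic between-participant spread — so a single-cohort check against a
±0.15 band would be underpowered). Monte-Carlo assertions carry explicit
slack (2 percentage points on grid monotonicity; ±0.03 on null accuracy).

## Known limitations

* The logistic fitter supports exactly the 2-D random-effect structure the
  analyses need (intercept + one slope), not arbitrary designs.
* Satterthwaite degrees of freedom are not implemented; fixed-effect tests
  are Wald z (logistic) / Wald with normal reference (linear). Model
  *selection* and sign recovery, not coefficient-for-coefficient
  replication, are the package's claims.
* γ is the only metacognitive measure: first-order performance differs
  between groups by design, which rules out measures that require matched
  performance (meta-d′ / M-ratio).
* The synthetic PANSS/SPQ-B marginals are crude; only the single coupling
  needed for correlation-recovery tests is modelled.
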