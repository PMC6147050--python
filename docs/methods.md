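# Methods

## The scientific problem

Helpers in cooperatively breeding societies may divide labour in
qualitatively different ways: all individuals may do all tasks, with overall
commitment changing with age (generalist helpers); individuals may switch
tasks as they age (temporal castes); or individuals may be permanently
specialized on particular tasks (permanent castes). The diagnostic for
*task specialization* is a within-individual trade-off: individuals that do
more of one cooperative task do systematically less of another. In a
hierarchical model of behaviour, such trade-offs appear as **negative
correlations between the individual-level random effects** of two
cooperative behaviour categories.

This package implements that test for instantaneous scan-sampling data from
social groups (the motivating system is captive Damaraland mole-rat colonies,
where each group is watched for 12 h sessions and every nonreproductive
member's behaviour is recorded at 4 min intervals, 180 sampling events per
individual per session).

## The model

Behaviour at each sampling event is one of six categories: `rest` (the
reference), `active_nonhelping`, `eat`, and the three cooperative categories
`food_carry`, `nest_building`, `work`. For observation row *r* (one
individual in one scan session) and non-reference category *k*:

    eta[r,k] = alpha_k + x_r' beta_k + u[ind(r),k] + v[scan(r),k]
               + w[litter(r),k] + z[group(r),k]
    P(k | r)    = exp(eta[r,k]) / (1 + sum_j exp(eta[r,j]))
    P(rest | r) = 1 / (1 + sum_j exp(eta[r,j]))

Random effects at each level are 5-variate normal with per-category SDs
`sigma` and correlation matrix `Omega`, parameterized noncentred through the
Cholesky factor `L` of `Omega`: `u = diag(sigma) L zeta`, `zeta ~ N(0, I)`.

Three nested variants are fitted **separately per sex**:

* **M1** — intercepts + individual-level random effects. Its `Omega_individual`
  carries the specialization test: individual effects are deviations from the
  population average across the whole sampled developmental window.
* **M2** — M1 plus fixed covariates: age (1st–3rd order polynomial),
  group size (1st–2nd order), pup presence (binary), relative body mass.
  All continuous covariates are z-scored; polynomial terms are raw powers of
  the z-scored base value (this keeps the linear coefficient interpretable;
  the powers are deliberately not re-standardized).
* **M3** — M2 plus random effects for scan session, litter and group.
  The scan effects absorb temporal pseudoreplication within a session; with
  these extra levels the individual effects are no longer deviations from the
  population average, so M3 is used for fixed-effect description, not for the
  specialization test.

The likelihood is evaluated on per-(individual, scan) multinomial count
vectors. Because every event within a scan shares its covariates and random
effects, these counts are the sufficient statistics of the event-level
categorical model; the collapse changes no posterior and shrinks the
computation by the number of events per scan. Events are treated as
conditionally independent given the random effects — real behavioural
sequences are autocorrelated at 4 min spacing, a simplification shared by
model and generator (see Limitations).

### Priors

Stated priors are "weakly informative"; the concrete defaults here are
intercepts `Normal(0, 5)`, slopes `Normal(0, 2)`, random-effect SDs
`Exponential(1)`, and correlation Cholesky factors `LKJ(2)`. All four are
configurable (`PriorConfig`) and recorded in output metadata. A
prior-predictive test (likelihood weight 0) verifies the sampler reproduces
these priors.

### Sampling

No probabilistic-programming backend is used: the package carries its own
No-U-Turn sampler (slice variant with doubling, dual-averaging step-size
adaptation targeting 0.8 acceptance, windowed diagonal mass-matrix
estimation, max tree depth 10, divergence threshold 1000 on the Hamiltonian
error). Gradients of the joint log density are analytic; the unconstrained
parameterization of each correlation matrix (canonical partial correlations
through `tanh`) and its LKJ-plus-Jacobian prior term are differentiated by
complex step (h = 1e-20, exact to machine precision). Defaults mirror the
study design: 3 chains of 1000 iterations, half warmup. Convergence policy:
warn (not fail) at split-R-hat > 1.05; error only if every post-warmup
transition diverges.

Reference sampler checks: analytic-gradient agreement with finite
differences; exact moments on correlated Gaussian targets; prior recovery
under zero likelihood weight; interval coverage in recovery simulations.

## Relative mass

"Relative mass" is the conditional residual of a sex-specific linear mixed
model `log(mass) ~ log(age) + (1 | group)` (REML by default, ML available),
evaluated at the mass record nearest in time to the scan (ties to the
earlier record). Subtracting the group effect makes the covariate "heavier
than expected for sex, age *and group*", matching its intended meaning of
mass relative to same-sex, same-age groupmates; whether the original
analysis conditioned on the group effect is not documented, so the
conditional interpretation is this package's choice. The model is fitted
with statsmodels `MixedLM`; group effects are conditional modes (BLUPs).

## Derived quantities

* **WAIC** = −2(lppd − p_waic), lppd via log-sum-exp over draws, p_waic the
  summed pointwise posterior variance of the log-likelihood; the pointwise
  unit is the (individual, scan) count row. Used as a general indicator of
  fit across M1→M3, not for model selection.
* **Correlation summaries**: posterior mean, SD and equal-tailed 95% CrI per
  behaviour pair, taken directly from the draw-wise correlation matrices
  (correlating point estimates of unit intercepts inflates the values and is
  deliberately avoided). Pairs involving the reference category are not
  estimable in this parameterization and are not reported; "significant"
  means the 95% CrI excludes zero. No multiple-testing correction is applied
  across the 10 pairs.
* **Specialization verdict**: "specialization detected" iff some cooperative
  pair (`work`, `food_carry`, `nest_building`) is significantly negative.
* **Predicted-probability curves**: fixed effects only (random effects
  excluded), other covariates at their sample mean (zero on the z scale,
  pups absent), 50 grid points over the observed covariate range, reported
  on the original scale, with 89% equal-tailed percentile bands.
* **Pup-presence contrast**: per posterior draw, the difference in each
  category's fixed-effects probability between pups present and absent;
  significance from the draw-wise contrast distribution (not from
  overlapping prediction intervals, which over-penalize shared covariate
  uncertainty).

## The synthetic-data generator

`TruthConfig` defaults emulate the motivating study design: 35 groups, 60
nonreproductive females and 56 males (plus a breeding pair per group,
excluded from analysis but counted in group size), 10 scan sessions per
individual of 180 events each, first-scan age ≈ 136 days (SD 9), inter-scan
interval 64.5 days (so last-scan age ≈ 716 days). Litters within a group are
staggered by one inter-scan interval; the youngest litters are under 40 days
old during their older groupmates' early sessions, which is what makes the
`pups_present` covariate vary. Group sizes are a random partition (uneven,
as in real colonies). Masses follow `log m = 2.2 + 0.42 log(age) + group
effect (SD 0.10) + noise (SD 0.05)` every 14 days, giving ~70 g yearlings
and ~140 g adults.

Default effect magnitudes sit in the range of the motivating study's
estimates (|rho| ≤ 0.8, individual-level SDs 0.3–0.9, scan/litter/group SDs
0.2–0.3); they are defaults for testing, not claims about any real
population. Scenario presets:

| scenario | fixed effects | individual-level Omega |
|---|---|---|
| `no_specialization` | shared hump-shaped age effects on cooperative categories | all pairs +0.4 |
| `temporal_caste` | age trajectories that cross (nest peaks early, work late) | identity |
| `permanent_caste` | mild age effects | work × food_carry = −0.8 |
| `null` | none | identity (SDs 0.5; zero SDs would leave the correlations unidentified and the calibration test meaningless) |

What the generator does **not** emulate: within-scan behavioural
autocorrelation, births/deaths/dispersal during the study, observation
error, and irregular inter-scan spacing (the real spacing varies; here it is
a configurable constant plus the litter stagger). Passing tests therefore
demonstrate correctness of the inferential machinery under the model's own
assumptions, not robustness to their violation.

## Numerical choices

* Reference category fixed to `rest` (configurable); non-reference order is
  fixed (`active_nonhelping, eat, food_carry, nest_building, work`).
* z-scores use the sample (n−1) SD within the sex-specific dataset; a
  zero-variance covariate is an error, not a silent constant column.
* Nearest-mass ties resolve to the earlier record. Ages are in days.
* Group size counts all living members including breeders (whether the
  original covariate included them is undocumented; this is configurable at
  the data level since group size is a column, not a derived quantity).
* Scan-level effects default to one unit per (individual × scan); a
  group-shared mode (`scan_effect_grain="group_scan"`) is available because
  the grain of the original scan effect is not documented.
* `correlated_secondary_levels=False` drops the correlation matrices (not
  the SDs) of scan/litter/group effects for speed; the individual level is
  always fully correlated.
* Multinomial coefficients are dropped from the pointwise log-likelihood
  (constant across parameters and variants, so WAIC differences are
  unaffected).

## Problem sizes in the test suite

Stochastic tests run at reduced scale, chosen as the smallest designs at
which the checks are well powered: recovery at 40 individuals × 400 events
with 2 chains × 600 iterations (20 replicates, pooled 95%-interval coverage
≥ 0.9 per parameter class); specialization power at 40 individuals × 480
events (20 replicates, ≥ 18 detections); WAIC ordering at 12 individuals
(M3 beats M1 in ≥ 8/10); curve recovery at 20 individuals (interior work
peak in ≥ 18/20). `scripts/acceptance.py` recomputes the same quantities
with slightly fewer replicates.

## Known limitations

* The NUTS implementation is serial; chains run sequentially.
* M3 at the full study design (≈ 1160 scan units) samples in minutes, not
  seconds; the diagonal-secondary-levels option is the intended default for
  exploratory use.
* Between-scan dependence (e.g. seasonal effects) is not modelled; scan
  effects are exchangeable.
* Rare behaviours are not handled specially; categories observed a handful
  of times yield prior-dominated intercepts (the motivating analysis
  excluded an extremely rare category for the same reason).
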