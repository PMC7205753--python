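# Methods

This note documents the statistical model, the simulation conventions, the
numerical choices, and the limitations of `seamtrial`. It is the package's
own account of its science; every number quoted here is computed by the test
suite or by `scripts/acceptance.py`.

## 1. The surrogate–primary linkage model

The linkage between the continuous surrogate score `X` and the time-to-event
primary endpoint `T` is a log-normal accelerated-failure-time regression

    log(T) = b·X + a + ε,   ε ~ N(0, σ²).

The direction convention throughout the package is that the primary endpoint
is *time to confirmed improvement*: shorter times and more events indicate
benefit, and a negative slope `b` means higher surrogate scores shorten the
time to improvement.

**Priors and sampler.** Coefficients `(a, b)` carry flat improper priors.
The scale carries a Gamma(0.001, 0.001) prior placed, by default, on the
precision `1/σ²`, which makes every conditional conjugate: the sampler is a
Gibbs scheme alternating (i) truncated-normal data augmentation of the
latent log event time of each right-censored record (lower-truncated at the
log censoring time; deep tails beyond 6 SDs use a Marsaglia exponential-tail
sampler), (ii) a joint bivariate-normal draw of `(a, b)`, and (iii) a Gamma
draw of the precision. Whether such a vague Gamma prior belongs on σ, σ², or
the precision is not identifiable from a reported posterior mean; the
package exposes `PriorSpec(scale_prior_on="sigma")`, which replaces step
(iii) with a random-walk Metropolis step on log σ (step 0.15), for users who
want the prior literally on σ. On complete data the two variants agree to
well within Monte-Carlo error (unit-tested).

Defaults: 6000 sweeps, 1000 burn-in, one chain, fixed seed. With flat priors
and no censoring the posterior mean of `(a, b)` equals the least-squares
solution up to Monte-Carlo error, which the tests verify against
`numpy.linalg.lstsq` using batch-means MC standard errors.

**Validity check.** `check_slope_validity` demands that the equal-tailed 95%
credible interval of `b` exclude zero (closed-interval convention: a
boundary zero fails). A slope interval covering zero means the surrogate
carries no usable information about the primary endpoint and surrogate-based
interim selection should not proceed.

**Reference fixture.** No real historical dataset ships with the package.
The synthetic generator draws `X ~ Uniform(−4, 4)` (the full surrogate
scale), `n = 500` complete records, and linkage parameters
`(a, b, σ) = (0.16, −1.37, 1.53)` — the reference posterior means used in
the worked design example, whose slope interval `[−1.53, −1.22]` excludes
zero. The uniform surrogate law and n are this package's own choice of a
realistic, well-conditioned fixture; fitting the model to this fixture
reproduces the generating values within sampling error (tested at ±5%
relative at n = 5000), but the fixture is a stand-in, not a reconstruction
of any particular study.

## 2. Trial simulation

**Enrollment** is deterministic at a constant rate (default
`n_arms·n_stage1/maturation = 80/26` subjects per week), subject `j`
arriving at week `j/rate`. Randomization uses permuted blocks over the open
arms (all arms before the interim; control + selected after). With the
defaults this puts the interim analysis (IA) — the first week at which 20
subjects per arm have completed the 26-week surrogate maturation window — at
calendar week 52, with 160 subjects on study, exactly reproducing the
design-example accounting.

**Event and dropout times.** Each subject's latent event time is exponential
with hazard `λ = −ln(1 − rate_3yr)/156` per week; dropout is an independent
exponential calibrated the same way to the 5% 3-year dropout fraction and
censors the primary endpoint only (the surrogate is assumed observed for
everyone reaching 26 weeks of exposure). Administrative censoring caps each
analysed subject's follow-up at 156 weeks.

**Surrogate generation** inverts the linkage at the *latent* event time:
`X = (log T − a)/b + ε′`, `ε′ ~ N(0, (σ/|b|)²)`. The model links the
surrogate to the event process itself; censoring is an observation process
and does not alter `X`. Slopes with `|b| < 1e−6` are rejected (the inversion
divides by `b`).

**Interim rule.** Let `X̄_max` be the largest active-arm surrogate mean among
the mature stage-1 subjects and `X̄_0` the control mean. If
`X̄_max − X̄_0 ≥ Δ` the best arm continues alongside control; otherwise the
trial stops for futility. Exact ties are broken uniformly at random. Only
single-arm selection is implemented.

**Stage-2 quota convention.** The preplanned 124/arm stage-2 subjects of
each continuing arm *include* that arm's pre-IA enrollees whose surrogate
was immature at the IA. This is the only reading under which the printed
totals close: 4·20 stage-1 + 2·124 stage-2 + 40 excluded immature
dropped-arm subjects = 368 preplanned, 328 analysed. The 40 dropped-arm
immature subjects remain on study but contribute to no test statistic.

**Counterfactual continuation.** For the false-stopping ("flip-flop")
probability, a stopped trial is re-completed with the observed-best arm
carried forward as if selected; the reported quantity is the *joint*
probability (stopped AND counterfactually significant) over all replicates —
the convention consistent in magnitude with the worked example (3.6% joint
vs 5.1% futility).

**Seeding.** A master seed spawns one `SeedSequence` per replicate; within a
replicate, separate streams drive stage-1, the tie-break, and stage-2, with
the stage-2 stream additionally keyed by the selected arm. Re-deciding the
same replicate at a different threshold therefore reuses identical stage-1
data and — whenever the same arm is selected — identical stage-2 data:
common random numbers across threshold sweeps and sample-size searches, and
bitwise reproducibility at a fixed master seed.

## 3. Final analysis

Per comparison (active arm i vs control), `U` is the log-rank
observed-minus-expected event count in the active arm with hypergeometric
variance `V`, positive `U` meaning benefit. Stage-1 statistics use the 20
mature stage-1 subjects per arm censored at the IA calendar week; the final
statistic for the selected comparison uses its full 144+144 analysed
subjects at full follow-up, and the stage-2 increment is
`Z₂ = (U₂−U₁)/√(V₂−V₁)` (zero-information guards: `V₁ = 0 ⇒ Z₁ = 0`;
`V₂−V₁ ≤ 1e−12 ⇒ Z₂ = 0`, i.e. p₂ = 0.5).

Stage-wise multiplicity uses Dunnett's many-to-one test with the
equal-allocation correlation ρ = 0.5: the adjusted p-value of a subset S is
`1 − P(max_{i∈S} Z_i < max observed z)`. For equicorrelated structures this
orthant probability is computed by an exact one-dimensional Gauss–Hermite
quadrature (96 nodes, agreeing with the general multivariate-normal CDF
routine to < 1e−6, unit-tested); general correlation matrices go through
`scipy.stats.multivariate_normal.cdf`.

The closed test enumerates all `2^k − 1` intersections. For each S, p₁ is
the stage-1 Dunnett p over S; p₂ is the unadjusted stage-2 p of the selected
arm if S contains it and 1 otherwise (the selection-respecting substitution
`p₂,S = p₂,S∩S₂`, with the empty intersection set to 1). The combination is
the weighted inverse-normal function with weights
`w₁ = √(n₁/(n₁+n₂))`, `w₂ = √(n₂/(n₁+n₂))` from the per-comparison
preplanned sample sizes (n₁ = 40, n₂ = 248 at the defaults); the square
root is forced by the constraint `w₁² + w₂² = 1`. `H_i` is rejected iff
every intersection containing i combines below α = 0.025 (one-sided).
P-values are clipped to `[1e−15, 1−1e−15]` before the normal quantile.

A consequence of the substitution rule is that only the selected arm can be
rejected — intersections containing only dropped arms carry p₂ = 1 and never
reject. Overall power is the probability of rejecting at least one
elementary hypothesis; a futility stop performs no final test and counts as
a failure.

The traditional comparator is a single-stage four-arm design: all subjects
followed 156 weeks, per-comparison log-rank Z, Dunnett critical value at
one-sided 2.5% (2.3490 for k = 3, ρ = 0.5), power = P(max Z exceeds the
critical value).

## 4. Operating characteristics and problem sizes

`run_oc` aggregates over replicates: per-arm selection probabilities,
carry-forward/futility, overall and conditional power, false stopping,
expected enrollment, with binomial MC standard errors. The package's
standard run size is 5000 replicates (MC SE ≤ 0.7 percentage points on a
probability), the size used by `scripts/acceptance.py` for every reported
quantity including the sample-size searches; several unit and property
tests use 150–1500 replicates, which is enough for the 3-SE bands they
assert. Sample-size searches (`find_stage2_n`, `traditional_design_n`)
bisect a monotone grid under common random numbers.

Exact identities hold by construction on realized counts and are tested:
carry-forward + futility = 1, Σ selection = carry-forward,
conditional power = overall power / carry-forward, and (with deterministic
enrollment) expected N = carry·368 + futility·160.

## 5. Design choices on genuinely open points

- **Prior placement** on the precision by default (conjugacy; the σ-variant
  is a switch) — the source formulation is ambiguous.
- **Null configuration** for threshold calibration: all four arms at the
  10% control rate.
- **False stopping** reported jointly, not conditionally on stopping.
- **Dropout** does not truncate the surrogate observation window; the
  surrogate of every subject reaching maturation is used.
- **Dropped-arm follow-up** after the IA is never used in test statistics;
  dropped-arm stage-1 subjects enter stage-1 statistics only (their stage-2
  increment is identically zero).
- **Stage-1 analysis set**: the mature 20/arm only; pre-IA immature
  enrollees of continuing arms carry no 26-week exposure at the IA and first
  appear in the stage-2 increment.
- **Weights** from per-comparison (not total-stage) preplanned sizes.

## 6. What the synthetic conditions do and do not show

The simulator *is* the study object here — the package's claims are about
design operating characteristics under its stated generative model:
exponential event times, a log-normal linkage with homogeneous `(a, b, σ)`
across arms, constant enrollment, independent exponential dropout. Passing
tests demonstrate correct implementation of that model and calibrated
operating characteristics under it. They do not demonstrate robustness to
real-data features outside the model: non-proportional or non-exponential
hazards, arm-dependent linkage (different mechanisms of action), enrollment
ramp-up, informative dropout, or surrogate measurement drift. The
historical-data generator likewise emulates structure (uniform surrogate,
optional administrative censoring), not any particular clinical dataset.

## 7. Known limitations

- Single-arm selection only (`n_select = 1`); the multi-arm-selection field
  is reserved but unimplemented.
- Log-normal errors only; Weibull/log-logistic variants are extension hooks.
- One historical study; no hierarchical borrowing across studies and no
  study-level summary-data mode.
- The closed test assumes k ≤ 5 active arms (full subset enumeration).
- Conditional power is a ratio estimate; its MC error exceeds that of the
  underlying probabilities at small replicate counts.
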