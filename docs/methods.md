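# Methods

## Model

`dissonet` models a pair of binary directed networks on one actor roster —
a friendship layer F and a dislike layer D, no self-ties — as a single
exponential-family distribution over all 2n(n−1) tie variables,
P(X=x) ∝ exp(θ·z(x)). The statistic vector z collects configuration counts;
the implemented effects and their exact definitions are documented in
`dissonet.effects`. Three conventions matter for interpretation:

- **Homophily** is the *negative* summed absolute attribute difference over
  ties, so a positive parameter means attraction to similar others.
- **Attributes enter uncentered** (raw instrument scores) in sender,
  receiver, homophily, mutual-product and mutual-sum-exchange effects.
- **Exchange counting is over ordered pairs** (i, j): "i befriends j while
  j dislikes i" and its mirror image are distinct events, so a dyad
  entangled in both orientations contributes 2. This matches the cross-layer
  exchange statistic Σ x^F_ij x^D_ji used by the model; reports describing
  "pairs exhibiting exchange" in the descriptive output use the same ordered
  convention.

The alternating statistics (in-/out-star, transitive triangle, two-path)
use a geometric damping constant λ, default 2, exposed per effect in
`EffectSpec`. λ = 2 is the conventional default of estimation software for
this model family; it is a smoothing choice, not an estimated quantity.

The default multivariate specification (`cohort_model_spec`) includes, for
friendship: arc, reciprocity, two-path, alternating in-star, alternating
out-star, alternating transitive triangle and alternating two-path; for
dislike the same minus the two-path and transitive-closure terms (sparse
negative-tie layers carry too few two-paths to identify them); one
cross-layer exchange effect; sender/receiver/homophily per attribute on
both layers; mutual product of wellbeing on friendship and of depressed
mood on dislike; and mutual-sum-exchange effects for wellbeing and
depressed mood. "Simple connectivity" is read as the within-layer directed
two-path count and "multiple connectivity" as the alternating two-path
statistic; path closure uses the transitive orientation (i→k→j closing
i→j). Cyclic closure variants are out of scope.

## Sampling

`simulate` runs a Metropolis chain proposing a uniformly random tie
variable (either layer) and toggling it with probability min(1, exp(θ·Δz)).
Change statistics Δz are computed incrementally from local neighbourhood
counts — never by recomputing z — in numba-compiled kernels; the test suite
audits the incremental bookkeeping against from-scratch recomputation at
every retained sample on small graphs, and the kernels against a pure-numpy
reference implementation. Defaults scale with the number of tie variables
N = 2n(n−1): burn-in 50·N proposals, thinning N proposals per retained
sample. A degeneracy guard warns when a layer's density exceeds 0.95 or the
acceptance rate falls below 0.1%.

All randomness flows through explicit integer seeds (numpy `SeedSequence`
spawning per chain segment); identical seeds give identical batches.
Simulation is unconditional — nothing is held fixed at observed margins.

## Estimation

`fit` solves the moment equation E_θ[z(X)] = z(x_obs) by three-phase
Robbins–Monro stochastic approximation:

1. **Phase 1** simulates `phase1_samples` (default 100) draws at θ₀ and
   estimates the scaling matrix D as the statistic covariance (the
   score-information identity), with a 1e-6 ridge. θ₀ is zero except arc
   effects, initialised at the log-odds of the observed layer density with
   a half-tie continuity correction.
2. **Phase 2** iterates θ ← θ − a·D⁻¹(z(X_t) − z_obs) against a persistent
   chain, with subphases of (100, 200, 400, 800) iterations and the gain a
   (initial 0.1) halved per subphase. Each update is clipped elementwise at
   ±0.5 to stop early-phase overshoot; the returned estimate is the average
   of θ over the final subphase (Polyak-style averaging).
3. **Phase 3** simulates `phase3_samples` (default 1000) draws at θ̂.
   Convergence t-ratios are (simulated mean − observed)/simulated SD per
   effect; |t| < 0.1 for all effects declares convergence. Standard errors
   are sqrt(diag(Σ̂⁻¹)) with Σ̂ the phase-3 covariance, and an effect is
   flagged significant when |θ̂| ≥ 2·SE.

On non-convergence, phase 2 restarts from the current θ̂ up to
`max_retries` (default 3) times; failure is returned with a flag and full
diagnostics, never silently. These schedule defaults are engineering
choices sized for cohorts around n≈60; none are reported quantities, and
all are overridable. Note that the estimated SE approximates a fixed
quantity (the inverse Fisher information); enlarging the phase-3 sample
reduces the Monte-Carlo scatter *of the SE estimate*, not the SE itself,
and that is what the corresponding regression test checks.

`gof` simulates at θ̂ while tracking both the fitted statistics and any
auxiliary (not-fitted) statistics, reporting t = (observed − simulated
mean)/simulated SD per statistic (NaN when the simulated SD is zero).
Auxiliary statistics are appended to the model vector with zero parameters,
which leaves the sampling distribution unchanged.

## Dissonance log-odds

Because the model is an exponential family, the log-probability change from
completing a dissonant dyad is θ·Δz, and its attribute-dependent part is

L(a_i, a_j) = s_F·a_i + r_F·a_j + s_D·a_j + r_D·a_i − (h_F + h_D)·|a_i − a_j| + m·(a_i + a_j)

with a_i the friendship sender's score (the dislike receiver) and a_j the
friendship receiver's (the dislike sender). `logodds_table` evaluates L on
the four low/high configurations A (low, low), B (low, high), C (high,
high), D (high, low) and rounds half-away-from-zero to one decimal,
reporting unrounded values alongside. Two caveats are deliberate:

- Purely structural contributions (arc, reciprocity, the bare exchange
  count) are constant across attribute configurations of the same dyad and
  omitted; the table shows contrasts, not full tie log-probabilities.
- The computation is per attribute: cross-terms from other attributes are
  likewise constant at fixed values of those attributes and excluded.

The uncentered-attribute and negative-absolute-difference conventions above
are the ones under which this composition is exactly the model's dyad-level
contrast; they are used consistently in estimation and reporting.

## Synthetic cohorts

No public peer-nomination dataset carries both a dislike layer and these
mental-health instruments, so the package ships a generator
(`dissonet.synth`) that emulates the study design end to end: two
same-gender cohorts of about 59 and 61 actors, friendship density near
0.07–0.09, dislike density near 0.02, substantial friendship reciprocity,
triadic clustering, a handful of dissonant dyads, and attribute
distributions with the cohorts' reported moments (wellbeing ≈ 61.1/11.6 and
58.2/12.6; depressed mood ≈ 4.0/5.0 and 6.0/5.1; 63% SES prevalence).

- **Wellbeing** is normal, rounded, clipped to the 14–84 instrument range;
  the pre-clip mean/SD are moment-matched by a fixed-point iteration over
  the discretised law so the *clipped* scores hit the profile moments
  (naive clipping at ~2σ would bias the mean by ≈ −0.15).
- **Depressed mood** is negative binomial (right-skewed, overdispersed,
  mode at low scores) matched to the profile mean/SD and clipped to 0–26;
  the distributional family is a modelling choice — the emulated studies
  report only means and SDs.
- **Networks** are drawn from the ERGM itself. Profile strengths map to
  effect weights: reciprocity strength → the friendship reciprocity
  parameter, closure strength → alternating transitive triangle,
  dissonance strength → exchange, and an optional
  `dissonance_attr_weight` → mutual-sum-exchange on wellbeing (default 0:
  a single scalar cannot set two weights independently, and the empirical
  sign pattern — large positive exchange, small negative mutual-sum — makes
  any hard-wired ratio arbitrary). The two arc parameters are tuned by
  damped stochastic root-finding on the logit scale: 5 probe simulations
  per step, a 0.35-damped clipped logit correction, acceptance when
  realised densities sit within half the ±30% band (or within two ties on
  sparse layers, where the relative band is smaller than one tie's worth of
  density). The final network is redrawn until it falls inside the full
  band, and tuning failure raises with diagnostics.
- The default closure strength is 0.3. Stronger closure (≳0.5 at these
  densities) pushes the model into the bistable near-degenerate regime —
  probe simulations then oscillate between a sparse and a clustered phase
  and no arc value yields the target density. The damping constant 0.35
  reflects that the realised density responds 2–3× more steeply than
  logistic in the arc parameter once positive structural effects are
  active.

What the generator does *not* emulate: cross-gender nomination patterns
(cohorts are generated single-gender and concatenated when a mixed roster
is needed), out-of-roster nominations, missing data, longitudinal change,
and any dependence of attributes on network position. Tests passing on
synthetic cohorts therefore demonstrate correctness of the machinery and
recoverability of known parameters — not that any substantive finding
generalises to real school data.

## Numerical choices and degenerate inputs

- Ridge 1e-6 on all inverted covariances.
- Tie variables are proposed uniformly; i=j is never proposed, and
  requesting a change statistic for i=j is an error.
- A constant attribute under an attribute effect is rejected before
  fitting (the moment equation for that effect is degenerate).
- Zero pooled variance makes the two-sample t undefined (error); a layer
  with no ties yields an explicit empty mixing-proportion result rather
  than NaNs.
- Reported densities and mean degrees carry 5 decimals in the descriptive
  tables; log-odds round half-away-from-zero to one decimal with unrounded
  values alongside.
- Actor ids are arbitrary strings externally and dense 0-based indices
  internally; self-nominations in input files are dropped with a warning
  (roster instruments permit accidental self-selection), unknown ids are
  fatal.

## Test problem sizes

The suite exercises exact-enumeration oracles at n=3 (all 4096 two-layer
states), change-statistic audits on 8-node fixtures (≥200 toggles against
full recomputation), parameter recovery at n=40 with 20 replicate fits of a
five-effect model, generator checks at n=30 over 10–12 seeds, and synthetic
end-to-end fits at n=30. These sizes are the package's chosen desk-scale
defaults for routine verification; the statistical assertions use fixed
seeds with tolerance bands sized from the Monte-Carlo error at those sizes
(e.g., attribute-moment checks pool several seeded cohorts of 2000 so the
band sits several standard errors wide). The refit-convergence check uses
an extended phase-2 schedule (an extra 1600-iteration subphase) because the
default schedule leaves just enough residual moment error that an
independent refit chain can land marginally outside |t| < 0.1.

## Known limitations

- No curved-ERGM estimation of λ; no Bayesian estimation; no missing-tie
  imputation; no tie-swap or tempered samplers; no undirected or 3+-layer
  variants.
- The dyad log-odds table deliberately excludes structural constants and is
  not a full conditional tie probability.
- Whether descriptive "exchange pairs" should be counted ordered or
  unordered is a genuine reporting ambiguity in the literature; the ordered
  convention used here is asserted in the documentation rather than claimed
  universal.
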