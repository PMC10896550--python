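# Methods

## Model

The severity process G(t) is a continuous-time Markov chain on the four
ordered stunting states, indexed by child age in months (the process
time scale).  The generator Q has non-negative off-diagonal intensities
q_uv (events per month) on the allowed transition set and diagonals
q_uu = −Σ_{v≠u} q_uv, so rows sum to zero.  Time homogeneity is
assumed throughout: q_uv(t) = q_uv.  Consequences used downstream:
sojourn times in state u are exponential with rate −q_uu (mean
−1/q_uu), the next state after leaving u is v with probability
−q_uv/q_uu, and the transition probability matrix over a gap Δ is the
matrix exponential P(Δ) = exp(ΔQ).

The default transition structure allows only adjacent-severity moves,
{1↔2, 2↔3, 3↔4} — six free intensities.  This is the structure the
published analysis actually fitted, and we keep it as the default even
though the stated pruning rule ("drop cells under 10% of a row") would
also retain some non-adjacent cells of the observed transition table
(a 15% normal→moderate cell, a 13% severe→marginal cell).
`prune_structure` exposes both conventions (`figure2` and `threshold`
modes) so the discrepancy is inspectable rather than hidden.

Covariates enter through proportional intensities,
q_uv(x) = exp(α_uv0 + α_uvᵀ x), with x a dummy encoding of categorical
variables (one indicator per non-reference level).  The full study
design has 11 variables and 19 dummies, giving 6 × (1 + 19) = 120 free
parameters on the adjacent structure; the covariate-free model has 6.

### HAZ classification

Bands are closed at their lower cut and open at their upper cut:
normal HAZ ≥ −1, marginal −2 ≤ HAZ < −1, moderate −3 ≤ HAZ < −2,
severe HAZ < −3; so HAZ = −1 is Normal and HAZ = −3 is Moderate.  Some
published descriptions print the normal band as "HAZ ≥ 1"; the layout
of the adjacent bands forces the cut point to be −1, and we treat the
printed value as a sign typo.

## Likelihood and estimation

Under panel observation the path between visits is latent, so each
consecutive pair of visits (state u at age t, state v at age t+Δ)
contributes log [exp(ΔQ(x))]_{uv}; children are independent and the
log-likelihood is the sum over all pairs.  Time-varying covariates are
held piecewise-constant at their interval-start value (the standard
left-endpoint convention for panel multi-state fitting); the child-age
band is refreshed at each visit, all other covariates are frozen at
entry.  Repeated same-state observations are genuine contributions
(log of a staying probability).  Exactly observed transition times and
censored states are out of scope; so are time-inhomogeneous, semi-
Markov, hidden-state and random-effects variants.

Matrix exponentials use scipy's scaling-and-squaring Padé
implementation, which is robust to repeated eigenvalues (we never
eigendecompose).  Likelihood evaluation groups observation pairs by
unique (covariate pattern, interval length), computing each distinct
exponential once; the grouped sum is algebraically identical to the
pair-by-pair computation.

Maximization is BFGS on the unconstrained scale — log for baseline
intensities (so positivity is automatic, matching the
q_uv0 = exp(α_uv0) parameterization), linear for coefficients — with
central-finite-difference gradients (relative step 1e−6).  Defaults:
gradient-norm tolerance 1e−5, iteration cap 500, optional multi-start
(`n_starts`) jittering the initial point, useful insurance on the flat
regions of the 120-parameter surface.  "Crude" initial values are
occurrence/exposure rates: observed u→v pair counts divided by total
pair time starting in u, with a half-count floor so never-observed
transitions start finite; coefficients start at 0.  The covariance is
the inverse of the central-finite-difference Hessian (relative step
1e−4) of the negative log-likelihood at the optimum; a non-invertible
or non-positive Hessian leaves the covariance absent with a warning
rather than failing the fit.  Non-convergence returns a flagged result.
A transition probability that underflows to zero makes the
log-likelihood −∞ with a diagnostic naming the offending pair;
parameter vectors whose rates overflow are likewise treated as
zero-likelihood regions so the optimizer retreats from them.

### Intervals and derived quantities

All intervals are Wald at 95% (normal quantile 1.959964) on the
working scale and back-transformed, so intensity and sojourn intervals
are asymmetric.  Mean sojourn intervals use the delta method on
log(exit rate); the published intervals are consistent with a
log-scale construction, though the method is not named there.
Hazard ratios are exp(coefficient) with exp(coef ± 1.96·SE) bounds.
Intensity tables and probability curves are evaluated by default at
the all-reference covariate profile (all dummies zero) — the published
with-covariate table does not state its profile, and the all-reference
choice reproduces its diagonal arithmetic; the profile used is always
echoed in the output.  Probability curves default to a 40-month
horizon (the study's follow-up) in half-month steps (a display
resolution choice).  Displayed tables round intensities to 4 decimals
and sojourns to 1; full precision is available programmatically.

One internal inconsistency of the source analysis is reproduced, not
"fixed": from the fitted with-covariate intensities, the marginal→
moderate vs marginal→normal rate ratio is 0.1714/0.4114 = 0.42, i.e.
58% lower, while the prose calls it "42% less likely"; and the state-4
sojourn rounds to 2.28 where 2.27 is printed.  We follow the table
arithmetic in both cases.

## Descriptive stages

The observed transition table counts consecutive observation pairs by
(earlier, later) state, with row percentages; displayed percentages
round half-up to whole percent, matching the printed table.  Entry
descriptives take each child's first observation ("at entry"),
tabulate column percentages by a grouping variable plus a combined
column, and attach an uncorrected Pearson chi-square p-value per
variable (undefined with a single group).  Cramér's V uses the
uncorrected formula V = sqrt(χ²/(n·(min(r,c)−1))); the conventional
"< 0.2 is weak" rule is surfaced as a flag, never as a filter.
Missing data are handled complete-case with dropped-row counts logged.

## Synthetic cohort generator

The generator emulates the shape of the study cohort; its defaults are
the study conditions:

- **n_children** 676, follow-up horizon 40 months.
- **Entry ages**: categorical over the four age bands [0,6), [6,12),
  [12,24), [24,36] with shares 11/18/41/31%, uniform within band —
  matching the printed entry marginals.
- **Visit schedule**: the study reports only "at most three visits per
  child per year", so per-child visit counts are drawn uniformly in
  {2, …, min(round(3·years), 10)} and visit ages are equally spaced
  from entry to the horizon with ±30%-of-gap uniform jitter (strict
  ordering and the horizon bound enforced).  This schedule is a
  stand-in: the real distribution of visit counts and gaps is not
  published.  A fixed-gap override (`visits_per_child`, `visit_gap`)
  supports dense-design recovery studies.
- **Covariates**: independent draws per variable from the cohort's
  entry marginals (the observed pairwise associations are weak,
  Cramér's V < 0.2, which justifies the independence simplification);
  a joint-sampler hook allows dependence.  Only the age band varies
  within a child; everything else is frozen at entry.
- **Initial states**: entry stunting shares 22/29/27/22% (the model's
  stationary distribution is available by passing it explicitly).
- **Trajectories**: exact Gillespie simulation — exponential sojourns
  at the exit rate, jump to v with probability rate/exit-rate —
  piecewise per observation interval with interval-start covariates,
  recorded only at visit ages.  Latent jumps respect the adjacent
  structure; recorded consecutive states may still skip levels.
- **Truth** (`make_study_truth`): baseline intensities set to the six
  fitted with-covariate rates (0.4214, 0.4114, 0.1714, 0.1909, 0.2845,
  0.4390 per month), zero coefficients unless supplied.

Everything is reproducible from one integer seed, and each dataset is
returned with the exact truth record used.

What passing tests on this generator do and do not show: they verify
the estimation machinery (simulate → fit closes the loop within
sampling error) and the descriptive plumbing, under exactly the
assumptions the model makes — Markov dynamics, exponential sojourns,
independent covariates, no dropout, no HAZ measurement error.  They
cannot validate those assumptions against real cohorts, and the
generator deliberately does not emulate mortality/out-migration or
measurement noise.

## Problem sizes used in checks

Parameter-recovery checks run 10 replicates of 2000 children with 10
monthly visits each (dense fixed-gap design), requiring all six
baseline log-intensities within 3 estimated standard errors of truth
in at least 9 of 10 replicates, and Wald coverage of a ln(3) effect
injected on the moderate→severe transition.  Generator fidelity uses
50,000-child covariate samples (marginals within ±1 percentage point)
and 100,000 Monte-Carlo sojourns at rate 0.5/month (mean within 1% of
2 months).  Engine correctness checks the two-state closed form to
1e−10, Chapman–Kolmogorov P(s+t) = P(s)P(t) to 1e−8 on random
generators, and single-pair likelihoods against an independent
truncated-Taylor matrix-exponential oracle to 1e−10.

## Known limitations

- The 120-parameter fit is supported but slow relative to the
  6-parameter fit (finite-difference gradients cost 2p likelihood
  evaluations each); analytic derivatives would be the natural next
  step.
- Wald intervals can be poor for transitions with few observed pairs
  (the never-observed-transition warning flags the worst case).
- The visit-schedule model is a documented guess; inference is
  conditional on visit times being non-informative.
- No support for exact transition times, censoring, misclassification
  or frailty.
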