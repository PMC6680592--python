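# Methods

## Model

Each subject contributes an ordered sequence of coded WCST responses
(`C`, `E`, `PE`) and a binary group label `x`. The sequence is
partitioned into `T` contiguous windows ("task phases"); window lengths
within a subject differ by at most one trial, with remainders assigned to
the earliest windows so the partition is deterministic and
order-preserving. Subjects may have different trial totals — phases are
interpreted as fractions of task progress, so unequal window lengths
across subjects are retained, never normalised away.

The generative model is a discrete latent Markov model:

- a hidden state chain `S_1 … S_T` with group-specific initial vector
  `pi_init[x]` and group-specific row-stochastic transition matrix
  `trans[x]` (time-homogeneous by default; a step-varying variant with
  `T-1` matrices per group is available but off by default, since a
  single matrix per group is the structure the analysis interprets);
- given the state, trials within a window are i.i.d. categorical with
  probabilities `phi[s]`, shared across groups. The measurement model is
  deliberately *not* group-specific: all group differences are carried by
  the latent process.

A window's emission likelihood is the product of per-trial probabilities,
i.e. the multinomial kernel **without** the combinatorial coefficient.
The coefficient does not depend on the parameters, so omitting it changes
no estimate and no likelihood difference between models; it is omitted
from all reported log-likelihoods, and exact oracles in the test suite
use the same convention.

## Codification

The perseveration criterion used by the original scoring literature is
not fully specified in public sources, so the raw-log path uses the
simplest defensible operationalisation: an error is perseverative when
the chosen feature equals the immediately preceding reinforced rule;
errors in the first rule block (no previous rule exists) are
non-perseverative. This choice only affects the optional raw-log
codification path — the statistical layers consume the three-category
stream directly, and the synthetic generator emits coded categories.

## Estimation

Parameters are estimated by EM:

- **E-step**: scaled forward–backward recursions, vectorised across
  subjects (all subjects share `T`). Scaling subtracts each window's
  maximum log-emission and renormalises the forward vector at every
  step, so window sizes up to thousands of trials do not underflow.
- **M-step** (closed form): group initial vectors proportional to
  expected first-window state counts; group transition matrices
  proportional to expected transition counts; the shared emission matrix
  proportional to expected per-state category counts pooled over groups.
  Every updated row receives a smoothing floor of 1e-10 before
  renormalisation, preventing a probability that touches zero from
  locking the algorithm out of part of the parameter space. Estimates
  are reported as-is (floored values appear as ~1e-10, visible as exact
  zeros after rounding).
- **Convergence**: relative log-likelihood change below 1e-8 or 1000
  iterations. Defaults: 20 random restarts with all probability rows
  drawn from flat Dirichlet distributions; fully deterministic given the
  configured seed; the best restart by final log-likelihood is returned.
- **Label switching** is resolved only after fitting: states are
  permuted so `P(C|state)` is non-increasing (ties broken by ascending
  `P(PE|state)`), and initial vectors, transition matrices and
  posteriors are permuted consistently. Nothing constrains the ordering
  during EM.
- A **degeneracy flag** (not an exception) is raised when a state ends
  with essentially zero posterior occupancy, the signature of asking for
  more states than the data identify.

Model selection uses AIC `= -2 ll + 2k` and BIC `= -2 ll + k log(n)`
with `n` = number of subjects (the conventional choice for subject-level
longitudinal mixtures) and
`k = S(R-1) + G(S-1) + G·S·(S-1)·[homogeneous ? 1 : T-1]`.
The basic (group-blind) and covariate models are nested — the emission
matrix is shared, the covariate model frees one initial vector and one
transition matrix per group — so the covariate model's maximised
likelihood is never lower, and BIC arbitrates the extra parameters.

## Dynamics

Post-fit analysis treats each group's fitted `(pi_init, P)` as a Markov
chain profile. Marginal trajectories use the exact recursion
`pi_{t+1} = pi_t P` (no simulation). Absorbing states are flagged when a
diagonal entry is within `tol` (default 0.01) of 1. Expected hitting
times solve the standard linear system `h[target] = 0`,
`h[s] = 1 + Σ_{s'≠target} P[s,s'] h[s']`, restricted to the states
actually reachable from the start; the result is infinite when the
target is unreachable or when the chain can, with positive probability,
enter a region from which the target cannot be reached (hitting
probability < 1 implies a divergent expectation). Reachability is
decided on the adjacency graph `P > 0`, and the transient sub-matrix is
additionally required to have spectral radius below 1 before solving.
Seeded Monte-Carlo rollouts (`simulate_forecast`) provide an independent
empirical counterpart for both the trajectories and the first-passage
distributions.

## Synthetic data

The generator ancestrally samples the model itself: per subject, draw a
trial total, a latent chain from the group's initial vector and
transition matrix, then each window's responses i.i.d. from the state's
emission row. True states are recorded so tests can check emissions and
initials directly against their generative values. Defaults mirror the
reference study design: 44 controls vs 38 substance-dependent subjects,
`T = 5` phases, and per-subject trial totals drawn uniformly from 80–128
(WCST administrations vary between the 64- and 128-card forms and
early-termination rules, so a subject-varying total in that range is the
realistic default; tests that need exact binomial arithmetic fix the
total instead).

The default truth uses published three-state point estimates for the
emission matrix — states read as optimal (94% correct), sub-optimal
(80% correct, balanced errors) and perseverative non-optimal (44%
correct, error-dominated) strategies — and for the two group initial
vectors. Published sources report the transition matrices only
graphically, so the generator stipulates matrices engineered to
reproduce the qualitative structure the analysis describes: the control
matrix sends nearly all mass to state 1 and gives state 3 a zero
self-transition; the substance-dependent matrix makes state 2
near-absorbing (0.96) and state 3 sticky (0.70). What passing
recovery tests show is therefore that the *pipeline* is correct and
well-calibrated at realistic signal strengths — not that these
particular transition values describe any real cohort. The generator
also does not emulate several features of real WCST data: rule-block
structure (coded categories are exchangeable within a window),
within-subject learning beyond the state chain, and any
emission-model differences between groups.

## Group comparison from summary statistics

`summary_ttest` reconstructs group standard deviations from printed
standard errors (`sd = se·√n`) and computes the pooled-variance Student
two-sample t with `df = n1 + n2 - 2`. The pooled variant (rather than
Welch) is the one consistent with the published degrees of freedom
(df = 80 for 44 vs 38). Applied to the published scoring table, the
perseverative-error row gives |t| ≈ 6.50 and the non-perseverative row
|t| ≈ 5.63 with df = 80 — the same pair as the published values (6.48,
5.62) with the two labels interchanged; the implementation reports the
computed values.

## Problem sizes and numerical checks

- Exact oracle: forward–backward agrees with exhaustive enumeration of
  all `S^T` state paths to 1e-10 (50 random parameter draws, S ≤ 3,
  T = 5).
- EM monotonicity: every restart's log-likelihood trace is
  non-decreasing to within 1e-8.
- Recovery: cohorts of 1000 subjects per group with five 25-trial
  windows, refit with 20 restarts over 20 replicates. Estimates are
  unbiased; the sampling SD of an initial-probability estimate at this
  size is ≈ 0.016–0.02 (binomial floor plus latent-state uncertainty),
  which is the resolution limit any check at this cohort size inherits.
- Selection: 500 subjects per group, 20 replicates for the state-count
  ranking (selection fits use 8 restarts), 10 replicates for the
  covariate comparison.
- Dynamics: exact marginals vs 10^6 simulated chains (agreement to
  0.002 per cell); analytic vs simulated hitting times within 3
  Monte-Carlo standard errors.
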