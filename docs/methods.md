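# Methods

## The SISa model

The package models binary states — obesity is the worked case study — that
spread both socially and non-socially.  Each individual is susceptible (S)
or infected (I).  Three elementary processes drive the dynamics, all with
exponential clocks and rates per year:

- **spontaneous ("automatic") infection** — a susceptible becomes infected
  at rate `a`, independent of contacts;
- **transmission** — each infected contact adds hazard `beta` to a
  susceptible's infection rate;
- **recovery** — an infected returns to susceptible at rate `g`,
  independent of contacts.

Because `a` acts on every susceptible, there is no epidemic threshold:
the equilibrium prevalence is strictly positive for any `a > 0`, however
small `beta` is.  The model neglects birth, death and tie formation: the
population and the contact network are fixed over a run.

### Well-mixed dynamics

With `k` effective contacts per person the infected fraction `i` obeys

    di/dt = a (1 - i) + beta k i (1 - i) - g i

Equilibrium is the root in [0, 1] of the quadratic balance; it is computed
in closed form with a cancellation-safe branch for `beta k << a + g`, and
reduces to `a/(a + g)` when transmission vanishes.  The basic reproductive
ratio is `R0 = beta k / g` — for the obesity rates (`beta = 0.005`,
`k = 2.8`, `g = 0.04`) this is 0.35, i.e. the epidemic would not be
self-sustaining on transmission alone.

Two derived scalars carry unit caveats.  *Lifetime* (`1/g`) and *cycle
length* (`1/a`) are reported as infinite when the rate is zero.
*Influence* — the probability of transmitting along one edge before
recovering — is computed as `beta/(beta + g)` by default (the exact
competing-exponentials probability); the cruder `beta/g` (expected
transmissions per edge) is available by flag.  At the rounded obesity
rates the two give 0.111 and 0.125; published summaries in this area quote
values near 0.13, between which the unrounded rates presumably fall.
Published cycle lengths for obesity are likewise quoted variously as 53
and 56 years at a rounded `a = 0.02`; the package simply reports `1/a`.

### Pair approximation on networks

On a network the quantity multiplying `beta` is the number of S–I edges,
which the well-mixed model overestimates once infecteds cluster.  The
pairwise description tracks node counts and adjacent-pair counts
(`[SS], [SI], [II]`, ordered convention: an undirected edge contributes two
ordered pairs, so `[SS] + 2[SI] + [II] = 2E`).  Writing unordered
edge-class counts `P_xy`, the dynamics are

    dI/dt    = a S + beta P_si - g I
    dP_si/dt = a (2 P_ss - P_si) + g (2 P_ii - P_si)
               + beta ([ISS] - [ISI] - P_si)
    dP_ii/dt = a P_si - 2 g P_ii + beta (P_si + [ISI])

with `P_ss` implied by edge conservation.  Triples are eliminated with the
transitivity-corrected moment closure

    [XYZ] = ((k-1)/k) ([XY][YZ]/[Y]) ((1-phi) + phi N [XZ]/(k [X][Z]))

where `k` is the contacts per node and `phi` the transitivity (triangles
over connected triples).  The closure assumes every node has the same `k`
and `phi` (n-regular approximation); degree heterogeneity is deliberately
left to the stochastic simulator.  Directed nomination networks are
handled by letting `k` be the mean out-degree, adequate when most ties are
mutual.

Spatial correlations are `C_XY = N^2 [XY] / (2E [X][Y])`: 1 for random
placement, `C_II > 1 > C_SI` once transmission clusters infecteds.  At any
pairwise equilibrium the prevalence satisfies the well-mixed balance with
`beta` replaced by `beta * C_SI` — the network's entire effect is the
reduction of effective transmission by the S–I correlation.

For `a = 0` and `phi = 0` the stationary system solves in closed form:
with `kappa = (k-1)/k` and `R = beta k / g`,

    i* = (R - 1/kappa) / (1 + R - 1/kappa)

positive only above the pair-approximation threshold `beta (k-1) > g`;
the accompanying `C_SI* = (k - g/(beta kappa)) / (k i*)`.  This closed
form is used purely as an independent oracle for the numerical
steady-state solver, which does damped root-finding on the reduced
3-variable system from random-mixing initial pairs (residual tolerance
1e-10, fallback to long-time integration).

Trajectories start from random-mixing pairs (pairs proportional to class
products), matching epidemics seeded without pre-existing clustering.
A consequence worth knowing: a run started at the *prevalence* equilibrium
still shows a sub-0.1-point transient while the pair structure relaxes.

### Stochastic simulation

`simulate_sisa` is an exact continuous-time Gillespie process (no
time-step discretisation).  Events are drawn from three channels —
spontaneous infection (total rate `a|S|`), recovery (`g|I|`) and
transmission (`beta * #{directed S->I edges}`) — with the node chosen by
rejection sampling inside the channel; all bookkeeping updates are
O(degree).  Influence follows nomination direction: a node's hazard counts
the infected among its *out*-neighbours.  Equilibrium summaries
time-average the trajectory after a burn-in of `5 / min(a+g, g)` years
(five relaxation times of the slowest single-node clock; configurable).

## Synthetic cohort networks and panels

The original cohort data are not public, so the generator emulates their
published structure: N ≈ 3500 subjects, Poisson-like degrees with mean
≈ 3 (including a fraction of degree-0 subjects, default 5%), and
transitivity ≈ 0.64.  A transitivity that high cannot come from any
configuration model at mean degree 3; in real social networks it comes
from kinship cliques.  The generator therefore partitions nodes into
"family" cliques whose size mixture (2–7, truncated-Poisson weights) is
solved, together with a Poisson "friend"-edge rate, to match the requested
mean degree and transitivity; a bounded degree-preserving double-edge-swap
pass then polishes the transitivity to within ±0.05 (typically ±0.02) of
target.  All ties are mutual (in the cohort data over 90% of ties are),
stored as two directed edges.

What this ensemble does *not* reproduce: the real network's degree
overdispersion beyond Poisson (large families, coworker groups), degree
assortativity, and tie churn between exams.  Consequently tests passing on
these networks validate the dynamics and the estimator under the stated
summary statistics, not under every feature of the real cohort.  One
measurable consequence: simulated equilibrium infected–infected
correlation is `C_II ≈ 1.15` here, whereas simulations reported on the
real network give ≈ 1.33 — a controlled experiment in the test suite shows
`C_II` rises to ≈ 1.4 when degree variance is pushed to ~4× Poisson, so
the gap is attributable to heterogeneity the published summary statistics
do not pin down.

`make_benchmark_panel` couples the generator to the simulator: it runs the
process from 14% initial prevalence and snapshots 7 waves at 4-year
spacing (defaults mirroring the case study's exam structure, truth rates
a = 0.02, g = 0.04, beta = 0.005), with optional permanent drop-out.

## Rate estimation from panels

For each consecutive exam pair, subjects in the origin state at the
earlier wave and observed at the later one contribute a binary transition
indicator, regressed (OLS; logistic as a cross-check, reported as a
marginal effect at the sample mean) on the number of contacts in a given
state at the earlier wave.  A significantly positive slope is the evidence
of contagion.  Under linearised transition probabilities the rates are

    beta = slope(S->I vs infected contacts) / dt
    a    = intercept(S->I) / dt
    g    = intercept(I->S vs susceptible contacts) / dt

with CIs divided by `dt` likewise.  Recovery is modelled
contact-independent; a significant recovery slope triggers a model-
violation warning, as does `rate * dt > 0.5` (double-transition regime).
Drop-outs are excluded, never imputed; subjects with zero contacts are
kept (they pin the intercept).

The linearisation ignores double transitions, biasing rates downward by
O(rate·dt) — about 12% for `g = 0.04` at `dt = 4` years.  For multi-year
intervals the package therefore provides an exact
discretely-observed two-state Markov-chain MLE (`method="mle"`): each
subject-interval's likelihood uses the exact two-state transition
probability with infection hazard `a + beta c` and recovery hazard `g`,
CIs from the observed information on the log-rate scale.  The default
exposure model averages the infected-contact count over the two bracketing
waves ("midpoint"), correcting the attenuation caused by contacts changing
state mid-interval; the earlier-wave-only count remains available
(`exposure="baseline"`).  In recovery experiments on benchmark panels the
MLE is unbiased to within sampling error and its 95% CIs cover the truth
at nominal rates, while the linearised estimator reproduces the published
procedure and its known bias.

Temporal trends in per-interval rate estimates are tested by
inverse-variance-weighted linear regression of the estimates on interval
midpoints.

## Forecasting and interventions

`forecast` integrates the pairwise equations through a piecewise-constant
parameter schedule, carrying the state across breakpoints (pair counts are
rescaled, correlations preserved, when the mean degree changes between
segments).  `time_to_equilibrium` reports the first time the pairwise
prevalence comes within a tolerance (default one percentage point) of its
equilibrium.  `uncertainty_band` evaluates the steady state at
prevalence-minimising and -maximising parameter sets.  `sensitivity`
takes central finite differences of the equilibrium with respect to each
rate (one-sided at a zero boundary, default step 1e-4) and reports them on
the conventional axis of percent-infected change per 0.01/yr rate change;
the largest-magnitude derivative identifies the most effective
intervention target — reducing `a` in weakly transmissive regimes,
raising `g` in strongly transmissive ones, with `beta` winning in the
obesity regime.

## Numerical choices

- Integrators: LSODA with rtol 1e-10 / atol 1e-12; trajectories clipped to
  the physical region before evaluating rates.
- Steady states: closed-form quadratic (well-mixed) and hybr root-finding
  with integration fallback (pairwise); all-zero rate sets are rejected
  rather than returning 0/0.
- Closure edge cases: an empty centre (or end, when `phi > 0`) class
  yields zero triples; correlations involving an empty class are NaN
  ("undefined"), never 0.
- Simulation reproducibility: one `numpy` Generator seeds initial
  placement and dynamics; identical seed and inputs give byte-identical
  event logs.
- Problem sizes: simulation-based checks use N = 3500 networks, 400-year
  horizons and 2–3 replicates, and the estimator-recovery experiment uses
  50 panels; these sizes put Monte-Carlo error well inside the tolerances
  being tested while keeping the whole suite fast.

## Known limitations

- The pairwise equations assume a homogeneous network; on heterogeneous
  networks with large `beta` they underpredict prevalence and
  correlations (by design — the stochastic simulator is the reference
  there).
- Estimation treats each subject's contact count as exogenous over an
  interval; reverse influence along mutual ties inflates `beta` slightly
  (~3% in benchmark recovery, well inside sampling error at cohort sizes).
- No adjustment for latent homophily: as with the original analysis,
  contagion and homophily are not separately identified from observational
  panels.
- Tie formation/dissolution during a simulation, multi-state dynamics and
  demographic turnover are out of scope.
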