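# Methods

## The model

BiSSE (binary-state speciation and extinction) describes a lineage that
carries a binary character (states 0 and 1) and diversifies at
state-dependent rates: speciation λ0, λ1, extinction μ0, μ1, and character
transitions q01 (0→1) and q10 (1→0), all in events per lineage per unit
time. Given a complete, ultrametric tree of contemporaneous extant species
with a known state at every tip, the likelihood of a rate set is computed by
the standard pruning recursion: for each point on the tree one tracks
E_s(t), the probability that a lineage in state s at time t before the
present leaves no surviving descendants, and D_s(t), the density of the
observed subtree given state s. Integrating rootward along a branch,

    E0' = μ0 − (λ0+μ0+q01)·E0 + q01·E1 + λ0·E0²
    D0' = −(λ0+μ0+q01)·D0 + q01·D1 + 2λ0·E0·D0

and symmetrically with 0↔1. Daughters join at a node as
D_s = λ_s·D_s^left·D_s^right; at the root the likelihood is
w0·D0 + w1·D1 for a root-prior weight vector w.

Assumptions worth stating: complete sampling (every extant species is a
tip with a known state), constant rates through time, at most two states,
strictly bifurcating topology. The likelihood is that of the reconstructed
tree itself; it is **not** conditioned on clade survival or on the observed
tip count. The simulator, however, only returns clades that reach the
target size, so estimates can differ from the generating rates by
small conditioning effects that shrink with tree size.

### Root prior

The default root weighting is the stationary character frequency implied by
the rate set (see below), matching the simulator's root-state rule, so
simulation and inference are internally consistent. `equal`, `fixed0`,
`fixed1` and explicit weights are available for sensitivity checks; at the
rate magnitudes used in the shipped scenarios the choice moves ln L by well
under one unit and the ML estimates imperceptibly (the package exposes both
rather than assuming this).

## Stationary character frequency and scenario construction

The long-run frequency x̂ of state 0 solves

    g·x̂(1−x̂) − x̂·q01 + (1−x̂)·q10 = 0,   g = λ0 − μ0 − λ1 + μ1,

linear when g = 0 (x̂ = q10/(q01+q10)), otherwise a quadratic with exactly
one root in [0,1] when q01+q10 > 0. The package solves the quadratic in
closed form with a bisection fallback, avoiding any iteration-count
sensitivity.

Matched-bias scenarios invert this relation: for a chosen process the two
rates are placed geometrically around their base value b as b/√r and b·√r —
the geometric placement is what reproduces the published scenario rates
(e.g. speciation 0.0936/0.10689 around 0.1) — with the sign arranged so
state 1 is favored when the target x̂ < 0.5 (higher λ in state 1, higher μ
in state 0, more 0→1 transitions). The ratio r is found by a bracketed
root search on log r; an unreachable target raises rather than
extrapolating. One published table lists the low-bias extinction pair with
the opposite subscripts (μ0 < μ1 for a state-1-favoring bias), which
contradicts the main-text convention; the package follows the main-text
direction and treats only the ratio magnitudes as authoritative.

The displayed tip ratio ("3:1") is a nearest-integer rendering; all
computation uses x̂ itself. Note the stationary frequency is an asymptotic
quantity: finite trees stopped at a fixed tip count show a slightly
different mean tip fraction (the shipped calibration scenario has
x̂ = 0.26 yet a mean of ~29% state-0 tips), which is reproduced by the
simulator, not an error.

## Simulator

Exact continuous-time (Gillespie) simulation. With n_s living lineages in
state s, the total event rate is Σ_s n_s(λ_s+μ_s+q_s→); the waiting time is
exponential with that rate, and the event type and lineage are drawn
proportionally to their contributions. The process starts from a single
stem lineage (state drawn from the stationary frequency by default) and
stops the first instant the living count reaches the target n; all
terminal branches are then extended to that instant, so tips are exactly
contemporaneous. Complete extinction triggers a restart with fresh
randomness, capped at 1000 attempts (the cap is reported). Pruning removes
extinct lineages, splices pass-through nodes (summing lengths), and
discards the stem above the survivors' most recent common ancestor, so the
returned tree is the crown clade the likelihood expects.

Replicate k of a batch uses the stream `default_rng([base_seed, k])`, so
batches are reproducible and any replicate can be regenerated alone.

What the generator does *not* emulate: incomplete sampling, fossils or
non-contemporaneous tips, rate variation through time, multifurcation.
Passing tests therefore say nothing about robustness to those features of
real data.

## Numerical integration

Branch ODEs are integrated with an embedded Runge–Kutta–Fehlberg 4(5) pair
with adaptive steps. Defaults: relative tolerance 1e-8, absolute 1e-10,
starting step = (tree height)/100, step sizes confined to 1/10×–10× of the
starting step, final step shortened to land exactly on the branch end. The
5th-order solution is propagated. E values are clipped into [0,1] (drift
beyond 1e-6 is an error); (D0,D1) are rescaled per node — and mid-branch on
underflow — with log factors accumulated, so 500-tip likelihoods never
underflow. If the clamp floor cannot meet the tolerance (rate × step ≫ 1)
the evaluation fails loudly; the optimizer retries such points with a
10×/100× smaller starting step before treating them as infeasible.
Against an independent fixed-step RK4 oracle the adaptive integrator agrees
to better than 1e-5 in ln L on random small trees, and to ~1e-8 against a
closed-form birth–death × Mk factorization in the state-independent case.

## Optimization

ML fitting maximizes ln L over log10-rates (bounds 1e-8–1e2) by cyclic
coordinate descent: one bounded Brent-style line search per free parameter
per cycle (fixed order λ0, λ1, μ0, μ1, q01, q10, collapsed by the
constraint pattern), plus one Powell-style acceleration search along the
cycle's net displacement, which cuts the λ/μ ridge crawling from ~60 to
~10 cycles. Cycling stops when a full cycle gains less than 1e-6 ln-units
or moves no coordinate by more than the line-search resolution (3e-3
log10-units by default).

The search runs from an optional warm start (the estimates of a more
constrained model) plus random restarts drawn log-uniformly from
1e-4–10; the best final ln L wins, ties broken by start index, so results
are bit-reproducible given the seed. Defaults: 3 restarts for standalone
fits, 2 in the power/recovery pipelines (the 3→5→6-parameter warm-start
chain supplies a near-optimal start, and in practice the restarts serve
only as a safeguard against local maxima). Restarts trailing the best
completed start by more than 5 ln-units after a cycle are abandoned.
Monomorphic tip data are fitted but flagged (boundary estimates expected);
estimates at a rate bound are flagged, kept in summaries, and counted.

## Hypothesis tests and power

The test for asymmetry in one process compares the model with that
process's rates free against the model with them constrained equal:
6-vs-5 parameters when the other processes stay free, 4-vs-3 when they are
assumed symmetric. The statistic is 2·(ln L_full − ln L_constrained)
(clipped to zero within 1e-6; larger negatives flag optimizer failure and
the replicate is redrawn). Because the χ² reference can be unreliable
here, critical values default to the empirical (1−α) quantile — linear
"type-7" interpolation — of the statistic over replicates simulated under
the matching symmetric rates; the χ²₁ cutoff (3.841 at α = 0.05) is
available as an option. Power is the fraction of alternative-scenario
statistics above the critical value, reported with a normal-approximation
binomial CI (±1.96·√(p(1−p)/n)).

Null scenarios use the alternative's base (non-elevated) rate for the
asymmetric process and the shared values elsewhere; the matched-bias grid
uses its explicit base rates (λ=0.1, μ=0.05, q=0.005).

## Recovery summaries

Recovery experiments refit the unconstrained model to each simulated
replicate and summarise per-rate estimates by mean, sample standard
deviation (the spread of replicate estimates, not the standard error of
the mean — the magnitudes reported for such experiments are only plausible
as SDs), bias, and 2.5/50/97.5% quantiles. Failed fits are excluded and
counted (a >10% failure rate flags the summary); boundary-pinned fits are
kept, since dropping them would understate the spread.

## Problem sizes used in the shipped checks

The full study design (500 replicates × 4 tree sizes × ~20 scenarios, all
with ML refits) is cluster-scale. The packaged checks use desk-scale
designs chosen to keep each quantity's Monte-Carlo error within its
comparison tolerance: exact solver identities (no replication), simulator
calibration at 500 replicates of 500-tip trees (simulation only),
parameter recovery at 25 replicates of 500-tip trees per scenario,
type-I calibration with 200 null replicates of 100-tip trees
(split-half cross-calibration of the critical value), and the
reduced-model power comparison at 50+50 replicates of 150-tip trees.

## Known limitations

- Extinction-rate estimates are intrinsically imprecise on reconstructed
  trees; the λ0–μ0 profile is nearly flat along a ridge when the minority
  state is rare, and individual replicate MLEs can sit far up that ridge
  even when the mean behaves well.
- No conditioning on survival or tip count means estimates carry small
  finite-size biases relative to the generating rates.
- Coordinate descent with restarts is a local method; pathological
  surfaces (very high tip bias) can still defeat it, which is flagged via
  boundary/failure counts rather than silently absorbed.
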