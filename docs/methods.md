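# Methods

## The model

`onoffseq` implements likelihood-based inference for the **on/off-seq-L
process**, a continuous-time Markov model of RNA transcription in a single
cell. The molecule count `M_t` (the *level*) changes by one at a time:

- **Births** require completing `L` sequential exponential phases with rates
  `lambda_1, ..., lambda_L`, and a new phase sequence can only be *initiated*
  while a promoter switch is on. The switch turns on at rate `q_on` and off
  at rate `q_off`; once a birth sequence is underway it runs to completion.
- **Deaths** are per-molecule: each of the `m` present molecules dies
  independently at rate `mu`, giving total death rate `m * mu`.

The bookkeeping lives in a hidden phase chain `X_t` on `{0, 1, ..., L}`:
state 0 is "switch off", state 1 "switch on / ready to initiate", states
`2..L` the later birth phases; completing phase `L` increments the count and
returns `X` to state 1. Dropping the switch gives the switchless "seq-L"
variants on `{1, ..., L}`. The model's initial phase `X_0` follows the
stationary distribution of the marginal phase chain.

Truncating the count at a level `C` makes `(X_t, M_t)` a finite **quasi
birth-death (QBD) process**: in level-major state ordering the generator
`Q` is block tridiagonal, with within-level blocks (switching and phase
progression), birth blocks (a single `lambda_L` entry at phase L -> phase 1)
and death blocks (`m * mu` times the identity).

## Likelihood by Erlangization

Each of `N` independent cells is observed at a fixed lag `Delta`, giving
counts `m_0, ..., m_n` (lengths may differ per cell). The likelihood of a
series sums over all hidden phase paths; it is computed by a forward
recursion over the (at most `L + 1`)-dimensional phase marginal, rescaling
the forward vector to sum one at each step and accumulating log scale
factors. Series of probability zero return a large negative sentinel
(`-1e15`) so an optimizer can continue rather than crash.

The ingredient is the lag-`Delta` transition matrix of the truncated QBD.
The state distribution at an *exponential* time `Exp(eta)` is the resolvent
kernel `Pi_eta = eta (eta I - Q)^{-1}` — one banded linear solve, since `Q`
has bandwidth equal to the phase-set size. An `Erlang(ell, ell/Delta)` time
concentrates on `Delta` as `ell` grows, so `(Pi_{ell/Delta})^ell`
approximates the deterministic-lag kernel with error `O(1/ell)`
(**Erlangization**). `ell` is restricted to powers of two so the power is
`log2(ell)` exact repeated squarings; every intermediate power is
renormalized to stay row-stochastic to machine precision. The default
`ell = 2048` makes the kernel error (~1e-4 relative, verified against a
uniformization matrix exponential in the tests) negligible against the
statistical error of every design considered here.

**Initial condition of a series.** The likelihood *conditions* on the
observed initial count `m_0` and assigns only the phase `X_0` a law (its
stationary distribution). A joint law for `(X_0, M_0)` would require a
stationary count distribution, which does not exist in the pure-birth
(`mu = 0`) designs; conditioning sidesteps that and is exact when the
experiment fixes the initial count.

**Truncation selection.** `choose_truncation` doubles `C` from
`max(2 * data_max, 20)` until the one-lag probability of reaching the top
10% of levels from any observed level is below `epsilon = 1e-8`, and always
returns at least `data_max + 1`. Fits with `C="auto"` use the schedule
floor during optimization and validate it at the optimum, refitting once at
the larger level if the boundary mass was not negligible. Pilot checks of
the tied-rate three-phase design gave identical estimates at `C = 20` and
`C = 100` to four decimals.

## Inter-birth times

The time `T` between consecutive births starts in the on-state and consists
of a geometric number `G - 1` of on/off loops — `G` on `{1, 2, ...}` with
success probability `p = lambda_1 / (lambda_1 + q_off)` — followed by the
passage through the `L` phases. Wald's equation gives

    E[T]   = sum_i 1/lambda_i + q_off / (q_on lambda_1)
    Var[T] = sum_i 1/lambda_i^2
             + (2 q_off lambda_1 + q_off^2 + 2 q_on q_off) / (lambda_1^2 q_on^2)

Both moments are invariant under permutations of `lambda_2..lambda_L`, and
near-invariant under swapping `lambda_1` with another phase rate while
adjusting `q_off` to keep `p` fixed. This is why the unconstrained
likelihood has near-equivalent maxima and why estimation must impose an
**order constraint** on the phase rates.

## Estimation

`fit_mle` maximizes the log-likelihood over the box `[0, b]^k` (default
`b = 10`) subject to an order chain on the phase rates. The chain is
enforced exactly by reparameterizing the ordered rates as a base rate plus
non-negative increments, which turns the constraint into plain bounds.
Optimization is bounded Nelder-Mead; the first start is a data-informed
moment start (the observed per-time upward traffic estimates the birth rate
`1/E[T]`, downward traffic per molecule estimates `mu`; phase rates are
staggered a factor two apart so the start lies in the interior of the
order cone), followed by log-uniform random starts over `[1e-3 b, b]`
(default 5 starts in the API; the simulation studies below use the moment
start alone, which pilot runs showed reaches the same optimum as a strict
multi-start reference to < 3e-4 per coordinate). If the optimum lands on
the upper box bound the domain is doubled and the search restarted from the
incumbent, at most three times.

An **unconstrained** fit of a multi-phase model (only sensible for
diagnostics; the API requires an explicit opt-in) is computed as the best
of the per-chain constrained fits: the order chains partition the box, so
the branch best is the global box maximum. The branch log-likelihoods
differ only through data noise (< 0.01 in pilot runs at n = 120, N = 375),
so which branch wins alternates across replicate datasets — reproducing the
characteristic two-peaked histograms of unconstrained estimates that the
order constraint removes.

Model selection uses `AIC = 2k - 2 log L` with `k` the number of free
parameters; `aic(fit, exclude=...)` can drop named parameters from `k` to
mirror reports that count a rate as known. The default candidate battery
is seq-1/2/3 and on/off-seq-1/2/3 with descending chains
`lambda_1 >= lambda_2 (>= lambda_3)`; a full battery with every chain
variant is available for real-data screening.

## The synthetic-data generator and the study conditions

`simulate_path` / `sample_series` are exact event-driven (Gillespie)
simulations of the untruncated process; datasets draw per-series RNG
substreams from a root seed so enlarging `N` leaves earlier series
unchanged. Inter-birth times can also be sampled directly from the
geometric-sum representation; closed-form moments and the simulator
cross-validate each other in the tests.

The recovery studies (`recovery_study`) reproduce the published simulation
designs: observation lag `Delta = 1` (one minute, as in the real promoter
experiments), every cell starting **empty with the switch just turned on**
(`m_0 = 0, x_0 = on`). That initial condition matters: the fitted
likelihood assumes a stationary initial phase, and the resulting transient
mismatch — largest when the series is short relative to the switch
timescale — produces the small upward bias of the recovered `q_on` (mean
~0.115 at n = 50 versus 0.107 at n = 120, truth 0.1) that vanishes as `1/n`.
Under stationary initial phases the bias disappears, which pins the
on-start as the condition behind the published tables. The generator
emulates exact molecule counts without measurement noise, partial
detection, cell division or lineage structure; passing tests therefore
speak to the estimator under the model, not to microscopy artifacts.

## Problem sizes and numerical choices

- Recovery studies run B = 25 replicates of each design (two-phase
  pure-birth: n = 120, N = 375, C = 100; tied-rate three-phase: n = 120,
  N = 375, b = 50; two-phase with deaths: n = 50, N = 350); model selection
  runs B = 15 datasets against the six-model battery. Sample means are
  compared with the published B = 1000 means at four published SDs over
  `sqrt(B)`.
- Study fits: Nelder-Mead `xatol = 3e-4`, `fatol = 1e-3`, `maxfev = 300`,
  moment start only. API defaults are stricter (`xatol = 1e-4`,
  `fatol = 1e-4`, 5 starts).
- Resolvent solves clip entries in `(-1e-12, 0)` to zero and renormalize;
  anything below `-1e-12` raises rather than silently repairing a broken
  solve. Rates during optimization are bounded below by `1e-8` where a
  zero would make the phase chain degenerate.
- Degenerate inputs: absorbing off-state (`q_on = 0 < q_off`) and infinite
  off-periods raise; a count above `C` raises a truncation error telling
  the caller to enlarge `C`.

## Known limitations

- Order constraints must be total chains over all phase rates; arbitrary
  partial orders are not supported (no published design needs them).
- The truncation selector assumes upward mobility is what threatens the
  boundary; it was not designed for initial counts far above the
  quasi-stationary range.
- Fits with `L >= 3` and free untied rates inherit the heavy-tailed
  estimator skew of that regime; the package reports across-replicate
  summaries but no per-fit standard errors.
- Unconstrained multi-phase fits cost `L!` constrained fits.
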