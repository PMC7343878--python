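# Methods

## Model

**Macroscopic layer.** A population of size *N* contains *A* certainly
acting, *C* contingent and *N − P* never-acting individuals, *P = A + C*.
With a cumulative emergent-threshold distribution *F*, the number of acting
individuals evolves as

    R(t+1) = A + C · F(R(t)),

the refined form of the classic recursion R(t+1) = N·F(R(t)) (recovered at
A = 0, C = N). Because F maps into [0, 1], all iterates lie in [A, P].
Equilibria solve R = A + C·F(R); graphically they are intersections of F
with the diagonal through (A, 0) and (P, 1), and an intersection where the
map crosses the diagonal from above is stable. Exact tangencies are labelled
`semistable` — transversal crossings are the generic case, but a root finder
will occasionally land on a fold, and silently calling it stable or unstable
would mislabel the dynamics on one side.

**Microscopic layer.** Individuals are nodes of an undirected social
network. At t = 0 exactly the certainly acting nodes are active. Each step,
every contingent inactive node activates iff its share of active neighbours
**strictly** exceeds the threshold fraction ρ; updates are synchronous,
activation is irreversible, and the cascade stops when a step activates no
one (R(t) = R(t−1)). The strict inequality makes ρ = 0.5 a true majority
rule on even degrees, and it implies two boundary conventions used
throughout: zero-degree contingent nodes never activate (share 0 is not
> ρ·0), and at ρ = 1 activation is impossible.

**Emergent threshold distribution.** For a node of an ER network G(N, ℓ)
with R of the other nodes active, the active/inactive neighbour counts are
independent binomials a_i ~ Bin(R, ℓ) and b_i ~ Bin(P′, ℓ) with
P′ = N − 1 − R (one's own state is excluded). The probability that the
activation condition a_i > ρ(a_i + b_i) holds is the exact emergent CDF
`F_exact`. Holding K = ℓ(N−1) fixed as N → ∞ the binomials become Poisson
with rates K·r and K − K·r, giving the analytic form `F_poisson`; its inner
truncated exponential sum equals the regularised upper incomplete gamma
function Q(m+1, K r) with m = ⌊ρ b/(1−ρ)⌋ (the Poisson-CDF identity), which
`F_gamma` evaluates directly. The identity is exact, so the two agree to
numerical precision; `F_gamma` is the default evaluation route in the
fixed-point solvers because the gamma function is cheaper than the explicit
sum at large m. The strict activation inequality means an exactly-integer
ρb/(1−ρ) does **not** activate, so the floor limit includes it in the
non-activation sum, keeping the analytic layer consistent with the
simulator; a 1e-9 absolute nudge before flooring absorbs float
representation error in ρb/(1−ρ).

All forms satisfy F(0) = 0 and, in the Poisson limit, F(1) = 1 − e^(−K):
the deficit is exactly the isolated-node mass, nodes with no neighbours can
never observe an active one.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| N | population / node count | 100 000 | reference study condition; scaled runs use 10 000 |
| K | mean degree of the ER network | 10 | reference condition; only needs K ≫ 0 for the analytic F |
| ℓ | ER linking probability | K/(N−1) | alternative parameterization, see below |
| ρ | threshold fraction | free; {0.2, 0.5, 0.8} in sweeps | spans easy / majority / hard regimes |
| a, p | certainly / potentially acting shares | free | the two tipping control parameters |
| n | ensemble size per parameter cell | 100 (20 in scaled runs) | reference condition |

K vs ℓ: the reference conditions state ℓ = 9·10⁻⁵ at N = 100 000 alongside
a nominal K = 10, but ℓ(N−1) ≈ 9.0. The package refuses to guess: ER
generation accepts exactly one of `mean_degree` or `link_prob`, and when K
is given it uses ℓ = K/(N−1) so the realised mean degree matches K. The
analytic-vs-exact comparison tests use K = ℓ(N−1) = 9.0 so both layers
describe the same network.

## Numerical choices

- **Fixed-point iteration** is real-valued with tolerance 1e-6·N (counts)
  or 1e-10 (fractions); R is treated as continuous, matching the analytic
  treatment, and reported equilibria are real numbers.
- **Root finding**: g(R) = A + C·F(R) − R is evaluated on a dense grid
  (10 001 points by default) and sign changes are refined by Brent
  bisection; F may be flat over wide ranges, so derivative-based steps are
  avoided. Roots closer than two grid steps are merged. Stability is read
  off the sign of g one grid step to each side.
- **Series truncation**: the outer sum over inactive-neighbour counts stops
  where the Poisson (or binomial) tail mass falls below 1e-12, giving ~10
  significant digits for K ≤ 100 without arbitrary caps. Binomial terms in
  `F_exact` use scipy's stable pmf/cdf routines, so no explicit log-space
  bookkeeping is needed up to N ~ 1e5.
- **Fold detection** scans the stable-fixed-point count along a parameter
  and bisects each change to 1e-4. Two stable points count as bistable only
  when separated by more than 1e-4 in r, so grid noise near the cusp cannot
  fabricate folds. The cusp is the smallest p at which a bistable a-window
  exists, refined by bisection on p.
- **Hysteresis** sweeps are adiabatic: at each new parameter value the
  previous equilibrium is relaxed under the new map, i.e. the quasi-static
  dynamics of a slowly drifting parameter. This follows stable branches
  automatically and jumps exactly at the folds; no numerical continuation
  through unstable branches is attempted (the unstable branch is available
  from the root finder instead).
- **Seeding**: every replicate's generator derives from
  `SeedSequence(master_seed, spawn_key=(cell, replicate))`, so single
  replicates are reproducible in isolation and parameter cells are
  statistically independent. Networks are regenerated per replicate, not
  reused with fresh group assignments.
- **critical_sigma** locates the tangency of N·Φ((R−μ)/σ) with the diagonal
  by bisection on the full-cascade predicate (equilibrium ≥ N−1; with the
  cut-off convention the upper fixed point approaches but need not equal N)
  and reports the critical σ rounded to the requested resolution. The
  Gaussian is censored, not renormalised: mass below 0 acts as threshold-0
  instigator mass, mass above N never acts — this convention reproduces the
  classic σ = 12.2 worked example at N = 100, μ = 25.

## Synthetic data

The simulator's default conditions are the reference study conditions
(N = 100 000, K = 10, n = 100; log-spaced a-grids). Scaled experiment
settings used by the test suite and the acceptance script are N = 10 000
with n = 20 replicates, sizes at which the tipping location and the
near-equilibrium threshold estimates are already stable across seeds.

The generator emulates: ER topology, uniformly random group membership, a
single common threshold fraction, synchronous noiseless updates. It does not
emulate real-data features: degree heterogeneity beyond Poisson (scale-free
or small-world structure), homophily or clustering in group membership,
heterogeneous or time-varying thresholds, spontaneous (noise-driven)
activation, or asynchronous updating. Passing tests therefore demonstrate
internal consistency of the micro/macro layers and correctness of the
analytic F on ER networks — not that real social networks tip at these
parameter values.

## Known limitations

- The analytic F is derived for ER networks only; the simulator accepts
  arbitrary edge lists, but no closed-form F is provided for other
  topologies.
- During transients the well-mixed assumption fails (active nodes cluster),
  so empirical threshold points away from equilibrium deviate from the
  analytic F, most visibly at intermediate ρ; the near-equilibrium filter
  (t ∈ {0, t_max − 1}) exposes rather than corrects this, and the package's
  quantitative acceptance band (RMS < 0.05 against the analytic F) applies
  to near-equilibrium points only — it is a package choice, not an external
  reference value.
- No pair-approximation or moment-generating-function corrections, no
  early-warning indicators, no normal-form analysis at the cusp.
- `find_equilibria` assumes a continuous F; genuinely discontinuous CDFs
  (e.g. the step form) can have map jumps across the diagonal that are not
  fixed points and are not reported as such.
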