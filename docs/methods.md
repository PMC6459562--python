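# Methods

## Model

A population of N individuals occupies the nodes of a random regular graph of
degree k.  Each edge carries one of n *types* — a fixed label standing for the
social, genetic or geographic character of the tie — and every node has exactly
g_i edges of type i (the degree profile `(k; g_1..g_n)`, Σg_i = k).  Each
individual plays one multiplayer game per generation with its whole
neighborhood and holds one of two strategies, A (cooperate) or B (defect).
Payoffs depend on the *neighborhood configuration* s = (s_1..s_n), the per-type
counts of A-neighbors: a focal A-player receives `a_s`, a focal B-player `b_s`.
Payoff π maps to fitness F = 1 − ω + ωπ with selection intensity ω; all
analytic results are first-order in ω (weak selection).  Strategies evolve by
death–birth (imitation) updating: a uniformly random individual updates and
adopts the strategy of a neighbor chosen with probability proportional to
fitness.  Edge types never change.

## Structure coefficients and the sigma rule

Whether A fixates more readily than B from a single random mutant is decided,
to first order in ω, by the sigma rule

    Σ_s σ_s (a_s − b_{g−s}) > 0,

with the flip g−s taken coordinate-wise.  The coefficients implemented in
`edgegames.coefficients` are

    σ_s = (k−2)^(k−S) / [k²(k+1)(k+2)] · Π_j C(g_j, s_j) / C(k, S)
          · Σ_{l=0}^{k} (k−l) {[2k+(k−2)l] Ψ(k,S,l) + [k²−(k−2)l] Φ(k,S,l)},

S = Σ s_j, with the kernels

    Ψ(k,i,l) = C(l, k−1−i) / [(k−2)(k−1)^l] + C(k−1−l, k−i) / (k−1)^(k−1−l)
    Φ(k,i,l) = C(l, k−i) / (k−1)^l + C(k−1−l, k−1−i) / [(k−2)(k−1)^(k−1−l)]

and the convention C(a,b) = 0 outside 0 ≤ b ≤ a.  All entries are positive,
the table sums to exactly 1 (so σ is a probability distribution over
configurations and the rule reads "the expected gain from flipping is
positive"), and σ factorizes as the single-type coefficient of the total count
S times the multivariate hypergeometric probability of the split (s_1..s_n)
given S.  Edge diversity therefore enters the success condition only through
that combinatorial factor.

**Derivation and cross-validation.**  The closed form is the pair-approximation
result for death–birth updating.  The package re-derives it from first
principles as an independent oracle: under pair approximation the neighbor of
an A-player is itself A with probability z + (1−z)x and the neighbor of a
B-player with probability (1−z)x, where z = 1/(k−1) is the local assortment
excess and x the global A-frequency.  Expanding the expected one-generation
frequency change to O(ω) yields the selection gradient

    D(x) = (k−1)/k² · Σ_{X∈{A,B}} w_X(x) Σ_t g_t q_X(1−q_X) [EA_t(X) − EB_t(X)],

(w_A = x, w_B = 1−x; EA_t/EB_t the expected payoff of an A-/B-neighbor on a
type-t edge, whose own neighborhood contains the focal plus k−1 pair-
approximation draws).  The diffusion approximation of the fixation-probability
difference then gives

    ρ_A − ρ_B ≈ ω ∫₀¹ D(x) / ((1−z) x (1−x)) dx,

and reading off the coefficient of each a_s identifies σ_s on a scale fixed by
the process itself — on which Σσ = 1 emerges as a theorem rather than a
normalization choice.  `sigma_table_from_dynamics` computes this route in exact
rational arithmetic; the test suite asserts exact equality with the Ψ/Φ closed
form across profiles.  All σ computations use integer/Fraction arithmetic and
convert to float only on output, which keeps tables exact up to at least
k = 40 (needed for the division-of-labor scans).

## Replicator dynamics

The same gradient gives the infinite-population dynamics
ẋ = ωD(x) = ω(k−2)x(1−x)f(x)/k².  `ReplicatorModel` assembles D as a float
polynomial from the exact per-configuration coefficient polynomials, exposes
f(x) and ẋ, finds interior equilibria by a sign scan on a 10⁻³ grid refined by
Brent bisection (tolerance 10⁻¹⁰; a root is stable when f crosses + → −), and
integrates trajectories with an adaptive Runge–Kutta scheme (rtol 10⁻⁸, atol
10⁻⁹, clipped to [0,1]).  A payoff tensor with f identically zero (below
10⁻¹² on the scan grid) is reported as degenerate rather than as a root list.

## Game families

* **Per-type two-player games** (`pairwise_tensor`): payoffs accumulate over
  the k pairwise interactions, each governed by its edge type's 2×2 matrix.
  The sigma rule collapses to the mean-matrix condition
  (k+1)/(k−1)·ᾱ + β̄ > γ̄ + (k+1)/(k−1)·θ̄ (entries averaged with weights
  g_i/k); the full-rule lhs is exactly (k−1)/2 times this simplified lhs.  For
  donation games the condition is B̄/C̄ > k.
* **Additive diverse multiplayer games** (`additive_tensor`): one independent
  game per edge type.  For equal group sizes the lhs equals n times the lhs of
  the single *averaged* game — diverse interactions behave like a unified
  average game.  Provided families: volunteer's dilemma (a_s = Bv−Cv,
  b_s = Bv·1{s>0}) and linear public goods.  The public-goods benefit is
  shared over all g+1 participants (focal plus g neighbors): a_s =
  (s+1)Bp/(g+1) − Cp, b_s = sBp/(g+1).
* **Weighted graphs** (`weighted_tables`): per-type edge weights ζ_j model
  interaction rates and scale each per-type game.  They scale the lhs (and ẋ)
  by the mean weight but cancel from every critical ratio and from the
  interior equilibria: strong ties accelerate evolution without changing its
  direction.
* **Division of labor** (`dol_tensor` / `ndol_tensor`): a two-role threshold
  public goods game.  Type-1 edges join same-role individuals, type-2 edges
  the complementary role; goods require a cooperator of each role (the focal
  cooperator covers its own role).  Accumulative variants grow the goods
  linearly above threshold; fixed-goods variants do not.  The no-division
  baseline uses a single threshold of 2 on the total count.  Critical ratios
  are evaluated both from the printed coefficient sums and through the generic
  affine root (`critical_ratio`, two lhs evaluations — exact, no iteration);
  the two routes agree to 10⁻⁹.  A non-positive denominator (cooperation never
  favored) is reported as +inf rather than an exception so scans can plot it.
* **Large-degree mean payoffs** (`dol_mean_payoffs`): the closed forms for
  fixed-goods games with r = (k−2)/(k−1).  The inequality π^dol < π^ndol is
  strict in exact arithmetic but the A-side gap underflows double precision
  for p ≳ 0.65 at k = 40; tests therefore also evaluate the gap in the
  factored form B·(r(1−p))^{g2}·(1−(r(1−p))^{g1}).

## Monte Carlo simulator

`estimate_fixation` starts each run from one mutant at a uniformly random node
and iterates elementary death–birth events (incremental configuration updates,
numba-compiled kernels) until absorption or a cap of 10⁴ generations (N events
per generation); A- and B-mutant batches use paired per-run seeds derived from
the master seed by fixed offsets.  Fitness positivity 1 − ω + ω·min payoff > 0
is checked before any run.  `exact_fixation` builds the full 2^N transition
matrix and solves the absorption system (sparse LU), serving as the exact
oracle for N ≤ 12; at ω = 0 it reproduces ρ = 1/N exactly.

**Drift protocol.**  `estimate_delta_p` measures the mean one-generation
change of the cooperator frequency.  Each replicate draws an independent
Bernoulli(p) assignment, first runs 10 relaxation generations, records the
realized frequency, then measures the change over one further generation.
The relaxation phase is essential: the analytic drift presumes pair
correlations at their local equilibrium, whereas a fresh Bernoulli state is
uncorrelated and initially follows well-mixed dynamics.  Predictions are
evaluated at the recorded post-relaxation frequency, which drifts away from
the nominal p (toward attractors) by an ω-dependent amount; reported standard
errors are over replicates.

## Validation scales and statistical design

The heavier stochastic checks run at deliberately chosen sizes:

* Oracle agreement: 10⁵ runs on the complete graph K4 and on an N = 8,
  g = (2,1) graph at ω = 0.01, compared to the exact chain within 3 SE.
* Weak-selection law: N = 500, k = 8, g = (3,5), accumulative labor-division
  game, C = 1, benefits at {0.5, 1, 1.5}× the critical ratio, ω = 0.004,
  2×10⁴ runs per strategy per point.  These values were fixed from the
  diffusion theory before simulating: the first-order prediction ω·lhs
  carries a systematic error governed by the full exponential diffusion
  formula, and at these settings that error is below 0.2 Monte Carlo standard
  errors while the signal is ≈ 4.5 SE.  (At, e.g., Nω·lhs ≈ 1.5 the
  first-order formula visibly underpredicts — the regime is then no longer
  weak selection in the fixation sense.)
* Drift agreement: N = 1000, g = (3,3), the two volunteer's dilemmas
  Bv = 1.05 and 10.05 (Cv = 1) and their half/half mixture, ω = 0.01,
  4×10³ replicates per grid point.  Sign agreement is asserted wherever the
  predicted drift exceeds 3 SE; the mixture curve is required to lie between
  the pure curves within the combined 3 SE band.

What the synthetic setting does *not* probe: heterogeneous degrees, dynamic or
multiplex ties, strong selection, mutation, and payoff asymmetry between
individuals.  Passing tests support the pair-approximation theory on large
random regular graphs only; on small graphs (N ≲ 20 at k = 8) or at Nω·|lhs|
of order one, quantitative deviations are expected and measurable.

## Numerical choices

* Exact rationals for all structure-coefficient work; float conversion last.
* Neutrality band: |lhs| < 10⁻¹² reported as neutral (float noise near
  criticality).
* Gaussian sampled-game fixtures truncate draws below 10⁻⁶ to keep benefits
  and costs positive.
* Graph generation overlays n independent per-type regular layers
  (configuration model with repair) and rejects overlays with a duplicated
  edge; retry budget 1000.  Node ids are 0-based, type indices 1-based.
* Random regular layers, per-run chain seeds and Gaussian fixtures all derive
  from explicit integer seeds; identical inputs reproduce identical outputs
  bit for bit.
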