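# edgegames

Evolutionary multiplayer games on regular graphs with **edge diversity** —
populations whose social ties are not interchangeable but carry distinct
meanings (kin vs. strangers, strong vs. weak ties, same vs. complementary
task roles).  The package is for researchers in evolutionary game theory and
the evolution of cooperation who want closed-form weak-selection predictions
on such structures and the simulations to check them.

## The model

Every individual occupies a node of a random regular graph of degree k whose
edges are partitioned into n types; each node has exactly g_i edges of type i
(the degree profile `(k; g_1..g_n)`, Σg_i = k).  Individuals play one
multiplayer game per generation with their whole neighborhood and hold one of
two strategies, A or B.  Payoffs depend on the per-type counts of A-neighbors
s = (s_1..s_n): a focal A-player earns a_s, a focal B-player b_s.  Fitness is
F = 1 − ω + ωπ and strategies spread by death–birth (imitation) updating.

Under weak selection (ω ≪ 1), strategy A fixates more readily than B exactly
when the **sigma rule** holds:

    Σ_s σ_s (a_s − b_{g−s}) > 0,

where the structure coefficients σ_s are computed in closed form (exact
rational arithmetic), are positive, sum to 1, and factorize as

    σ_s = σ_S × Π_j C(g_j, s_j) / C(k, S),        S = Σ_j s_j

— the single-type coefficient for the total count times the multivariate
hypergeometric probability of the per-type split.  To first order,
ρ_A − ρ_B = ω × (left side).  The package also provides the matching
infinite-population replicator dynamics ẋ = ω(k−2)x(1−x)f(x)/k², builders for
the standard game families (per-type two-player games, volunteer's dilemmas,
public goods, weighted graphs, division-of-labor threshold games), a numba
Monte Carlo death–birth simulator, and an exact Markov-chain fixation oracle
for tiny graphs.  See `docs/methods.md` for formulas and derivations.

## Worked example

Each individual plays two volunteer's dilemmas, one per edge type, on a graph
with g = (3, 3) (k = 6): one game has benefit 1.05, the other 10.05, both at
cost 1.

```python
from edgegames import (DegreeProfile, additive_tensor, volunteers_table,
                       sigma_table, marginal_sigma, verdict,
                       ReplicatorModel, equilibria)

prof  = DegreeProfile((3, 3))
table = sigma_table(prof)
tilde = marginal_sigma(table, mode="first")
print(1 / tilde[-1])                      # 3.4965034965034962

tensor = additive_tensor([volunteers_table(3, 1.05, 1.0),
                          volunteers_table(3, 10.05, 1.0)], prof)
print(verdict(table, tensor, omega=0.01))
# SelectionVerdict(lhs=1.1746000000000005, favored='A', omega=0.01,
#                  predicted_difference=0.011746000000000006)

print(equilibria(ReplicatorModel(tensor, 0.01)).roots)
# (0.5232106764792984,)
```

Reading the numbers: a volunteer's dilemma on this graph needs
Bv/Cv > 1/σ̃_g ≈ 3.50 for cooperation to be favored.  The two concurrent
dilemmas average to a unified dilemma with Bv = (1.05+10.05)/2 = 5.55 > 3.50,
so cooperation wins (`favored='A'`), with a predicted fixation-probability
edge of ω × 1.1746 ≈ 0.0117.  In infinite populations the same model has a
stable cooperator–defector coexistence at x ≈ 0.523.  Rescaling either game
by a per-type edge weight changes none of these thresholds or equilibria —
only the speed of selection.

A division-of-labor scan (two task roles, benefit requires a cooperator of
each, fixed goods, k = 40):

```
$ edgegames dol-scan --k 40 --fixed-goods | head -3
g1      bc_dol  bc_ndol
1       1.9839823276724948      24.50168952779901
2       3.9394190362552935      24.50168952779901
```

With rare own-role partners (g1 = 1) cooperation needs only B/C > 1.98
versus 24.5 without labor division — task specialization dramatically lowers
the barrier to cooperation.

The same is available from the shell: `edgegames sigma | predict | critical |
dol-scan | replicate | simulate | make-graph` (see `--help`; `--seed`
everywhere randomness exists).

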