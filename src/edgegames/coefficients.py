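"""Structure coefficients for death-birth updating on edge-typed regular graphs.

Under weak selection, whether strategy A fixates more readily than B on a
large random regular graph is decided by the sigma rule

    sum_s  sigma_s * (a_s - b_{g-s})  >  0,

a payoff-independent weighting of the "gains from flipping" over all
neighborhood configurations s = (s_1..s_n).  This module computes the
closed-form coefficients

    sigma_s = (k-2)^(k-S) / [k^2 (k+1)(k+2)]
              * prod_j C(g_j, s_j) / C(k, S)
              * sum_{l=0}^{k} (k-l) { [2k+(k-2)l] Psi(k,S,l)
                                      + [k^2-(k-2)l] Phi(k,S,l) },

with S = sum_j s_j and the kernels Psi/Phi defined below (binomials vanish
outside their range).  The coefficients are positive, sum to exactly 1, and
factorize into the single-type coefficient for the total count S times the
multivariate hypergeometric probability of the split (s_1..s_n) given S —
edge diversity enters only through that combinatorial factor.

The same pair-approximation calculation behind the closed form yields the
selection gradient D(x) of the infinite-population dynamics; the drift
engine here computes D's per-configuration payoff coefficients as exact
rational polynomials in the A-frequency x.  Integrating
D(x) / ((1-z) x (1-x)) over [0,1] (the diffusion fixation-difference scale,
z = 1/(k-1)) reproduces sigma, which serves as an independent cross-check
of the closed form and powers the replicator module.

All arithmetic is exact (integers / ``fractions.Fraction``) until the final
conversion to float, so tables remain reliable for degrees up to k ~ 40.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb
from typing import Mapping, Sequence

from .graphs import DegreeProfile

__all__ = [
    "SigmaTable",
    "psi",
    "phi",
    "sigma",
    "sigma_table",
    "sigma_table_from_dynamics",
    "marginal_sigma",
    "expected_config",
    "drift_polynomials",
]

Config = tuple[int, ...]

# ---------------------------------------------------------------------------
# exact polynomials: tuple of Fraction coefficients, index = power of x
# ---------------------------------------------------------------------------


def _padd(p: Sequence[Fraction], q: Sequence[Fraction]) -> tuple[Fraction, ...]:
    if len(p) < len(q):
        p, q = q, p
    return tuple(
        c + (q[i] if i < len(q) else 0) for i, c in enumerate(p)
    )


def _pmul(p: Sequence[Fraction], q: Sequence[Fraction]) -> tuple[Fraction, ...]:
    out = [Fraction(0)] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        if a:
            for j, b in enumerate(q):
                if b:
                    out[i + j] += a * b
    return tuple(out)


def _pscale(p: Sequence[Fraction], c: Fraction) -> tuple[Fraction, ...]:
    return tuple(c * a for a in p)


def _ppow(p: Sequence[Fraction], n: int) -> tuple[Fraction, ...]:
    out: tuple[Fraction, ...] = (Fraction(1),)
    for _ in range(n):
        out = _pmul(out, p)
    return out


def _pdiv_x_1mx(p: Sequence[Fraction]) -> tuple[Fraction, ...]:
    """Divide p by x(1-x); p must vanish at 0 and 1."""
    if p[0] != 0:
        raise ArithmeticError("polynomial does not vanish at x=0")
    q = list(p[1:])  # divided by x
    # synthetic division by (1 - x): q(x) = (1-x) r(x) requires sum(q) == 0
    r = [Fraction(0)] * (len(q) - 1) if len(q) > 1 else []
    acc = Fraction(0)
    for i in range(len(r)):
        acc += q[i]
        r[i] = acc
    if acc + (q[-1] if q else 0) != 0:
        raise ArithmeticError("polynomial does not vanish at x=1")
    return tuple(r)


def _pint01(p: Sequence[Fraction]) -> Fraction:
    return sum((c / (i + 1) for i, c in enumerate(p)), Fraction(0))


# ---------------------------------------------------------------------------
# closed form
# ---------------------------------------------------------------------------


def _bino(a: int, b: int) -> int:
    """Binomial coefficient with C(a, b) = 0 outside 0 <= b <= a."""
    if b < 0 or a < 0 or b > a:
        return 0
    return comb(a, b)


def _psi_exact(k: int, i: int, l: int) -> Fraction:
    if k < 3:
        raise ValueError("kernels require k >= 3")
    out = Fraction(0)
    n1 = _bino(l, k - 1 - i)
    if n1:
        out += Fraction(n1, (k - 2) * (k - 1) ** l)
    n2 = _bino(k - 1 - l, k - i)
    if n2:
        out += Fraction(n2, (k - 1) ** (k - 1 - l))
    return out


def _phi_exact(k: int, i: int, l: int) -> Fraction:
    if k < 3:
        raise ValueError("kernels require k >= 3")
    out = Fraction(0)
    n1 = _bino(l, k - i)
    if n1:
        out += Fraction(n1, (k - 1) ** l)
    n2 = _bino(k - 1 - l, k - 1 - i)
    if n2:
        out += Fraction(n2, (k - 2) * (k - 1) ** (k - 1 - l))
    return out


def psi(k: int, i: int, l: int) -> float:
    """Kernel Psi(k, i, l) = C(l, k-1-i)/[(k-2)(k-1)^l] + C(k-1-l, k-i)/(k-1)^(k-1-l)."""
    return float(_psi_exact(k, i, l))


def phi(k: int, i: int, l: int) -> float:
    """Kernel Phi(k, i, l) = C(l, k-i)/(k-1)^l + C(k-1-l, k-1-i)/[(k-2)(k-1)^(k-1-l)]."""
    return float(_phi_exact(k, i, l))


@lru_cache(maxsize=None)
def _sigma_total_exact(k: int, S: int) -> Fraction:
    """Single-type structure coefficient for total A-count S (exact)."""
    if not 0 <= S <= k:
        raise ValueError(f"total count S={S} outside 0..{k}")
    lsum = Fraction(0)
    for l in range(k + 1):
        lsum += (k - l) * (
            (2 * k + (k - 2) * l) * _psi_exact(k, S, l)
            + (k * k - (k - 2) * l) * _phi_exact(k, S, l)
        )
    return Fraction((k - 2) ** (k - S), k * k * (k + 1) * (k + 2)) * lsum


def _sigma_exact(profile: DegreeProfile, config: Config) -> Fraction:
    s = profile.validate_config(config)
    k, S = profile.k, sum(s)
    hyper = Fraction(1, _bino(k, S))
    for gj, sj in zip(profile.g, s):
        hyper *= _bino(gj, sj)
    return _sigma_total_exact(k, S) * hyper


def sigma(
    profile: DegreeProfile, config: Sequence[int], exact: bool = False
) -> float | Fraction:
    """Closed-form structure coefficient for one neighborhood configuration."""
    val = _sigma_exact(profile, tuple(config))
    return val if exact else float(val)


@dataclass(frozen=True)
class SigmaTable:
    """Structure coefficients over the full configuration lattice.

    Entries are positive and sum to 1 (exactly, in exact mode), so the
    table is a probability distribution over neighborhood configurations
    and the sigma rule reads as "the expected gain from flipping is
    positive".
    """

    profile: DegreeProfile
    values: Mapping[Config, float | Fraction]

    def total(self) -> float | Fraction:
        return sum(self.values.values())

    def as_floats(self) -> "SigmaTable":
        return SigmaTable(
            self.profile, {c: float(v) for c, v in self.values.items()}
        )


def sigma_table(profile: DegreeProfile, exact: bool = False) -> SigmaTable:
    """Closed-form coefficients for all prod(g_i + 1) configurations."""
    vals = {c: _sigma_exact(profile, c) for c in profile.configurations()}
    if not exact:
        vals = {c: float(v) for c, v in vals.items()}
    return SigmaTable(profile, vals)


def marginal_sigma(table: SigmaTable, mode: str = "total") -> list[float | Fraction]:
    """Marginal coefficients sigma-tilde.

    mode='total'  -- sum configurations sharing the same total A-count S
                     (length k+1); equals the single-type table for g=(k,).
    mode='first'  -- sum out all coordinates but the first (length g_1+1);
                     this is the per-game marginal used by the averaging
                     rule for equal group sizes.
    """
    zero = Fraction(0) if any(
        isinstance(v, Fraction) for v in table.values.values()
    ) else 0.0
    if mode == "total":
        out = [zero] * (table.profile.k + 1)
        for c, v in table.values.items():
            out[sum(c)] += v
    elif mode == "first":
        out = [zero] * (table.profile.g[0] + 1)
        for c, v in table.values.items():
            out[c[0]] += v
    else:
        raise ValueError("mode must be 'total' or 'first'")
    return out


def expected_config(table: SigmaTable) -> list[float | Fraction]:
    """Per-type means E[s_i] under the table; equal to g_i (k+1) / (2k)."""
    n = table.profile.n
    out = [
        sum(v * c[i] for c, v in table.values.items()) for i in range(n)
    ]
    return out


# ---------------------------------------------------------------------------
# pair-approximation drift engine
# ---------------------------------------------------------------------------
#
# Death-birth updating: a random individual dies and its k neighbors
# compete for the slot proportionally to fitness F = 1 - w + w*pi.  Under
# pair approximation the neighbor of an A-player is itself A with
# probability qA = z + (1-z)x and the neighbor of a B-player with
# probability qB = (1-z)x, where z = 1/(k-1) is the local assortment
# excess.  Expanding the per-generation change of the A-frequency x to
# first order in w gives  dx/dt = w D(x)  with
#
#   D(x) = (k-1)/k^2 * sum_{X in {A,B}} w_X(x) *
#          sum_t g_t qX(1-qX) [ EA_t(X) - EB_t(X) ],
#
# where w_A = x, w_B = 1-x, and EA_t(X) (EB_t(X)) is the expected payoff
# of an A-neighbor (B-neighbor) reached along a type-t edge from an
# X-focal: its own neighborhood has one sure slot occupied by the focal
# and the remaining k-1 slots filled with independent qA (qB) draws.
# D(x) is linear in the payoff entries; drift_polynomials returns the
# exact coefficient polynomial of every a_c and b_c.


@lru_cache(maxsize=32)
def _drift_polynomials_cached(g: tuple[int, ...]):
    profile = DegreeProfile(g)
    k, n = profile.k, profile.n
    z = Fraction(1, k - 1)
    x = (Fraction(0), Fraction(1))
    one_minus_x = (Fraction(1), Fraction(-1))
    qA = (z, 1 - z)
    qB = (Fraction(0), 1 - z)

    def binpmf(m: int, j: int, q) -> tuple[Fraction, ...]:
        # P(Binom(m, q) = j) as a polynomial in x
        if j < 0 or j > m:
            return (Fraction(0),)
        one_minus_q = _padd((Fraction(1),), _pscale(q, Fraction(-1)))
        return _pscale(
            _pmul(_ppow(q, j), _ppow(one_minus_q, m - j)), Fraction(comb(m, j))
        )

    configs = profile.configurations()
    pa = {c: (Fraction(0),) for c in configs}
    pb = {c: (Fraction(0),) for c in configs}
    front = Fraction(k - 1, k * k)
    for focal_A, w_focal, q_focal in ((True, x, qA), (False, one_minus_x, qB)):
        qf1mqf = _pmul(q_focal, _padd((Fraction(1),), _pscale(q_focal, Fraction(-1))))
        base = _pscale(_pmul(w_focal, qf1mqf), front)
        for nbr_A, q_nbr, target in ((True, qA, pa), (False, qB, pb)):
            sign = Fraction(1) if nbr_A else Fraction(-1)
            for t in range(n):
                weight = _pscale(base, sign * profile.g[t])
                # neighbor's config: type t has the focal occupying one slot
                pmfs = [
                    [
                        binpmf(
                            profile.g[m] - (1 if m == t else 0),
                            j - (1 if (m == t and focal_A) else 0),
                            q_nbr,
                        )
                        for j in range(profile.g[m] + 1)
                    ]
                    for m in range(n)
                ]
                for c in configs:
                    prob = pmfs[0][c[0]]
                    for m in range(1, n):
                        prob = _pmul(prob, pmfs[m][c[m]])
                    if any(prob):
                        target[c] = _padd(target[c], _pmul(weight, prob))
    return pa, pb


def drift_polynomials(profile: DegreeProfile):
    """Exact payoff-coefficient polynomials (pa, pb) of the drift D(x).

    D(x) = sum_c pa[c](x) * a_c + pb[c](x) * b_c is the O(omega)
    per-generation selection drift of the A-frequency; both maps are keyed
    by configuration, values are tuples of Fraction coefficients.
    """
    return _drift_polynomials_cached(profile.g)


def sigma_table_from_dynamics(profile: DegreeProfile, exact: bool = True) -> SigmaTable:
    """Structure coefficients recovered from the selection gradient.

    Integrates D(x) / ((1-z) x (1-x)) over [0,1] — the diffusion
    approximation of the weak-selection fixation-probability difference —
    and reads off the coefficient of each a_c.  Independent of the
    Psi/Phi closed form; used to cross-validate it.
    """
    k = profile.k
    z = Fraction(1, k - 1)
    pa, _ = drift_polynomials(profile)
    vals = {
        c: _pint01(_pdiv_x_1mx(p)) / (1 - z) for c, p in pa.items()
    }
    if not exact:
        vals = {c: float(v) for c, v in vals.items()}
    return SigmaTable(profile, vals)
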