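"""The sigma rule: weak-selection success conditions and critical ratios.

Strategy A is favored over B (fixates more readily from a single random
mutant) when the sigma-weighted expected gain from flipping is positive:

    lhs = sum_s sigma_s (a_s - b_{g-s}) > 0,

and to first order in the selection intensity the fixation-probability
difference is rho_A - rho_B = omega * lhs.  Because every implemented game
family is affine in its benefit parameter, critical benefit-to-cost ratios
follow from two lhs evaluations in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

from .coefficients import SigmaTable, marginal_sigma, sigma_table
from .graphs import DegreeProfile
from .payoffs import PayoffTensor

__all__ = [
    "SelectionVerdict",
    "NEUTRAL_BAND",
    "sigma_rule_lhs",
    "verdict",
    "critical_ratio",
    "critical_dol",
    "pairwise_condition",
    "coefficient_count",
]

#: |lhs| below this is reported as neutral (float noise near criticality).
NEUTRAL_BAND = 1e-12


@dataclass(frozen=True)
class SelectionVerdict:
    lhs: float
    favored: str  # "A" | "B" | "neutral"
    omega: float
    predicted_difference: float  # rho_A - rho_B to first order in omega


def sigma_rule_lhs(table: SigmaTable, tensor: PayoffTensor) -> float:
    """Left side of the sigma rule: sum_s sigma_s (a_s - b_{g-s})."""
    if table.profile.g != tensor.profile.g:
        raise ValueError(
            f"profile mismatch: table g={table.profile.g}, tensor g={tensor.profile.g}"
        )
    g = table.profile.g
    out = 0.0
    for c, w in table.values.items():
        flipped = tuple(gi - si for gi, si in zip(g, c))
        out += float(w) * (tensor.a[c] - tensor.b[flipped])
    return out


def verdict(table: SigmaTable, tensor: PayoffTensor, omega: float) -> SelectionVerdict:
    """Favored strategy and predicted fixation difference omega * lhs."""
    if omega <= 0:
        raise ValueError("selection intensity omega must be positive")
    lhs = sigma_rule_lhs(table, tensor)
    if abs(lhs) < NEUTRAL_BAND:
        favored = "neutral"
    else:
        favored = "A" if lhs > 0 else "B"
    return SelectionVerdict(
        lhs=lhs, favored=favored, omega=omega, predicted_difference=omega * lhs
    )


def critical_ratio(
    family: Callable[[float], PayoffTensor],
    table: SigmaTable,
    cost: float = 1.0,
) -> float:
    """Critical benefit-to-cost ratio (B/C)* where the sigma rule is neutral.

    ``family(B)`` must build the tensor at benefit B with the cost held at
    ``cost``; the lhs is affine in B for every implemented family, so the
    root comes from two evaluations.  Returns +inf when the lhs slope is
    non-positive (cooperation never favored at finite benefit).
    """
    l0 = sigma_rule_lhs(table, family(cost))
    l1 = sigma_rule_lhs(table, family(2.0 * cost))
    slope = (l1 - l0) / cost
    if abs(slope) < NEUTRAL_BAND:
        raise ValueError("lhs is independent of the benefit parameter")
    b_star = cost - l0 / slope
    if slope < 0 or b_star <= 0:
        return math.inf
    return b_star / cost


def critical_dol(
    k: int,
    g1: int | None = None,
    g2: int | None = None,
    labor_division: bool = True,
    accumulative: bool = True,
) -> float:
    """(B/C)* for the threshold public goods game, with or without labor division.

    With division of labor (profile (g1, g2), benefit requires a
    cooperator of each role):

        accumulative:      1 / [ sum_{s1, s2>=1} (s1+s2+1) sigma_{s1 s2}
                                 - sum_{s1<g1, s2<g2} (k-s1-s2) sigma_{s1 s2} ]
        fixed goods:       1 / [ sum_{s1, s2>=1} sigma_{s1 s2}
                                 - sum_{s1<g1, s2<g2} sigma_{s1 s2} ]

    Without labor division (single threshold 2 on the total count, per-S
    coefficients sigma_s):

        accumulative:      1 / [ sum_{s>=1} (s+1) sigma_s
                                 - sum_{s<=k-2} (k-s) sigma_s ]
        fixed goods:       1 / [ sum_{s>=1} sigma_s - sum_{s<=k-2} sigma_s ]

    Returns +inf when the denominator is non-positive (cooperation never
    favored).  Agrees with ``critical_ratio`` applied to the matching
    tensor builder.
    """
    if labor_division:
        if g1 is None or g2 is None or g1 + g2 != k:
            raise ValueError("labor division requires g1 + g2 = k")
        table = sigma_table(DegreeProfile((g1, g2)))
        denom = 0.0
        for (s1, s2), w in table.values.items():
            if s2 >= 1:
                denom += w * ((s1 + s2 + 1) if accumulative else 1.0)
            if s1 <= g1 - 1 and s2 <= g2 - 1:
                denom -= w * ((k - s1 - s2) if accumulative else 1.0)
    else:
        tilde = marginal_sigma(sigma_table(DegreeProfile((k,))), mode="total")
        denom = 0.0
        for s, w in enumerate(tilde):
            if s >= 1:
                denom += w * ((s + 1) if accumulative else 1.0)
            if s <= k - 2:
                denom -= w * ((k - s) if accumulative else 1.0)
    if denom <= 0:
        return math.inf
    return 1.0 / denom


def pairwise_condition(
    matrices: Sequence[tuple[float, float, float, float]],
    profile: DegreeProfile,
    omega: float = 0.01,
) -> SelectionVerdict:
    """Closed-form condition for accumulated per-type two-player games.

    A is favored iff  (k+1)/(k-1) abar + bbar > gbar + (k+1)/(k-1) tbar,
    with the entries averaged over types weighted by g_i / k — the unified
    game carries the familiar pairwise structure coefficient (k+1)/(k-1).
    The reported lhs is on this simplified scale; the full sigma-rule lhs
    is exactly (k-1)/2 times it, and the predicted fixation difference
    uses that full scale.
    """
    if len(matrices) != profile.n:
        raise ValueError("need one matrix per type")
    k = profile.k
    abar = sum(g * m[0] for g, m in zip(profile.g, matrices)) / k
    bbar = sum(g * m[1] for g, m in zip(profile.g, matrices)) / k
    gbar = sum(g * m[2] for g, m in zip(profile.g, matrices)) / k
    tbar = sum(g * m[3] for g, m in zip(profile.g, matrices)) / k
    coef = (k + 1) / (k - 1)
    lhs = coef * abar + bbar - gbar - coef * tbar
    if abs(lhs) < NEUTRAL_BAND:
        favored = "neutral"
    else:
        favored = "A" if lhs > 0 else "B"
    return SelectionVerdict(
        lhs=lhs,
        favored=favored,
        omega=omega,
        predicted_difference=omega * lhs * (k - 1) / 2.0,
    )


def coefficient_count(profile: DegreeProfile, payoff_class: str = "general") -> int:
    """Number of structure coefficients needed to predict the outcome.

    With m distinct group sizes g_i of multiplicities n_i:
    'general' payoff structures need prod_i C(g_i + n_i, n_i) coefficients,
    additive diverse games ('diverse-additive') only sum_i (g_i + 1).
    """
    distinct: dict[int, int] = {}
    for gi in profile.g:
        distinct[gi] = distinct.get(gi, 0) + 1
    if payoff_class == "general":
        out = 1
        for gi, ni in distinct.items():
            out *= math.comb(gi + ni, ni)
        return out
    if payoff_class == "diverse-additive":
        return sum(gi + 1 for gi in distinct)
    raise ValueError("payoff_class must be 'general' or 'diverse-additive'")
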