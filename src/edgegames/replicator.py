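"""Infinite-population replicator dynamics on edge-typed regular graphs.

The pair-approximation selection gradient gives the frequency dynamics

    dx/dt = omega * D(x),          D(x) = (k-2) x (1-x) f(x) / k^2,

where x is the frequency of A-players and f collects the expected local
payoff advantage of A-neighbors over B-neighbors in the competition for a
vacated site (see ``edgegames.coefficients`` for the derivation).  D is a
polynomial with exact rational payoff coefficients, evaluated here in
floating point.  Interior equilibria are the roots of f on (0, 1); a root
is stable when f crosses from positive to negative.

Also provided: the large-degree mean-payoff formulas for the fixed-goods
threshold game with and without division of labor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .coefficients import _pdiv_x_1mx, drift_polynomials
from .graphs import DegreeProfile
from .payoffs import PayoffTensor

__all__ = [
    "ReplicatorModel",
    "EquilibriaResult",
    "DolMeanPayoffs",
    "lambda_a",
    "lambda_b",
    "f_of_x",
    "xdot",
    "equilibria",
    "trajectory",
    "dol_mean_payoffs",
    "payoff_ratio_compare",
]


class ReplicatorModel:
    """Replicator dynamics for one payoff tensor at selection intensity omega."""

    def __init__(self, tensor: PayoffTensor, omega: float = 0.01):
        if omega <= 0:
            raise ValueError("omega must be positive")
        self.tensor = tensor
        self.omega = float(omega)
        self.profile: DegreeProfile = tensor.profile
        k = self.profile.k
        self.z = 1.0 / (k - 1)
        # f(x) = D(x) k^2 / ((k-2) x (1-x)); each payoff-coefficient
        # polynomial of D vanishes at 0 and 1, so divide exactly first.
        pa, pb = drift_polynomials(self.profile)
        scale = Fraction(k * k, k - 2)
        terms: dict[int, float] = {}
        for table, polys in ((tensor.a, pa), (tensor.b, pb)):
            for c, poly in polys.items():
                val = table[c]
                if val == 0.0:
                    continue
                for i, coef in enumerate(_pdiv_x_1mx(poly)):
                    if coef:
                        terms[i] = terms.get(i, 0.0) + float(coef * scale) * val
        deg = max(terms, default=0)
        self._f_coeffs = np.array(
            [terms.get(i, 0.0) for i in range(deg + 1)], dtype=float
        )

    @property
    def k(self) -> int:
        return self.profile.k

    def f(self, x):
        x = np.asarray(x, dtype=float)
        if np.any((x < 0) | (x > 1)):
            raise ValueError("x must lie in [0, 1]")
        # Horner on ascending coefficients
        out = np.zeros_like(x)
        for coef in self._f_coeffs[::-1]:
            out = out * x + coef
        return out if out.shape else float(out)

    def xdot(self, x):
        x = np.asarray(x, dtype=float)
        k = self.k
        out = self.omega * (k - 2) * x * (1.0 - x) * self.f(x) / k**2
        return out if out.shape else float(out)


def f_of_x(x, model: ReplicatorModel):
    """Selection gradient factor f(x); its sign is the direction of selection."""
    return model.f(x)


def xdot(x, model: ReplicatorModel):
    """dx/dt = omega (k-2) x (1-x) f(x) / k^2; vanishes at x = 0 and 1."""
    return model.xdot(x)


def _neighbor_payoff_terms(model: ReplicatorModel, x: float, focal_A: bool):
    """(EA_t, EB_t): expected payoff of an A-/B-neighbor per edge type."""
    prof = model.profile
    z = model.z
    qA = z + (1 - z) * x
    qB = (1 - z) * x
    tensor = model.tensor

    def pmf(m, j, q):
        if j < 0 or j > m:
            return 0.0
        return math.comb(m, j) * q**j * (1 - q) ** (m - j)

    EA, EB = [], []
    for t in range(prof.n):
        for is_A, q, table, out in ((True, qA, tensor.a, EA), (False, qB, tensor.b, EB)):
            tot = 0.0
            for c in prof.configurations():
                w = 1.0
                for m in range(prof.n):
                    w *= pmf(
                        prof.g[m] - (1 if m == t else 0),
                        c[m] - (1 if (m == t and focal_A) else 0),
                        q,
                    )
                    if w == 0.0:
                        break
                tot += w * table[c]
            out.append(tot)
    return EA, EB


def _kappa(model: ReplicatorModel, x: float, focal_A: bool) -> float:
    prof = model.profile
    z = model.z
    q = (z + (1 - z) * x) if focal_A else (1 - z) * x
    EA, EB = _neighbor_payoff_terms(model, x, focal_A)
    return sum(
        g * q * (1 - q) * (ea - eb) for g, ea, eb in zip(prof.g, EA, EB)
    )


def lambda_a(model: ReplicatorModel, x: float) -> float:
    """Local payoff advantage of A- over B-neighbors around an updating A-player.

    Weighted by the per-type chance that the contested edge carries the
    respective strategy; enters the gradient as
    D(x) = (k-1)/k^2 [x lambda_a + (1-x) lambda_b].
    """
    return _kappa(model, x, focal_A=True)


def lambda_b(model: ReplicatorModel, x: float) -> float:
    """Companion kernel for an updating B-player; see ``lambda_a``."""
    return _kappa(model, x, focal_A=False)


@dataclass(frozen=True)
class EquilibriaResult:
    degenerate: bool  # f is identically ~0 (neutral game)
    roots: tuple[float, ...]
    stable: tuple[bool, ...]  # per root: f crosses + -> -


def equilibria(
    model: ReplicatorModel, tol: float = 1e-10, grid: int = 1000
) -> EquilibriaResult:
    """Interior roots of f on (0, 1) by sign scan plus bisection refinement."""
    xs = np.linspace(0.0, 1.0, grid + 1)
    fs = model.f(xs)
    if np.max(np.abs(fs)) < 1e-12:
        return EquilibriaResult(degenerate=True, roots=(), stable=())
    roots, stable = [], []
    for i in range(grid):
        lo, hi = fs[i], fs[i + 1]
        if lo == 0.0 and 0 < i:  # grid point root, handled via bracket below
            continue
        if lo * hi < 0:
            r = brentq(model.f, xs[i], xs[i + 1], xtol=tol)
            if 0.0 < r < 1.0:
                roots.append(float(r))
                stable.append(bool(lo > 0 > hi))
    return EquilibriaResult(
        degenerate=False, roots=tuple(roots), stable=tuple(stable)
    )


def trajectory(
    model: ReplicatorModel,
    x0: float,
    horizon: float,
    step: float | None = None,
):
    """Integrate dx/dt = omega (k-2) x (1-x) f(x)/k^2 from x0 over [0, horizon].

    Returns (t, x) arrays; x stays inside [0, 1].
    """
    if not 0 < x0 < 1:
        raise ValueError("x0 must lie in (0, 1)")
    if step is None:
        step = horizon / 200.0
    t_eval = np.arange(0.0, horizon + step / 2, step)
    sol = solve_ivp(
        lambda _, y: [model.xdot(min(max(y[0], 0.0), 1.0))],
        (0.0, horizon),
        [x0],
        t_eval=t_eval,
        rtol=1e-8,
        atol=1e-9,
        method="RK45",
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol.t, np.clip(sol.y[0], 0.0, 1.0)


# ---------------------------------------------------------------------------
# large-k mean payoffs for the fixed-goods threshold game (Example: division
# of labor with roles of sizes g1 and g2, r = (k-2)/(k-1))
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DolMeanPayoffs:
    p: float
    pi_A_ndol: float
    pi_B_ndol: float
    pi_A_dol: float
    pi_B_dol: float
    r: float


def dol_mean_payoffs(
    p: float, B: float, C: float, k: int, g1: int, g2: int
) -> DolMeanPayoffs:
    """Mean payoffs of cooperators and defectors at cooperator frequency p.

    Large-degree closed forms for the fixed-goods threshold game:

        pi_A^ndol = [1 - r^k (1-p)^k] B - C
        pi_B^ndol = [1 - (1 - r p)^(k-1) (1 + k p - 2 p)] B
        pi_A^dol  = [1 - r^g2 (1-p)^g2] B - C
        pi_B^dol  = [1 - (1 - r p)^g1][1 - (1 - r p)^g2] B

    with r = (k-2)/(k-1).  Division of labor transiently lowers both mean
    payoffs (the provision condition is stricter), but reshapes the payoff
    *ratio* in favor of cooperators when the focal's own role is rare.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if g1 + g2 != k:
        raise ValueError("need g1 + g2 = k")
    r = (k - 2) / (k - 1)
    return DolMeanPayoffs(
        p=p,
        pi_A_ndol=(1 - r**k * (1 - p) ** k) * B - C,
        pi_B_ndol=(1 - (1 - r * p) ** (k - 1) * (1 + k * p - 2 * p)) * B,
        pi_A_dol=(1 - r**g2 * (1 - p) ** g2) * B - C,
        pi_B_dol=(1 - (1 - r * p) ** g1) * (1 - (1 - r * p) ** g2) * B,
        r=r,
    )


def payoff_ratio_compare(
    p_grid, B: float, C: float, k: int, g1: int, g2: int
) -> list[dict]:
    """Compare pi_A/pi_B with and without labor division along a p grid.

    Each record reports both ratios and which regime advantages
    cooperators; grid points where a defector mean payoff vanishes are
    marked excluded.
    """
    out = []
    for p in p_grid:
        m = dol_mean_payoffs(float(p), B, C, k, g1, g2)
        rec = {"p": float(p)}
        if m.pi_B_dol == 0.0 or m.pi_B_ndol == 0.0:
            rec["excluded"] = "defector mean payoff is zero"
        else:
            rec["ratio_dol"] = m.pi_A_dol / m.pi_B_dol
            rec["ratio_ndol"] = m.pi_A_ndol / m.pi_B_ndol
            rec["dol_advantages_A"] = rec["ratio_dol"] > rec["ratio_ndol"]
        out.append(rec)
    return out
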