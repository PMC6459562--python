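"""Payoff tensors over neighborhood configurations.

A game on an edge-typed graph assigns a focal A-player the payoff
``a[s1..sn]`` and a focal B-player ``b[s1..sn]``, where ``s_i`` counts
A-neighbors along type-i edges.  Builders cover the standard families:
per-type 2x2 matrices accumulated over neighbors, additive collections of
independent per-type multiplayer games (volunteer's dilemma, linear public
goods), weighted-graph rescalings, and threshold public-goods games with
division of labor.  Tensors are stored keyed by the full configuration
tuple even for games that depend on the total count only, so a single
sigma-rule evaluator serves every family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .graphs import DegreeProfile

__all__ = [
    "PayoffTensor",
    "pairwise_tensor",
    "additive_tensor",
    "per_s_tensor",
    "average_game",
    "volunteers_table",
    "pgg_table",
    "weighted_tables",
    "dol_tensor",
    "ndol_tensor",
    "sampled_game_fixture",
    "read_tensor",
    "write_tensor",
]

Config = tuple[int, ...]


@dataclass(frozen=True)
class PayoffTensor:
    profile: DegreeProfile
    a: Mapping[Config, float]
    b: Mapping[Config, float]

    def __post_init__(self) -> None:
        configs = set(self.profile.configurations())
        for name, table in (("a", self.a), ("b", self.b)):
            if set(table) != configs:
                raise ValueError(
                    f"{name} must cover all {self.profile.n_configs} configurations"
                )
            if not all(math.isfinite(v) for v in table.values()):
                raise ValueError(f"{name} contains non-finite payoffs")

    def scaled(self, factor: float) -> "PayoffTensor":
        return PayoffTensor(
            self.profile,
            {c: factor * v for c, v in self.a.items()},
            {c: factor * v for c, v in self.b.items()},
        )

    def payoff(self, is_A: bool, config: Config) -> float:
        table = self.a if is_A else self.b
        return table[self.profile.validate_config(config)]

    def min_payoff(self) -> float:
        return min(min(self.a.values()), min(self.b.values()))


def _build(profile: DegreeProfile, fa: Callable, fb: Callable) -> PayoffTensor:
    configs = profile.configurations()
    return PayoffTensor(
        profile,
        {c: float(fa(c)) for c in configs},
        {c: float(fb(c)) for c in configs},
    )


def pairwise_tensor(
    matrices: Sequence[tuple[float, float, float, float]], profile: DegreeProfile
) -> PayoffTensor:
    """Accumulated two-player games, one 2x2 matrix per edge type.

    ``matrices[i] = (alpha_i, beta_i, gamma_i, theta_i)`` is the payoff
    matrix for interactions on type-(i+1) edges (row player vs A / vs B).
    a_s = sum_i [s_i alpha_i + (g_i - s_i) beta_i] and
    b_s = sum_i [s_i gamma_i + (g_i - s_i) theta_i].
    """
    if len(matrices) != profile.n:
        raise ValueError(f"need one matrix per type ({profile.n}), got {len(matrices)}")
    g = profile.g
    return _build(
        profile,
        lambda s: sum(s[i] * m[0] + (g[i] - s[i]) * m[1] for i, m in enumerate(matrices)),
        lambda s: sum(s[i] * m[2] + (g[i] - s[i]) * m[3] for i, m in enumerate(matrices)),
    )


def additive_tensor(
    per_type_games: Sequence[tuple[Sequence[float], Sequence[float]]],
    profile: DegreeProfile,
) -> PayoffTensor:
    """Independent multiplayer games played within each edge type.

    ``per_type_games[j] = (a_table, b_table)`` of length ``g_j + 1``; the
    focal accumulates payoffs across its n concurrent games:
    a_s = sum_j a^(j)[s_j].
    """
    if len(per_type_games) != profile.n:
        raise ValueError("need one game per type")
    for j, (ta, tb) in enumerate(per_type_games):
        if len(ta) != profile.g[j] + 1 or len(tb) != profile.g[j] + 1:
            raise ValueError(
                f"game {j + 1} tables must have length g_{j + 1}+1 = {profile.g[j] + 1}"
            )
    return _build(
        profile,
        lambda s: sum(per_type_games[j][0][s[j]] for j in range(profile.n)),
        lambda s: sum(per_type_games[j][1][s[j]] for j in range(profile.n)),
    )


def per_s_tensor(
    a_table: Sequence[float], b_table: Sequence[float], profile: DegreeProfile
) -> PayoffTensor:
    """Tensor for a game that depends on the total A-count S only."""
    if len(a_table) != profile.k + 1 or len(b_table) != profile.k + 1:
        raise ValueError("per-S tables must have length k+1")
    return _build(profile, lambda s: a_table[sum(s)], lambda s: b_table[sum(s)])


def average_game(
    per_type_games: Sequence[tuple[Sequence[float], Sequence[float]]]
) -> tuple[list[float], list[float]]:
    """Unified game averaging n same-size games: abar_s = (1/n) sum_j a^(j)_s."""
    sizes = {len(ta) for ta, _ in per_type_games} | {len(tb) for _, tb in per_type_games}
    if len(sizes) != 1:
        raise ValueError("averaging requires equal group sizes g_j")
    n = len(per_type_games)
    length = sizes.pop()
    abar = [sum(g[0][s] for g in per_type_games) / n for s in range(length)]
    bbar = [sum(g[1][s] for g in per_type_games) / n for s in range(length)]
    return abar, bbar


def volunteers_table(g: int, Bv: float, Cv: float) -> tuple[list[float], list[float]]:
    """Volunteer's dilemma among g+1 participants.

    One cooperator suffices: a_s = Bv - Cv for all s (the focal cooperator
    itself volunteers), b_s = Bv for s > 0 and b_0 = 0.
    """
    if g < 1 or Bv <= 0 or Cv <= 0:
        raise ValueError("need g >= 1 and positive Bv, Cv")
    return (
        [Bv - Cv] * (g + 1),
        [0.0] + [Bv] * g,
    )


def pgg_table(g: int, Bp: float, Cp: float) -> tuple[list[float], list[float]]:
    """Linear public goods game among g+1 participants.

    Each cooperator invests Cp producing a benefit Bp shared evenly over
    all g+1 participants: a_s = (s+1) Bp/(g+1) - Cp, b_s = s Bp/(g+1).
    """
    if g < 1:
        raise ValueError("need g >= 1")
    share = Bp / (g + 1)
    return (
        [(s + 1) * share - Cp for s in range(g + 1)],
        [s * share for s in range(g + 1)],
    )


def weighted_tables(
    base_tables: Sequence[tuple[Sequence[float], Sequence[float]]],
    zeta: Sequence[float],
) -> list[tuple[list[float], list[float]]]:
    """Scale game j by the edge weight zeta_j (interaction rate)."""
    if len(zeta) != len(base_tables):
        raise ValueError("need one weight per game")
    if any(z <= 0 for z in zeta):
        raise ValueError("edge weights must be positive")
    return [
        ([z * v for v in ta], [z * v for v in tb])
        for z, (ta, tb) in zip(zeta, base_tables)
    ]


def dol_tensor(
    profile: DegreeProfile, B: float, C: float, accumulative: bool = True
) -> PayoffTensor:
    """Division-of-labor threshold public goods game (two roles).

    Type-1 edges link individuals performing the focal's own subtask,
    type-2 edges the complementary subtask.  Goods are produced only when
    both subtasks have a cooperator; a focal cooperator covers its own
    subtask, so it needs only s_2 >= 1, while a focal defector needs
    s_1 >= 1 and s_2 >= 1.  With ``accumulative`` goods the benefit grows
    linearly with the number of cooperators above threshold; otherwise it
    is fixed at B.
    """
    if profile.n != 2:
        raise ValueError("division of labor with two roles needs n = 2")
    if B <= 0 or C <= 0:
        raise ValueError("need positive B and C")
    if accumulative:
        fa = lambda s: (s[0] + s[1] + 1) * B - C if s[1] >= 1 else -C
        fb = lambda s: (s[0] + s[1]) * B if (s[0] >= 1 and s[1] >= 1) else 0.0
    else:
        fa = lambda s: B - C if s[1] >= 1 else -C
        fb = lambda s: B if (s[0] >= 1 and s[1] >= 1) else 0.0
    return _build(profile, fa, fb)


def ndol_tensor(
    k: int, B: float, C: float, accumulative: bool = True
) -> tuple[list[float], list[float]]:
    """Single-threshold counterpart with no labor division (threshold 2).

    Per-S tables of length k+1: a_s = (s+1)B - C for s >= 1 (focal
    cooperator counts toward the threshold) and -C otherwise;
    b_s = s B for s >= 2 (or the fixed-goods variants of both).
    """
    if k < 3:
        raise ValueError("need k >= 3")
    if accumulative:
        a = [-C] + [(s + 1) * B - C for s in range(1, k + 1)]
        b = [0.0, 0.0] + [s * B for s in range(2, k + 1)]
    else:
        a = [-C] + [B - C] * k
        b = [0.0, 0.0] + [B] * (k - 1)
    return a, b


def sampled_game_fixture(
    g: int,
    n_games: int,
    mean_benefit: float,
    var_benefit: float,
    mean_cost: float,
    var_cost: float,
    family: str,
    seed: int,
    floor: float = 1e-6,
) -> list[tuple[list[float], list[float]]]:
    """Per-interaction games with Gaussian benefits and costs.

    Draws ``n_games`` independent (benefit, cost) pairs from normal
    distributions (truncated below at ``floor`` to keep them positive) and
    builds the requested family ('vd' or 'pgg') for each.
    """
    if mean_benefit <= 0 or mean_cost <= 0 or var_benefit < 0 or var_cost < 0:
        raise ValueError("need positive means and non-negative variances")
    rng = np.random.default_rng(seed)
    benefits = np.maximum(
        rng.normal(mean_benefit, math.sqrt(var_benefit), n_games), floor
    )
    costs = np.maximum(rng.normal(mean_cost, math.sqrt(var_cost), n_games), floor)
    builder = {"vd": volunteers_table, "pgg": pgg_table}[family.lower()]
    return [builder(g, float(b), float(c)) for b, c in zip(benefits, costs)]


# ---------------------------------------------------------------------------
# Tensor TSV: header "#profile g=<g1,...,gn>", then columns s1..sn a b.
# ---------------------------------------------------------------------------


def write_tensor(tensor: PayoffTensor, path: str | Path) -> None:
    prof = tensor.profile
    lines = [f"#profile g={','.join(map(str, prof.g))}"]
    lines.append("\t".join(f"s{i + 1}" for i in range(prof.n)) + "\ta\tb")
    for c in prof.configurations():
        lines.append(
            "\t".join(map(str, c)) + f"\t{tensor.a[c]!r}\t{tensor.b[c]!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_tensor(path: str | Path) -> PayoffTensor:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#profile"):
        raise ValueError(f"{path}: missing '#profile' header")
    header = dict(item.split("=", 1) for item in lines[0].split()[1:] if "=" in item)
    profile = DegreeProfile([int(x) for x in header["g"].split(",")])
    a: dict[Config, float] = {}
    b: dict[Config, float] = {}
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#") or line.startswith("s1"):
            continue
        cols = line.split("\t")
        if len(cols) != profile.n + 2:
            raise ValueError(f"{path}:{ln}: expected {profile.n + 2} columns")
        c = profile.validate_config(tuple(int(x) for x in cols[: profile.n]))
        a[c] = float(cols[-2])
        b[c] = float(cols[-1])
    return PayoffTensor(profile, a, b)
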