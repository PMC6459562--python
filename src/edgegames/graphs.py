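"""Edge-typed regular graphs.

Population structure for evolutionary games with edge diversity: every
individual occupies a node of an N-node graph of uniform degree k whose
incident edges are partitioned into n types, with exactly ``g[i]`` edges of
type ``i`` at every node (the *degree profile* ``(k; g_1..g_n)``).  Edge
types carry the social meaning of a tie (genetic similarity, geographic
proximity, task assignment, interaction rate) and stay fixed while
strategies evolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "DegreeProfile",
    "EdgeTypedGraph",
    "GraphGenerationError",
    "generate_typed_graph",
    "neighborhood_config",
    "read_graph",
    "write_graph",
]


class GraphGenerationError(RuntimeError):
    """No collision-free overlay of the per-type regular layers was found."""


@dataclass(frozen=True)
class DegreeProfile:
    """Local edge-type composition ``(k; g_1..g_n)`` shared by every node.

    ``g[i-1]`` is the number of type-``i`` edges at each node; the total
    degree is ``k = sum(g)``.  Type indices are 1-based throughout, matching
    the usual subscript convention; ``k >= 3`` is required by the
    structure-coefficient closed form (it contains ``k - 2`` factors).
    """

    g: tuple[int, ...]

    def __init__(self, g: Sequence[int]):
        object.__setattr__(self, "g", tuple(int(x) for x in g))
        if not self.g or any(x < 1 for x in self.g):
            raise ValueError("every g_i must be a positive integer")
        if self.k < 3:
            raise ValueError(f"total degree k={self.k} must be >= 3")
        if self.n > self.k:
            raise ValueError("cannot have more edge types than edges per node")

    @property
    def k(self) -> int:
        return sum(self.g)

    @property
    def n(self) -> int:
        return len(self.g)

    @property
    def n_configs(self) -> int:
        """Number of neighborhood configurations, prod(g_i + 1)."""
        out = 1
        for gi in self.g:
            out *= gi + 1
        return out

    def configurations(self):
        """All neighborhood states ``(s_1..s_n)``, lexicographic order."""
        return _lattice(self.g)

    def validate_config(self, s: Sequence[int]) -> tuple[int, ...]:
        s = tuple(int(x) for x in s)
        if len(s) != self.n or any(not 0 <= si <= gi for si, gi in zip(s, self.g)):
            raise ValueError(f"configuration {s} invalid for profile g={self.g}")
        return s

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DegreeProfile(k={self.k}, g={self.g})"


def _lattice(g: Sequence[int]):
    out = [()]
    for gi in g:
        out = [c + (s,) for c in out for s in range(gi + 1)]
    return out


@dataclass
class EdgeTypedGraph:
    """N-node regular graph whose incident edges realize a degree profile.

    ``adjacency[v]`` lists ``(neighbor, type)`` pairs with 1-based types.
    Optional per-type positive weights ``zeta`` model interaction rates;
    they attach to types, not individual edges.
    """

    N: int
    profile: DegreeProfile
    adjacency: list[list[tuple[int, int]]]
    zeta: tuple[float, ...] | None = None
    _arrays: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def neighbors(self, v: int) -> list[tuple[int, int]]:
        if not 0 <= v < self.N:
            raise KeyError(f"node {v} not in graph of size {self.N}")
        return self.adjacency[v]

    def edges(self):
        """Each undirected edge once, as (u, v, type) with u < v."""
        for u, nbrs in enumerate(self.adjacency):
            for v, t in nbrs:
                if u < v:
                    yield (u, v, t)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(neighbors, types) as (N, k) int arrays, types 0-based; cached."""
        if self._arrays is None:
            k = self.profile.k
            nbr = np.empty((self.N, k), dtype=np.int64)
            typ = np.empty((self.N, k), dtype=np.int64)
            for v, lst in enumerate(self.adjacency):
                nbr[v] = [u for u, _ in lst]
                typ[v] = [t - 1 for _, t in lst]
            self._arrays = (nbr, typ)
        return self._arrays

    def validate(self) -> None:
        """Check symmetry, simplicity and per-type regularity; raise if violated."""
        if self.N <= self.profile.k:
            raise ValueError("need N > k")
        seen: set[tuple[int, int]] = set()
        for u, nbrs in enumerate(self.adjacency):
            counts = [0] * self.profile.n
            for v, t in nbrs:
                if v == u:
                    raise ValueError(f"self-loop at node {u}")
                pair = (min(u, v), max(u, v))
                if u < v and pair in seen:
                    raise ValueError(f"parallel edge {pair}")
                if u < v:
                    seen.add(pair)
                if (u, t) not in self.adjacency[v]:
                    raise ValueError(f"asymmetric edge {u}-{v} type {t}")
                counts[t - 1] += 1
            if tuple(counts) != self.profile.g:
                raise ValueError(
                    f"node {u} has per-type degrees {tuple(counts)}, "
                    f"expected {self.profile.g}"
                )


def generate_typed_graph(
    N: int,
    profile: DegreeProfile,
    seed: int,
    zeta: Sequence[float] | None = None,
    max_retries: int = 1000,
) -> EdgeTypedGraph:
    """Random edge-typed regular graph realizing ``profile`` at every node.

    Each type-i layer is an independent random g_i-regular simple graph on
    the same vertex set (configuration model with repair, via networkx);
    the overlay is rejected and resampled whenever two layers share an
    edge, so the union is simple.  Deterministic given ``seed``.
    """
    k, g = profile.k, profile.g
    if N <= k:
        raise ValueError(f"need N > k (got N={N}, k={k})")
    for i, gi in enumerate(g, start=1):
        if (N * gi) % 2:
            raise ValueError(
                f"infeasible parity: N*g_{i} = {N}*{gi} is odd, "
                "no g-regular layer exists"
            )
    if zeta is not None:
        zeta = tuple(float(z) for z in zeta)
        if len(zeta) != profile.n or any(z <= 0 for z in zeta):
            raise ValueError("zeta must give one positive weight per type")

    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        layers = [
            nx.random_regular_graph(gi, N, seed=int(rng.integers(2**31)))
            for gi in g
        ]
        used: set[tuple[int, int]] = set()
        collision = False
        for layer in layers:
            for u, v in layer.edges():
                e = (min(u, v), max(u, v))
                if e in used:
                    collision = True
                    break
                used.add(e)
            if collision:
                break
        if collision:
            continue
        adjacency: list[list[tuple[int, int]]] = [[] for _ in range(N)]
        for t, layer in enumerate(layers, start=1):
            for u, v in layer.edges():
                adjacency[u].append((v, t))
                adjacency[v].append((u, t))
        return EdgeTypedGraph(N=N, profile=profile, adjacency=adjacency, zeta=zeta)
    raise GraphGenerationError(
        f"no collision-free overlay found in {max_retries} attempts "
        f"for N={N}, g={g}"
    )


def neighborhood_config(
    graph: EdgeTypedGraph, node: int, strategies: Sequence[int]
) -> tuple[int, ...]:
    """Neighborhood state (s_1..s_n): A-neighbors of ``node`` per edge type.

    ``strategies[v]`` is truthy for strategy A.
    """
    s = [0] * graph.profile.n
    for v, t in graph.neighbors(node):
        if strategies[v]:
            s[t - 1] += 1
    return tuple(s)


# ---------------------------------------------------------------------------
# Typed edge-list files: header "#edgegames v1 N=<N> k=<k> g=<g1,...,gn>",
# then one undirected edge per line "u<TAB>v<TAB>type[<TAB>weight]" with
# u < v and each edge listed exactly once (the reader symmetrizes).
# ---------------------------------------------------------------------------


def write_graph(graph: EdgeTypedGraph, path: str | Path) -> None:
    path = Path(path)
    prof = graph.profile
    lines = [
        f"#edgegames v1 N={graph.N} k={prof.k} g={','.join(map(str, prof.g))}"
    ]
    for u, v, t in graph.edges():
        if graph.zeta is not None:
            lines.append(f"{u}\t{v}\t{t}\t{graph.zeta[t - 1]:g}")
        else:
            lines.append(f"{u}\t{v}\t{t}")
    path.write_text("\n".join(lines) + "\n")


def read_graph(path: str | Path) -> EdgeTypedGraph:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#edgegames v1"):
        raise ValueError(f"{path}: missing '#edgegames v1' header")
    header = dict(
        item.split("=", 1) for item in lines[0].split()[2:] if "=" in item
    )
    try:
        N = int(header["N"])
        profile = DegreeProfile([int(x) for x in header["g"].split(",")])
        if int(header["k"]) != profile.k:
            raise ValueError("header k inconsistent with g")
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{path}: malformed header: {exc}") from exc

    adjacency: list[list[tuple[int, int]]] = [[] for _ in range(N)]
    weights: dict[int, float] = {}
    seen: set[tuple[int, int]] = set()
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) not in (3, 4):
            raise ValueError(f"{path}:{ln}: expected 3 or 4 columns, got {len(cols)}")
        try:
            u, v, t = int(cols[0]), int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-integer field") from exc
        if not (0 <= u < N and 0 <= v < N):
            raise ValueError(f"{path}:{ln}: node id out of range 0..{N - 1}")
        if u >= v:
            raise ValueError(f"{path}:{ln}: edges must be listed with u < v")
        if not 1 <= t <= profile.n:
            raise ValueError(f"{path}:{ln}: unknown type index {t}")
        if (u, v) in seen:
            raise ValueError(f"{path}:{ln}: duplicate edge {u}-{v}")
        seen.add((u, v))
        if len(cols) == 4:
            w = float(cols[3])
            if weights.setdefault(t, w) != w:
                raise ValueError(
                    f"{path}:{ln}: weight {w} disagrees with earlier weight "
                    f"{weights[t]} for type {t}"
                )
        adjacency[u].append((v, t))
        adjacency[v].append((u, t))

    zeta = None
    if weights:
        if set(weights) != set(range(1, profile.n + 1)):
            raise ValueError(f"{path}: weights given for only some types")
        zeta = tuple(weights[t] for t in range(1, profile.n + 1))
    graph = EdgeTypedGraph(N=N, profile=profile, adjacency=adjacency, zeta=zeta)
    graph.validate()
    return graph
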