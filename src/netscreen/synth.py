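"""Synthetic graphs, planted modules, and input perturbation.

Everything here is a pure function of its seed, so the full pipeline is
testable without downloads; :func:`perturb_node_set` is also the knob for
robustness analyses of real annotation sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ParameterError, ValidationError
from .network import Interactome, NodeSet

__all__ = ["FixtureSpec", "generate_graph", "plant_connected_module", "perturb_node_set"]


@dataclass(frozen=True)
class FixtureSpec:
    kind: str = "erdos_renyi"
    n: int = 100
    p: float | None = None   # edge probability (erdos_renyi)
    m: int | None = None     # edges per new node (barabasi_albert)
    weighted: bool = False
    weight_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("erdos_renyi", "barabasi_albert"):
            raise ParameterError(f"unknown graph kind {self.kind!r}")
        if self.n < 1:
            raise ParameterError("n must be >= 1")
        if self.kind == "erdos_renyi":
            if self.p is None or not 0.0 <= self.p <= 1.0:
                raise ParameterError("erdos_renyi requires p in [0, 1]")
        else:
            if self.m is None or not 1 <= self.m < self.n:
                raise ParameterError("barabasi_albert requires 1 <= m < n")
        lo, hi = self.weight_range
        if self.weighted and not (0 < lo <= hi and math.isfinite(hi)):
            raise ParameterError(f"invalid weight range {self.weight_range}")


def _node_id(i: int) -> str:
    return f"n{i:05d}"


def generate_graph(spec: FixtureSpec) -> Interactome:
    """Seeded ER or BA graph with zero-padded string node ids; optional
    uniform edge weights in ``weight_range``."""
    if spec.kind == "erdos_renyi":
        raw = nx.gnp_random_graph(spec.n, spec.p, seed=spec.seed)
    else:
        raw = nx.barabasi_albert_graph(spec.n, spec.m, seed=spec.seed)
    g = nx.Graph()
    g.add_nodes_from(_node_id(i) for i in raw.nodes())
    edges = sorted(tuple(sorted(e)) for e in raw.edges())
    if spec.weighted:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, len(edges)]))
        lo, hi = spec.weight_range
        weights = rng.uniform(lo, hi, size=len(edges))
    else:
        weights = np.ones(len(edges))
    for (u, v), w in zip(edges, weights):
        g.add_edge(_node_id(u), _node_id(v), weight=float(w))
    return Interactome(g, name=f"{spec.kind}(n={spec.n}, seed={spec.seed})")


def plant_connected_module(g: Interactome, k: int, seed: int = 0, name: str = "module") -> NodeSet:
    """Grow a k-node connected induced subgraph by seeded breadth-first
    expansion from a random start with uniformly shuffled frontiers."""
    comps = sorted(nx.connected_components(g.graph), key=lambda c: (-len(c), min(c)))
    if not comps or k < 1 or k > len(comps[0]):
        raise ParameterError(
            f"cannot plant a connected module of size {k} "
            f"(largest component has {len(comps[0]) if comps else 0} nodes)"
        )
    component = sorted(comps[0])
    rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
    start = component[int(rng.integers(len(component)))]
    chosen = {start}
    frontier = sorted(g.graph.neighbors(start))
    while len(chosen) < k:
        rng.shuffle(frontier)
        nxt = frontier.pop()
        if nxt in chosen:
            continue
        chosen.add(nxt)
        frontier.extend(n for n in sorted(g.graph.neighbors(nxt)) if n not in chosen)
    return NodeSet(name=name, members=frozenset(chosen))


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def perturb_node_set(
    s: NodeSet,
    remove_frac: float,
    add_frac: float,
    pool,
    rng: np.random.Generator,
) -> NodeSet:
    """Remove ``round(remove_frac * |s|)`` members uniformly, then add
    ``round(add_frac * |s|)`` nodes drawn uniformly from ``pool \\ s``.

    Rounding is half-away-from-zero.  Removing every member leaves nothing to
    analyze and raises the same validation error an empty set raises anywhere
    else in the pipeline.
    """
    if not 0.0 <= remove_frac <= 1.0 or not 0.0 <= add_frac <= 1.0:
        raise ParameterError("perturbation fractions must lie in [0, 1]")
    n_remove = _round_half_away(remove_frac * len(s))
    n_add = _round_half_away(add_frac * len(s))
    members = s.sorted_members()
    keep_idx = rng.choice(len(members), size=len(members) - n_remove, replace=False)
    kept = {members[i] for i in keep_idx}
    addable = sorted(set(pool) - s.members)
    if n_add > len(addable):
        raise ValidationError(
            f"pool too small: need {n_add} additions, only {len(addable)} candidates"
        )
    add_idx = rng.choice(len(addable), size=n_add, replace=False) if n_add else []
    kept.update(addable[i] for i in add_idx)
    return NodeSet(name=s.name, members=frozenset(kept))
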