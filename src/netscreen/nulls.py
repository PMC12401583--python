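"""Degree/strength-aware random node-set generation, the benchmark for all
Z-scores and empirical p-values.

Randomization schemes
---------------------
degree_match
    Each member is replaced by a uniform draw among nodes of identical degree.
log_binning / strength_binning
    Nodes are binned by degree (or strength) via greedy accumulation: sorted
    distinct property values are merged into one bin until it holds at least
    ``min_bin_size`` nodes; a trailing undersized bin merges backward.  Each
    member is replaced by a uniform draw from its bin.
uniform
    Uniform over all nodes.
custom
    A user-provided ``sampler(graph, size, rng) -> iterable of node ids``.

Within one sample all draws are without replacement (pools for distinct
degrees/bins are disjoint, so the sampled set always has exactly ``|s|``
distinct members) and the original node remains an admissible draw.

Reproducibility: every (iteration, set-name) draw derives its RNG stream from
``(master seed, iteration index, hash(set name))``, so results do not depend
on scheduling or on which other sets are screened alongside.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ParameterError, SamplingError, ValidationError
from .network import Interactome, NodeSet

__all__ = [
    "NullModelSpec",
    "Bin",
    "BinPartition",
    "build_bins",
    "sample_null_set",
    "null_distribution",
    "rng_for",
]


@dataclass(frozen=True)
class NullModelSpec:
    kind: str = "degree_match"
    min_bin_size: int = 100
    custom_sampler: Callable[[Interactome, int, np.random.Generator], Sequence[str]] | None = None

    KINDS = ("degree_match", "log_binning", "strength_binning", "uniform", "custom")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ParameterError(f"unknown null model kind {self.kind!r}")
        if self.min_bin_size < 1:
            raise ParameterError(f"min_bin_size must be >= 1, got {self.min_bin_size}")
        if self.kind == "custom" and self.custom_sampler is None:
            raise ParameterError("custom null model requires custom_sampler")


@dataclass(frozen=True)
class Bin:
    lower: float
    upper: float
    members: tuple[str, ...]


@dataclass(frozen=True)
class BinPartition:
    property_name: str
    bins: tuple[Bin, ...]

    def bin_of(self, value: float) -> int:
        for i, b in enumerate(self.bins):
            if b.lower <= value <= b.upper:
                return i
        raise KeyError(value)


def _property_values(g: Interactome, prop: str) -> dict[str, float]:
    if prop == "degree":
        return {n: float(g.degree(n)) for n in g.graph.nodes()}
    if prop == "strength":
        return {n: g.strength(n) for n in g.graph.nodes()}
    raise ParameterError(f"unknown node property {prop!r}")


def build_bins(g: Interactome, property: str = "degree", min_bin_size: int = 100) -> BinPartition:
    """Greedy accumulation of sorted distinct property values into bins of at
    least ``min_bin_size`` nodes; a trailing undersized bin merges backward."""
    values = _property_values(g, property)
    if min_bin_size > len(values):
        raise ParameterError(
            f"min_bin_size={min_bin_size} exceeds node count {len(values)}"
        )
    by_value: dict[float, list[str]] = {}
    for node, val in values.items():
        by_value.setdefault(val, []).append(node)
    bins: list[Bin] = []
    cur_members: list[str] = []
    cur_lower: float | None = None
    cur_upper = 0.0
    for val in sorted(by_value):
        if cur_lower is None:
            cur_lower = val
        cur_upper = val
        cur_members.extend(sorted(by_value[val]))
        if len(cur_members) >= min_bin_size:
            bins.append(Bin(cur_lower, cur_upper, tuple(cur_members)))
            cur_members, cur_lower = [], None
    if cur_members:
        if bins:
            last = bins.pop()
            bins.append(Bin(last.lower, cur_upper, last.members + tuple(cur_members)))
        else:
            bins.append(Bin(cur_lower, cur_upper, tuple(cur_members)))
    return BinPartition(property_name=property, bins=tuple(bins))


#: pool key: (property name, lower bound, upper bound) — sorts numerically so
#: degree matching and single-size bins consume the RNG in the same order.
PoolKey = tuple[str, float, float]


def _pools(g: Interactome, spec: NullModelSpec) -> tuple[dict[str, PoolKey], dict[PoolKey, tuple[str, ...]]]:
    """Map node -> pool key and pool key -> candidate tuple for one scheme."""
    if spec.kind == "uniform":
        nodes = tuple(g.sorted_nodes())
        key = ("node", -np.inf, np.inf)
        return {n: key for n in nodes}, {key: nodes}
    if spec.kind == "degree_match":
        values = _property_values(g, "degree")
        assign = {n: ("degree", values[n], values[n]) for n in values}
    else:
        prop = "degree" if spec.kind == "log_binning" else "strength"
        part = build_bins(g, prop, spec.min_bin_size)
        values = _property_values(g, prop)
        keys = [(prop, b.lower, b.upper) for b in part.bins]
        assign = {n: keys[part.bin_of(values[n])] for n in values}
    candidates: dict[PoolKey, list[str]] = {}
    for node in sorted(assign):
        candidates.setdefault(assign[node], []).append(node)
    return assign, {k: tuple(v) for k, v in candidates.items()}


def sample_null_set(
    g: Interactome,
    s: NodeSet,
    spec: NullModelSpec,
    rng: np.random.Generator,
    _pools_cache: tuple[dict, dict] | None = None,
) -> NodeSet:
    """Draw a random set of exactly ``|s|`` distinct nodes matched to ``s``
    under the chosen scheme."""
    if len(s) > g.number_of_nodes():
        raise SamplingError(f"set {s.name!r} larger than the network")
    if spec.kind == "custom":
        drawn = list(spec.custom_sampler(g, len(s), rng))
        members = frozenset(drawn)
        if len(members) != len(s) or not members <= g.nodes:
            raise ValidationError(
                f"custom sampler returned an invalid set for {s.name!r}"
            )
        return NodeSet(name=s.name, members=members)
    assign, candidates = _pools_cache if _pools_cache is not None else _pools(g, spec)
    needed: dict[PoolKey, int] = {}
    for node in s.sorted_members():
        try:
            key = assign[node]
        except KeyError:
            raise SamplingError(f"node {node!r} of set {s.name!r} not in the network") from None
        needed[key] = needed.get(key, 0) + 1
    drawn: list[str] = []
    for key in sorted(needed):
        pool = candidates[key]
        count = needed[key]
        if count > len(pool):
            prop, lo, hi = key
            label = f"{prop} {lo:g}" if lo == hi else f"{prop} bin [{lo:g}, {hi:g}]"
            raise SamplingError(
                f"pool exhausted for {label} ({len(pool)} candidate(s), {count} needed) "
                f"while sampling set {s.name!r}"
            )
        picks = rng.choice(len(pool), size=count, replace=False)
        drawn.extend(pool[i] for i in picks)
    return NodeSet(name=s.name, members=frozenset(drawn))


def _name_key(name: str) -> int:
    return int.from_bytes(hashlib.blake2b(name.encode(), digest_size=8).digest(), "big")


def rng_for(seed: int, iteration: int, set_name: str) -> np.random.Generator:
    """Per-(iteration, set) stream, independent of scheduling order."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(iteration), _name_key(set_name)])
    )


def null_distribution(
    score_fn: Callable[..., float],
    g: Interactome,
    sets: Sequence[NodeSet],
    spec: NullModelSpec,
    n_iter: int,
    seed: int = 0,
    resample: Sequence[bool] | None = None,
) -> list[float]:
    """``n_iter`` scores of independently resampled set tuples.

    By default every set is resampled each iteration; pass ``resample`` flags
    to freeze individual sets.  Fully reproducible from ``seed``.
    """
    if n_iter < 1:
        raise ParameterError(f"n_iter must be >= 1, got {n_iter}")
    if resample is None:
        resample = [True] * len(sets)
    pools = _pools(g, spec) if spec.kind != "custom" else None
    try:
        samples = []
        for i in range(n_iter):
            drawn = [
                sample_null_set(g, s, spec, rng_for(seed, i, s.name), _pools_cache=pools)
                if flag
                else s
                for s, flag in zip(sets, resample)
            ]
            samples.append(float(score_fn(*drawn)))
    except SamplingError as exc:
        raise SamplingError(f"null iteration {i}: {exc}") from exc
    return samples
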