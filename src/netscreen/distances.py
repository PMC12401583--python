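"""All-pairs graph distance matrices: computation, disk cache, plug-ins.

Built-in metrics
----------------
shortest_path
    Hop counts (unweighted) or minimal weight sums (weighted); unreachable
    pairs are ``+inf``.
random_walk
    Random walk with restart.  With row-stochastic transition matrix
    ``W[i, j] = w_ij / strength(i)`` and restart probability ``r``, the
    visiting distribution seeded at ``p`` is
    ``pi(p) = r * (I - (1 - r) * W.T)^-1 * e_p`` and the distance is
    ``d(p, q) = -ln(pi(p)_q)`` with the diagonal forced to 0.  Asymmetric.
biased_random_walk
    Same machinery with target-degree-biased transitions
    ``W[i, j] ∝ w_ij * degree(j)**beta``; ``beta = 0`` reduces exactly to
    the unbiased walk.
communicability
    ``G = expm(A)`` on the (weighted) adjacency matrix and the Euclidean
    embedding distance ``xi(p, q) = sqrt(G_pp + G_qq - 2 G_pq)``.  Note that
    large edge weights can overflow ``expm``; rescale weights if needed.

The cache file layout is versioned and documented in :func:`save_distance_matrix`.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import networkx as nx
import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .errors import FormatError, ParameterError, ValidationError
from .network import Interactome

__all__ = [
    "DistanceMatrix",
    "MetricSpec",
    "all_pairs_shortest_path",
    "random_walk_distance",
    "biased_random_walk_distance",
    "communicability_distance",
    "compute_distance_matrix",
    "save_distance_matrix",
    "load_distance_matrix",
    "matrix_computation_count",
]

#: Counts full-matrix computations; screening must not bump it (tests assert).
_MATRIX_COMPUTATIONS = 0


def matrix_computation_count() -> int:
    return _MATRIX_COMPUTATIONS


def _bump() -> None:
    global _MATRIX_COMPUTATIONS
    _MATRIX_COMPUTATIONS += 1


@dataclass
class DistanceMatrix:
    """All-pairs node-node distances under one metric.

    ``values[i, j]`` is the distance from ``ids[i]`` to ``ids[j]``; the
    diagonal is identically 0, entries are nonnegative and ``+inf`` marks
    unreachable pairs.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    metric_name: str
    symmetric: bool
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.index = {node: i for i, node in enumerate(self.ids)}

    def __getitem__(self, pair: tuple[str, str]) -> float:
        u, v = pair
        return float(self.values[self.index[u], self.index[v]])

    def rows(self, nodes) -> np.ndarray:
        return np.fromiter((self.index[n] for n in sorted(nodes)), dtype=np.intp)

    def validate(self, g: Interactome | None = None) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix is not square over its id table")
        if np.isnan(self.values).any():
            raise ValidationError("distance matrix contains NaN")
        if (self.values[np.isfinite(self.values)] < 0).any():
            raise ValidationError("distance matrix contains negative entries")
        if np.any(np.diagonal(self.values) != 0):
            raise ValidationError("distance matrix diagonal must be identically 0")
        if self.symmetric and not np.array_equal(self.values, self.values.T):
            raise ValidationError("matrix flagged symmetric but values != values.T")
        if g is not None and set(self.ids) != set(g.nodes):
            raise ValidationError("distance matrix ids do not match network nodes")


@dataclass(frozen=True)
class MetricSpec:
    """Which metric to run and its parameters."""

    kind: str = "shortest_path"
    r: float = 0.15
    beta: float = 1.0
    custom_fn: Callable[[Interactome], DistanceMatrix] | None = None

    KINDS = ("shortest_path", "random_walk", "biased_random_walk", "communicability", "custom")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ParameterError(f"unknown metric kind {self.kind!r}")
        if self.kind in ("random_walk", "biased_random_walk") and not 0 < self.r < 1:
            raise ParameterError(f"restart probability r={self.r} outside (0, 1)")
        if self.kind == "custom" and self.custom_fn is None:
            raise ParameterError("custom metric requires custom_fn")


def _adjacency(g: Interactome, ids: list[str]) -> sp.csr_array:
    return nx.to_scipy_sparse_array(g.graph, nodelist=ids, weight="weight", format="csr")


def all_pairs_shortest_path(g: Interactome, workers: int = 1) -> DistanceMatrix:
    """Hop counts on unweighted graphs, Dijkstra weight sums otherwise.

    ``workers`` only chunks the source nodes; the result is independent of it.
    """
    _bump()
    ids = g.sorted_nodes()
    adj = _adjacency(g, ids)
    unweighted = not g.is_weighted()
    n = len(ids)
    if workers <= 1 or n == 0:
        vals = _csgraph_shortest_path(adj, method="D", directed=False, unweighted=unweighted)
    else:
        chunks = np.array_split(np.arange(n), min(workers, n))
        vals = np.vstack(
            [
                _csgraph_shortest_path(
                    adj, method="D", directed=False, unweighted=unweighted, indices=chunk
                )
                for chunk in chunks
                if len(chunk)
            ]
        )
    vals = np.asarray(vals, dtype=np.float64)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(tuple(ids), vals, "shortest_path", symmetric=True)


def _walk_visiting(g: Interactome, r: float, beta: float) -> tuple[list[str], np.ndarray]:
    """Rows of the returned matrix are visiting distributions pi(p); entries
    for nodes outside p's component are 0."""
    ids = g.sorted_nodes()
    index = {node: i for i, node in enumerate(ids)}
    n = len(ids)
    visit = np.zeros((n, n))
    for comp in nx.connected_components(g.graph):
        comp_ids = sorted(comp)
        idx = np.fromiter((index[c] for c in comp_ids), dtype=np.intp)
        m = len(comp_ids)
        if m == 1:
            visit[idx[0], idx[0]] = 1.0
            continue
        A = nx.to_numpy_array(g.graph, nodelist=comp_ids, weight="weight")
        k = A.astype(bool).sum(axis=1).astype(np.float64)
        M = A * k[np.newaxis, :] ** beta
        W = M / M.sum(axis=1, keepdims=True)
        # columns of r * (I - (1-r) W^T)^-1 are pi(p); transpose to rows
        P = r * np.linalg.solve(np.eye(m) - (1.0 - r) * W.T, np.eye(m))
        visit[np.ix_(idx, idx)] = P.T
    return ids, visit


def _walk_distance(g: Interactome, r: float, beta: float, name: str, params: dict) -> DistanceMatrix:
    if not 0 < r < 1:
        raise ParameterError(f"restart probability r={r} outside (0, 1)")
    _bump()
    ids, visit = _walk_visiting(g, r, beta)
    with np.errstate(divide="ignore"):
        vals = -np.log(visit)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(tuple(ids), vals, name, symmetric=False, params=params)


def random_walk_distance(g: Interactome, r: float = 0.15) -> DistanceMatrix:
    """Random-walk-with-restart distance; cross-component pairs are ``+inf``."""
    return _walk_distance(g, r, 0.0, "random_walk", {"r": r})


def biased_random_walk_distance(g: Interactome, r: float = 0.15, beta: float = 1.0) -> DistanceMatrix:
    """Degree-biased walk-with-restart distance; ``beta=0`` is the unbiased walk."""
    return _walk_distance(g, r, beta, "biased_random_walk", {"r": r, "beta": beta})


def communicability_distance(g: Interactome) -> DistanceMatrix:
    _bump()
    ids = g.sorted_nodes()
    A = nx.to_numpy_array(g.graph, nodelist=ids, weight="weight")
    G = scipy.linalg.expm(A)
    d = np.diagonal(G)
    sq = d[:, np.newaxis] + d[np.newaxis, :] - 2.0 * G
    vals = np.sqrt(np.maximum(sq, 0.0))
    vals = (vals + vals.T) / 2.0  # enforce exact symmetry against fp noise
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(tuple(ids), vals, "communicability", symmetric=True)


def compute_distance_matrix(g: Interactome, spec: MetricSpec, workers: int = 1) -> DistanceMatrix:
    """Dispatch to a built-in metric or a user-supplied plug-in.

    Plug-in results are validated against the :class:`DistanceMatrix`
    invariants before being accepted.
    """
    if spec.kind == "shortest_path":
        return all_pairs_shortest_path(g, workers=workers)
    if spec.kind == "random_walk":
        return random_walk_distance(g, r=spec.r)
    if spec.kind == "biased_random_walk":
        return biased_random_walk_distance(g, r=spec.r, beta=spec.beta)
    if spec.kind == "communicability":
        return communicability_distance(g)
    assert spec.kind == "custom"
    result = spec.custom_fn(g)
    if not isinstance(result, DistanceMatrix):
        raise ValidationError("custom metric must return a DistanceMatrix")
    result.validate(g)
    return result


_MAGIC = b"NMDM1"


def save_distance_matrix(d: DistanceMatrix, path: str | Path) -> None:
    """Write the versioned binary cache.

    Layout: magic ``NMDM1``; u32-length-prefixed UTF-8 metric name;
    u32-length-prefixed JSON params; symmetric flag byte; u64 node count;
    per node a u32-length-prefixed UTF-8 id; then row-major little-endian
    float64 values.  Round trip is bit-exact.
    """
    path = Path(path)
    params_blob = json.dumps(d.params, sort_keys=True).encode()
    name_blob = d.metric_name.encode()
    with path.open("wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", len(name_blob)))
        fh.write(name_blob)
        fh.write(struct.pack("<I", len(params_blob)))
        fh.write(params_blob)
        fh.write(struct.pack("<B", 1 if d.symmetric else 0))
        fh.write(struct.pack("<Q", len(d.ids)))
        for node in d.ids:
            blob = node.encode()
            fh.write(struct.pack("<I", len(blob)))
            fh.write(blob)
        fh.write(np.ascontiguousarray(d.values, dtype="<f8").tobytes())


def _read_exact(fh, n: int, what: str) -> bytes:
    blob = fh.read(n)
    if len(blob) != n:
        raise FormatError(f"truncated distance cache while reading {what}")
    return blob


def load_distance_matrix(path: str | Path) -> DistanceMatrix:
    path = Path(path)
    with path.open("rb") as fh:
        if _read_exact(fh, len(_MAGIC), "magic") != _MAGIC:
            raise FormatError(f"{path}: not a distance cache (bad magic)")
        (name_len,) = struct.unpack("<I", _read_exact(fh, 4, "metric name length"))
        metric_name = _read_exact(fh, name_len, "metric name").decode()
        (params_len,) = struct.unpack("<I", _read_exact(fh, 4, "params length"))
        params = json.loads(_read_exact(fh, params_len, "params"))
        (flag,) = struct.unpack("<B", _read_exact(fh, 1, "symmetric flag"))
        (n,) = struct.unpack("<Q", _read_exact(fh, 8, "node count"))
        ids = []
        for i in range(n):
            (id_len,) = struct.unpack("<I", _read_exact(fh, 4, f"id length {i}"))
            ids.append(_read_exact(fh, id_len, f"id {i}").decode())
        blob = _read_exact(fh, 8 * n * n, "values")
        if fh.read(1):
            raise FormatError(f"{path}: trailing bytes after matrix values")
    values = np.frombuffer(blob, dtype="<f8").reshape(n, n).copy()
    return DistanceMatrix(tuple(ids), values, metric_name, symmetric=bool(flag), params=params)
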