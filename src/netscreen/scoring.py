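"""Score layer: AMSPL/proximity, separation, LCC size — each raw and with a
Z-score and empirical p-value against a null model.

Orientation convention
----------------------
The asymmetric proximity averages over the FIRST argument (the source set,
conventionally the drug targets): ``amspl(A, B) = mean_a min_b D[a, b]``.

Statistics conventions
----------------------
* ``sigma`` is the population (n-denominator) standard deviation of the null.
* Empirical p-values use the add-one convention
  ``p = (1 + #{as-or-more-extreme}) / (n + 1)`` and never return 0.
* A null with zero spread sets the ``degenerate`` flag; ``z`` is absent but
  the p-value is still reported.
* Members of the source set with no finite distance to the other set are
  excluded from the average with a logged warning; losing every member is an
  error.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np

from .distances import DistanceMatrix
from .errors import ParameterError, ValidationError
from .network import Interactome, NodeSet, induced_subgraph
from .nulls import NullModelSpec, null_distribution

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreResult",
    "SeparationValue",
    "amspl",
    "symmetric_amspl",
    "internal_distance",
    "separation",
    "z_and_p",
    "proximity",
    "separation_significance",
    "lcc_significance",
    "module_lcc_size",
]

Side = Literal["lower", "upper", "two_sided"]


@dataclass
class ScoreResult:
    """A raw score plus its null-distribution summary."""

    score_kind: str
    raw: float
    null_samples: list[float]
    mu: float
    sigma: float
    z: float | None
    p_empirical: float
    side: Side
    n_iter: int
    seed: int
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "score_kind": self.score_kind,
            "raw": self.raw,
            "mu": self.mu,
            "sigma": self.sigma,
            "z": self.z,
            "p_empirical": self.p_empirical,
            "side": self.side,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "degenerate": self.degenerate,
            "null_samples": list(self.null_samples),
            **self.extra,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class SeparationValue:
    """s_ab = d_ab - (d_aa + d_bb) / 2, by construction."""

    s_ab: float
    d_ab: float
    d_aa: float
    d_bb: float


def _indices(D: DistanceMatrix, s: NodeSet) -> np.ndarray:
    try:
        return np.fromiter((D.index[n] for n in s.sorted_members()), dtype=np.intp)
    except KeyError as exc:
        raise ValidationError(
            f"node {exc.args[0]!r} of set {s.name!r} missing from the distance matrix"
        ) from None


def _finite_mean(mins: np.ndarray, set_name: str, other_name: str) -> float:
    finite = np.isfinite(mins)
    n_bad = int((~finite).sum())
    if n_bad:
        logger.warning(
            "%d member(s) of %r unreachable from %r excluded from the average",
            n_bad, set_name, other_name,
        )
    if not finite.any():
        raise ValidationError(
            f"no member of {set_name!r} has a finite distance to {other_name!r}"
        )
    return float(mins[finite].mean())


def amspl(A: NodeSet, B: NodeSet, D: DistanceMatrix) -> float:
    """Average minimum distance from each member of A to the closest member
    of B (rows = A, columns = B; asymmetric in general)."""
    rows, cols = _indices(D, A), _indices(D, B)
    mins = D.values[np.ix_(rows, cols)].min(axis=1)
    return _finite_mean(mins, A.name, B.name)


def symmetric_amspl(A: NodeSet, B: NodeSet, D: DistanceMatrix) -> float:
    """(sum_a min_b D[a,b] + sum_b min_a D[b,a]) / (|A| + |B|)."""
    rows, cols = _indices(D, A), _indices(D, B)
    sub = D.values[np.ix_(rows, cols)]
    mins_a = sub.min(axis=1)
    mins_b = D.values[np.ix_(cols, rows)].min(axis=1)
    finite_a, finite_b = np.isfinite(mins_a), np.isfinite(mins_b)
    n_bad = int((~finite_a).sum() + (~finite_b).sum())
    if n_bad:
        logger.warning(
            "%d member(s) with no finite cross-distance excluded from "
            "symmetric AMSPL of %r vs %r", n_bad, A.name, B.name,
        )
    denom = int(finite_a.sum() + finite_b.sum())
    if denom == 0:
        raise ValidationError(
            f"no finite distances between {A.name!r} and {B.name!r}"
        )
    return float((mins_a[finite_a].sum() + mins_b[finite_b].sum()) / denom)


def internal_distance(A: NodeSet, D: DistanceMatrix) -> float:
    """Mean distance from each member to its nearest *other* member;
    0 for singletons by convention."""
    if len(A) == 1:
        return 0.0
    rows = _indices(D, A)
    sub = D.values[np.ix_(rows, rows)].copy()
    np.fill_diagonal(sub, np.inf)
    return _finite_mean(sub.min(axis=1), A.name, A.name)


def separation(A: NodeSet, B: NodeSet, D: DistanceMatrix) -> SeparationValue:
    d_ab = symmetric_amspl(A, B, D)
    d_aa = internal_distance(A, D)
    d_bb = internal_distance(B, D)
    return SeparationValue(s_ab=d_ab - (d_aa + d_bb) / 2.0, d_ab=d_ab, d_aa=d_aa, d_bb=d_bb)


def z_and_p(raw: float, null_samples: list[float], side: Side = "lower") -> tuple[float | None, float]:
    """Z-score (population sd) and add-one empirical p-value.

    lower: p of ``x <= raw``; upper: p of ``x >= raw``;
    two_sided: ``min(1, 2 * min(lower, upper))``.
    """
    if len(null_samples) < 2:
        raise ParameterError("need at least 2 null samples for z and p")
    if side not in ("lower", "upper", "two_sided"):
        raise ParameterError(f"unknown side {side!r}")
    x = np.asarray(null_samples, dtype=np.float64)
    mu = float(x.mean())
    sigma = float(x.std(ddof=0))
    n = len(x)
    p_lower = (1 + int((x <= raw).sum())) / (n + 1)
    p_upper = (1 + int((x >= raw).sum())) / (n + 1)
    if side == "lower":
        p = p_lower
    elif side == "upper":
        p = p_upper
    else:
        p = min(1.0, 2.0 * min(p_lower, p_upper))
    z = (raw - mu) / sigma if sigma > 0 else None
    return z, float(p)


def _result(
    kind: str, raw: float, samples: list[float], side: Side, n_iter: int, seed: int, **extra
) -> ScoreResult:
    z, p = z_and_p(raw, samples, side)
    x = np.asarray(samples, dtype=np.float64)
    return ScoreResult(
        score_kind=kind,
        raw=float(raw),
        null_samples=[float(v) for v in samples],
        mu=float(x.mean()),
        sigma=float(x.std(ddof=0)),
        z=z,
        p_empirical=p,
        side=side,
        n_iter=n_iter,
        seed=seed,
        degenerate=z is None,
        extra=extra,
    )


def proximity(
    g: Interactome,
    A: NodeSet,
    B: NodeSet,
    D: DistanceMatrix,
    spec: NullModelSpec,
    n_iter: int = 1000,
    symmetric: bool = False,
    seed: int = 0,
    side: Side = "lower",
    resample: tuple[bool, bool] = (True, True),
) -> ScoreResult:
    """Proximity of source set A to target set B versus the null ensemble.

    A negative z means A is closer to B than matched random sets.  Both sets
    are resampled each iteration unless frozen via ``resample``.
    """
    if n_iter < 2:
        raise ParameterError("proximity requires n_iter >= 2")
    score = symmetric_amspl if symmetric else amspl
    raw = score(A, B, D)
    samples = null_distribution(
        lambda a, b: score(a, b, D), g, [A, B], spec, n_iter, seed=seed, resample=resample
    )
    kind = "proximity_symmetric" if symmetric else "proximity"
    return _result(kind, raw, samples, side, n_iter, seed, source=A.name, target=B.name)


def separation_significance(
    g: Interactome,
    A: NodeSet,
    B: NodeSet,
    D: DistanceMatrix,
    spec: NullModelSpec,
    n_iter: int = 1000,
    seed: int = 0,
    side: Side = "lower",
    resample: tuple[bool, bool] = (True, True),
) -> ScoreResult:
    """Topological separation s_AB with significance against the null."""
    if n_iter < 2:
        raise ParameterError("separation significance requires n_iter >= 2")
    raw = separation(A, B, D).s_ab
    samples = null_distribution(
        lambda a, b: separation(a, b, D).s_ab, g, [A, B], spec, n_iter, seed=seed, resample=resample
    )
    return _result("separation", raw, samples, side, n_iter, seed, source=A.name, target=B.name)


def module_lcc_size(g: Interactome, A: NodeSet) -> int:
    """Size of the largest connected component of the subgraph induced by A."""
    sub = induced_subgraph(g, A).graph
    return max(len(c) for c in nx.connected_components(sub))


def lcc_significance(
    g: Interactome,
    A: NodeSet,
    spec: NullModelSpec,
    n_iter: int = 1000,
    seed: int = 0,
    side: Side = "upper",
) -> ScoreResult:
    """Significance of the module's LCC size versus matched random sets."""
    if n_iter < 2:
        raise ParameterError("lcc significance requires n_iter >= 2")
    raw = module_lcc_size(g, A)
    samples = null_distribution(
        lambda a: float(module_lcc_size(g, a)), g, [A], spec, n_iter, seed=seed
    )
    return _result("lcc", float(raw), samples, side, n_iter, seed, set=A.name)
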