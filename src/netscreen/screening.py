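"""All-pairs screening of source sets against target sets on one precomputed
distance matrix, deterministic under parallelism.

Each (source, target) pair is scored exactly as the corresponding single-pair
operation, with an RNG stream keyed by ``(master seed, source name, target
name)`` — adding or removing a set never changes another pair's result, and
the table is identical for any worker count.  Per-pair failures are recorded
in the row (``degenerate`` flag, NaN statistics) instead of aborting the
screen.
"""

from __future__ import annotations

import hashlib
import logging
import math
from multiprocessing import get_context
from pathlib import Path
from typing import Mapping

import pandas as pd

from .distances import DistanceMatrix
from .errors import NetscreenError, ParameterError
from .network import Interactome, NodeSet
from .nulls import NullModelSpec
from .scoring import proximity, separation, separation_significance

logger = logging.getLogger(__name__)

__all__ = ["SCORE_KINDS", "COLUMNS", "screen", "write_table", "read_table"]

SCORE_KINDS = ("proximity", "proximity_symmetric", "separation", "separation_z")

COLUMNS = [
    "source", "target", "score_kind",
    "raw", "mu", "sigma", "z", "p_empirical", "n_iter", "degenerate",
]


def pair_seed(master_seed: int, source_name: str, target_name: str) -> int:
    """Stable per-pair seed keyed by names, not enumeration order."""
    blob = f"{master_seed}\x00{source_name}\x00{target_name}".encode()
    return int.from_bytes(hashlib.blake2b(blob, digest_size=8).digest(), "big")


def _score_pair(
    source: NodeSet,
    target: NodeSet,
    g: Interactome,
    D: DistanceMatrix,
    score_kind: str,
    spec: NullModelSpec,
    n_iter: int,
    master_seed: int,
) -> dict:
    row = {
        "source": source.name, "target": target.name, "score_kind": score_kind,
        "raw": math.nan, "mu": math.nan, "sigma": math.nan, "z": math.nan,
        "p_empirical": math.nan, "n_iter": n_iter, "degenerate": False,
    }
    seed = pair_seed(master_seed, source.name, target.name)
    try:
        if score_kind == "separation":
            row.update(raw=separation(source, target, D).s_ab, n_iter=0)
            return row
        if score_kind in ("proximity", "proximity_symmetric"):
            res = proximity(
                g, source, target, D, spec, n_iter=n_iter,
                symmetric=(score_kind == "proximity_symmetric"), seed=seed,
            )
        elif score_kind == "separation_z":
            res = separation_significance(g, source, target, D, spec, n_iter=n_iter, seed=seed)
        else:
            raise ParameterError(f"unknown score kind {score_kind!r}")
        row.update(
            raw=res.raw, mu=res.mu, sigma=res.sigma,
            z=math.nan if res.z is None else res.z,
            p_empirical=res.p_empirical, degenerate=res.degenerate,
        )
    except NetscreenError as exc:
        logger.warning("pair (%s, %s) failed: %s", source.name, target.name, exc)
        row["degenerate"] = True
    return row


_WORKER_STATE: dict = {}


def _pool_init(g, D, score_kind, spec, n_iter, master_seed) -> None:
    _WORKER_STATE.update(
        g=g, D=D, score_kind=score_kind, spec=spec, n_iter=n_iter, master_seed=master_seed
    )


def _pool_task(pair: tuple[NodeSet, NodeSet]) -> dict:
    s = _WORKER_STATE
    return _score_pair(
        pair[0], pair[1], s["g"], s["D"], s["score_kind"], s["spec"], s["n_iter"], s["master_seed"]
    )


def screen(
    sources: Mapping[str, NodeSet],
    targets: Mapping[str, NodeSet],
    g: Interactome,
    D: DistanceMatrix,
    score_kind: str = "proximity",
    spec: NullModelSpec | None = None,
    n_iter: int = 1000,
    workers: int = 1,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Score every (source, target) pair; rows ordered lexicographically.

    The distance matrix is computed once outside and only indexed here — the
    screen itself performs no graph traversal.
    """
    if score_kind not in SCORE_KINDS:
        raise ParameterError(f"unknown score kind {score_kind!r}")
    if spec is None:
        spec = NullModelSpec()
    pairs = [
        (sources[sn], targets[tn])
        for sn in sorted(sources)
        for tn in sorted(targets)
    ]
    if workers <= 1 or len(pairs) <= 1:
        rows = [
            _score_pair(a, b, g, D, score_kind, spec, n_iter, master_seed) for a, b in pairs
        ]
    else:
        ctx = get_context()
        with ctx.Pool(
            processes=min(workers, len(pairs)),
            initializer=_pool_init,
            initargs=(g, D, score_kind, spec, n_iter, master_seed),
        ) as pool:
            rows = pool.map(_pool_task, pairs)
    df = pd.DataFrame(rows, columns=COLUMNS)
    return df.sort_values(["source", "target"], kind="stable", ignore_index=True)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """RFC-4180 CSV with header; floats printed with 17 significant digits so
    they round-trip exactly."""
    table.to_csv(Path(path), index=False, float_format="%.17g", lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    # default C parser is fast but not correctly rounded; we promise exactness
    return pd.read_csv(Path(path), float_precision="round_trip")
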