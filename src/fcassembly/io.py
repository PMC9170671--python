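"""File formats: item pools, trait correlation matrices, questionnaires,
result bundles.  All files are plain CSV/JSON (UTF-8, comma-separated, dot
decimal); trait dimensions are 1-based throughout."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import Item, ItemPool, Block, Questionnaire

__all__ = [
    "read_item_pool",
    "write_item_pool",
    "read_phi",
    "write_phi",
    "read_questionnaire",
    "write_questionnaire",
    "write_results",
    "make_fixture_pool",
]

_POOL_COLUMNS = ("id", "dim", "a", "b")


def read_item_pool(path: str | Path) -> ItemPool:
    """Load an item pool from CSV with columns ``id,dim,a,b``.

    Extra columns (e.g. ``keyed``, ``sd_rating``) are tolerated and ignored;
    the intercept is always derived as c = -a*b.  Errors name the offending
    row (1-based data line, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in _POOL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    dup = df["id"][df["id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate item id {dup.iloc[0]} "
                         f"(line {dup.index[0] + 2})")
    D = int(df["dim"].max())
    items = []
    for line, row in df.iterrows():
        dim = int(row["dim"])
        if not 1 <= dim <= D:
            raise ValueError(f"{path}: dim {dim} out of range (line {line + 2})")
        items.append(Item(id=int(row["id"]), dim=dim,
                          a=float(row["a"]), b=float(row["b"])))
    return ItemPool(items, D=D)


def write_item_pool(pool: ItemPool, path: str | Path) -> None:
    df = pd.DataFrame({
        "id": pool.ids, "dim": pool.dims, "a": pool.a, "b": pool.b,
        "keyed": pool.keyed,
    })
    df.to_csv(path, index=False)


def read_phi(path: str | Path) -> np.ndarray:
    """Trait correlation matrix from a header-less CSV of D rows x D cols."""
    Phi = np.loadtxt(path, delimiter=",", ndmin=2)
    if Phi.shape[0] != Phi.shape[1]:
        raise ValueError(f"{path}: matrix is {Phi.shape}, expected square")
    if not np.allclose(Phi, Phi.T) or not np.allclose(np.diag(Phi), 1.0):
        raise ValueError(f"{path}: not a correlation matrix")
    return Phi


def write_phi(Phi: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(Phi, dtype=float), delimiter=",", fmt="%.10g")


def read_questionnaire(path: str | Path, pool: ItemPool) -> Questionnaire:
    """Questionnaire from CSV ``block,first_id,second_id``; within-block
    order is preserved (it fixes the response-coding sign convention)."""
    df = pd.read_csv(path)
    for col in ("block", "first_id", "second_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    blocks = []
    for _, row in df.sort_values("block").iterrows():
        first = pool.items[pool.index_of(int(row["first_id"]))]
        second = pool.items[pool.index_of(int(row["second_id"]))]
        blocks.append(Block.from_items(first, second, pool.D))
    return Questionnaire(blocks=blocks)


def write_questionnaire(q: Questionnaire, path: str | Path) -> None:
    pd.DataFrame({
        "block": np.arange(1, q.J + 1),
        "first_id": [b.first for b in q.blocks],
        "second_id": [b.second for b in q.blocks],
    }).to_csv(path, index=False)


def write_results(metrics: dict, path: str | Path,
                  config: dict | None = None,
                  seed: int | None = None) -> None:
    """Metrics JSON with a config echo, the seed and the package version."""
    payload = {
        "fcassembly_version": __version__,
        "seed": seed,
        "config": config or {},
        "metrics": _jsonable(metrics),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def make_fixture_pool(N: int, D: int, seed: int, path: str | Path,
                      polarity_mode: str = "positive") -> ItemPool:
    """Write a small deterministic pool CSV for tests and examples."""
    from .simulate import generate_item_pool

    rng = np.random.default_rng(seed)
    pool = generate_item_pool(D, N, polarity_mode, rng)
    write_item_pool(pool, path)
    return pool
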