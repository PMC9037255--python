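"""Shared helpers: seeding, canonical edge handling, deterministic I/O formatting."""

from __future__ import annotations

import hashlib
import json
from typing import Iterable

import numpy as np

FLOAT_FMT = "%.6g"


def derive_seed(root_seed: int, name: str) -> int:
    """Derive a per-stage/substream seed (< 2**31) from a root seed and a label.

    Stable across runs and platforms (sha256-based, not Python hash()).
    """
    h = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def rng_for(root_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(root_seed, name))


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Unordered gene pair stored with the lexicographically smaller gene first."""
    return (a, b) if a <= b else (b, a)


def edge_id(edge: tuple[str, str]) -> str:
    return f"{edge[0]}|{edge[1]}"


def parse_edge_id(s: str) -> tuple[str, str]:
    a, _, b = s.partition("|")
    return (a, b)


def json_dumps_stable(obj) -> str:
    return json.dumps(obj, sort_keys=True, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def check_unique(ids: Iterable[str], what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dups))[:5]}")
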