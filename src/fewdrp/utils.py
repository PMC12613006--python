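"""Shared small utilities: seeded random substreams and checkpoint IO."""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np

from .autodiff import Tensor


def rng_for(seed: int, *names) -> np.random.Generator:
    """Named, reproducible substream of a run-level seed.

    Every source of randomness in the package draws from one of these, so a
    single integer seed pins the whole run.
    """
    keys = [int(seed) & 0x7FFFFFFF]
    for name in names:
        keys.append(zlib.crc32(str(name).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(keys)


def save_checkpoint(path, params: dict, config: dict | None = None) -> None:
    """Round-trip-exact parameter checkpoint (npz + json sidecar header)."""
    path = Path(path)
    arrays = {k: v.data for k, v in params.items()}
    header = json.dumps(config or {})
    with open(path, "wb") as fh:  # keep the exact filename (no .npz appending)
        np.savez(fh, __config__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)


def load_checkpoint(path) -> tuple[dict, dict]:
    with np.load(Path(path), allow_pickle=False) as z:
        config = json.loads(bytes(z["__config__"]).decode()) if "__config__" in z else {}
        params = {k: Tensor(z[k]) for k in z.files if k != "__config__"}
    return params, config
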