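"""Shared helpers: deterministic seed fan-out and file checksums."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np


def stage_seed_sequence(global_seed: int, stage: str) -> np.random.SeedSequence:
    """Derive a per-stage seed stream from one global seed.

    The stage name is hashed (SHA-256) into the spawn key so adding a new
    stage never reshuffles the randomness of existing ones.
    """
    digest = hashlib.sha256(stage.encode("utf-8")).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.SeedSequence([int(global_seed), key])


def stage_rng(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed_sequence(global_seed, stage))


def sha256_file(path: Path | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
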