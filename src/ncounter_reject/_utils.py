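"""Small shared numerics and plumbing helpers."""

from __future__ import annotations

import hashlib

import numpy as np


def geomean(x) -> float:
    """Geometric mean of a positive vector.

    Raises ValueError on nonpositive entries: callers decide pseudocount
    policy before getting here.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("geometric mean of empty vector")
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(x))))


def sample_sd(x) -> float:
    """Standard deviation with n-1 denominator (0.0 for a single value)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    return float(np.std(x, ddof=1))


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed below 2**31.

    Hash-based so stages can be rerun in isolation with the same stream
    they would see inside a full pipeline run.
    """
    h = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def format_float(x: float) -> str:
    """Round-trippable float formatting for text artifacts."""
    return repr(float(x))
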