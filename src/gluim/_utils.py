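"""Shared helpers: validation, seeding, small numerics."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["check_positive", "check_nonnegative", "child_seed", "as_rng"]


def check_positive(value: float, name: str) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be positive and finite, got {value!r}")


def check_nonnegative(value: float, name: str) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be nonnegative and finite, got {value!r}")


def child_seed(global_seed: int, stage: str) -> np.random.SeedSequence:
    """Derive a per-stage seed from a single global seed.

    The derivation is deterministic (CRC32 of the stage name mixed into a
    ``SeedSequence``), so each pipeline stage can be re-run independently and
    still reproduce its stream.
    """
    return np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])


def as_rng(seed) -> np.random.Generator:
    """Accept None, int, SeedSequence or Generator and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
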