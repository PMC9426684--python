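"""Shared helpers: seed fan-out and input validation."""

from __future__ import annotations

import zlib

import numpy as np

_SEED_MOD = 2**31 - 1


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed from a global seed and stage name.

    The derivation is a CRC32 hash of the stage name mixed with the global
    seed, reduced below 2**31 so it is portable to any RNG API.
    """
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % _SEED_MOD


def check_same_shape(a: np.ndarray, b: np.ndarray, what: str = "images") -> None:
    if np.shape(a) != np.shape(b):
        raise ValueError(f"{what} must have the same shape, got {np.shape(a)} and {np.shape(b)}")


def as_float_image(img) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={arr.ndim}")
    return arr
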