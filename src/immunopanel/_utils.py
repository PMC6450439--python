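"""Shared numeric helpers."""

from __future__ import annotations

import zlib

import numpy as np


def safe_log2(x):
    """log2 with the package-wide pseudocount rule.

    Zero (or negative, after background subtraction flooring) values are
    replaced by 0.5 before taking log2; positive values are untouched.
    """
    arr = np.asarray(x, dtype=float)
    return np.log2(np.where(arr > 0, arr, 0.5))


def geometric_mean(x, axis=None):
    """Geometric mean on the safe-log2 scale (zeros count as 0.5)."""
    return 2.0 ** np.mean(safe_log2(x), axis=axis)


def derive_seed(seed: int, *salts) -> int:
    """Deterministically derive an independent stream seed below 2**31."""
    salted = [zlib.crc32(str(s).encode()) & 0x7FFFFFFF for s in salts]
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *salted])
    return int(ss.generate_state(1)[0] % (2**31))
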