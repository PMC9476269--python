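"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np


def holm_adjust(p) -> np.ndarray:
    """Holm step-down multiple-testing adjustment.

    Sorted ascending, the i-th smallest p-value (1-based, m tests) is
    multiplied by (m − i + 1); adjusted values are made monotone
    non-decreasing in that order by a cumulative maximum and capped at 1.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("holm_adjust expects a 1-D vector of p-values")
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="stable")
    scaled = arr[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty_like(arr)
    out[order] = adjusted_sorted
    return out
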