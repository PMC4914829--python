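"""Small interval-arithmetic helpers on (start, end) arrays.

All coordinates are 0-based half-open (BED convention). Intervals are
represented as integer arrays of shape (n, 2); per-genome sets as
``dict[chrom] -> (n, 2) array``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge",
    "total_length",
    "intersect",
    "overlap_matrix",
]


def merge(iv: np.ndarray, gap: int = 0) -> np.ndarray:
    """Sort and merge intervals closer than ``gap`` bp (0 = merge touching)."""
    iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    out = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out, dtype=np.int64)


def total_length(iv: np.ndarray) -> int:
    iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if len(iv) == 0:
        return 0
    m = merge(iv)
    return int((m[:, 1] - m[:, 0]).sum())


def intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two interval sets (each merged internally first)."""
    a, b = merge(np.asarray(a)), merge(np.asarray(b))
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def overlap_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise overlap lengths, shape (len(a), len(b)). O(n*m); fine for
    gene-vs-region assignment where one side is small."""
    a = np.asarray(a, dtype=np.int64).reshape(-1, 2)
    b = np.asarray(b, dtype=np.int64).reshape(-1, 2)
    lo = np.maximum(a[:, None, 0], b[None, :, 0])
    hi = np.minimum(a[:, None, 1], b[None, :, 1])
    return np.clip(hi - lo, 0, None)
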