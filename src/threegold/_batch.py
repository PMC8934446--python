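"""Vectorised unit-weight border computations for many pairs at once.

Used by clustering and the centroid generator, where all sequences share
one length L.  The DP runs row-by-row across the whole batch, so the
Python-level work is O(L^2) regardless of how many pairs are scored.
Results agree exactly with the scalar routines in :mod:`threegold.distance`
(property-tested).
"""

from __future__ import annotations

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def encode(seqs: list[str]) -> np.ndarray:
    """(n, L) uint8 codes; requires uniform length."""
    lens = {len(s) for s in seqs}
    if len(lens) > 1:
        raise ValueError("sequences must have uniform length")
    arr = np.zeros((len(seqs), lens.pop() if lens else 0), dtype=np.uint8)
    for i, s in enumerate(seqs):
        arr[i] = [_CODE[c] for c in s.upper()]
    return arr


def unit_borders(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-weight bottom row and rightmost column for each pair.

    A, B: (P, L) uint8 code arrays (row string / column string per pair).
    Returns (bottom, right), each (P, L+1), indexed by matrix coordinate
    (bottom[:, j] = cell (L, j); right[:, i] = cell (i, L)).  'N' (code 4)
    mismatches everything, itself included.
    """
    P, L = A.shape
    bottom = np.empty((P, L + 1), dtype=np.int32)
    right = np.empty((P, L + 1), dtype=np.int32)
    prev = np.broadcast_to(np.arange(L + 1, dtype=np.int32), (P, L + 1)).copy()
    right[:, 0] = prev[:, L]
    cur = np.empty_like(prev)
    for i in range(1, L + 1):
        cur[:, 0] = i
        ai = A[:, i - 1]
        mismatch = ((ai[:, None] != B) | (ai[:, None] == 4) | (B == 4)).astype(np.int32)
        for j in range(1, L + 1):
            np.minimum(prev[:, j] + 1, prev[:, j - 1] + mismatch[:, j - 1], out=cur[:, j])
            np.minimum(cur[:, j], cur[:, j - 1] + 1, out=cur[:, j])
        right[:, i] = cur[:, L]
        prev, cur = cur, prev
    bottom[:] = prev
    return bottom, right


def sld_min(bottom: np.ndarray, right: np.ndarray, frameshift: int | None = None) -> np.ndarray:
    """Per-pair border minimum, optionally capped at ``frameshift`` offsets."""
    L = bottom.shape[1] - 1
    f = L if frameshift is None else min(frameshift, L)
    lo = L - f
    return np.minimum(bottom[:, lo:].min(axis=1), right[:, lo:].min(axis=1))


def corner(bottom: np.ndarray) -> np.ndarray:
    return bottom[:, -1]
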