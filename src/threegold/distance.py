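"""Edit-distance computations over DNA strings.

The dynamic-programming matrix puts the first string ``a`` on the rows
(index ``i``) and the second string ``b`` on the columns (index ``j``).
Cell (i, j) holds the cost of editing ``a[:i]`` into ``b[:j]``:

* the column-consuming move (i, j-1) -> (i, j) adds a base of ``b``
  (an **insertion**, cost ``w_ins``);
* the row-consuming move (i-1, j) -> (i, j) drops a base of ``a``
  (a **deletion**, cost ``w_del``);
* the diagonal move costs 0 on a match and ``w_sub`` on a mismatch.

Borders are always initialised to the unweighted values max(i, j), even
under weighted schemes.  That choice makes the weighted border minimum
("weighted SLD") systematically unreliable — the documented failure mode
that motivates composition inference (:mod:`threegold.inference`).

The border minimum over the bottommost row and rightmost column is the
Sequence-Levenshtein distance (SLD): it forgives a truncation or elongation
at the downstream end of either string.  Reversing both strings converts an
upstream frameshift into a downstream one, which is why consumers combine
the forward and mirrored computations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import DistanceParams, WeightScheme

DNA_ALPHABET = frozenset("ACGTN")

#: Border label for the bottommost row of the matrix (offsets truncate ``b``).
ROW = "row"
#: Border label for the rightmost column (offsets truncate ``a``).
COLUMN = "column"


def _clean(s: str) -> str:
    s = s.upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters {sorted(bad)} (alphabet is A,C,G,T,N)")
    return s


def _match(x: str, y: str) -> bool:
    # 'N' is an unknown base: it never matches, not even another 'N'.
    return x == y and x != "N"


@dataclass(frozen=True)
class SldOutcome:
    """Border minimum of the edit matrix.

    ``positions`` lists every border cell achieving the minimum as
    ``(border, offset)`` pairs, offsets counted from the corner (offset 0 is
    the corner itself, reported once under the ``row`` border).
    """

    value: float
    positions: tuple[tuple[str, int], ...]
    corner_value: float


@dataclass(frozen=True)
class BandedSldOutcome:
    """Result of the banded computation.

    ``exceeded`` is set when every path cost reached the early-termination
    bound before touching a border; ``value``/``positions`` are then None.
    ``cells_computed`` counts evaluated matrix cells (border initialisation
    included) for structural speed checks.
    """

    value: Optional[float]
    positions: Optional[tuple[tuple[str, int], ...]]
    corner_value: Optional[float]
    exceeded: bool
    cells_computed: int


def strip_common_prefix(a: str, b: str) -> tuple[str, str]:
    """Drop the longest shared prefix of ``a`` and ``b``.

    Under unit weights, upstream matching bases contribute zero to every
    entry of the sub-matrix reachable from them, so corner distance, border
    minima and inferred compositions are all unchanged.  Under non-unit
    weights stripping is *not* value-preserving (the unweighted borders of
    the stripped matrix open cheap escape paths), so the weighted routines
    only strip when the scheme is unit.  'N' never matches, so it is never
    stripped.
    """
    k = 0
    n = min(len(a), len(b))
    while k < n and _match(a[k], b[k]):
        k += 1
    return a[k:], b[k:]


def edit_matrix(a: str, b: str, weights: Optional[WeightScheme] = None) -> np.ndarray:
    """Full DP matrix under the weighted recurrence with unweighted borders."""
    a, b = _clean(a), _clean(b)
    w = weights or WeightScheme.unit()
    la, lb = len(a), len(b)
    m = np.empty((la + 1, lb + 1), dtype=float)
    m[:, 0] = np.arange(la + 1)
    m[0, :] = np.arange(lb + 1)
    for i in range(1, la + 1):
        ai = a[i - 1]
        row = m[i]
        prev = m[i - 1]
        for j in range(1, lb + 1):
            k = 0.0 if _match(ai, b[j - 1]) else w.w_sub
            row[j] = min(prev[j] + w.w_del, row[j - 1] + w.w_ins, prev[j - 1] + k)
    return m


def _maybe_strip(a: str, b: str, w: WeightScheme) -> tuple[str, str]:
    return strip_common_prefix(a, b) if w.is_unit else (a, b)


def levenshtein(a: str, b: str, weights: Optional[WeightScheme] = None) -> float:
    """Corner value of the edit matrix (classic LD under unit weights)."""
    w = weights or WeightScheme.unit()
    a, b = _maybe_strip(_clean(a), _clean(b), w)
    if not a and not b:
        return 0.0
    return float(edit_matrix(a, b, w)[-1, -1])


def _border_scan(m: np.ndarray) -> SldOutcome:
    la, lb = m.shape[0] - 1, m.shape[1] - 1
    best = np.inf
    positions: list[tuple[str, int]] = []
    for d in range(lb + 1):
        v = m[la, lb - d]
        if v < best:
            best, positions = v, [(ROW, d)]
        elif v == best:
            positions.append((ROW, d))
    for d in range(1, la + 1):  # corner already scanned as (ROW, 0)
        v = m[la - d, lb]
        if v < best:
            best, positions = v, [(COLUMN, d)]
        elif v == best:
            positions.append((COLUMN, d))
    positions.sort(key=lambda p: (p[0] != ROW, p[1]))
    return SldOutcome(float(best), tuple(positions), float(m[la, lb]))


def sld(a: str, b: str, weights: Optional[WeightScheme] = None) -> SldOutcome:
    """Minimum over the bottommost row and rightmost column.

    Under unit weights this is the Sequence-Levenshtein distance.  Under
    non-unit weights the value is reported as defined but is not a reliable
    weighted distance (unweighted borders inflate or deflate it); see
    :func:`threegold.inference.threegold_distance` for the corrected metric.
    """
    w = weights or WeightScheme.unit()
    a, b = _maybe_strip(_clean(a), _clean(b), w)
    if not a and not b:
        return SldOutcome(0.0, ((ROW, 0),), 0.0)
    return _border_scan(edit_matrix(a, b, w))


def mirrored_sld(
    a: str, b: str, weights: Optional[WeightScheme] = None
) -> tuple[SldOutcome, SldOutcome]:
    """Forward and mirrored border minima.

    The mirrored computation runs on character-reversed copies of both
    strings (not reverse complements), converting upstream frameshift into
    the downstream frameshift that the border scan forgives.  Consumers use
    the lower of the two values.
    """
    return sld(a, b, weights), sld(a[::-1], b[::-1], weights)


def banded_sld(a: str, b: str, params: DistanceParams) -> BandedSldOutcome:
    """Border minimum via a value-pruned diagonal band with early termination.

    Borders are initialised in the traditional manner while their values stay
    below the bound; the computed region then extends diagonally, halted
    border values still feeding the recurrence.  Cells whose value reaches
    ``H = max(tau + frameshift, 1)`` are pruned, and the computation stops as
    soon as a whole row offers no cell below the bound — every remaining path
    would cost at least H, so the outcome is reported as exceeded.

    Whenever a result below H exists, value and positions are identical to
    the full-matrix scan: step costs are non-negative, so the running cost
    along any optimal path is non-decreasing and never meets a pruned cell.
    """
    w = params.weights
    a, b = _maybe_strip(_clean(a), _clean(b), w)
    hh = max(params.h, 1)
    la, lb = len(a), len(b)
    if la == 0 and lb == 0:
        return BandedSldOutcome(0.0, ((ROW, 0),), 0.0, False, 1)

    cells = 0
    inf = np.inf
    # prev maps j -> value for the previous row (pruned cells absent).
    prev: dict[int, float] = {}
    for j in range(0, lb + 1):
        cells += 1
        if j >= hh:
            break
        prev[j] = float(j)

    # border results accumulated on the fly: right column from each row,
    # bottom row at the end.
    right_col: dict[int, float] = {}  # i -> value at (i, lb)
    if lb in prev:
        right_col[0] = prev[lb]

    bottom_row: dict[int, float] = {}
    row: dict[int, float] = prev
    for i in range(1, la + 1):
        ai = a[i - 1]
        row = {}
        if i < hh:
            cells += 1
            row[0] = float(i)
        for j in range(1, lb + 1):
            up = prev.get(j, inf)
            left = row.get(j - 1, inf)
            diag = prev.get(j - 1, inf)
            if up == inf and left == inf and diag == inf:
                continue  # unreachable: not a computed cell
            cells += 1
            k = 0.0 if _match(ai, b[j - 1]) else w.w_sub
            v = min(up + w.w_del, left + w.w_ins, diag + k)
            if v < hh:
                row[j] = v
        if lb in row:
            right_col[i] = row[lb]
        if not row:
            # every path through row i costs >= H; cells (i', lb) with i' < i
            # were already recorded, the bottom row is unreachable.
            break
        prev = row
    else:
        bottom_row = dict(row)

    best = inf
    positions: list[tuple[str, int]] = []
    for d in range(lb + 1):
        j = lb - d
        if j in bottom_row:
            v = bottom_row[j]
            if v < best:
                best, positions = v, [(ROW, d)]
            elif v == best:
                positions.append((ROW, d))
    for d in range(1, la + 1):
        i = la - d
        if i in right_col:
            v = right_col[i]
            if v < best:
                best, positions = v, [(COLUMN, d)]
            elif v == best:
                positions.append((COLUMN, d))
    if best == inf:
        return BandedSldOutcome(None, None, None, True, cells)
    positions.sort(key=lambda p: (p[0] != ROW, p[1]))
    corner = bottom_row.get(lb)
    return BandedSldOutcome(
        float(best), tuple(positions), None if corner is None else float(corner), False, cells
    )


def full_matrix_cells(a: str, b: str) -> int:
    """Cell count of the naive full-matrix computation."""
    return (len(a) + 1) * (len(b) + 1)
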