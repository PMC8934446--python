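"""Error-composition inference and the weighted 3GOLD distance.

Weighted border minima are unreliable (unweighted border initialisation
inflates them), so the weighted distance is instead *inferred* from the
unweighted matrix: the value and border position of the unweighted SLD,
compared against the unweighted corner LD, reveal how many errors of each
type separate the strings.

Reading direction: compositions describe editing the first argument into
the second.  A displacement of the border minimum away from the corner
along the bottommost row means net deletions; a displacement up the
rightmost column means net insertions.  Residual cost at the chosen cell is
carried by substitutions, or by insertion+deletion pairs whenever the pair
is cheaper than a substitution — which deliberately over-counts the total
number of errors in that case.

Position rules: if the minimum repeats along one border, the cell closest
to the corner characterises the errors; if it occurs on both borders
(corner excluded), the candidate with the lowest combined penalty wins,
except that equal insertion/deletion weights short-circuit to the
rightmost-column candidate.  The corner cell always remains a fallback
candidate, so the inferred penalty never exceeds the corner's own best
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

from .distance import COLUMN, ROW, _clean, edit_matrix, strip_common_prefix
from .params import DistanceParams, WeightScheme

FORWARD = "forward"
REVERSED = "reversed"


@dataclass(frozen=True)
class ErrorComposition:
    """Counts of each error type between two sequences."""

    n_ins: int = 0
    n_del: int = 0
    n_sub: int = 0

    @property
    def total(self) -> int:
        return self.n_ins + self.n_del + self.n_sub

    def cost(self, weights: WeightScheme) -> float:
        return (
            self.n_ins * weights.w_ins
            + self.n_del * weights.w_del
            + self.n_sub * weights.w_sub
        )


@dataclass(frozen=True)
class DistanceResult:
    """Weighted distance with its supporting interpretation."""

    weighted_value: float
    composition: ErrorComposition
    orientation: str  # FORWARD or REVERSED
    within_threshold: bool


def _compositions(v: float, n_ins0: int, n_del0: int) -> Iterator[ErrorComposition]:
    """Compositions consistent with a border cell of unit value ``v``.

    ``n_ins0``/``n_del0`` are the net indels implied by the cell's position;
    the residual ``v - net`` is split between substitutions and extra
    insertion+deletion pairs (each pair trades away one substitution, or two
    units of residual when both came from indels).
    """
    r = v - n_ins0 - n_del0
    if r < 0 or r != int(r):
        return
    r = int(r)
    for m in range(r, -1, -1):
        k = -(-(r - m) // 2)  # ceil: enough pairs to absorb the residual
        yield ErrorComposition(n_ins0 + k, n_del0 + k, m)


def _candidate_cells(
    m, la: int, lb: int, frameshift: Optional[int], weights: WeightScheme
) -> list[tuple[str, int, float]]:
    """Border cells whose position characterises the errors.

    Returns (border, offset, unit value) triples: the closest-to-corner
    minimum of each border within the frameshift allowance, plus the corner.
    """
    fr = frameshift if frameshift is not None else max(la, lb)
    cells = [(ROW, d, float(m[la, lb - d])) for d in range(min(fr, lb) + 1)]
    cells += [(COLUMN, d, float(m[la - d, lb])) for d in range(1, min(fr, la) + 1)]
    s = min(v for _, _, v in cells)
    closest: dict[str, tuple[str, int, float]] = {}
    for border, d, v in cells:
        if v == s and (border not in closest or d < closest[border][1]):
            closest[border] = (border, d, v)
    chosen = list(closest.values())
    if len(chosen) == 2 and weights.w_ins == weights.w_del and all(c[1] > 0 for c in chosen):
        # equal indel weights: the rightmost-column candidate suffices
        chosen = [c for c in chosen if c[0] == COLUMN]
    corner = (ROW, 0, float(m[la, lb]))
    if corner not in chosen:
        chosen.append(corner)
    return chosen


def _net_indels(border: str, d: int, la: int, lb: int) -> tuple[int, int]:
    """Net (insertions, deletions) at a border cell, editing ``a`` into ``b``.

    A bottom-row cell at offset ``d`` compares ``a`` against ``b`` with its
    last ``d`` bases truncated; the rightmost column truncates ``a``.
    """
    if border == ROW:
        diff = la - (lb - d)
    else:
        diff = (la - d) - lb
    return (max(-diff, 0), max(diff, 0))


def _infer_one(
    a: str,
    b: str,
    weights: WeightScheme,
    frameshift: Optional[int],
) -> tuple[float, ErrorComposition, float, tuple[str, int]]:
    """Returns (weighted cost, composition, unweighted SLD value, chosen cell)."""
    a, b = strip_common_prefix(a, b)
    la, lb = len(a), len(b)
    if la == 0 and lb == 0:
        return 0.0, ErrorComposition(), 0.0, (ROW, 0)
    m = edit_matrix(a, b)  # unit weights throughout; weights only score compositions
    ranked: list[tuple[float, int, int, int, ErrorComposition]] = []
    for border, d, v in _candidate_cells(m, la, lb, frameshift, weights):
        ni0, nd0 = _net_indels(border, d, la, lb)
        for comp in _compositions(v, ni0, nd0):
            ranked.append((comp.cost(weights), comp.total, border != COLUMN, d, comp))
    cost, _, is_row, d, comp = min(ranked, key=lambda t: t[:4])
    s = min(min(m[la, :]), min(m[:, lb]))
    return cost, comp, float(s), (ROW if is_row else COLUMN, d)


def infer_composition(
    a: str,
    b: str,
    weights: Optional[WeightScheme] = None,
    *,
    frameshift: Optional[int] = None,
) -> ErrorComposition:
    """Infer the error composition turning ``a`` into ``b``.

    ``frameshift`` caps how far from the corner a border minimum may be
    considered (None: uncapped).  The lowest-penalty composition over all
    candidate cells is reported.
    """
    w = weights or WeightScheme.unit()
    return _infer_one(_clean(a), _clean(b), w, frameshift)[1]


def threegold_distance(a: str, b: str, params: DistanceParams) -> DistanceResult:
    """Bidirectional weighted distance between ``a`` and ``b``.

    Runs the inference on the strings as given and on character-reversed
    copies (upstream frameshift becomes downstream), and keeps the
    orientation with the lower weighted penalty, forward winning ties.

    ``within_threshold`` holds when the weighted penalty is inside the
    weight threshold *and* the chosen orientation's unweighted border
    minimum stays below the termination bound h = tau + frameshift (a pair
    at or past h is treated as unrelated — the banded computation would
    have terminated on it).
    """
    a, b = _clean(a), _clean(b)
    w = params.weights
    fwd = _infer_one(a, b, w, params.frameshift)
    rev = _infer_one(a[::-1], b[::-1], w, params.frameshift)
    if rev[0] < fwd[0]:
        (cost, comp, s, _), orientation = rev, REVERSED
    else:
        (cost, comp, s, _), orientation = fwd, FORWARD
    within = cost <= params.weight_threshold and s < max(params.h, 1)
    return DistanceResult(cost, comp, orientation, within)
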