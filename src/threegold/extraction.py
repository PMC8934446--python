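"""Sliding-window discovery of sequences of interest inside longer reads.

Barcodes/UMIs sit embedded in long reads at unknown offsets.  Each window
of probe length is scored against the probes with the bidirectional
weighted distance; windows under the weight threshold are hits.  The scan
step starts at 1 and, once a perfect (weight-0) match is seen, may switch
to the probe length — tandem copies then line up window after window.

The weight threshold itself is chosen empirically: score every window
without a threshold, histogram the match weights, and take the point at the
steepest drop of the count curve that also covers the bulk (>99 % by
default) of the matches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .inference import threegold_distance
from .params import DistanceParams


@dataclass(frozen=True)
class MatchHit:
    """A window of a read matching a probe, [start, start+L) half-open."""

    read_id: str
    probe_id: str
    start: int
    weight: float
    orientation: str


@dataclass
class WeightHistogram:
    """Counts of match weights, used to pick the clustering threshold."""

    counts: dict[float, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, weight: float) -> None:
        self.counts[weight] = self.counts.get(weight, 0) + 1


def sliding_window_extract(
    read_id: str,
    read: str,
    probes: list[tuple[str, str]],
    params: DistanceParams,
    *,
    after_perfect_step: int = 1,
    unthresholded: bool = False,
) -> list[MatchHit]:
    """Scan ``read`` for windows matching any probe.

    ``probes`` is a list of (probe_id, sequence) with a common length.
    ``after_perfect_step`` is the step adopted once a weight-0 match occurs
    (use the probe length when copies are tandem; keep 1 for a best-match
    search).  With ``unthresholded`` every window's best probe match is
    emitted regardless of the thresholds — the mode used to build weight
    histograms.
    """
    lengths = {len(p) for _, p in probes}
    if len(lengths) != 1:
        raise ValueError("probes must be non-empty and of uniform length")
    L = lengths.pop()
    if len(read) < L:
        warnings.warn(f"read {read_id!r} is shorter than the probes; no hits")
        return []
    hits: list[MatchHit] = []
    step = 1
    pos = 0
    while pos + L <= len(read):
        window = read[pos : pos + L]
        best = None
        for probe_id, probe in probes:
            # probe first: compositions count errors in the window relative
            # to the probe, so insertion weights price the read's extra bases
            res = threegold_distance(probe, window, params)
            ok = res.within_threshold or unthresholded
            if ok and (best is None or res.weighted_value < best[1].weighted_value):
                best = (probe_id, res)
        if best is not None:
            probe_id, res = best
            hits.append(MatchHit(read_id, probe_id, pos, res.weighted_value, res.orientation))
            if res.weighted_value == 0:
                step = after_perfect_step
        pos += step
    return hits


def best_match_per_read(
    read_id: str,
    read: str,
    probes: list[tuple[str, str]],
    params: DistanceParams,
) -> MatchHit | None:
    """The single minimum-weight window across all probes, or None.

    Ties resolve to the leftmost window, then the lowest probe index.
    The scan keeps step 1 throughout so no window is skipped.
    """
    hits = sliding_window_extract(read_id, read, probes, params, after_perfect_step=1)
    if not hits:
        return None
    order = {pid: k for k, (pid, _) in enumerate(probes)}
    return min(hits, key=lambda h: (h.weight, h.start, order[h.probe_id]))


def determine_weight_threshold(
    hist: WeightHistogram, coverage: float = 0.99
) -> tuple[float, float]:
    """Pick the clustering weight threshold from a match-weight histogram.

    Returns (threshold, achieved coverage).  The threshold is the smallest
    weight that lies at or after the steepest drop of the count curve and
    whose cumulative share of matches exceeds ``coverage``.  The steepest
    drop is the largest decrease between consecutive occupied bins, the
    empty tail after the last bin included.
    """
    if hist.total == 0:
        raise ValueError("empty weight histogram")
    weights = sorted(hist.counts)
    counts = [hist.counts[w] for w in weights] + [0]
    drops = [counts[k] - counts[k + 1] for k in range(len(weights))]
    w_steep = weights[max(range(len(weights)), key=lambda k: drops[k])]
    total = hist.total
    cum = 0
    w_cov = weights[-1]
    for w, c in zip(weights, counts):
        cum += c
        if cum / total > coverage:
            w_cov = w
            break
    threshold = max(w_steep, w_cov)
    achieved = sum(c for w, c in hist.counts.items() if w <= threshold) / total
    return threshold, achieved
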