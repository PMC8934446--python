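"""Labeled benchmark generation emulating error-rich long-read data.

Clusters are built from well-separated random centroids (all pairwise
distances above a floor, so a 20-mer can absorb 20 % error without clusters
bleeding into each other) whose copies are corrupted by indel-biased error
profiles.  Two presets mirror measured simulator profiles:

* ``pacbio``  — 11.10 % total error, 66.35 % insertions / 33.70 % deletions;
* ``nanopore`` — 10.13 % total error, 30.30 % insertions / 69.70 % deletions.

Errors are injected independently per base at the configured per-type
rates; no homopolymer or sequence context is modelled, so these benchmarks
exercise the metric and pipeline, not simulator-faithful read physics.
Every read carries its true centroid label and edit log, which replays
exactly onto the centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _batch
from .io import SequenceRecord

_BASES = "ACGT"

#: The benchmark cluster layouts exercised throughout: (clusters, copies each).
STANDARD_LAYOUTS = ((4, 125), (5, 100), (10, 50), (20, 25), (25, 20), (50, 10))


@dataclass(frozen=True)
class ErrorRates:
    """Per-base, per-type injection probabilities."""

    p_ins: float = 0.0
    p_del: float = 0.0
    p_sub: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_ins", "p_del", "p_sub"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def total(self) -> float:
        return self.p_ins + self.p_del + self.p_sub


PRESETS = {
    "pacbio": ErrorRates(p_ins=0.1110 * 0.6635, p_del=0.1110 * 0.3370, p_sub=0.0),
    "nanopore": ErrorRates(p_ins=0.1013 * 0.3030, p_del=0.1013 * 0.6970, p_sub=0.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    n_centroids: int = 50
    centroid_length: int = 20
    min_pairwise_ld: int = 8  # exclusive floor: all pairs strictly farther
    rates: ErrorRates = field(default_factory=ErrorRates)
    copies_per_centroid: int = 10
    tandem: bool = False
    seed: int = 0


@dataclass(frozen=True)
class LabeledRead:
    sequence: str
    true_centroid_id: str
    edits: tuple[tuple[str, int, str], ...]
    """Edit log in centroid coordinates: ("ins", pos, base) inserts before
    ``pos``; ("del", pos, "") removes ``pos``; ("sub", pos, base) replaces
    ``pos``.  Replaying the log onto the centroid reproduces the read."""


def replay_edits(centroid: str, edits: tuple[tuple[str, int, str], ...]) -> str:
    """Apply an edit log (as recorded by :func:`mutate`) to a centroid."""
    out: list[str] = []
    by_pos: dict[int, list[tuple[str, str]]] = {}
    for op, pos, base in edits:
        by_pos.setdefault(pos, []).append((op, base))
    for pos in range(len(centroid) + 1):
        keep = pos < len(centroid)
        cur = centroid[pos] if keep else ""
        for op, base in by_pos.get(pos, ()):
            if op == "ins":
                out.append(base)
            elif op == "del":
                cur = ""
            elif op == "sub":
                cur = base
        out.append(cur)
    return "".join(out)


def generate_centroids(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Rejection-sample centroids until all pairwise distances exceed the floor.

    Candidates are uniform random sequences; one failing the separation
    constraint against any accepted centroid is discarded.  Separation is
    enforced in the metric the clustering actually uses: the classic corner
    distance *and* the frameshift-forgiving border minima (both string
    orientations, truncations up to 20 % of the length) must all exceed
    ``min_pairwise_ld`` — a pair separated only at the corner can still fall
    inside the clustering threshold through a truncated reading and let
    neighbouring clusters bleed into each other.
    """
    accepted: list[str] = []
    f = max(int(np.floor(config.centroid_length * 0.2 + 0.5)), 1)
    attempts = 0
    max_attempts = 1000 * max(config.n_centroids, 1)
    while len(accepted) < config.n_centroids:
        if attempts >= max_attempts:
            raise RuntimeError(
                "could not place all centroids at the requested separation; "
                "use longer centroids or fewer clusters"
            )
        attempts += 1
        cand = "".join(rng.choice(list(_BASES), size=config.centroid_length))
        if accepted:
            A = _batch.encode(accepted)
            B = _batch.encode([cand] * len(accepted))
            sep = np.inf
            for X, Y in ((A, B), (A[:, ::-1], B[:, ::-1])):
                bottom, right = _batch.unit_borders(X, Y)
                sep = min(sep, int(_batch.sld_min(bottom, right, f).min()))
            if sep <= config.min_pairwise_ld:
                continue
        accepted.append(cand)
    return accepted


def mutate(sequence: str, rates: ErrorRates, rng: np.random.Generator,
           centroid_id: str = "") -> LabeledRead:
    """Corrupt a sequence with i.i.d. per-base errors, logging every edit.

    At each position an insertion may occur before the base, and the base
    itself is then deleted or substituted at the configured rates; a final
    insertion slot sits after the last base.
    """
    out: list[str] = []
    edits: list[tuple[str, int, str]] = []
    n = len(sequence)
    for pos in range(n + 1):
        if rng.random() < rates.p_ins:
            base = _BASES[rng.integers(4)]
            out.append(base)
            edits.append(("ins", pos, base))
        if pos == n:
            break
        b = sequence[pos]
        r = rng.random()
        if r < rates.p_del:
            edits.append(("del", pos, ""))
        elif r < rates.p_del + rates.p_sub:
            base = _BASES[(int(_BASES.index(b)) + int(rng.integers(1, 4))) % 4]
            out.append(base)
            edits.append(("sub", pos, base))
        else:
            out.append(b)
    return LabeledRead("".join(out), centroid_id, tuple(edits))


def build_benchmark(
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], dict[str, list[str]], list[LabeledRead]]:
    """Reads plus ground truth for one cluster layout.

    Returns (records, truth, labeled reads).  In tandem mode each cluster
    yields a single long read of ``copies_per_centroid`` corrupted copies
    laid end to end (for extraction experiments).  Otherwise each copy
    becomes one record of exactly ``centroid_length`` bases, emulating a
    probe-length window cut from a tandem read: a copy shortened by net
    deletions is completed by the start of the following copy, and one
    lengthened by net insertions is truncated.  The clustering pipeline
    requires this uniform length.  Fixed seeds give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    centroids = generate_centroids(config, rng)
    records: list[SequenceRecord] = []
    truth: dict[str, list[str]] = {}
    labeled: list[LabeledRead] = []
    for c_idx, centroid in enumerate(centroids):
        cid = f"centroid_{c_idx + 1:03d}"
        truth[cid] = []
        copies = []
        for k in range(config.copies_per_centroid):
            read = mutate(centroid, config.rates, rng, cid)
            labeled.append(read)
            copies.append(read.sequence)
        if config.tandem:
            rid = f"{cid}_tandem"
            records.append(SequenceRecord(rid, "".join(copies)))
            truth[cid].append(rid)
        else:
            L = config.centroid_length
            trailer = mutate(centroid, config.rates, rng, cid).sequence
            for k, copy in enumerate(copies):
                nxt = copies[k + 1] if k + 1 < len(copies) else trailer
                window = (copy + nxt + centroid)[:L]
                rid = f"{cid}_read_{k + 1:03d}"
                records.append(SequenceRecord(rid, window))
                truth[cid].append(rid)
    return records, truth, labeled


def centroid_records(centroids: list[str]) -> list[SequenceRecord]:
    return [
        SequenceRecord(f"centroid_{k + 1:03d}", c) for k, c in enumerate(centroids)
    ]


def layout_config(
    n_clusters: int, copies: int, rates: ErrorRates, seed: int, **kw
) -> SimulationConfig:
    return SimulationConfig(
        n_centroids=n_clusters, copies_per_centroid=copies, rates=rates, seed=seed, **kw
    )
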