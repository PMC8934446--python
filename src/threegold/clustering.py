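"""Density-based clustering on all-to-all weighted distances.

Every sequence seeds a candidate cluster: the set of sequences within the
weight threshold of it.  Candidates that share at least 80 % of their
members with a larger candidate collapse into it (members exclusive to the
smaller candidate join only if they are themselves within threshold of the
larger candidate's seed).  Each surviving cluster elects as centroid the
member that links the most of its members, breaking ties by shortest
average distance and then input order.  Sequences linked to nothing are
singletons; after election, singletons within threshold of a centroid are
rescued into the nearest cluster, joining the larger cluster when
equidistant.

The pipeline is deterministic: its output depends only on the input order.
Input sequences must be of uniform length — the border-displacement
interpretation underlying the metric assumes it.

Three metrics are supported so the same pipeline can be compared across
distance definitions: the full bidirectional weighted metric
(``threegold``), the plain forward unweighted border minimum (``sld``), and
the plain corner distance (``ld``).  The unweighted metrics link sequences
at distance <= tau; the weighted metric links within the weight threshold
and the tau error budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _batch
from .inference import threegold_distance
from .io import SequenceRecord
from .params import DistanceParams

METRICS = ("threegold", "sld", "ld")


@dataclass
class Cluster:
    centroid_id: str
    member_ids: list[str]
    member_distances: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    singletons: list[str]

    def all_ids(self) -> list[str]:
        out = [m for c in self.clusters for m in c.member_ids]
        out.extend(self.singletons)
        return out


def _pair_links(
    records: list[SequenceRecord], params: DistanceParams, metric: str
) -> dict[str, dict[str, float]]:
    """Directional within-threshold link map id -> {other id: distance}."""
    n = len(records)
    links: dict[str, dict[str, float]] = {r.id: {} for r in records}
    if n < 2:
        return links
    seqs = [r.sequence for r in records]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError(
            "input sequences must have uniform length; trim reads before clustering"
        )
    enc = _batch.encode(seqs)
    ia, ib = np.triu_indices(n, k=1)
    A, B = enc[ia], enc[ib]
    if metric == "ld":
        bottom, _ = _batch.unit_borders(A, B)
        d = _batch.corner(bottom)
        keep = d <= params.tau
        for x, y, v in zip(ia[keep], ib[keep], d[keep]):
            links[records[x].id][records[y].id] = float(v)
            links[records[y].id][records[x].id] = float(v)
        return links
    if metric == "sld":
        bottom, right = _batch.unit_borders(A, B)
        d = _batch.sld_min(bottom, right)
        keep = d <= params.tau
        for x, y, v in zip(ia[keep], ib[keep], d[keep]):
            links[records[x].id][records[y].id] = float(v)
            links[records[y].id][records[x].id] = float(v)
        return links
    if metric != "threegold":
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    # cheap exact pre-filter: a within-threshold link needs an unweighted
    # border minimum below the termination bound h, and every composition
    # of a border value v costs at least v times the cheapest per-unit rate.
    w = params.weights
    bf, rf = _batch.unit_borders(A, B)
    br, rr = _batch.unit_borders(A[:, ::-1], B[:, ::-1])
    s = np.minimum(_batch.sld_min(bf, rf), _batch.sld_min(br, rr))
    cmin = min(w.w_ins, w.w_del, w.w_sub, (w.w_ins + w.w_del) / 2)
    keep = (s < max(params.h, 1)) & (s * cmin <= params.weight_threshold)
    for x, y in zip(ia[keep], ib[keep]):
        a, b = records[x], records[y]
        res = threegold_distance(a.sequence, b.sequence, params)
        if res.within_threshold:
            links[a.id][b.id] = res.weighted_value
        res = threegold_distance(b.sequence, a.sequence, params)
        if res.within_threshold:
            links[b.id][a.id] = res.weighted_value
    return links


def build_cluster_matrix(
    records: list[SequenceRecord], params: DistanceParams, metric: str = "threegold"
) -> dict[str, dict[str, float]]:
    """All-to-all comparison: for each sequence, its within-threshold links.

    Links are directional (the weighted metric is not symmetric when
    insertion and deletion weights differ); both directions are stored.
    """
    return _pair_links(records, params, metric)


def collapse_clusters(matrix: dict[str, dict[str, float]]) -> list[tuple[str, set[str]]]:
    """Merge candidate clusters sharing >= 80 % of their members.

    Candidates are processed smallest first and merge into the largest
    qualifying candidate (equal sizes: the earlier seed).  Members exclusive
    to the smaller candidate join only when within threshold of the larger
    candidate's seed.  Restarts after every merge until stable.  Returns
    (seed id, member set) candidates surviving collapse.
    """
    order = {sid: k for k, sid in enumerate(matrix)}
    cand: dict[str, set[str]] = {
        sid: {sid, *linked} for sid, linked in matrix.items() if linked
    }
    changed = True
    while changed:
        changed = False
        by_size = sorted(cand, key=lambda s: (len(cand[s]), order[s]))
        for small in by_size:
            smembers = cand[small]
            hosts = [
                h
                for h in cand
                if h != small
                and len(cand[h]) >= len(smembers)
                and len(smembers & cand[h]) >= 0.8 * len(smembers)
            ]
            if not hosts:
                continue
            host = max(hosts, key=lambda h: (len(cand[h]), -order[h]))
            exclusive = smembers - cand[host]
            admitted = {m for m in exclusive if m in matrix[host] or m == host}
            cand[host] |= (smembers & cand[host]) | admitted
            del cand[small]
            changed = True
            break
    return [(sid, cand[sid]) for sid in sorted(cand, key=lambda s: order[s])]


def elect_centroid(
    members: list[str], matrix: dict[str, dict[str, float]], order: dict[str, int]
) -> str:
    """Densest member: most members linked to it, then shortest average
    distance to its linked members, then first in input order."""
    mset = set(members)

    def key(c: str) -> tuple:
        linked = [m for m in matrix.get(c, {}) if m in mset and m != c]
        avg = (
            sum(matrix[c][m] for m in linked) / len(linked) if linked else float("inf")
        )
        return (-len(linked), avg, order[c])

    return min(members, key=key)


def rescue_singletons(
    clusters: list[Cluster],
    singletons: list[str],
    matrix: dict[str, dict[str, float]],
) -> ClusterSet:
    """Attach singletons to the nearest within-threshold centroid.

    A singleton equidistant between two centroids joins the larger cluster;
    remaining ties go to the earlier cluster.  Unresolvable singletons stay.
    """
    left: list[str] = []
    for s in singletons:
        best = None
        for k, cl in enumerate(clusters):
            d = matrix.get(s, {}).get(cl.centroid_id)
            if d is None:
                continue
            cand = (d, -cl.size, k)
            if best is None or cand < best[0]:
                best = (cand, cl)
        if best is None:
            left.append(s)
        else:
            d, cl = best[0][0], best[1]
            cl.member_ids.append(s)
            cl.member_distances[s] = d
    return ClusterSet([c for c in clusters if c.size > 1], left)


def cluster(
    records: list[SequenceRecord], params: DistanceParams, metric: str = "threegold"
) -> ClusterSet:
    """Full pipeline: matrix build, collapse, election, singleton rescue."""
    if not records:
        return ClusterSet([], [])
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in input")
    order = {rid: k for k, rid in enumerate(ids)}
    matrix = build_cluster_matrix(records, params, metric)
    candidates = collapse_clusters(matrix)

    # exclusivity: a sequence appearing in several surviving candidates is
    # assigned to the largest (then earliest-seeded) one.
    assigned: dict[str, str] = {}
    for seed, members in sorted(
        candidates, key=lambda c: (-len(c[1]), order[c[0]])
    ):
        for m in members:
            assigned.setdefault(m, seed)

    clusters: list[Cluster] = []
    pool: list[str] = [rid for rid in ids if rid not in assigned]
    for seed, members in candidates:
        mine = [rid for rid in ids if assigned.get(rid) == seed]
        if not mine:
            continue
        centroid = elect_centroid(mine, matrix, order)
        kept, dists = [centroid], {centroid: 0.0}
        for m in mine:
            if m == centroid:
                continue
            d = matrix.get(m, {}).get(centroid)
            if d is None:
                pool.append(m)  # beyond threshold of the elected centroid
            else:
                kept.append(m)
                dists[m] = d
        if len(kept) > 1:
            clusters.append(Cluster(centroid, kept, dists))
        else:
            pool.append(centroid)
    pool.sort(key=lambda rid: order[rid])
    return rescue_singletons(clusters, pool, matrix)
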