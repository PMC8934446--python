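"""Scoring a clustering against reference clusters.

For a matched reference/experimental cluster pair with reference members R
and experimental members E:

* sensitivity = 100 - 100 * p / m, where p = |R \\ E| (reference members the
  experimental cluster missed) and m = |R|;
* specificity = 100 * (t - u) / t, where t = |R| and u counts the false
  inclusions |E \\ R| (sequences wrongly present in the experimental
  cluster).  An alternative reading of u as the number of reference members
  left unclustered is selectable with ``u_definition="unclustered"``.

Clusters qualify for the headline metrics when their sensitivity reaches
20 % and they survive the size cutoff that limits the cluster count to the
expected number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .clustering import ClusterSet


@dataclass(frozen=True)
class ClusterScore:
    reference_id: str
    matched_centroid: Optional[str]
    ref_size: int
    exp_size: int
    p: int
    u: int
    sensitivity: float
    specificity: float
    qualified: bool = True


@dataclass(frozen=True)
class EvaluationReport:
    rows: tuple[ClusterScore, ...]
    total_clustered: int
    n_singletons: int
    n_qualified: int
    size_range: tuple[int, int]

    @property
    def mean_sensitivity(self) -> float:
        if not self.rows:
            return 0.0
        return sum(r.sensitivity for r in self.rows) / len(self.rows)

    @property
    def mean_specificity(self) -> float:
        if not self.rows:
            return 0.0
        return sum(r.specificity for r in self.rows) / len(self.rows)


def sensitivity(reference: set[str], experimental: set[str]) -> float:
    if not reference:
        raise ValueError("empty reference cluster")
    p = len(reference - experimental)
    return 100.0 - 100.0 * p / len(reference)


def specificity(
    reference: set[str], experimental: set[str], u_definition: str = "false_inclusions"
) -> float:
    t = len(reference)
    if t == 0:
        raise ValueError("empty reference cluster")
    if u_definition == "false_inclusions":
        u = len(experimental - reference)
    elif u_definition == "unclustered":
        u = len(reference - experimental)
    else:
        raise ValueError("u_definition must be 'false_inclusions' or 'unclustered'")
    return 100.0 * (t - u) / t


def qualify_clusters(rows: list[ClusterScore], expected_count: int) -> list[ClusterScore]:
    """Keep clusters with >= 20 % sensitivity, then apply the smallest size
    cutoff that leaves at most ``expected_count`` clusters."""
    eligible = [r for r in rows if r.sensitivity >= 20.0]
    if len(eligible) <= expected_count:
        return eligible
    sizes = sorted((r.exp_size for r in eligible), reverse=True)
    cutoff = sizes[expected_count - 1] if expected_count > 0 else sizes[0] + 1
    kept = [r for r in eligible if r.exp_size >= cutoff]
    while len(kept) > expected_count:
        cutoff += 1
        kept = [r for r in eligible if r.exp_size >= cutoff]
    return kept


def _match_clusters(
    cluster_set: ClusterSet, reference: dict[str, list[str]]
) -> dict[str, Optional[int]]:
    """Match each reference cluster to an experimental cluster index.

    A cluster containing the reference's centroid-named sequence wins;
    otherwise the cluster with the largest member overlap (ties to the
    earlier cluster).  Each experimental cluster is matched at most once,
    larger overlaps first.
    """
    exp_sets = [set(c.member_ids) for c in cluster_set.clusters]
    pairs: list[tuple[int, int, str, int]] = []
    for rid, members in reference.items():
        rset = set(members)
        for k, eset in enumerate(exp_sets):
            ov = len(rset & eset)
            if ov or rid in eset or cluster_set.clusters[k].centroid_id == rid:
                bonus = 1 if (rid in eset or cluster_set.clusters[k].centroid_id == rid) else 0
                pairs.append((ov + bonus, k, rid, ov))
    matched: dict[str, Optional[int]] = {rid: None for rid in reference}
    used: set[int] = set()
    for score, k, rid, _ in sorted(pairs, key=lambda t: (-t[0], t[1], t[2])):
        if k in used or matched[rid] is not None:
            continue
        matched[rid] = k
        used.add(k)
    return matched


def characterize(
    cluster_set: ClusterSet,
    reference: dict[str, list[str]],
    expected_count: Optional[int] = None,
    u_definition: str = "false_inclusions",
) -> EvaluationReport:
    """Full report: per-cluster scores, qualification, and totals."""
    known = {m for members in reference.values() for m in members}
    seen = set(cluster_set.all_ids())
    unknown = seen - known
    if unknown:
        raise ValueError(f"clustered ids absent from the reference: {sorted(unknown)[:5]}")
    matched = _match_clusters(cluster_set, reference)
    rows: list[ClusterScore] = []
    for rid, members in reference.items():
        rset = set(members)
        k = matched[rid]
        eset = set(cluster_set.clusters[k].member_ids) if k is not None else set()
        centroid = cluster_set.clusters[k].centroid_id if k is not None else None
        rows.append(
            ClusterScore(
                reference_id=rid,
                matched_centroid=centroid,
                ref_size=len(rset),
                exp_size=len(eset),
                p=len(rset - eset),
                u=len(eset - rset),
                sensitivity=sensitivity(rset, eset),
                specificity=specificity(rset, eset, u_definition),
            )
        )
    expected = expected_count if expected_count is not None else len(reference)
    qualified_ids = {r.reference_id for r in qualify_clusters(rows, expected)}
    rows = [
        ClusterScore(
            r.reference_id, r.matched_centroid, r.ref_size, r.exp_size,
            r.p, r.u, r.sensitivity, r.specificity,
            qualified=r.reference_id in qualified_ids,
        )
        for r in rows
    ]
    sizes = [c.size for c in cluster_set.clusters]
    return EvaluationReport(
        rows=tuple(rows),
        total_clustered=sum(sizes),
        n_singletons=len(cluster_set.singletons),
        n_qualified=len(qualified_ids),
        size_range=(min(sizes), max(sizes)) if sizes else (0, 0),
    )
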