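"""Matrix building, collapse, centroid election and singleton rescue."""

import pytest

from threegold.clustering import (
    Cluster,
    ClusterSet,
    build_cluster_matrix,
    cluster,
    collapse_clusters,
    elect_centroid,
    rescue_singletons,
)
from threegold.distance import mirrored_sld
from threegold.io import SequenceRecord
from threegold.params import DistanceParams, PACBIO_WEIGHTS, WeightScheme

from conftest import random_dna

PACBIO = DistanceParams(tau=3, frameshift=4, weights=PACBIO_WEIGHTS, weight_threshold=8)


def recs(seqs):
    return [SequenceRecord(f"s{k}", s) for k, s in enumerate(seqs, start=1)]


class TestMatrix:
    def test_identical_sequences_all_linked_at_zero(self):
        m = build_cluster_matrix(recs(["ACGTACGT"] * 3), PACBIO)
        assert m == {
            "s1": {"s2": 0.0, "s3": 0.0},
            "s2": {"s1": 0.0, "s3": 0.0},
            "s3": {"s1": 0.0, "s2": 0.0},
        }

    def test_distant_sequences_unlinked(self):
        m = build_cluster_matrix(recs(["AAAAAAAAAA", "CCCCCCCCCC"]), PACBIO)
        assert m == {"s1": {}, "s2": {}}

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="uniform length"):
            build_cluster_matrix(recs(["ACGT", "ACGTA"]), PACBIO)

    def test_unit_weight_links_match_bidirectional_sld_filter(self, rnd):
        # with unit weights the metric degenerates to the mirrored border
        # minimum, so link sets must equal a brute-force SLD filter
        seqs = [random_dna(rnd, 20) for _ in range(25)]
        params = DistanceParams(tau=3, frameshift=20, weights=WeightScheme.unit(),
                                weight_threshold=3)
        m = build_cluster_matrix(recs(seqs), params)
        for i, a in enumerate(seqs, start=1):
            for j, b in enumerate(seqs, start=1):
                if i == j:
                    continue
                fwd, rev = mirrored_sld(a, b)
                expected = min(fwd.value, rev.value) <= 3
                assert (f"s{j}" in m[f"s{i}"]) == expected


class TestCollapse:
    def mk(self, links):
        return {k: {m: 1.0 for m in v} for k, v in links.items()}

    def test_boundary_overlap_fully_merges(self):
        # candidate {A,B,C,D,E}: 4 of 5 members (80 %) sit in the larger
        # cluster and the exclusive member A links the larger seed
        matrix = self.mk(
            {
                "L": ["B", "C", "D", "E", "F", "G", "A"],
                "A": ["B", "C", "D", "E"],
                **{x: ["L"] for x in "BCDEFG"},
            }
        )
        out = dict(collapse_clusters(matrix))
        assert set(out) == {"L"}
        assert out["L"] == {"L", "A", "B", "C", "D", "E", "F", "G"}

    def test_exclusive_member_outside_threshold_left_behind(self):
        matrix = self.mk(
            {
                "L": ["B", "C", "D", "E", "F", "G"],
                "A": ["B", "C", "D", "E"],
                **{x: ["L"] for x in "BCDEFG"},
            }
        )
        out = dict(collapse_clusters(matrix))
        assert set(out) == {"L"}
        assert "A" not in out["L"]

    def test_disjoint_clusters_never_mix(self):
        # mirror-image candidates inside each pair deduplicate, but nothing
        # crosses between the two unrelated pairs
        matrix = self.mk({"A": ["B"], "B": ["A"], "C": ["D"], "D": ["C"]})
        out = dict(collapse_clusters(matrix))
        assert sorted(map(sorted, out.values())) == [["A", "B"], ["C", "D"]]


class TestElection:
    def test_identical_cluster_first_by_input_order(self):
        matrix = {x: {y: 0.0 for y in "ABC" if y != x} for x in "ABC"}
        order = {x: k for k, x in enumerate("ABC")}
        assert elect_centroid(["A", "B", "C"], matrix, order) == "A"

    def test_hub_wins(self):
        matrix = {"A": {"B": 1.0, "C": 1.0, "D": 1.0}, "B": {"A": 1.0},
                  "C": {"A": 1.0}, "D": {"A": 1.0}}
        order = {x: k for k, x in enumerate("ABCD")}
        assert elect_centroid(["A", "B", "C", "D"], matrix, order) == "A"

    def test_equal_counts_lower_mean_distance_wins(self):
        matrix = {
            "A": {"B": 2.0, "C": 2.0},
            "D": {"B": 1.0, "C": 1.0},
            "B": {"A": 2.0, "D": 1.0},
            "C": {"A": 2.0, "D": 1.0},
        }
        order = {x: k for k, x in enumerate("ABCD")}
        assert elect_centroid(["A", "B", "C", "D"], matrix, order) == "D"


class TestRescue:
    def test_joins_unique_centroid_within_threshold(self):
        clusters = [Cluster("C1", ["C1", "m1"], {"C1": 0.0, "m1": 1.0})]
        matrix = {"x": {"C1": 2.0}}
        out = rescue_singletons(clusters, ["x"], matrix)
        assert "x" in out.clusters[0].member_ids and out.singletons == []

    def test_equidistant_singleton_joins_larger_cluster(self):
        big = Cluster("B", [f"b{k}" for k in range(10)], {})
        small = Cluster("S", [f"s{k}" for k in range(5)], {})
        matrix = {"x": {"B": 3.0, "S": 3.0}}
        out = rescue_singletons([big, small], ["x"], matrix)
        assert "x" in out.clusters[0].member_ids
        assert out.clusters[0].centroid_id == "B"

    def test_unreachable_singleton_stays(self):
        out = rescue_singletons([Cluster("C1", ["C1", "m"], {})], ["x"], {"x": {}})
        assert out.singletons == ["x"]


class TestPipeline:
    def test_error_free_copies_form_exact_clusters(self, rnd):
        a, b = random_dna(rnd, 20), random_dna(rnd, 20)
        records = recs([a] * 5 + [b] * 5)
        out = cluster(records, PACBIO)
        assert sorted(c.size for c in out.clusters) == [5, 5]
        assert out.singletons == []

    def test_empty_input(self):
        out = cluster([], PACBIO)
        assert out.clusters == [] and out.singletons == []

    def test_partition_and_determinism(self):
        from threegold import synthetic

        cfg = synthetic.layout_config(5, 10, synthetic.PRESETS["pacbio"], seed=3)
        records, truth, _ = synthetic.build_benchmark(cfg)
        out1 = cluster(records, PACBIO)
        out2 = cluster(records, PACBIO)
        ids = sorted(out1.all_ids())
        assert ids == sorted(r.id for r in records)  # exact cover, no dups
        assert [c.member_ids for c in out1.clusters] == [c.member_ids for c in out2.clusters]
        assert out1.singletons == out2.singletons

    def test_raising_weight_threshold_never_adds_singletons(self):
        from threegold import synthetic

        cfg = synthetic.layout_config(5, 10, synthetic.PRESETS["pacbio"], seed=4)
        records, _, _ = synthetic.build_benchmark(cfg)
        n_singletons = []
        for wt in (2, 5, 8, 12):
            p = DistanceParams(tau=3, frameshift=4, weights=PACBIO_WEIGHTS,
                               weight_threshold=wt)
            n_singletons.append(len(cluster(records, p).singletons))
        assert n_singletons == sorted(n_singletons, reverse=True)

    def test_duplicate_ids_rejected(self):
        rs = [SequenceRecord("x", "ACGT"), SequenceRecord("x", "ACGT")]
        with pytest.raises(ValueError, match="duplicate"):
            cluster(rs, PACBIO)
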