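import math

import numpy as np
import pytest

from drgpop.errors import ValidationError
from drgpop.mcl import MclParams
from drgpop.network import (
    build_correlation_graph,
    cluster_membership_by_group,
    cluster_pipeline,
    filter_small_clusters,
    label_clusters,
    merge_clusters,
)
from drgpop.protocol import make_protocol
from drgpop.synth import PopulationConfig, simulate_population
from drgpop.traces import FeatureMatrix, build_feature_matrix, compute_dff_population

import pandas as pd


def _fm(rows, labels=None):
    ids = [f"c{i}" for i in range(len(rows))]
    labels = labels or [f"e{j}" for j in range(len(rows[0]))]
    return FeatureMatrix(ids, labels, np.asarray(rows, dtype=float))


class TestCorrelationGraph:
    def test_perfect_linear_relation_draws_edge(self):
        g = build_correlation_graph(_fm([[1, 2, 3, 4], [2, 4, 6, 8]]))
        assert g.has_edge("c0", "c1")
        assert g.edges["c0", "c1"]["r"] == pytest.approx(1.0)

    def test_anticorrelation_never_draws_edge(self):
        g = build_correlation_graph(_fm([[1, 2, 3, 4], [4, 3, 2, 1]]))
        assert g.number_of_edges() == 0

    def test_hand_computed_pearson_threshold(self):
        # r between (1,2,3,4) and (1,2,3,3.2) by the product-moment formula:
        x = np.array([1, 2, 3, 4.0])
        y = np.array([1, 2, 3, 3.2])
        r_hand = ((x - x.mean()) * (y - y.mean())).sum() / (
            math.sqrt(((x - x.mean()) ** 2).sum()) * math.sqrt(((y - y.mean()) ** 2).sum())
        )
        g = build_correlation_graph(_fm([x, y]), r_threshold=0.9)
        assert g.has_edge("c0", "c1") == (r_hand > 0.9)
        if g.has_edge("c0", "c1"):
            assert g.edges["c0", "c1"]["r"] == pytest.approx(r_hand)

    def test_zero_variance_cell_excluded(self):
        g = build_correlation_graph(_fm([[1, 2, 3, 4], [2, 4, 6, 8], [5, 5, 5, 5]]))
        assert g.graph["excluded"] == ["c2"]
        assert "c2" not in g

    def test_isolated_nodes_absent(self):
        g = build_correlation_graph(_fm([[1, 2, 3, 4], [2, 4, 6, 8], [4, 1, 5, 2]]))
        assert "c2" not in g  # uncorrelated with both others

    def test_too_few_cells_or_epochs_rejected(self):
        with pytest.raises(ValidationError):
            build_correlation_graph(_fm([[1, 2, 3]]))
        with pytest.raises(ValidationError):
            build_correlation_graph(_fm([[1, 2], [2, 4]]))


class TestFilterSmallClusters:
    def test_small_clusters_dissolved(self):
        clusters = [frozenset(range(12)), frozenset(range(20, 27)), frozenset({90, 91, 92})]
        kept, unclustered = filter_small_clusters(clusters, 5)
        assert [len(c) for c in kept] == [12, 7]
        assert unclustered == {90, 91, 92}

    def test_min_size_one_is_identity(self):
        clusters = [frozenset({1}), frozenset({2, 3})]
        kept, unclustered = filter_small_clusters(clusters, 1)
        assert kept == clusters and unclustered == set()

    def test_conservation(self):
        clusters = [frozenset({1, 2, 3}), frozenset({4}), frozenset({5, 6})]
        kept, unclustered = filter_small_clusters(clusters, 2)
        total = sum(len(c) for c in kept) + len(unclustered)
        assert total == 6


class TestMergeClusters:
    def test_identical_centroids_merge(self):
        fm = _fm([[1, 2, 3], [1, 2, 3], [1, 2, 3], [1, 2, 3]])
        res = merge_clusters([frozenset({"c0", "c1"}), frozenset({"c2", "c3"})], fm)
        assert res.n_clusters == 1
        assert len(res.merge_log) == 1

    def test_uncorrelated_centroids_do_not_merge(self):
        fm = _fm([[10, 0, 0, 1], [10, 0, 1, 0], [0, 1, 10, 3], [1, 0, 10, 3]])
        res = merge_clusters([frozenset({"c0", "c1"}), frozenset({"c2", "c3"})], fm)
        assert res.n_clusters == 2

    def test_merge_map_overrides_automation(self):
        fm = _fm([[10, 0, 0, 1], [10, 0, 1, 0], [0, 1, 10, 3], [1, 0, 10, 3]])
        res = merge_clusters(
            [frozenset({"c0", "c1"}), frozenset({"c2", "c3"})], fm, merge_map={1: 0}
        )
        assert res.n_clusters == 1
        assert res.merge_log[0]["rule"] == "map"

    def test_merge_map_unknown_id_rejected(self):
        fm = _fm([[1, 2, 3], [1, 2, 3]])
        with pytest.raises(ValidationError):
            merge_clusters([frozenset({"c0", "c1"})], fm, merge_map={5: 0})

    def test_centroid_is_member_mean(self):
        fm = _fm([[0, 0, 4], [0, 0, 8]])
        res = merge_clusters([frozenset({"c0", "c1"})], fm)
        np.testing.assert_allclose(res.centroids["C1"], [0, 0, 6])

    def test_split_archetypes_remerge(self, pressure_protocol):
        """Six raw clusters carved out of four tuning shapes collapse back
        to four after centroid merging."""
        rng = np.random.default_rng(0)
        shapes = {
            "ramp": np.linspace(20, 150, 8),
            "low": np.array([120, 60, 10, 2, 0, 0, 0, 0.0]),
            "mid": np.array([5, 30, 90, 140, 115, 50, 12, 2.0]),
            "high": np.array([0, 0, 0, 0, 0, 25, 100, 140.0]),
        }
        rows, raw_clusters, start = [], [], 0
        pieces = [("ramp", 6), ("ramp", 6), ("low", 5), ("mid", 5), ("mid", 7), ("high", 5)]
        for shape, k in pieces:
            for _ in range(k):
                rows.append(shapes[shape] + rng.normal(0, 1.0, 8))
            raw_clusters.append(frozenset(f"c{i}" for i in range(start, start + k)))
            start += k
        fm = _fm(rows, labels=list(pressure_protocol.stimulation_labels))
        res = merge_clusters(raw_clusters, fm)
        assert res.n_clusters == 4


class TestLabelClusters:
    def _result(self, centroid, pressure_protocol):
        fm = _fm([centroid, centroid], labels=list(pressure_protocol.stimulation_labels))
        res = merge_clusters([frozenset({"c0", "c1"})], fm)
        return label_clusters(res, pressure_protocol)

    def test_linear_centroid_is_ramp(self, pressure_protocol):
        res = self._result(list(np.arange(1.0, 9.0) * 15), pressure_protocol)
        assert res.labels["C1"] == "Ramp"

    def test_peak_200_poor_linear_fit_is_mid(self, pressure_protocol):
        res = self._result([5, 30, 90, 140, 115, 50, 12, 2], pressure_protocol)
        assert res.labels["C1"] == "Mid"

    def test_peak_50_is_low(self, pressure_protocol):
        res = self._result([120, 60, 10, 2, 0, 0, 0, 0], pressure_protocol)
        assert res.labels["C1"] == "Low"

    def test_peak_400_nonlinear_is_high(self, pressure_protocol):
        res = self._result([0, 0, 0, 0, 0, 25, 100, 140], pressure_protocol)
        assert res.labels["C1"] == "High"

    def test_zero_centroid_is_unknown(self, pressure_protocol):
        res = self._result([0, 0, 0, 0, 0, 0, 0, 0], pressure_protocol)
        assert res.labels["C1"] == "unknown"

    def test_movement_labels(self, movement_protocol):
        ext = [90, 3, 85, 3, 80, 3, 76, 3, 72, 2.0]
        flx = [3, 90, 3, 85, 3, 80, 3, 76, 2, 72.0]
        const = [90, 91, 88, 86, 83, 81, 78, 76, 74, 72.0]
        fm = _fm(
            [ext, ext, flx, flx, const, const],
            labels=[e.label for e in movement_protocol.stimulation_epochs],
        )
        clusters = [
            frozenset({"c0", "c1"}), frozenset({"c2", "c3"}), frozenset({"c4", "c5"}),
        ]
        res = label_clusters(merge_clusters(clusters, fm), movement_protocol)
        assert sorted(res.labels.values()) == ["Const", "Extension", "Flexion"]


class TestMembershipByGroup:
    def _setup(self, pressure_protocol):
        fm = _fm(
            [[1, 2, 3, 4, 5, 6, 7, 8.0]] * 6,
            labels=list(pressure_protocol.stimulation_labels),
        )
        res = merge_clusters([frozenset({"c0", "c1", "c2"}), frozenset({"c3", "c4", "c5"})],
                             fm, centroid_r_threshold=1.1)
        return res

    def test_all_sham_gives_zero_cibp_column(self, pressure_protocol):
        res = self._setup(pressure_protocol)
        records = pd.DataFrame(
            {"cell_id": [f"c{i}" for i in range(6)], "group": ["sham"] * 6}
        )
        table = cluster_membership_by_group(res, records)
        assert "n_CIBP" not in table.columns or (table["n_CIBP"] == 0).all()
        assert table["n_sham"].sum() == 6

    def test_counts_partition_clustered_cells(self, pressure_protocol):
        res = self._setup(pressure_protocol)
        records = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(6)],
                "group": ["sham", "sham", "CIBP", "CIBP", "CIBP", "sham"],
            }
        )
        table = cluster_membership_by_group(res, records)
        assert table["n_sham"].sum() == 3
        assert table["n_CIBP"].sum() == 3
        assert table["size"].sum() == 6

    def test_missing_group_label_rejected(self, pressure_protocol):
        res = self._setup(pressure_protocol)
        records = pd.DataFrame({"cell_id": ["c0"], "group": ["sham"]})
        with pytest.raises(ValidationError):
            cluster_membership_by_group(res, records)


def test_mid_cluster_enriched_in_cibp(pressure_protocol):
    """With the group mixtures (Mid enriched in CIBP), the CIBP percentage
    of the Mid cluster exceeds the sham percentage after clustering."""
    all_traces, truths = [], []
    for group, n in (("sham", 400), ("CIBP", 400)):
        cfg = PopulationConfig.compression(group, n, seed=33 if group == "sham" else 34)
        traces, truth = simulate_population(cfg, pressure_protocol)
        all_traces.extend(traces)
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True)
    dffs, _ = compute_dff_population(all_traces, pressure_protocol.baseline)
    responder_ids = set(truth.loc[truth["is_responder"], "cell_id"])
    fm = build_feature_matrix(
        [d for d in dffs if d.cell_id in responder_ids], pressure_protocol
    )
    res, _, _ = cluster_pipeline(fm, pressure_protocol)
    table = cluster_membership_by_group(res, truth)
    mid = table[table["label"] == "Mid"]
    assert len(mid) >= 1
    assert (mid["pct_CIBP"].sum()) > (mid["pct_sham"].sum())
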