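"""Pair clustering, type assignment, embedding and heat-map ordering."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

import twinupv as tw
from twinupv.cohort import DiscordanceMatrix, Orientation
from twinupv.errors import ConfigurationError, InsufficientDataError

from conftest import mz_discordance, truth_groups


def matrix_from_values(values: pd.DataFrame) -> DiscordanceMatrix:
    tab = pd.DataFrame(
        {
            "light": [f"{p}a" for p in values.index],
            "heavy": [f"{p}b" for p in values.index],
            "tie": False,
        },
        index=values.index,
    )
    return DiscordanceMatrix(values, Orientation(tab), "e")


class TestClusterPairs:
    def test_recovery_on_planted_groups(self, default_cohort, default_oriented):
        ori, Dmz = default_oriented
        labels = tw.cluster_cotwin_pairs(Dmz, k_neighbors=20, resolution=0.8, seed=0)
        truth = truth_groups(default_cohort, labels.index)
        assert adjusted_rand_score(truth, labels) >= 0.8

    def test_determinism(self, default_oriented):
        _, Dmz = default_oriented
        a = tw.cluster_cotwin_pairs(Dmz, seed=3)
        b = tw.cluster_cotwin_pairs(Dmz, seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_duplicated_rows_cocluster(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, size=(40, 6))
        base[:20] += 4.0
        base[38] = base[0]
        base[39] = base[0]
        values = pd.DataFrame(base, index=[f"P{i}" for i in range(40)])
        labels = tw.cluster_cotwin_pairs(matrix_from_values(values), k_neighbors=5)
        assert labels.loc["P38"] == labels.loc["P39"] == labels.loc["P0"]

    def test_insufficient_pairs(self):
        values = pd.DataFrame(np.zeros((4, 3)), index=[f"P{i}" for i in range(4)])
        with pytest.raises(InsufficientDataError, match="insufficient pairs"):
            tw.cluster_cotwin_pairs(matrix_from_values(values), k_neighbors=10)

    def test_missing_cells_rejected(self, small_oriented):
        _, Dmz = small_oriented
        vals = Dmz.values.copy()
        vals.iloc[0, 0] = np.nan
        with pytest.raises(ConfigurationError):
            tw.cluster_cotwin_pairs(DiscordanceMatrix(vals, Dmz.orientation, "e"))

    def test_zero_effect_reports_no_stable_structure(self):
        cfg = tw.SimulationConfig(
            n_pairs_per_group={g: 20 for g in tw.simulate.GROUPS},
            n_dz_pairs=0,
            n_genes=10,
            n_signature_genes=2,
            hdac_set_size=2,
            effect_fat=0.0,
            effect_lean=0.0,
            seed=21,
        )
        cohort = tw.simulate_twin_cohort(cfg)
        _, Dmz = mz_discordance(cohort)
        res = tw.cluster_stability_null(Dmz, k_neighbors=10, seed=0, n_null=15)
        assert not res["stable"]
        assert res["n_stable_clusters"] == 1

    def test_planted_effects_are_stable(self, default_oriented):
        _, Dmz = default_oriented
        res = tw.cluster_stability_null(Dmz, seed=0, n_null=10)
        assert res["stable"]
        assert res["n_stable_clusters"] >= 4


class TestModularityOracle:
    def test_two_cliques_recovered_and_optimal(self):
        """Louvain on two 6-cliques joined by one edge finds the cliques.

        Oracle: exhaustive search over all partitions of the 12 nodes into
        at most 3 blocks (restricted growth strings) shows the two-clique
        split maximizes modularity, and the pipeline's community step
        returns exactly that split.
        """
        g = nx.Graph()
        for off in (0, 6):
            for i, j in itertools.combinations(range(off, off + 6), 2):
                g.add_edge(i, j, weight=1.0)
        g.add_edge(0, 6, weight=1.0)

        best_q, best_parts = -1.0, None
        nodes = list(range(12))

        def partitions_upto_3(n):
            labels = [0] * n
            def rec(i, used):
                if i == n:
                    yield tuple(labels)
                    return
                for lab in range(min(used + 1, 3)):
                    labels[i] = lab
                    yield from rec(i + 1, max(used, lab + 1))
            yield from rec(1, 1)  # node 0 fixed in block 0 (canonical form)

        for assignment in partitions_upto_3(12):
            blocks = {}
            for node, lab in zip(nodes, (0,) + assignment[1:] if len(assignment) == 12 else assignment):
                blocks.setdefault(lab, set()).add(node)
            q = nx.community.modularity(g, blocks.values(), weight="weight")
            if q > best_q:
                best_q, best_parts = q, [frozenset(b) for b in blocks.values()]

        cliques = {frozenset(range(6)), frozenset(range(6, 12))}
        assert set(best_parts) == cliques
        found = nx.community.louvain_communities(g, weight="weight", seed=0)
        assert {frozenset(c) for c in found} == cliques
        q_found = nx.community.modularity(g, found, weight="weight")
        assert q_found == pytest.approx(best_q, abs=1e-12)


class TestAssignTypes:
    @staticmethod
    def _centroid_matrix():
        """Four 2-row clusters matching the rule-application example."""
        fat, lean = ["fat_mass_a"], ["lean_mass_a"]
        rows, labels = [], []
        for cid, (mf, ml) in enumerate(
            [(0.01, 0.00), (0.30, -0.05), (0.35, 0.20), (0.20, 0.06)]
        ):
            for r in range(2):
                rows.append({"fat_mass_a": mf, "lean_mass_a": ml})
                labels.append(cid)
        values = pd.DataFrame(rows, index=[f"P{i}" for i in range(len(rows))])
        D = matrix_from_values(values)
        labels = pd.Series(labels, index=values.index)
        return D, labels, fat, lean

    def test_rule_application_example(self):
        D, labels, fat, lean = self._centroid_matrix()
        cl = tw.assign_cluster_types(labels, D, fat, lean, tau_lean=0.1)
        assert cl.cluster_types == {
            0: "Concordant", 1: "TypeA", 2: "TypeB", 3: "Intermediate",
        }

    def test_single_cluster_is_concordant(self):
        values = pd.DataFrame(
            np.random.default_rng(0).normal(0.3, 0.05, size=(6, 2)),
            columns=["fat_mass_a", "lean_mass_a"],
            index=[f"P{i}" for i in range(6)],
        )
        labels = pd.Series(0, index=values.index)
        cl = tw.assign_cluster_types(
            labels, matrix_from_values(values), ["fat_mass_a"], ["lean_mass_a"]
        )
        assert cl.cluster_types == {0: "Concordant"}

    def test_exactly_one_typeb(self):
        fat, lean = ["fat_mass_a"], ["lean_mass_a"]
        rows, labels = [], []
        for cid, (mf, ml) in enumerate([(0.0, 0.0), (0.35, 0.20), (0.20, 0.15)]):
            for r in range(2):
                rows.append({"fat_mass_a": mf, "lean_mass_a": ml})
                labels.append(cid)
        values = pd.DataFrame(rows, index=[f"P{i}" for i in range(len(rows))])
        cl = tw.assign_cluster_types(
            pd.Series(labels, index=values.index),
            matrix_from_values(values), fat, lean, tau_lean=0.1,
        )
        types = list(cl.cluster_types.values())
        assert types.count("TypeB") == 1
        assert cl.cluster_types[1] == "TypeB"
        assert cl.cluster_types[2] == "Intermediate"

    def test_idempotent_and_order_invariant(self, default_oriented, default_cohort):
        _, Dmz = default_oriented
        labels = tw.cluster_cotwin_pairs(Dmz, seed=0)
        fat, lean = tw.default_trait_tags()
        cl1 = tw.assign_cluster_types(labels, Dmz, fat, lean)
        perm = np.random.default_rng(1).permutation(len(labels))
        shuffled = DiscordanceMatrix(
            Dmz.values.iloc[perm],
            Orientation(Dmz.orientation.table.iloc[perm]),
            "e",
        )
        cl2 = tw.assign_cluster_types(labels.iloc[perm], shuffled, fat, lean)
        assert cl1.cluster_types == cl2.cluster_types
        pd.testing.assert_series_equal(
            cl1.pair_types.sort_index(), cl2.pair_types.sort_index()
        )

    def test_no_tags_is_error(self, small_oriented):
        _, Dmz = small_oriented
        labels = pd.Series(0, index=Dmz.values.index)
        with pytest.raises(ConfigurationError):
            tw.assign_cluster_types(labels, Dmz, ["absent"], ["alsoabsent"])


class TestHeatmapOrder:
    def test_identical_rows_merge_at_zero(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [5.0, 1.0, 0.0]],
            index=["P0", "P1", "P2"],
        )
        order = tw.heatmap_order(values, scale_rows=False)
        assert order.row_linkage[0, 2] == 0.0  # first merge height
        merged = {int(order.row_linkage[0, 0]), int(order.row_linkage[0, 1])}
        assert merged == {0, 1}

    def test_complete_linkage_hand_computed(self):
        """1-D points 0, 1, 10: merges {0,1} at height 1, then at 10."""
        values = pd.DataFrame({"x": [0.0, 1.0, 10.0]}, index=["a", "b", "c"])
        order = tw.heatmap_order(values, scale_rows=False)
        heights = order.row_linkage[:, 2]
        np.testing.assert_allclose(heights, [1.0, 10.0])

    def test_row_permutation_same_topology(self, small_oriented):
        _, Dmz = small_oriented
        o1 = tw.heatmap_order(Dmz)
        perm = np.random.default_rng(0).permutation(len(Dmz.values))
        shuffled = Dmz.values.iloc[perm]
        o2 = tw.heatmap_order(shuffled, scale_rows=True)
        np.testing.assert_allclose(
            np.sort(o1.row_linkage[:, 2]), np.sort(o2.row_linkage[:, 2]), rtol=1e-9
        )

    def test_constant_row_scaled_to_zeros(self, caplog):
        values = pd.DataFrame(
            [[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [3.0, 1.0, 2.0]],
            index=["a", "b", "c"],
        )
        order = tw.heatmap_order(values, scale_rows=True)
        assert (order.scaled.loc["a"] == 0).all()


class TestEmbedding:
    def test_determinism_and_identical_rows(self, small_oriented):
        _, Dmz = small_oriented
        vals = Dmz.values.copy()
        vals.iloc[1] = vals.iloc[0]
        D = DiscordanceMatrix(vals, Dmz.orientation, "e")
        e1 = tw.embed_pairs(D, n_neighbors=10, seed=0)
        e2 = tw.embed_pairs(D, n_neighbors=10, seed=0)
        pd.testing.assert_frame_equal(e1, e2)
        gap = np.linalg.norm(e1.iloc[0] - e1.iloc[1])
        spread = np.linalg.norm(e1.to_numpy().std(axis=0))
        assert gap < 0.1 * spread

    def test_planted_groups_positive_silhouette(self, default_cohort, default_oriented):
        _, Dmz = default_oriented
        emb = tw.embed_pairs(Dmz, n_neighbors=15, seed=0)
        truth = truth_groups(default_cohort, emb.index)
        assert silhouette_score(emb.to_numpy(), truth.to_numpy()) > 0

    def test_too_many_neighbors(self, small_oriented):
        _, Dmz = small_oriented
        with pytest.raises(InsufficientDataError):
            tw.embed_pairs(Dmz, n_neighbors=len(Dmz.pairs))
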