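"""Distance computation and neighbor-joining inference, checked against
closed forms, an exhaustive least-squares oracle, dendropy's independent
NJ implementation and hypothesis-driven additive-matrix recovery."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treescan.mafio import ScanConfig
from treescan.tree import bipartitions, patristic_distance
from treescan.trees import (
    bootstrap_tree,
    build_tree,
    infer_window,
    jc_correct,
    least_squares_tree,
    neighbor_joining,
    pairwise_distances,
    random_additive_tree,
)


class TestPairwiseDistances:
    def test_identical_sequences_distance_zero(self, make_window):
        w = make_window({"a": "ACGTACGT", "b": "ACGTACGT"})
        res = pairwise_distances(w)
        assert res.matrix[0, 1] == 0.0

    def test_matches_closed_form_on_random_pair(self, make_window):
        rng = np.random.default_rng(3)
        a_arr = rng.choice(list("ACGT-"), size=500)
        b_arr = a_arr.copy()
        mut = rng.random(500) < 0.12  # divergent but far from saturation
        b_arr[mut] = rng.choice(list("ACGT"), size=int(mut.sum()))
        a, b = "".join(a_arr), "".join(b_arr)
        w = make_window({"a": a, "b": b}, end=500)
        res = pairwise_distances(w, min_determined_frac=0.0)
        shared = [
            i for i in range(500) if a[i] in "ACGT" and b[i] in "ACGT"
        ]
        p = sum(a[i] != b[i] for i in shared) / len(shared)
        expect = -0.75 * np.log(1 - 4 * p / 3)
        assert res.matrix[0, 1] == pytest.approx(expect)

    def test_saturation_flagged(self, make_window):
        # complementary sequences: p-distance 1.0 >= 0.75
        w = make_window({"a": "ACGT" * 10, "b": "TGCA" * 10})
        res = pairwise_distances(w)
        assert np.isnan(res.matrix[0, 1])
        assert frozenset(("a", "b")) in res.saturated

    def test_large_finite_distance_below_saturation(self):
        p = 0.74
        d = jc_correct(np.array([p]))[0]
        assert np.isfinite(d) and d > 2.0
        assert np.isnan(jc_correct(np.array([0.75]))[0])

    def test_no_shared_columns_flagged_missing(self, make_window):
        w = make_window({"a": "AAAA----", "b": "----CCCC"})
        res = pairwise_distances(w, min_determined_frac=0.0)
        assert frozenset(("a", "b")) in res.missing

    def test_gappy_taxon_dropped(self, make_window):
        w = make_window({"a": "ACGTACGT", "b": "ACGTACGT", "c": "AC------"})
        res = pairwise_distances(w, min_determined_frac=0.5)
        assert res.dropped == ["c"]
        assert res.taxa == ["a", "b"]


class TestNeighborJoining:
    def test_four_taxon_additive_recovery_vs_exhaustive_ls(self):
        rng = np.random.default_rng(8)
        labels = ["A", "B", "C", "D"]
        for _ in range(20):
            true, D = random_additive_tree(labels, rng)
            nj = neighbor_joining(labels, D)
            ls = least_squares_tree(labels, D)
            assert bipartitions(nj) == bipartitions(true) == bipartitions(ls)

    def test_ultrametric_exact_branch_length_recovery(self):
        # cherry (A,B) at height 1, C at height 2, D outgroup at height 3
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0.0, 2.0, 4.0, 6.0],
                [2.0, 0.0, 4.0, 6.0],
                [4.0, 4.0, 0.0, 6.0],
                [6.0, 6.0, 6.0, 0.0],
            ]
        )
        nj = neighbor_joining(labels, D)
        for i in range(4):
            for j in range(i + 1, 4):
                assert patristic_distance(nj, labels[i], labels[j]) == pytest.approx(
                    D[i, j]
                )

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(21)
        labels = [f"T{i}" for i in range(7)]
        _, D = random_additive_tree(labels, rng)
        base = neighbor_joining(labels, D)
        for _ in range(5):
            perm = rng.permutation(7)
            permuted = neighbor_joining(
                [labels[i] for i in perm], D[np.ix_(perm, perm)]
            )
            assert bipartitions(permuted) == bipartitions(base)

    def test_matches_dendropy_nj_topology(self):
        rng = np.random.default_rng(30)
        labels = [f"T{i}" for i in range(8)]
        _, D = random_additive_tree(labels, rng)
        nj = neighbor_joining(labels, D)
        csv = "," + ",".join(labels) + "\n"
        for i, lab in enumerate(labels):
            csv += lab + "," + ",".join(str(D[i, j]) for j in range(8)) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv)
        )
        dtree = pdm.nj_tree()
        dsplits = set()
        leaves = set(labels)
        anchor = min(leaves)
        for node in dtree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if anchor in side:
                side = frozenset(leaves - side)
            if 1 < len(side) < len(leaves) - 1:
                dsplits.add(side)
        assert bipartitions(nj) == dsplits

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(5, 9), st.integers(0, 10_000))
    def test_additive_matrix_consistency_property(self, n, seed):
        """NJ recovers the generating topology from any additive matrix."""
        labels = [f"T{i}" for i in range(n)]
        true, D = random_additive_tree(labels, np.random.default_rng(seed))
        nj = neighbor_joining(labels, D)
        assert bipartitions(nj) == bipartitions(true)

    def test_negative_branch_clamped_with_deficit_to_sibling(self):
        # matrix engineered to give one negative NJ branch estimate
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0.0, 0.1, 1.0, 1.05],
                [0.1, 0.0, 1.05, 1.0],
                [1.0, 1.05, 0.0, 0.2],
                [1.05, 1.0, 0.2, 0.0],
            ]
        )
        nj = neighbor_joining(labels, D)
        for node in nj.iter_nodes():
            if node is not nj:
                assert node.length >= 0.0

    def test_missing_entries_rejected(self):
        D = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            neighbor_joining(["a", "b"], D)


class TestRooting:
    def test_outgroup_is_child_of_root(self):
        rng = np.random.default_rng(2)
        labels = [f"T{i}" for i in range(6)]
        _, D = random_additive_tree(labels, rng)
        rooted = build_tree(labels, D, outgroup="T4")
        assert any(c.is_leaf and c.name == "T4" for c in rooted.children)


class TestBootstrap:
    def _clean_window(self, make_window, length=2000):
        # four taxa with unambiguous signal: AB share derived states, CD too
        rng = np.random.default_rng(1)
        anc = rng.choice(list("ACGT"), size=length)
        a = anc.copy()
        b = anc.copy()
        c = anc.copy()
        d = anc.copy()
        sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
        idx_ab = rng.choice(length, size=200, replace=False)
        for i in idx_ab[:100]:
            a[i] = b[i] = sub[anc[i]]
        for i in idx_ab[100:]:
            c[i] = d[i] = sub[anc[i]]
        rows = {
            "a": "".join(a),
            "b": "".join(b),
            "c": "".join(c),
            "d": "".join(d),
        }
        return make_window(rows, end=length)

    def test_clean_signal_gives_full_support(self, make_window):
        w = self._clean_window(make_window)
        wt = bootstrap_tree(w, n_reps=100, outgroup="d", seed=5)
        supports = [
            n.support for n in wt.tree.iter_nodes() if n.support is not None
        ]
        assert supports and all(s == 100 for s in supports)

    def test_single_replicate_supports_binary(self, make_window):
        w = self._clean_window(make_window)
        wt = bootstrap_tree(w, n_reps=1, outgroup="d", seed=5)
        supports = [
            n.support for n in wt.tree.iter_nodes() if n.support is not None
        ]
        assert supports and set(supports) <= {0, 100}

    def test_same_seed_reproducible(self, make_window):
        w = self._clean_window(make_window)
        n1 = bootstrap_tree(w, 50, "d", seed=9).newick()
        n2 = bootstrap_tree(w, 50, "d", seed=9).newick()
        assert n1 == n2


class TestInferWindow:
    def test_missing_required_taxon_skips(self, small_sim, scan_cfg):
        from treescan.mafio import partition_windows

        _, blocks, _ = small_sim
        win = partition_windows(blocks, scan_cfg)[0]
        cfg = ScanConfig(
            focal="fontenillei", expected_sister="bwambae", outgroup="absent_taxon"
        )
        wt, reason = infer_window(win, cfg, n_boot=1, seed=0)
        assert wt is None and "absent_taxon" in reason
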