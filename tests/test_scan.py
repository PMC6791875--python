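"""Topology canonicalization, tallying, relationship classification
(against a brute-force clade-enumeration oracle), block segmentation and
regional contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from treescan.mafio import ScanConfig
from treescan.scan import (
    RelationshipCall,
    canonicalize,
    classify_window,
    region_contrast,
    segment_blocks,
    sister_fraction,
    tally_topologies,
)
from treescan.tree import Clade, reroot_on_outgroup
from treescan.trees import WindowTree, random_additive_tree


def call(chrom, start, end, sister_ok, label, topo="t"):
    return RelationshipCall(
        window_id=f"{chrom}:{start}-{end}",
        chrom=chrom,
        start=start,
        end=end,
        sister_ok=sister_ok,
        after_label=label if sister_ok else None,
        before_label=None if sister_ok else label,
        canonical=topo,
    )


def wtree(newick, chrom="X", start=0, end=50_000):
    t = Clade.from_newick(newick)
    return WindowTree(
        window_id=f"{chrom}:{start}-{end}",
        chrom=chrom,
        start=start,
        end=end,
        tree=t,
        taxa=sorted(t.leaf_names()),
    )


@pytest.fixture
def cfg():
    return ScanConfig(
        focal="F",
        expected_sister="B",
        outgroup="O",
        clade_definitions={"GC": {"G", "C"}, "A(GC)": {"A", "G", "C"}},
    )


class TestCanonical:
    def test_child_order_irrelevant(self):
        a = Clade.from_newick("((B:1,F:1):1,Q:1);")
        b = Clade.from_newick("((F:1,B:1):2,Q:3);")
        assert canonicalize(a) == canonicalize(b)

    def test_outgroup_dropping(self):
        t = Clade.from_newick("(O:1,((F:1,B:1):1,Q:1):1);")
        assert canonicalize(t, outgroup="O") == "((B,F),Q)"

    def test_all_rootings_of_a_quartet_distinct_with_outgroup_kept(self):
        """Rooting a fixed unrooted quartet on each of its edges changes the
        rooted canonical string (enumerated over all 5 edges)."""
        base = Clade.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        strings = set()
        for leaf in ["A", "B", "C", "D"]:
            strings.add(canonicalize(reroot_on_outgroup(base, leaf)))
        assert len(strings) == 4


class TestTally:
    def test_x_chromosome_arithmetic(self):
        """264 sister-positive of 319 retained windows -> 82.8%."""
        calls = [call("X", i * 50_000, (i + 1) * 50_000, i < 264, "Q") for i in range(319)]
        ok, total, pct = sister_fraction(calls)
        assert (ok, total, pct) == (264, 319, 82.8)

    def test_empty_input(self):
        assert tally_topologies([]).empty

    def test_counts_match_dict_oracle(self):
        rng = np.random.default_rng(0)
        topos = ["((B,F),Q)", "((F,G),B)", "((B,F),(C,G))"]
        calls = []
        for i in range(200):
            t = topos[rng.integers(3)]
            c = call("2L" if i % 2 else "3L", i * 100, i * 100 + 100, True, "x", t)
            calls.append(c)
        df = tally_topologies(calls)
        oracle = {}
        for c in calls:
            oracle[c.canonical] = oracle.get(c.canonical, 0) + 1
        gw = df[df["chrom"] == "genome-wide"].set_index("topology")["count"]
        assert dict(gw) == oracle
        assert gw.sum() == 200
        # per-chromosome counts also sum to the total
        assert df[df["chrom"] != "genome-wide"]["count"].sum() == 200


class TestClassify:
    def test_after_speciation_with_named_sister(self, cfg):
        wt = wtree("(O:1,(((F:1,B:1):1,Q:1):1,(G:1,C:1):1):1);")
        c = classify_window(wt, cfg)
        assert c.sister_ok and c.after_label == "Q" and c.before_label is None

    def test_after_speciation_with_clade_mapping(self, cfg):
        wt = wtree("(O:1,((F:1,B:1):1,(G:1,C:1):1):1);")
        c = classify_window(wt, cfg)
        assert c.sister_ok and c.after_label == "GC"

    def test_before_speciation(self, cfg):
        wt = wtree("(O:1,((F:1,G:1):1,(B:1,Q:1):1):1);")
        c = classify_window(wt, cfg)
        assert not c.sister_ok and c.before_label == "G"
        assert c.after_label is None

    def test_missing_required_taxon_raises(self, cfg):
        wt = wtree("(O:1,((F:1,G:1):1,Q:1):1);")
        with pytest.raises(KeyError):
            classify_window(wt, cfg)

    def test_against_clade_enumeration_oracle(self, cfg):
        """On random trees, sister_ok and the reported neighbour agree with
        a brute-force enumeration of all clades of the ingroup tree."""
        rng = np.random.default_rng(44)
        labels = ["F", "B", "Q", "A", "G", "C", "O"]
        for _ in range(200):
            unrooted, _ = random_additive_tree(labels, rng)
            rooted = reroot_on_outgroup(unrooted, "O")
            wt = WindowTree("w", "X", 0, 1, rooted, sorted(labels))
            c = classify_window(wt, cfg)
            from treescan.tree import drop_leaf

            ingroup = drop_leaf(rooted, "O")
            clades = [
                n.leaf_set() for n in ingroup.iter_nodes() if not n.is_leaf
            ]
            assert c.sister_ok == (frozenset("FB") in clades)
            if c.sister_ok:
                # smallest clade strictly containing {F,B}
                container = min(
                    (s for s in clades if frozenset("FB") < s), key=len,
                    default=ingroup.leaf_set(),
                )
                expect = container - frozenset("FB")
            else:
                container = min(
                    (
                        s
                        for s in clades + [ingroup.leaf_set()]
                        if "F" in s and len(s) > 1
                    ),
                    key=len,
                )
                expect = container - {"F"}
            got = c.after_label if c.sister_ok else c.before_label
            for name, members in cfg.clade_definitions.items():
                if expect == members:
                    expect_label = name
                    break
            else:
                expect_label = (
                    next(iter(expect)) if len(expect) == 1 else "+".join(sorted(expect))
                )
            assert got == expect_label


class TestSegmentBlocks:
    def test_uniform_sequence_single_block(self):
        calls = [call("X", i * 10, i * 10 + 10, True, "Q") for i in range(4)]
        (blk,) = segment_blocks(calls)
        assert blk.n_windows == 4
        assert blk.left_breakpoint is None and blk.right_breakpoint is None

    def test_transitions_give_breakpoints(self):
        labels = ["Q", "Q", "G", "G", "Q"]
        calls = [
            call("X", i * 10, i * 10 + 10, True, lab)
            for i, lab in enumerate(labels)
        ]
        blocks = segment_blocks(calls, min_run=1)
        assert [b.label for b in blocks] == ["A:Q", "A:G", "A:Q"]
        assert blocks[0].right_breakpoint == (20, 20)
        assert blocks[1].left_breakpoint == (20, 20)
        assert blocks[1].right_breakpoint == (40, 40)

    def test_short_runs_absorbed_by_min_run(self):
        labels = ["Q", "Q", "Q", "G", "Q", "Q"]
        calls = [
            call("X", i * 10, i * 10 + 10, True, lab)
            for i, lab in enumerate(labels)
        ]
        blocks = segment_blocks(calls, min_run=2)
        assert [b.label for b in blocks] == ["A:Q"]
        assert blocks[0].n_windows == 6

    def test_window_count_conserved(self):
        rng = np.random.default_rng(1)
        calls = []
        for chrom in ("2L", "3L"):
            for i in range(30):
                calls.append(
                    call(chrom, i * 10, i * 10 + 10, True, rng.choice(["Q", "G"]))
                )
        blocks = segment_blocks(calls, min_run=1)
        for chrom in ("2L", "3L"):
            assert sum(b.n_windows for b in blocks if b.chrom == chrom) == 30


class TestRegionContrast:
    def test_proportions_match_hand_count(self):
        calls = (
            [call("2L", i * 10, i * 10 + 10, True, "Q") for i in range(6)]
            + [call("2L", (6 + i) * 10, (7 + i) * 10, False, "G") for i in range(4)]
        )
        regions = {"centromere": [("2L", 0, 60)]}
        rc = region_contrast(calls, regions, n_sample=3, seed=0)
        assert rc.counts.loc["centromere", "A:Q"] == 6
        assert rc.counts.loc["other", "B:G"] == 4
        assert rc.proportions.loc["centromere", "A:Q"] == 1.0

    def test_overlapping_regions_rejected(self):
        calls = [call("2L", 0, 10, True, "Q")]
        with pytest.raises(ValueError):
            region_contrast(
                calls,
                {"a": [("2L", 0, 50)], "b": [("2L", 40, 90)]},
            )

    def test_subsample_reproducible_under_seed(self):
        calls = [call("2L", i * 10, i * 10 + 10, True, "Q") for i in range(50)]
        regions = {"left": [("2L", 0, 250)]}
        s1 = region_contrast(calls, regions, n_sample=5, seed=7).sampled
        s2 = region_contrast(calls, regions, n_sample=5, seed=7).sampled
        s3 = region_contrast(calls, regions, n_sample=5, seed=8).sampled
        assert s1 == s2
        assert s1 != s3
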