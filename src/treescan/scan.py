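"""Topology canonicalization, tallying, per-window relationship calls, and
segmentation of chromosomes into topology blocks.

The relationship call mirrors how a focal taxon's placement is read off a
window tree: either the focal taxon and its expected sister form a clade
("after speciation": the interesting quantity is that clade's sister group),
or they do not ("before speciation": the focal taxon's own sister group is
reported).  Runs of equal calls along a chromosome form topology blocks whose
boundaries estimate inversion or introgression breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .mafio import AlignmentWindow, ScanConfig, alignment_stats
from .tree import Clade, canonical_topology as _canon_string, drop_leaf
from .trees import WindowTree


@dataclass
class RelationshipCall:
    window_id: str
    chrom: str
    start: int
    end: int
    sister_ok: bool
    after_label: Optional[str]  # sister group of the (focal, sister) clade
    before_label: Optional[str]  # sister group of the focal taxon alone
    canonical: str  # canonical ingroup topology string
    ambiguous: bool = False

    def __post_init__(self):
        if self.sister_ok and self.before_label is not None:
            raise ValueError("sister_ok call cannot carry a before_label")
        if not self.sister_ok and self.after_label is not None:
            raise ValueError("non-sister call cannot carry an after_label")

    @property
    def class_label(self) -> str:
        return f"A:{self.after_label}" if self.sister_ok else f"B:{self.before_label}"


@dataclass
class TopologyBlock:
    chrom: str
    start: int  # start of first window in the block
    end: int  # end of last window in the block
    label: str
    n_windows: int
    left_breakpoint: Optional[tuple[int, int]] = None
    right_breakpoint: Optional[tuple[int, int]] = None


def canonicalize(tree: Clade, outgroup: Optional[str] = None) -> str:
    """Canonical topology string: branch lengths and supports stripped,
    children sorted recursively by smallest leaf label.  If `outgroup` is
    given it is removed first (ingroup topology)."""
    t = tree
    if outgroup is not None:
        t = drop_leaf(t, outgroup)
    return _canon_string(t)


def _label_for(leaves: frozenset[str], config: ScanConfig) -> str:
    for name, members in config.clade_definitions.items():
        if leaves == members:
            return name
    if len(leaves) == 1:
        return next(iter(leaves))
    return "+".join(sorted(leaves))


def classify_window(wtree: WindowTree, config: ScanConfig) -> RelationshipCall:
    """Relationship call for the focal taxon on an outgroup-rooted tree.

    `sister_ok` holds iff {focal, expected_sister} is exactly a clade of the
    ingroup tree (outgroup removed after rooting).  The reported neighbour
    is the smallest sister clade, mapped to a configured clade name when its
    leaf set matches one.  Multifurcating sister groups are reported as the
    union and flagged ambiguous.
    """
    required = {config.focal, config.expected_sister, config.outgroup}
    present = wtree.tree.leaf_set()
    if not required <= present:
        raise KeyError(f"required taxa absent: {sorted(required - present)}")
    ingroup = drop_leaf(wtree.tree, config.outgroup)
    pair = frozenset((config.focal, config.expected_sister))

    parents: dict[int, Optional[Clade]] = {id(ingroup): None}
    for n in ingroup.iter_nodes():
        for c in n.children:
            parents[id(c)] = n

    def sister_group(node: Clade) -> tuple[frozenset[str], bool]:
        par = parents[id(node)]
        if par is None:
            return frozenset(), True
        others = [c for c in par.children if c is not node]
        leaves = frozenset().union(*(c.leaf_set() for c in others))
        return leaves, len(others) > 1

    target = None
    for n in ingroup.iter_nodes():
        if not n.is_leaf and n.leaf_set() == pair:
            target = n
            break

    if target is not None:
        leaves, ambiguous = sister_group(target)
        label = _label_for(leaves, config) if leaves else ""
        return RelationshipCall(
            window_id=wtree.window_id,
            chrom=wtree.chrom,
            start=wtree.start,
            end=wtree.end,
            sister_ok=True,
            after_label=label,
            before_label=None,
            canonical=canonicalize(wtree.tree, config.outgroup),
            ambiguous=ambiguous or not leaves,
        )
    focal_leaf = ingroup.find_leaf(config.focal)
    leaves, ambiguous = sister_group(focal_leaf)
    label = _label_for(leaves, config) if leaves else ""
    return RelationshipCall(
        window_id=wtree.window_id,
        chrom=wtree.chrom,
        start=wtree.start,
        end=wtree.end,
        sister_ok=False,
        after_label=None,
        before_label=label,
        canonical=canonicalize(wtree.tree, config.outgroup),
        ambiguous=ambiguous or not leaves,
    )


def tally_topologies(calls: list[RelationshipCall]) -> pd.DataFrame:
    """Counts and percentages (to 0.1) of canonical topologies, per
    chromosome and genome-wide (chrom = "genome-wide")."""
    if not calls:
        return pd.DataFrame(columns=["chrom", "topology", "count", "percent"])
    rows = [(c.chrom, c.canonical) for c in calls]
    df = pd.DataFrame(rows, columns=["chrom", "topology"])
    out = []
    for scope, sub in [("genome-wide", df)] + [
        (ch, g) for ch, g in df.groupby("chrom", sort=True)
    ]:
        counts = sub["topology"].value_counts()
        total = len(sub)
        for topo, cnt in counts.items():
            out.append((scope, topo, int(cnt), round(100.0 * cnt / total, 1)))
    return pd.DataFrame(out, columns=["chrom", "topology", "count", "percent"])


def sister_fraction(calls: list[RelationshipCall]) -> tuple[int, int, float]:
    """(n_sister_ok, n_total, percent-to-0.1) over the given calls."""
    total = len(calls)
    ok = sum(c.sister_ok for c in calls)
    pct = round(100.0 * ok / total, 1) if total else float("nan")
    return ok, total, pct


def segment_blocks(
    calls: list[RelationshipCall], min_run: int = 1
) -> list[TopologyBlock]:
    """Maximal runs of equal relationship class along each chromosome.

    Runs shorter than `min_run` are absorbed into the larger flanking run
    (ties go left) before blocks are finalised.  Breakpoint intervals span
    the gap between the last window of one block and the first window of
    the next (empty when windows are contiguous).
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    blocks: list[TopologyBlock] = []
    by_chrom: dict[str, list[RelationshipCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        cs = sorted(by_chrom[chrom], key=lambda c: c.start)
        labels = [c.class_label for c in cs]

        def build_runs(lbls: list[str]) -> list[tuple[int, int, str]]:
            runs: list[tuple[int, int, str]] = []  # (first, last, label)
            for i, lbl in enumerate(lbls):
                if runs and runs[-1][2] == lbl:
                    runs[-1] = (runs[-1][0], i, lbl)
                else:
                    runs.append((i, i, lbl))
            return runs

        runs = build_runs(labels)
        # absorb runs shorter than min_run into the larger neighbour
        # (ties -> left) until stable
        while len(runs) > 1:
            short = next(
                (i for i, (a, b, _) in enumerate(runs) if b - a + 1 < min_run), None
            )
            if short is None:
                break
            a, b, _ = runs[short]
            left = runs[short - 1] if short > 0 else None
            right = runs[short + 1] if short + 1 < len(runs) else None
            if right is None or (
                left is not None
                and (left[1] - left[0]) >= (right[1] - right[0])
            ):
                new_label = left[2]
            else:
                new_label = right[2]
            for i in range(a, b + 1):
                labels[i] = new_label
            runs = build_runs(labels)
        chrom_blocks = []
        for a, b, lbl in runs:
            chrom_blocks.append(
                TopologyBlock(
                    chrom=chrom,
                    start=cs[a].start,
                    end=cs[b].end,
                    label=lbl,
                    n_windows=b - a + 1,
                )
            )
        for i, blk in enumerate(chrom_blocks):
            if i > 0:
                blk.left_breakpoint = (chrom_blocks[i - 1].end, blk.start)
            if i + 1 < len(chrom_blocks):
                blk.right_breakpoint = (blk.end, chrom_blocks[i + 1].start)
        blocks.extend(chrom_blocks)
    return blocks


# ---------------------------------------------------------------------------
# regional contrast
# ---------------------------------------------------------------------------


@dataclass
class RegionContrast:
    proportions: pd.DataFrame  # region x class_label proportions
    counts: pd.DataFrame
    sampled: dict[str, list[str]]  # region -> sampled window ids
    stats: Optional[pd.DataFrame] = None  # alignment stats of the subsample


def region_contrast(
    calls: list[RelationshipCall],
    regions: dict[str, list[tuple[str, int, int]]],
    n_sample: int = 30,
    seed: int = 0,
    windows: Optional[dict[str, AlignmentWindow]] = None,
) -> RegionContrast:
    """Per-region relationship-class proportions, with an optional seeded
    subsample of windows per region summarised by alignment statistics.

    Every window is assigned to exactly one region class by its midpoint;
    windows matching no named region fall into "other".  Overlapping region
    definitions are a configuration error.
    """
    flat: list[tuple[str, str, int, int]] = []
    for name, ivs in regions.items():
        for chrom, s, e in ivs:
            flat.append((name, chrom, s, e))
    for a in range(len(flat)):
        for b in range(a + 1, len(flat)):
            na, ca, sa, ea = flat[a]
            nb, cb, sb, eb = flat[b]
            if ca == cb and sa < eb and sb < ea:
                raise ValueError(
                    f"overlapping region definitions: {na} and {nb} on {ca}"
                )

    def assign(call: RelationshipCall) -> str:
        mid = (call.start + call.end) // 2
        for name, chrom, s, e in flat:
            if call.chrom == chrom and s <= mid < e:
                return name
        return "other"

    rows = [(assign(c), c.class_label, c.window_id) for c in calls]
    df = pd.DataFrame(rows, columns=["region", "class", "window_id"])
    counts = (
        df.groupby(["region", "class"]).size().unstack(fill_value=0)
        if len(df)
        else pd.DataFrame()
    )
    proportions = counts.div(counts.sum(axis=1), axis=0) if len(counts) else counts

    rng = np.random.default_rng(seed)
    sampled: dict[str, list[str]] = {}
    stats_rows = []
    for region, grp in df.groupby("region"):
        ids = sorted(grp["window_id"])
        k = min(n_sample, len(ids))
        pick = sorted(rng.choice(len(ids), size=k, replace=False).tolist())
        sampled[region] = [ids[i] for i in pick]
        if windows is not None:
            for wid in sampled[region]:
                if wid not in windows:
                    continue
                st = alignment_stats(windows[wid])
                stats_rows.append(
                    (
                        region,
                        wid,
                        st.aligned_length,
                        st.length_without_undetermined,
                        st.gap_fraction,
                        st.n_patterns,
                    )
                )
    stats = (
        pd.DataFrame(
            stats_rows,
            columns=[
                "region",
                "window_id",
                "aligned_length",
                "length_without_undetermined",
                "gap_fraction",
                "n_patterns",
            ],
        )
        if stats_rows
        else None
    )
    return RegionContrast(
        proportions=proportions, counts=counts, sampled=sampled, stats=stats
    )
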