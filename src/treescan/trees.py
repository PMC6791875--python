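"""Per-window tree inference: Jukes–Cantor distances, deterministic
neighbor-joining with outgroup rooting, and nonparametric bootstrap support.

The engine is distance-based NJ rather than full ML: the quantities the scan
consumes downstream (topology frequencies and patristic-distance medians)
are robust to this choice at the divergences involved, and NJ is exactly
reproducible.  Determinism under taxon-order permutation is guaranteed by a
lexicographic tie-break on the Q criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mafio import AlignmentWindow, ScanConfig
from .tree import Clade, bipartitions, patristic_distance, reroot_on_outgroup

__all__ = [
    "DistanceResult",
    "WindowTree",
    "pairwise_distances",
    "neighbor_joining",
    "build_tree",
    "bootstrap_tree",
    "infer_window",
    "patristic_distance",
]

JC_MAX_P = 0.75  # p-distances at/above this are unresolvable under JC


@dataclass
class DistanceResult:
    taxa: list[str]
    matrix: np.ndarray  # JC distances; NaN where missing/saturated
    dropped: list[str]  # taxa removed for excess missing data
    saturated: set[frozenset[str]]
    missing: set[frozenset[str]]

    @property
    def complete(self) -> bool:
        return not np.isnan(self.matrix[np.triu_indices(len(self.taxa), k=1)]).any()


@dataclass
class WindowTree:
    window_id: str
    chrom: str
    start: int
    end: int
    tree: Clade  # rooted on the outgroup; supports on internal nodes
    taxa: list[str]
    dropped: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def newick(self) -> str:
        return self.tree.to_newick(lengths=True, supports=True)


def jc_correct(p: np.ndarray) -> np.ndarray:
    """Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3); NaN at saturation."""
    p = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(p < JC_MAX_P, -0.75 * np.log(1.0 - 4.0 * p / 3.0), np.nan)
    return d


def pairwise_distances(
    window: AlignmentWindow, min_determined_frac: float = 0.5
) -> DistanceResult:
    """JC-corrected per-site distances over columns determined in both taxa.

    Taxa determined in fewer than `min_determined_frac` of the window's
    aligned columns are dropped before any pair is formed, so a single
    gappy row cannot poison the matrix.
    """
    det = window.determined_mask()
    width = window.width
    keep_idx = [
        i
        for i in range(len(window.taxa))
        if width > 0 and det[i].sum() >= min_determined_frac * width
    ]
    dropped = [t for i, t in enumerate(window.taxa) if i not in keep_idx]
    taxa = [window.taxa[i] for i in keep_idx]
    n = len(taxa)
    mat = np.zeros((n, n), dtype=float)
    saturated: set[frozenset[str]] = set()
    missing: set[frozenset[str]] = set()
    codes = window.matrix.view(np.uint8)
    for a in range(n):
        for b in range(a + 1, n):
            i, j = keep_idx[a], keep_idx[b]
            shared = det[i] & det[j]
            n_shared = int(shared.sum())
            pair = frozenset((taxa[a], taxa[b]))
            if n_shared == 0:
                mat[a, b] = mat[b, a] = np.nan
                missing.add(pair)
                continue
            p = float((codes[i, shared] != codes[j, shared]).sum()) / n_shared
            d = jc_correct(p)
            if np.isnan(d):
                saturated.add(pair)
            mat[a, b] = mat[b, a] = float(d)
    return DistanceResult(taxa, mat, dropped, saturated, missing)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(taxa: list[str], dmat: np.ndarray) -> Clade:
    """Saitou–Nei neighbor joining, deterministic under permutation of the
    input order.

    When two pairs minimise the Q criterion equally (within 1e-9 relative
    tolerance), the pair whose clusters carry the lexicographically smallest
    representative leaf labels is joined.  Negative branch lengths are
    clamped to zero with the deficit moved to the sibling branch, preserving
    the joined pair's path length.
    """
    if len(taxa) != dmat.shape[0] or dmat.shape[0] != dmat.shape[1]:
        raise ValueError("distance matrix does not match taxa")
    if np.isnan(dmat).any():
        raise ValueError("distance matrix contains missing entries")
    nodes = [Clade(name=t) for t in taxa]
    reps = list(taxa)  # smallest leaf label per active cluster
    D = dmat.astype(float).copy()

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best = None  # (key, i, j, q)
        best_q = np.inf
        scale = max(abs(D).max(), 1.0)
        tol = 1e-9 * scale
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                key = tuple(sorted((reps[i], reps[j])))
                if q < best_q - tol or (abs(q - best_q) <= tol and key < best[0]):
                    best_q = q
                    best = (key, i, j)
        _, i, j = best
        dij = D[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        a, b = nodes[i], nodes[j]
        a.length, b.length = li, lj
        joined = Clade(children=[a, b])
        new_rep = min(reps[i], reps[j])
        du = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.empty((n - 1, n - 1))
        D2[: n - 2, : n - 2] = D[np.ix_(keep, keep)]
        D2[n - 2, : n - 2] = D2[: n - 2, n - 2] = du[keep]
        D2[n - 2, n - 2] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [joined]
        reps = [reps[k] for k in keep] + [new_rep]

    if len(nodes) == 1:
        return nodes[0]
    if len(nodes) == 2:
        d = D[0, 1]
        nodes[0].length = nodes[1].length = max(d / 2.0, 0.0)
        order = np.argsort(reps)
        return Clade(children=[nodes[k] for k in order])
    # final trifurcation
    la = (D[0, 1] + D[0, 2] - D[1, 2]) / 2.0
    lb = (D[0, 1] + D[1, 2] - D[0, 2]) / 2.0
    lc = (D[0, 2] + D[1, 2] - D[0, 1]) / 2.0
    for node, ln in zip(nodes, (la, lb, lc)):
        node.length = max(ln, 0.0)
    order = np.argsort(reps)
    return Clade(children=[nodes[k] for k in order])


def build_tree(taxa: list[str], dmat: np.ndarray, outgroup: str) -> Clade:
    """NJ tree rooted on the outgroup branch."""
    if outgroup not in taxa:
        raise KeyError(f"outgroup {outgroup!r} not among taxa")
    unrooted = neighbor_joining(taxa, dmat)
    if len(taxa) < 3:
        return unrooted if len(taxa) == 1 else reroot_on_outgroup(unrooted, outgroup)
    return reroot_on_outgroup(unrooted, outgroup)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _pair_site_arrays(window: AlignmentWindow, keep_idx: list[int]):
    """Per-pair boolean site arrays (shared-determined, differing) used to
    recompute distances on resampled columns without touching characters."""
    det = window.determined_mask()
    codes = window.matrix.view(np.uint8)
    pairs = []
    shared_rows = []
    diff_rows = []
    for a in range(len(keep_idx)):
        for b in range(a + 1, len(keep_idx)):
            i, j = keep_idx[a], keep_idx[b]
            sh = det[i] & det[j]
            pairs.append((a, b))
            shared_rows.append(sh)
            diff_rows.append(sh & (codes[i] != codes[j]))
    return pairs, np.array(shared_rows), np.array(diff_rows)


def bootstrap_tree(
    window: AlignmentWindow,
    n_reps: int,
    outgroup: str,
    seed: int,
    min_determined_frac: float = 0.5,
) -> WindowTree:
    """Tree for one window with bootstrap supports.

    Columns are resampled with replacement `n_reps` times; each internal
    branch of the original outgroup-rooted tree is labelled with the
    percentage of replicate trees containing the same (unrooted)
    bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    dres = pairwise_distances(window, min_determined_frac)
    if not dres.complete:
        raise ValueError("distance matrix incomplete; window should be skipped")
    rooted = build_tree(dres.taxa, dres.matrix, outgroup)
    n = len(dres.taxa)

    width = window.width
    keep_idx = [window.taxa.index(t) for t in dres.taxa]
    pairs, shared, diff = _pair_site_arrays(window, keep_idx)
    rng = np.random.default_rng(seed)

    counts: dict[frozenset, int] = {}
    targets = bipartitions(rooted)
    for split in targets:
        counts[split] = 0
    for _ in range(n_reps):
        idx = rng.integers(0, width, size=width)
        sh = shared[:, idx].sum(axis=1)
        df = diff[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore"):
            p = np.where(sh > 0, df / np.maximum(sh, 1), np.nan)
        d = jc_correct(p)
        if np.isnan(d).any():
            continue  # replicate uninformative for some pair; counts unchanged
        mat = np.zeros((n, n))
        for (a, b), dv in zip(pairs, d):
            mat[a, b] = mat[b, a] = dv
        rep_tree = build_tree(dres.taxa, mat, outgroup)
        rep_splits = bipartitions(rep_tree)
        for split in targets:
            if split in rep_splits:
                counts[split] += 1

    all_leaves = rooted.leaf_set()
    anchor = min(all_leaves)
    for node in rooted.iter_nodes():
        if node is rooted or node.is_leaf:
            continue
        side = node.leaf_set()
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            node.support = round(100.0 * counts[frozenset(side)] / n_reps)

    return WindowTree(
        window_id=window.window_id,
        chrom=window.chrom,
        start=window.start,
        end=window.end,
        tree=rooted,
        taxa=list(dres.taxa),
        dropped=list(dres.dropped),
        flags=(["few_taxa"] if n < 4 else []),
    )


# ---------------------------------------------------------------------------
# exhaustive reference method (small taxon sets)
# ---------------------------------------------------------------------------


def enumerate_unrooted_topologies(labels: list[str]):
    """All unrooted binary topologies over `labels` (1*3*5*...*(2n-5) trees),
    yielded as rooted `Clade`s with an arbitrary trifurcating root.  Only
    feasible for small n; intended as an exhaustive reference against which
    heuristic reconstructions can be checked."""
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    base = Clade(
        children=[Clade(name=labels[0]), Clade(name=labels[1]), Clade(name=labels[2])]
    )

    def grow(tree: Clade, remaining: list[str]):
        if not remaining:
            yield tree.copy()
            return
        nxt, rest = remaining[0], remaining[1:]
        edges = [(p, c) for p in tree.iter_nodes() for c in p.children]
        for parent, child in edges:
            i = parent.children.index(child)
            joint = Clade(children=[child, Clade(name=nxt)])
            parent.children[i] = joint
            yield from grow(tree, rest)
            parent.children[i] = child  # undo

    yield from grow(base, list(labels[3:]))


def least_squares_tree(labels: list[str], dmat: np.ndarray) -> Clade:
    """Best topology by exhaustive ordinary-least-squares fit of branch
    lengths to the distance matrix, over all unrooted topologies.

    On an additive matrix the generating topology fits with zero residual,
    so this recovers it exactly.  Cost grows as (2n-5)!!; use only for
    n <= ~7.
    """
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    d = np.array([dmat[i, j] for i, j in pairs])
    best = None
    for topo in enumerate_unrooted_topologies(labels):
        # design matrix: row per pair, column per edge on the path
        nodes = [nd for nd in topo.iter_nodes() if nd is not topo]
        col = {id(nd): k for k, nd in enumerate(nodes)}
        paths = {}
        for leaf in topo.iter_leaves():
            paths[leaf.name] = _root_path(topo, leaf.name)
        A = np.zeros((len(pairs), len(nodes)))
        for r, (i, j) in enumerate(pairs):
            pa, pb = paths[labels[i]], paths[labels[j]]
            k = 0
            while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
                k += 1
            for nd in pa[k:] + pb[k:]:
                A[r, col[id(nd)]] = 1.0
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        resid = float(((A @ x - d) ** 2).sum())
        if best is None or resid < best[0] - 1e-12:
            for nd, ln in zip(nodes, x):
                nd.length = float(ln)
            best = (resid, topo.copy())
    return best[1]


def _root_path(root: Clade, leaf: str) -> list[Clade]:
    if root.is_leaf:
        return [] if root.name == leaf else None
    for c in root.children:
        if leaf in c.leaf_names():
            sub = _root_path(c, leaf)
            return [c] + (sub or [])
    raise KeyError(leaf)


def random_additive_tree(
    labels: list[str], rng: np.random.Generator
) -> tuple[Clade, np.ndarray]:
    """Random unrooted binary topology with uniform(0.05, 1) branch lengths
    and its (exactly additive) patristic distance matrix."""
    root = Clade(children=[Clade(name=labels[0]), Clade(name=labels[1])])
    for nm in labels[2:]:
        edges = [(p, c) for p in root.iter_nodes() for c in p.children]
        parent, child = edges[int(rng.integers(len(edges)))]
        i = parent.children.index(child)
        parent.children[i] = Clade(children=[child, Clade(name=nm)])
    for nd in root.iter_nodes():
        if nd is not root:
            nd.length = float(rng.uniform(0.05, 1.0))
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = patristic_distance(root, labels[i], labels[j])
    return root, D


def infer_window(
    window: AlignmentWindow,
    config: ScanConfig,
    n_boot: int = 1000,
    seed: int = 0,
    min_determined_frac: float = 0.5,
) -> tuple[Optional[WindowTree], Optional[str]]:
    """Full per-window inference with the skip rules applied.

    Returns ``(WindowTree, None)`` or ``(None, reason)``.  A window is
    skipped when the focal, expected sister or outgroup taxon is absent or
    dropped for missing data, or when any taxon pair lacks shared
    determined columns / is saturated.
    """
    dres = pairwise_distances(window, min_determined_frac)
    required = (config.focal, config.expected_sister, config.outgroup)
    absent = [t for t in required if t not in dres.taxa]
    if absent:
        return None, f"required taxa missing: {','.join(absent)}"
    if dres.missing:
        return None, "taxon pairs without shared determined columns"
    if dres.saturated:
        return None, "saturated taxon pairs"
    return (
        bootstrap_tree(window, n_boot, config.outgroup, seed, min_determined_frac),
        None,
    )
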