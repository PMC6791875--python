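"""Lightweight rooted-tree structure shared by the simulator, the NJ engine
and the topology scan.

Branch lengths are dimensionless here: the simulator uses generations, the
inference code substitutions/site.  Supports are integer percentages attached
to internal nodes (the edge above the node).
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional


class Clade:
    """A node of a rooted tree; a tree is just its root Clade."""

    __slots__ = ("name", "length", "children", "support")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        children: Optional[list["Clade"]] = None,
        support: Optional[int] = None,
    ):
        self.name = name
        self.length = length
        self.children: list[Clade] = children if children is not None else []
        self.support = support

    # -- basic queries -------------------------------------------------

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def iter_nodes(self) -> Iterator["Clade"]:
        yield self
        for c in self.children:
            yield from c.iter_nodes()

    def iter_leaves(self) -> Iterator["Clade"]:
        for n in self.iter_nodes():
            if n.is_leaf:
                yield n

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.iter_leaves()]

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_names())

    def find_leaf(self, name: str) -> Optional["Clade"]:
        for n in self.iter_leaves():
            if n.name == name:
                return n
        return None

    def copy(self) -> "Clade":
        return Clade(
            self.name,
            self.length,
            [c.copy() for c in self.children],
            self.support,
        )

    # -- newick --------------------------------------------------------

    def to_newick(self, lengths: bool = True, supports: bool = False) -> str:
        return _write_newick(self, lengths, supports) + ";"

    @classmethod
    def from_newick(cls, s: str) -> "Clade":
        """Parse a newick string (supports internal labels read as support
        values when they are plain integers, otherwise as node names)."""
        s = s.strip()
        if s.endswith(";"):
            s = s[:-1]
        node, pos = _parse_newick(s, 0)
        if pos != len(s):
            raise ValueError(f"trailing characters in newick at {pos}: {s[pos:]!r}")
        return node

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Clade({self.to_newick()})"


def _write_newick(node: Clade, lengths: bool, supports: bool) -> str:
    if node.is_leaf:
        out = node.name or ""
    else:
        inner = ",".join(_write_newick(c, lengths, supports) for c in node.children)
        label = ""
        if supports and node.support is not None:
            label = str(node.support)
        elif node.name:
            label = node.name
        out = f"({inner}){label}"
    if lengths and node.length is not None:
        out += f":{node.length:.10g}"
    return out


def _parse_newick(s: str, i: int) -> tuple[Clade, int]:
    node = Clade()
    if i < len(s) and s[i] == "(":
        i += 1
        while True:
            child, i = _parse_newick(s, i)
            node.children.append(child)
            if i >= len(s):
                raise ValueError("unbalanced parentheses in newick")
            if s[i] == ",":
                i += 1
                continue
            if s[i] == ")":
                i += 1
                break
            raise ValueError(f"unexpected character {s[i]!r} at {i}")
    # label
    j = i
    while j < len(s) and s[j] not in ",():;":
        j += 1
    label = s[i:j].strip()
    if label:
        if node.is_leaf:
            node.name = label
        elif label.isdigit():
            node.support = int(label)
        else:
            node.name = label
    i = j
    # branch length
    if i < len(s) and s[i] == ":":
        j = i + 1
        while j < len(s) and s[j] not in ",():;":
            j += 1
        node.length = float(s[i + 1 : j])
        i = j
    return node, i


# -- rerooting ---------------------------------------------------------


def reroot_on_outgroup(root: Clade, outgroup: str) -> Clade:
    """Return a new tree rooted on the branch leading to `outgroup`.

    The root is placed at the midpoint of the outgroup's terminal branch, so
    the outgroup is always a direct child of the returned root.  Supports are
    discarded (they belong to the previous rooting's edges).
    """
    tree = root.copy()
    parents: dict[int, Optional[Clade]] = {id(tree): None}
    for n in tree.iter_nodes():
        for c in n.children:
            parents[id(c)] = n
    og = tree.find_leaf(outgroup)
    if og is None:
        raise KeyError(f"outgroup {outgroup!r} not in tree")
    par = parents[id(og)]
    if par is None:
        raise ValueError("cannot root a single-leaf tree")
    og_len = og.length if og.length is not None else 0.0
    if par is tree and len(tree.children) == 2:
        # already rooted on this edge; rebalance to the midpoint
        sib = next(c for c in tree.children if c is not og)
        total = og_len + (sib.length or 0.0)
        og.length = total / 2.0
        sib.length = total / 2.0
        return tree

    def hang(node: Clade, exclude: Clade, carry: float) -> Clade:
        """Rebuild `node` as a subtree hanging away from `exclude`."""
        kids = [c for c in node.children if c is not exclude]
        up = parents[id(node)]
        if up is not None:
            kids.append(hang(up, node, node.length or 0.0))
        if len(kids) == 1:
            # suppress the unary node left behind at the old root
            only = kids[0]
            merged = only.copy()
            merged.length = (only.length or 0.0) + carry
            return merged
        return Clade(name=node.name, length=carry, children=kids)

    new_og = Clade(name=og.name, length=og_len / 2.0)
    rest = hang(par, og, og_len / 2.0)
    return Clade(children=[new_og, rest])


def drop_leaf(root: Clade, name: str) -> Clade:
    """Return a copy of the tree with one leaf removed and unary nodes
    suppressed (branch lengths added through)."""

    def prune(node: Clade) -> Optional[Clade]:
        if node.is_leaf:
            return None if node.name == name else node.copy()
        kids = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            only = kids[0]
            merged = only.copy()
            if node.length is not None or only.length is not None:
                merged.length = (node.length or 0.0) + (only.length or 0.0)
            return merged
        return Clade(node.name, node.length, kids, node.support)

    out = prune(root)
    if out is None:
        raise ValueError(f"dropping {name!r} empties the tree")
    return out


# -- metrics -----------------------------------------------------------


def patristic_distance(root: Clade, a: str, b: str) -> float:
    """Sum of branch lengths on the path between two leaves."""
    if a == b:
        if root.find_leaf(a) is None:
            raise KeyError(f"taxon {a!r} not in tree")
        return 0.0

    def path_to(node: Clade, target: str) -> Optional[list[Clade]]:
        if node.is_leaf:
            return [node] if node.name == target else None
        for c in node.children:
            p = path_to(c, target)
            if p is not None:
                return [node] + p
        return None

    pa = path_to(root, a)
    pb = path_to(root, b)
    if pa is None:
        raise KeyError(f"taxon {a!r} not in tree")
    if pb is None:
        raise KeyError(f"taxon {b!r} not in tree")
    # strip common prefix down to the LCA
    k = 0
    while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
        k += 1
    dist = 0.0
    for n in pa[k:]:
        dist += n.length or 0.0
    for n in pb[k:]:
        dist += n.length or 0.0
    return dist


def bipartitions(root: Clade) -> set[frozenset[str]]:
    """Unrooted bipartitions as canonical leaf-set halves.

    Each internal edge splits the leaves in two; the half not containing the
    alphabetically first leaf is used as the canonical representative.
    Trivial (single-leaf / all-leaf) splits are omitted.
    """
    all_leaves = root.leaf_set()
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()
    for n in root.iter_nodes():
        if n is root or n.is_leaf:
            continue
        side = n.leaf_set()
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def canonical_topology(root: Clade) -> str:
    """Branch-length/support-free string; children sorted recursively by
    their smallest leaf label so equal topologies give equal strings."""

    def canon(node: Clade) -> tuple[str, str]:
        if node.is_leaf:
            return node.name, node.name
        parts = sorted(canon(c) for c in node.children)
        key = parts[0][0]
        return key, "(" + ",".join(p[1] for p in parts) + ")"

    return canon(root)[1]
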