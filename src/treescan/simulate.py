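"""Synthetic multi-species alignment generator with known ground truth.

Emulates the data a windowed phylogenomic scan consumes: a reference-anchored
multiple alignment (MAF) over 8 ingroup taxa plus one outgroup, generated
window by window under the multispecies coalescent (MSC) on a dated species
tree.  Two departures from the species history can be configured:

* introgression pulses — inside a stated genomic interval, with a stated
  probability per window, the recipient lineage is re-attached as sister of
  the donor at the pulse time before the coalescent runs (block-wise lineage
  replacement, the signal a window scan detects);
* inversion regions — windows inside the interval draw their genealogy under
  an override species tree (inversions suppress recombination, so the whole
  region carries one, typically older, genealogy).

One genealogy per window (no intra-window recombination) and Jukes–Cantor
mutation only: the unit of downstream inference is the window, and dating
uses a single per-site rate, so finer realism adds nothing testable.
Missing data is injected i.i.d. per column per taxon as undetermined (``N``)
characters so reference coordinates stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .tree import Clade

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# species tree with ages
# ---------------------------------------------------------------------------


class SpNode:
    __slots__ = ("name", "age", "ne", "children")

    def __init__(self, name=None, age=0.0, ne=None, children=None):
        self.name = name
        self.age = age  # generations before present
        self.ne = ne  # haploid effective size of the branch above this node
        self.children: list[SpNode] = children if children is not None else []

    @property
    def is_leaf(self):
        return not self.children

    def iter_nodes(self):
        yield self
        for c in self.children:
            yield from c.iter_nodes()

    def copy(self):
        return SpNode(self.name, self.age, self.ne, [c.copy() for c in self.children])


class SpeciesTree:
    """Dated, ultrametric species tree with per-branch haploid Ne.

    Constructed from a newick string whose branch lengths are in
    generations; leaves sit at age 0 and every internal node's age is the
    (common) leafward path length below it.
    """

    def __init__(self, root: SpNode):
        self.root = root

    @classmethod
    def from_newick(cls, newick: str, ne: float | dict[str, float] = 50_000.0):
        clade = Clade.from_newick(newick)

        def build(node: Clade) -> SpNode:
            sp = SpNode(name=node.name)
            sp.children = [build(c) for c in node.children]
            if sp.is_leaf:
                sp.age = 0.0
            else:
                ages = [c.age + (ch.length or 0.0) for c, ch in zip(sp.children, node.children)]
                if max(ages) - min(ages) > 1e-6 * max(max(ages), 1.0):
                    raise ValueError(
                        f"species tree not ultrametric at node {node.name or '<internal>'}: {ages}"
                    )
                sp.age = float(np.mean(ages))
                if sp.age <= 0:
                    raise ValueError("internal node ages must be > 0")
            return sp

        root = build(clade)
        default_ne = ne if isinstance(ne, (int, float)) else ne.get("default", 50_000.0)
        for n in root.iter_nodes():
            if isinstance(ne, dict) and n.name in ne:
                n.ne = float(ne[n.name])
            else:
                n.ne = float(default_ne)
        return cls(root)

    # -- queries -------------------------------------------------------

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.iter_nodes() if n.is_leaf]

    def mrca_age(self, a: str, b: str) -> float:
        """Split age (generations) of a pair of taxa."""

        def find(node: SpNode, target: str) -> Optional[list[SpNode]]:
            if node.is_leaf:
                return [node] if node.name == target else None
            for c in node.children:
                p = find(c, target)
                if p is not None:
                    return [node] + p
            return None

        pa, pb = find(self.root, a), find(self.root, b)
        if pa is None or pb is None:
            raise KeyError(f"pair ({a}, {b}) not in species tree")
        k = 0
        while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
            k += 1
        return pa[k - 1].age

    def move_leaf(self, leaf: str, onto: str, time: float) -> "SpeciesTree":
        """Lineage-replacement surgery: detach `leaf` and re-attach it as
        sister of `onto`'s lineage at age `time`.

        Models a pulse of introgression from donor `onto` into recipient
        `leaf` that fully replaced the window: the recipient's ancestry
        joins the donor's species branch `time` generations ago.
        """
        root = self.root.copy()

        parents: dict[int, Optional[SpNode]] = {id(root): None}
        for n in root.iter_nodes():
            for c in n.children:
                parents[id(c)] = n

        def leaf_node(name):
            for n in root.iter_nodes():
                if n.is_leaf and n.name == name:
                    return n
            raise KeyError(name)

        moved = leaf_node(leaf)
        # detach
        par = parents[id(moved)]
        if par is None:
            raise ValueError("cannot move the root")
        par.children.remove(moved)
        while par is not None and len(par.children) == 1 and parents[id(par)] is not None:
            gp = parents[id(par)]
            gp.children[gp.children.index(par)] = par.children[0]
            parents[id(par.children[0])] = gp
            par = gp
        if par is root and len(root.children) == 1:
            root = root.children[0]
            parents[id(root)] = None

        # refresh parent map after splicing
        parents = {id(root): None}
        for n in root.iter_nodes():
            for c in n.children:
                parents[id(c)] = n

        # walk up from the donor to the edge spanning `time`
        target = leaf_node(onto)
        while True:
            par = parents[id(target)]
            top = par.age if par is not None else float("inf")
            if target.age <= time < top:
                break
            if par is None:
                raise ValueError(f"event time {time} is above the root")
            target = par
        par = parents[id(target)]
        joint = SpNode(age=time, ne=target.ne, children=[target, moved])
        if par is None:
            root = joint
        else:
            par.children[par.children.index(target)] = joint
        return SpeciesTree(root)


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass
class IntrogressionEvent:
    donor: str
    recipient: str
    chrom: str
    start: int
    end: int
    time: float  # generations before present
    probability: float  # per-window replacement probability

    def covers(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start < self.end and end > self.start


@dataclass
class InversionRegion:
    chrom: str
    start: int
    end: int
    override_newick: str  # dated species tree the region's genealogy follows

    def covers(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start < self.end and end > self.start


@dataclass
class SimulationConfig:
    species_newick: str
    chrom_lengths: dict[str, int]
    reference: str
    outgroup: str
    window_size: int = 50_000
    mu: float = 1.1e-9  # substitutions / site / generation
    gens_per_year: float = 10.0
    ne: float = 50_000.0  # haploid, applied to every branch unless overridden
    missing_data_rate: float = 0.0
    introgression_events: list[IntrogressionEvent] = field(default_factory=list)
    inversion_regions: list[InversionRegion] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.gens_per_year <= 0:
            raise ValueError("gens_per_year must be > 0")
        if not 0.0 <= self.missing_data_rate <= 1.0:
            raise ValueError("missing_data_rate must lie in [0, 1]")
        for ev in self.introgression_events:
            if not 0.0 <= ev.probability <= 1.0:
                raise ValueError("replacement probability must lie in [0, 1]")
            self._check_interval(ev.chrom, ev.start, ev.end)
        for inv in self.inversion_regions:
            self._check_interval(inv.chrom, inv.start, inv.end)

    def _check_interval(self, chrom, start, end):
        if chrom not in self.chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= self.chrom_lengths[chrom]):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome (length "
                f"{self.chrom_lengths[chrom]})"
            )

    def species_tree(self) -> SpeciesTree:
        return SpeciesTree.from_newick(self.species_newick, ne=self.ne)


@dataclass
class WindowTruth:
    chrom: str
    start: int
    end: int
    label: str  # "species" | "introgressed" | "inversion"


@dataclass
class GroundTruth:
    windows: list[WindowTruth]
    breakpoints: list[tuple[str, int, str]]  # (chrom, position, kind)
    trees: dict[str, SpeciesTree]  # label -> dated tree the label's windows follow

    def pair_age(self, a: str, b: str, label: str = "species") -> float:
        """True split age in generations for a taxon pair under a label."""
        return self.trees[label].mrca_age(a, b)

    def labels_for(self, chrom: str) -> list[str]:
        return [w.label for w in self.windows if w.chrom == chrom]


# ---------------------------------------------------------------------------
# coalescent sampling
# ---------------------------------------------------------------------------


def sample_msc_genealogy(species_tree: SpeciesTree, rng: np.random.Generator) -> Clade:
    """Draw one genealogy (one haploid lineage per species) under the MSC.

    Within the branch above each species-tree node, `k` lineages coalesce at
    rate k(k-1)/2 / Ne per generation (Ne in haploid individuals, so the
    pairwise coalescence time scale is Ne generations).  Returns a rooted
    binary `Clade` with branch lengths in generations.
    """

    def visit(sp: SpNode, top: float) -> list[tuple[Clade, float]]:
        if sp.is_leaf:
            lineages = [(Clade(name=sp.name), 0.0)]
        else:
            lineages = []
            for c in sp.children:
                lineages.extend(visit(c, sp.age))
        t = sp.age
        while len(lineages) > 1:
            k = len(lineages)
            wait = rng.exponential(sp.ne / (k * (k - 1) / 2.0))
            if t + wait >= top:
                break
            t += wait
            i, j = rng.choice(k, size=2, replace=False)
            (na, ta), (nb, tb) = lineages[i], lineages[j]
            na.length = t - ta
            nb.length = t - tb
            parent = Clade(children=[na, nb])
            lineages = [lineages[m] for m in range(k) if m not in (i, j)]
            lineages.append((parent, t))
        return lineages

    final = visit(species_tree.root, float("inf"))
    assert len(final) == 1
    return final[0][0]


def sample_window_genealogy(
    config: SimulationConfig,
    chrom: str,
    start: int,
    end: int,
    rng: np.random.Generator,
) -> tuple[Clade, str]:
    """Genealogy for one window, with its ground-truth label.

    Inversion regions take precedence over introgression pulses; outside
    both, the plain MSC on the species tree applies.
    """
    config._check_interval(chrom, start, end)
    for inv in config.inversion_regions:
        if inv.covers(chrom, start, end):
            tree = SpeciesTree.from_newick(inv.override_newick, ne=config.ne)
            return sample_msc_genealogy(tree, rng), "inversion"
    base = config.species_tree()
    for ev in config.introgression_events:
        if ev.covers(chrom, start, end):
            if rng.random() < ev.probability:
                moved = base.move_leaf(ev.recipient, ev.donor, ev.time)
                return sample_msc_genealogy(moved, rng), "introgressed"
            break  # at most one event per window decides
    return sample_msc_genealogy(base, rng), "species"


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------


def mutate_and_emit(
    genealogy: Clade,
    length: int,
    mu: float,
    rng: np.random.Generator,
    missing_data_rate: float = 0.0,
) -> dict[str, str]:
    """Evolve a Jukes–Cantor sequence of `length` sites down `genealogy`.

    Branch lengths are generations; a site changes along a branch of t
    generations with probability (3/4)(1 - exp(-4 mu t / 3)) and moves to
    each of the other three bases equally.  Missing data is then injected
    i.i.d. per column per taxon as 'N'.
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    out: dict[str, np.ndarray] = {}
    root_seq = rng.integers(0, 4, size=length, dtype=np.int8)

    def descend(node: Clade, seq: np.ndarray):
        for child in node.children:
            t = child.length or 0.0
            p = 0.75 * (1.0 - np.exp(-4.0 * mu * t / 3.0))
            child_seq = seq.copy()
            if p > 0:
                hit = rng.random(length) < p
                n_hit = int(hit.sum())
                if n_hit:
                    child_seq[hit] = (
                        child_seq[hit] + rng.integers(1, 4, size=n_hit, dtype=np.int8)
                    ) % 4
            if child.is_leaf:
                out[child.name] = child_seq
            else:
                descend(child, child_seq)

    if genealogy.is_leaf:
        out[genealogy.name] = root_seq
    else:
        descend(genealogy, root_seq)

    emitted = {}
    for name, seq in out.items():
        chars = _BASES[seq].copy()
        if missing_data_rate > 0:
            chars[rng.random(length) < missing_data_rate] = b"N"
        emitted[name] = chars.tobytes().decode("ascii")
    return emitted


# ---------------------------------------------------------------------------
# whole-alignment emission
# ---------------------------------------------------------------------------


def simulate_maf(config: SimulationConfig):
    """Simulate the full alignment, one MAF block per window-sized chunk.

    Returns ``(blocks, truth)`` where blocks are `treescan.mafio.MafBlock`
    records (reference taxon first) and truth labels every chunk.  The
    output is a pure function of the config, including its seed; per-
    chromosome RNG streams are split from the top-level seed in sorted
    chromosome order so neither dict order nor chromosome subsetting
    reorders draws within a chromosome.
    """
    from .mafio import MafBlock, MafRow

    sp = config.species_tree()
    taxa = sorted(sp.leaf_names())
    if config.reference not in taxa:
        raise ValueError(f"reference {config.reference!r} not among taxa {taxa}")
    row_order = [config.reference] + [t for t in taxa if t != config.reference]

    chroms = sorted(config.chrom_lengths)
    streams = np.random.SeedSequence(config.seed).spawn(len(chroms))

    blocks: list[MafBlock] = []
    truths: list[WindowTruth] = []
    trees: dict[str, SpeciesTree] = {"species": sp}
    for inv in config.inversion_regions:
        trees["inversion"] = SpeciesTree.from_newick(inv.override_newick, ne=config.ne)
    for ev in config.introgression_events:
        trees["introgressed"] = sp.move_leaf(ev.recipient, ev.donor, ev.time)

    for chrom, ss in zip(chroms, streams):
        rng = np.random.default_rng(ss)
        clen = config.chrom_lengths[chrom]
        for start in range(0, clen, config.window_size):
            end = min(start + config.window_size, clen)
            genealogy, label = sample_window_genealogy(config, chrom, start, end, rng)
            seqs = mutate_and_emit(
                genealogy, end - start, config.mu, rng, config.missing_data_rate
            )
            rows = [
                MafRow(
                    src=f"{name}.{chrom}",
                    start=start,
                    size=end - start,
                    strand="+",
                    src_size=clen,
                    text=seqs[name],
                )
                for name in row_order
            ]
            blocks.append(MafBlock(rows=rows))
            truths.append(WindowTruth(chrom, start, end, label))

    breakpoints = []
    for inv in config.inversion_regions:
        breakpoints.append((inv.chrom, inv.start, "inversion"))
        breakpoints.append((inv.chrom, inv.end, "inversion"))
    for ev in config.introgression_events:
        breakpoints.append((ev.chrom, ev.start, "introgression"))
        breakpoints.append((ev.chrom, ev.end, "introgression"))

    return blocks, GroundTruth(windows=truths, breakpoints=breakpoints, trees=trees)


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

#: Dated default species history for the 8-ingroup + 1-outgroup scenario,
#: ages in generations (10 generations/year).  The focal pair split 0.53 Ma
#: ago and the most recently diverged reference pair 0.31 Ma ago; the
#: ingroup radiation sits at 2.0 Ma and the outgroup at 8 Ma.
DEFAULT_TAXA = {
    "focal": "fontenillei",
    "sister": "bwambae",
    "outgroup": "christyi",
    "reference": "gambiae",
}


def default_species_newick(
    fb_split_ma: float = 0.53,
    gc_split_ma: float = 0.31,
    radiation_ma: float = 2.0,
    outgroup_ma: float = 8.0,
    gens_per_year: float = 10.0,
) -> str:
    """Newick (lengths in generations) for the default dated species tree."""
    g = gens_per_year * 1e6  # generations per Ma

    def a(ma):  # age in generations
        return ma * g

    fb, gc = a(fb_split_ma), a(gc_split_ma)
    fbq, fbqa, fbqal = a(1.4), a(1.6), a(1.8)
    gcr, root_in, og = a(1.2), a(radiation_ma), a(outgroup_ma)

    def join(children: list[tuple[str, float]], age: float) -> tuple[str, float]:
        inner = ",".join(f"{s}:{age - child_age:g}" for s, child_age in children)
        return f"({inner})", age

    fb_n = join([("fontenillei", 0), ("bwambae", 0)], fb)
    fbq_n = join([fb_n, ("quadriannulatus", 0)], fbq)
    fbqa_n = join([fbq_n, ("arabiensis", 0)], fbqa)
    fbqal_n = join([fbqa_n, ("melas", 0)], fbqal)
    gc_n = join([("gambiae", 0), ("coluzzii", 0)], gc)
    gcr_n = join([gc_n, ("merus", 0)], gcr)
    ingroup = join([fbqal_n, gcr_n], root_in)
    root = join([ingroup, ("christyi", 0)], og)
    return root[0] + ";"


def inversion_override_newick(gens_per_year: float = 10.0) -> str:
    """Dated tree for an inversion region whose genealogy predates the
    radiation: the three inversion carriers (focal, sister, melas) form a
    clade that split from everything else before the complex radiated, so
    focal–quadriannulatus dates to ~2.5 Ma inside the region instead of
    ~1.4 Ma outside it."""
    g = gens_per_year * 1e6
    fb = 0.53 * g
    fbl = 1.1 * g  # melas joins the carriers
    deep = 2.53 * g  # carriers vs non-carriers, older than the 2.0 Ma radiation
    gc = 0.31 * g
    gcr = 1.2 * g
    qa = 1.0 * g
    non = 1.6 * g
    og = 8.0 * g

    def join(children: list[tuple[str, float]], age: float) -> tuple[str, float]:
        inner = ",".join(f"{s}:{age - child_age:g}" for s, child_age in children)
        return f"({inner})", age

    carriers = join(
        [join([("fontenillei", 0), ("bwambae", 0)], fb), ("melas", 0)], fbl
    )
    gc_n = join([("gambiae", 0), ("coluzzii", 0)], gc)
    gcr_n = join([gc_n, ("merus", 0)], gcr)
    qa_n = join([("quadriannulatus", 0), ("arabiensis", 0)], qa)
    non_carriers = join([gcr_n, qa_n], non)
    ingroup = join([carriers, non_carriers], deep)
    root = join([ingroup, ("christyi", 0)], og)
    return root[0] + ";"


def demo_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Small end-to-end scenario: two chromosomes, one introgression pulse
    near one centromere, one inversion region on the other chromosome."""
    params = dict(
        species_newick=default_species_newick(),
        chrom_lengths={"2L": 2_000_000, "3L": 2_000_000},
        reference="gambiae",
        outgroup="christyi",
        window_size=50_000,
        mu=1.1e-9,
        gens_per_year=10.0,
        ne=50_000.0,
        missing_data_rate=0.02,
        introgression_events=[
            IntrogressionEvent(
                donor="gambiae",
                recipient="fontenillei",
                chrom="2L",
                start=0,
                end=400_000,
                time=50_000.0,  # 5 kya: very recent pulse
                probability=1.0,
            )
        ],
        inversion_regions=[
            InversionRegion(
                chrom="3L",
                start=600_000,
                end=1_400_000,
                override_newick=inversion_override_newick(),
            )
        ],
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)
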