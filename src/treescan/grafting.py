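"""Placing de novo assembly scaffolds into a reference-anchored multiple
alignment as a new taxon row.

The placement logic has three stages: a seed-and-extend homology search over
the scaffold set (fixed-length exact seeds, chained by diagonal, refined by
a banded edit-distance alignment and trimmed to the maximal-scoring local
segment), Karlin–Altschul e-values with database-size correction, and the
hit-filtering decision rule: a region is placed when it has exactly one raw
hit, or exactly one hit surviving the e-value / query-coverage filter
(a "recovered" unique hit); anything still ambiguous is left unplaced and
gets an all-gap row.  Grafting never alters the existing rows' characters —
only gap-only columns may be inserted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import edlib
import numpy as np

from .mafio import MafBlock, MafRow

_COMP = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SearchParams:
    word_size: int = 11
    match: float = 1.0
    mismatch: float = -2.0
    gap: float = -2.0  # per gap character
    ka_lambda: float = 1.28  # Karlin-Altschul, ungapped +1/-2 nucleotide values
    ka_k: float = 0.46
    evalue_ceiling: float = 10.0  # hits above this are not reported at all
    diagonal_band: int = 30
    chain_gap: int = 250
    envelope_margin: int = 100
    min_cluster_seeds: int = 2  # two-hit seeding: lone random seeds skipped
    max_clusters: int = 20  # alignments attempted per strand, best seeds first
    cluster_count_floor: float = 0.10  # skip clusters with < this x best count


@dataclass
class HomologyHit:
    query_id: str
    scaffold: str
    start: int  # forward-strand scaffold coordinates, 0-based half-open
    end: int
    strand: str
    score: float
    evalue: float
    coverage: float  # aligned query span / query length
    query_start: int = 0
    query_end: int = 0


def _kmer_index(scaffolds: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for name, seq in scaffolds.items():
        s = seq.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((name, i))
    return index


def _local_trim(query: str, target: str, cigar: str, p: SearchParams):
    """Expand an edlib cigar and keep the maximal-scoring contiguous
    segment (Kadane), mimicking a local alignment built on the global path.

    Returns (score, q_interval, t_interval) or None when nothing scores
    positively.
    """
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    qi = ti = 0
    cols = []  # (score, q_advance, t_advance)
    for op, n in ops:
        for _ in range(n):
            if op == "=":
                cols.append((p.match, 1, 1))
                qi += 1
                ti += 1
            elif op == "X":
                cols.append((p.mismatch, 1, 1))
                qi += 1
                ti += 1
            elif op == "I":  # consumes query
                cols.append((p.gap, 1, 0))
                qi += 1
            elif op == "D":  # consumes target
                cols.append((p.gap, 0, 1))
                ti += 1
    best = None
    run_score = 0.0
    run_start = 0
    qpos = np.cumsum([c[1] for c in cols])
    tpos = np.cumsum([c[2] for c in cols])
    for i, (s, _, _) in enumerate(cols):
        if run_score <= 0:
            run_score = s
            run_start = i
        else:
            run_score += s
        if run_score > 0 and (best is None or run_score > best[0]):
            best = (run_score, run_start, i)
    if best is None:
        return None
    score, a, b = best
    q0 = int(qpos[a - 1]) if a > 0 else 0
    t0 = int(tpos[a - 1]) if a > 0 else 0
    return float(score), (q0, int(qpos[b])), (t0, int(tpos[b]))


def search_homologs(
    query: str,
    scaffolds: dict[str, str],
    params: Optional[SearchParams] = None,
    query_id: str = "query",
    index: Optional[dict] = None,
) -> list[HomologyHit]:
    """Seed-and-extend search of `query` against a scaffold set, both
    strands.  Returns all hits with e-value at or below the reporting
    ceiling, best first."""
    p = params or SearchParams()
    if not scaffolds:
        raise ValueError("empty scaffold set")
    if index is None:
        index = _kmer_index(scaffolds, p.word_size)
    db_size = sum(len(s) for s in scaffolds.values())
    qlen = len(query)
    hits: list[HomologyHit] = []
    for strand in "+-":
        q = query.upper() if strand == "+" else revcomp(query.upper())
        seeds: dict[str, list[tuple[int, int]]] = {}
        for i in range(0, qlen - p.word_size + 1):
            kmer = q[i : i + p.word_size]
            for name, pos in index.get(kmer, ()):
                seeds.setdefault(name, []).append((pos - i, i))
        candidates: list[tuple[int, str, list[tuple[int, int]]]] = []
        for name, ds in seeds.items():
            # linear clustering on the (diagonal, query-position)-sorted
            # seed list: a new cluster starts at a diagonal jump beyond the
            # band or a query gap beyond the chaining distance
            ds.sort()
            clusters: list[list[tuple[int, int]]] = []
            for diag, qpos in ds:
                if (
                    clusters
                    and abs(diag - clusters[-1][-1][0]) <= p.diagonal_band
                    and abs(qpos - clusters[-1][-1][1]) <= p.chain_gap
                ):
                    clusters[-1].append((diag, qpos))
                else:
                    clusters.append([(diag, qpos)])
            for cl in clusters:
                if len(cl) >= p.min_cluster_seeds:
                    candidates.append((len(cl), name, cl))
        # align the best-seeded clusters only: genuine homologs (and genuine
        # duplicate loci, which the unique-hit filter must see) carry orders
        # of magnitude more seeds than random k-mer noise
        candidates.sort(key=lambda c: -c[0])
        seen_spans: set[tuple[str, int, int]] = set()
        for rank, (count, name, cl) in enumerate(candidates):
            if rank >= p.max_clusters:
                break
            if candidates and count < p.cluster_count_floor * candidates[0][0]:
                break
            scaffold = scaffolds[name].upper()
            diags = [d for d, _ in cl]
            # window on the scaffold generous enough for the whole query
            t_lo = max(0, min(diags) - p.envelope_margin)
            t_hi = min(len(scaffold), max(diags) + qlen + p.envelope_margin)
            window = scaffold[t_lo:t_hi]
            if not window:
                continue
            res = edlib.align(q, window, mode="HW", task="path")
            if res["editDistance"] < 0 or not res["locations"]:
                continue
            w_start = res["locations"][0][0]
            w_end = res["locations"][0][1] + 1
            trimmed = _local_trim(q, window[w_start:w_end], res["cigar"], p)
            if trimmed is None:
                continue
            score, (q0, q1), (t0, t1) = trimmed
            s_start = t_lo + w_start + t0
            s_end = t_lo + w_start + t1
            if (name, s_start, s_end) in seen_spans:
                continue
            seen_spans.add((name, s_start, s_end))
            evalue = p.ka_k * qlen * db_size * np.exp(-p.ka_lambda * score)
            if evalue > p.evalue_ceiling:
                continue
            if strand == "+":
                qs0, qs1 = q0, q1
            else:
                qs0, qs1 = qlen - q1, qlen - q0
            hits.append(
                HomologyHit(
                    query_id=query_id,
                    scaffold=name,
                    start=s_start,
                    end=s_end,
                    strand=strand,
                    score=score,
                    evalue=float(evalue),
                    coverage=(q1 - q0) / qlen,
                    query_start=qs0,
                    query_end=qs1,
                )
            )
    hits.sort(key=lambda h: (h.evalue, -h.score, h.scaffold, h.start))
    return hits


def select_unique_hit(
    hits: list[HomologyHit],
    evalue_max: float = 1e-4,
    min_coverage: float = 0.40,
) -> Optional[HomologyHit]:
    """The hit-filtering decision rule.

    A single raw hit is selected regardless of quality.  With multiple raw
    hits, those with e-value above `evalue_max` or query coverage at or
    below `min_coverage` are excluded; if exactly one survives it is
    recovered, otherwise (0 or >=2 survivors) the region stays unplaced.
    """
    if len(hits) == 1:
        return hits[0]
    surviving = [
        h for h in hits if h.evalue <= evalue_max and h.coverage > min_coverage
    ]
    if len(surviving) == 1:
        return surviving[0]
    return None


# ---------------------------------------------------------------------------
# grafting
# ---------------------------------------------------------------------------


@dataclass
class Placement:
    scaffold: str
    start: int
    end: int
    strand: str

    @classmethod
    def from_hit(cls, hit: HomologyHit) -> "Placement":
        return cls(hit.scaffold, hit.start, hit.end, hit.strand)


def graft_taxon(
    blocks: list[MafBlock],
    placements: dict[str, Placement],
    scaffolds: dict[str, str],
    new_label: str,
) -> list[MafBlock]:
    """Splice scaffold slices into MAF blocks as a new taxon row.

    `placements` is keyed by the block's reference window id
    (``chrom:start-end``).  The slice is orientation-normalised and aligned
    against the reference row's ungapped sequence; the existing rows'
    relative column order is never altered (only gap-only columns may be
    inserted at new-taxon insertion points).  Blocks without a placement
    get an all-gap row.
    """
    out: list[MafBlock] = []
    for block in blocks:
        ref = block.reference
        region_id = f"{ref.chrom}:{ref.start}-{ref.start + ref.size}"
        placement = placements.get(region_id)
        if placement is None:
            gap_row = MafRow(
                src=f"{new_label}.unplaced",
                start=0,
                size=0,
                strand="+",
                src_size=0,
                text="-" * block.width,
            )
            out.append(MafBlock(rows=[r for r in block.rows] + [gap_row]))
            continue
        scaffold = scaffolds[placement.scaffold]
        if not 0 <= placement.start < placement.end <= len(scaffold):
            raise IndexError(
                f"placement {placement.start}-{placement.end} outside scaffold "
                f"{placement.scaffold} (length {len(scaffold)})"
            )
        piece = scaffold[placement.start : placement.end].upper()
        if placement.strand == "-":
            piece = revcomp(piece)
        new_block = _thread_row(block, piece, placement, new_label)
        out.append(new_block)
    return out


def _thread_row(
    block: MafBlock, piece: str, placement: Placement, new_label: str
) -> MafBlock:
    ref = block.reference
    ref_ungapped = ref.text.replace("-", "")
    res = edlib.align(piece, ref_ungapped, mode="NW", task="path")
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    # flatten into per-step ops
    steps = [op for op, n in ops for _ in range(n)]
    step_i = 0
    piece_i = 0
    new_texts: list[list[str]] = [[] for _ in block.rows]
    new_row: list[str] = []

    def emit_insertions():
        nonlocal step_i, piece_i
        while step_i < len(steps) and steps[step_i] == "I":
            for col in new_texts:
                col.append("-")
            new_row.append(piece[piece_i])
            piece_i += 1
            step_i += 1

    for col_idx in range(block.width):
        ref_char = ref.text[col_idx]
        if ref_char != "-":
            emit_insertions()
            op = steps[step_i] if step_i < len(steps) else "D"
            step_i += 1
            if op in ("=", "X"):
                new_row.append(piece[piece_i])
                piece_i += 1
            else:  # 'D': reference base unmatched in the new sequence
                new_row.append("-")
        else:
            new_row.append("-")
        for row_i, r in enumerate(block.rows):
            new_texts[row_i].append(r.text[col_idx])
    emit_insertions()

    rows = [
        MafRow(r.src, r.start, r.size, r.strand, r.src_size, "".join(t))
        for r, t in zip(block.rows, new_texts)
    ]
    size = len(piece)
    rows.append(
        MafRow(
            src=f"{new_label}.{placement.scaffold}",
            start=placement.start,
            size=size,
            strand=placement.strand,
            src_size=0,
            text="".join(new_row),
        )
    )
    return MafBlock(rows=rows)
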