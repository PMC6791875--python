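"""MAF reading/writing and fixed-window partitioning of a reference-anchored
multiple genome alignment.

Coordinates are 0-based half-open internally (BED convention); human-readable
reports are 1-based inclusive and say so in their headers.  The reference
taxon is the first row of every block; negative-strand reference blocks are
flipped into reference orientation at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio import AlignIO

logger = logging.getLogger(__name__)

_DETERMINED = frozenset(b"ACGT")
_COMP = bytes.maketrans(b"ACGTNacgtn-", b"TGCANtgcan-")


class MafFormatError(ValueError):
    pass


class MafDataError(ValueError):
    pass


@dataclass
class MafRow:
    src: str  # "taxon.chrom"
    start: int  # on `strand`, 0-based
    size: int  # ungapped length
    strand: str  # "+" or "-"
    src_size: int
    text: str  # aligned sequence, may contain '-' and 'N'

    @property
    def taxon(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def chrom(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) == 2 else parts[0]


@dataclass
class MafBlock:
    rows: list[MafRow]

    @property
    def reference(self) -> MafRow:
        return self.rows[0]

    @property
    def width(self) -> int:
        return len(self.rows[0].text)


@dataclass
class ScanConfig:
    """Parameters of the windowed scan (shared by partitioning, filtering and
    classification)."""

    focal: str
    expected_sister: str
    outgroup: str
    window_size: int = 50_000
    min_informative_fraction: float = 0.10
    clade_definitions: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        names = {self.focal, self.expected_sister, self.outgroup}
        if len(names) != 3:
            raise ValueError("focal, expected_sister and outgroup must be distinct")
        self.clade_definitions = {
            k: frozenset(v) for k, v in self.clade_definitions.items()
        }

    @property
    def min_informative(self) -> float:
        return self.min_informative_fraction * self.window_size


@dataclass
class AlignmentWindow:
    chrom: str
    start: int
    end: int
    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, n_cols) of dtype S1, uppercase

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("window start must be < end")
        if self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix row count != taxa count")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def window_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def determined_mask(self) -> np.ndarray:
        codes = self.matrix.view(np.uint8)
        return (codes == 65) | (codes == 67) | (codes == 71) | (codes == 84)

    @property
    def informative_count(self) -> int:
        """Columns with a determined (non-gap, non-N) character in every
        taxon."""
        if self.width == 0:
            return 0
        return int(self.determined_mask().all(axis=0).sum())


@dataclass
class AlignmentStats:
    aligned_length: int
    length_without_undetermined: int
    gap_fraction: float
    n_patterns: int


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


def read_maf(path) -> list[MafBlock]:
    """Read a UCSC-dialect MAF into blocks sorted by reference coordinate.

    The first s-line of each block is taken as the reference row.  Blocks
    whose reference row is on the minus strand are reverse-complemented into
    plus orientation.  Ragged rows or a duplicated taxon within one block
    raise `MafFormatError`.
    """
    blocks: list[MafBlock] = []
    try:
        alignments = list(AlignIO.parse(str(path), "maf"))
    except ValueError as exc:
        raise MafFormatError(str(exc)) from exc
    for aln in alignments:
        rows = []
        for rec in aln:
            ann = rec.annotations
            rows.append(
                MafRow(
                    src=rec.id,
                    start=int(ann["start"]),
                    size=int(ann["size"]),
                    strand="+" if int(ann["strand"]) >= 0 else "-",
                    src_size=int(ann["srcSize"]),
                    text=str(rec.seq).upper(),
                )
            )
        widths = {len(r.text) for r in rows}
        if len(widths) > 1:
            raise MafFormatError("ragged rows within one MAF block")
        taxa = [r.taxon for r in rows]
        if len(set(taxa)) != len(taxa):
            raise MafFormatError(f"duplicate taxon within one block: {sorted(taxa)}")
        block = MafBlock(rows=rows)
        if block.reference.strand == "-":
            block = _flip_block(block)
        blocks.append(block)
    keys = [(b.reference.chrom, b.reference.start) for b in blocks]
    if keys != sorted(keys):
        logger.warning("MAF blocks out of reference-coordinate order; sorting")
        blocks.sort(key=lambda b: (b.reference.chrom, b.reference.start))
    return blocks


def _flip_block(block: MafBlock) -> MafBlock:
    rows = []
    for r in block.rows:
        rows.append(
            MafRow(
                src=r.src,
                start=r.src_size - (r.start + r.size),
                size=r.size,
                strand="-" if r.strand == "+" else "+",
                src_size=r.src_size,
                text=r.text.translate(_COMP)[::-1],
            )
        )
    return MafBlock(rows=rows)


def write_maf(blocks: Iterable[MafBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        for block in blocks:
            fh.write("a\n")
            width = max(len(r.src) for r in block.rows)
            for r in block.rows:
                fh.write(
                    f"s {r.src.ljust(width)} {r.start} {r.size} {r.strand} "
                    f"{r.src_size} {r.text}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------


def partition_windows(
    blocks: list[MafBlock], config: ScanConfig
) -> list[AlignmentWindow]:
    """Tile each reference chromosome with fixed windows and assign every
    alignment column to a window by its reference coordinate.

    Columns where the reference carries a gap (insertions in other taxa) go
    with the most recent preceding reference base; leading gap columns go
    with the block's first reference base.  Taxa absent from a block are
    padded with gaps over that block's columns.  Overlapping reference
    coordinates across blocks raise `MafDataError`.
    """
    w = config.window_size
    by_chrom: dict[str, list[MafBlock]] = {}
    chrom_len: dict[str, int] = {}
    taxa_by_chrom: dict[str, set[str]] = {}
    for b in blocks:
        ref = b.reference
        by_chrom.setdefault(ref.chrom, []).append(b)
        chrom_len[ref.chrom] = ref.src_size
        taxa_by_chrom.setdefault(ref.chrom, set()).update(r.taxon for r in b.rows)

    windows: list[AlignmentWindow] = []
    for chrom in sorted(by_chrom):
        cblocks = sorted(by_chrom[chrom], key=lambda b: b.reference.start)
        ref_taxon = cblocks[0].reference.taxon
        taxa = [ref_taxon] + sorted(taxa_by_chrom[chrom] - {ref_taxon})
        tindex = {t: i for i, t in enumerate(taxa)}
        n_windows = max(1, -(-chrom_len[chrom] // w))
        parts: list[list[np.ndarray]] = [[] for _ in range(n_windows)]

        last_end = -1
        for b in cblocks:
            ref = b.reference
            if ref.start < last_end:
                raise MafDataError(
                    f"overlapping reference coordinates on {chrom} at {ref.start}"
                )
            last_end = ref.start + ref.size
            mat = np.full((len(taxa), b.width), b"-", dtype="S1")
            for r in b.rows:
                mat[tindex[r.taxon]] = np.frombuffer(
                    r.text.encode("ascii"), dtype="S1"
                )
            ref_row = mat[tindex[ref.taxon]].view(np.uint8)
            nongap = ref_row != ord("-")
            if int(nongap.sum()) != ref.size:
                raise MafFormatError(
                    f"reference row size mismatch in block at {chrom}:{ref.start}"
                )
            offsets = np.maximum(np.cumsum(nongap) - 1, 0)
            col_pos = ref.start + offsets
            col_win = col_pos // w
            for widx in np.unique(col_win):
                parts[int(widx)].append(mat[:, col_win == widx])

        for widx in range(n_windows):
            start = widx * w
            end = min(start + w, chrom_len[chrom])
            if parts[widx]:
                matrix = np.concatenate(parts[widx], axis=1)
            else:
                matrix = np.empty((len(taxa), 0), dtype="S1")
            windows.append(AlignmentWindow(chrom, start, end, list(taxa), matrix))
    return windows


def filter_windows(
    windows: list[AlignmentWindow], config: ScanConfig
) -> tuple[list[AlignmentWindow], list[tuple[AlignmentWindow, str]]]:
    """Exclude windows with fewer informative columns than the absolute
    threshold `min_informative_fraction × window_size` (strictly fewer:
    a window exactly at the threshold is retained).  Terminal short windows
    face the same absolute threshold."""
    retained, excluded = [], []
    thr = config.min_informative
    for win in windows:
        count = win.informative_count
        if count >= thr:
            retained.append(win)
        else:
            excluded.append((win, f"informative {count} < {thr:g}"))
    return retained, excluded


def alignment_stats(window: AlignmentWindow) -> AlignmentStats:
    """Alignment length, length without completely undetermined columns,
    gap proportion, and the number of distinct column patterns (computed on
    the columns that are not entirely undetermined)."""
    mat = window.matrix
    n_taxa, width = mat.shape
    if width == 0:
        return AlignmentStats(0, 0, 0.0, 0)
    det = window.determined_mask()
    keep = det.any(axis=0)
    kept = mat[:, keep]
    if kept.shape[1]:
        cols = np.ascontiguousarray(kept.T).view(
            np.dtype((np.void, n_taxa))
        )
        n_patterns = len(np.unique(cols))
    else:
        n_patterns = 0
    gap_fraction = float((mat.view(np.uint8) == ord("-")).mean())
    return AlignmentStats(
        aligned_length=width,
        length_without_undetermined=int(keep.sum()),
        gap_fraction=gap_fraction,
        n_patterns=n_patterns,
    )
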