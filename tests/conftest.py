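import numpy as np
import pytest

from treescan.mafio import AlignmentWindow, ScanConfig
from treescan.simulate import (
    IntrogressionEvent,
    InversionRegion,
    demo_config,
    inversion_override_newick,
    simulate_maf,
)


@pytest.fixture
def scan_cfg():
    return ScanConfig(
        focal="fontenillei",
        expected_sister="bwambae",
        outgroup="christyi",
        window_size=50_000,
        clade_definitions={
            "GC": {"gambiae", "coluzzii"},
            "A(GC)": {"arabiensis", "gambiae", "coluzzii"},
        },
    )


@pytest.fixture(scope="session")
def small_sim():
    """8 windows over 2 chromosomes: 2 introgressed, 2 inversion, 4 plain."""
    cfg = demo_config(
        seed=11,
        chrom_lengths={"2L": 200_000, "3L": 200_000},
        window_size=50_000,
        introgression_events=[
            IntrogressionEvent(
                "gambiae", "fontenillei", "2L", 0, 100_000, 50_000.0, 1.0
            )
        ],
        inversion_regions=[
            InversionRegion("3L", 50_000, 150_000, inversion_override_newick())
        ],
    )
    blocks, truth = simulate_maf(cfg)
    return cfg, blocks, truth


def window_from_strings(rows: dict[str, str], chrom="X", start=0, end=None):
    taxa = list(rows)
    width = len(next(iter(rows.values())))
    if end is None:
        end = start + width
    mat = np.array(
        [np.frombuffer(rows[t].upper().encode(), dtype="S1") for t in taxa]
    )
    return AlignmentWindow(chrom, start, end, taxa, mat)


@pytest.fixture
def make_window():
    return window_from_strings
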