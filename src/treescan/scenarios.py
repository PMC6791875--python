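"""Canonical synthetic study conditions used by the verification analyses.

Two scaled-down scenarios complement the full demo configuration in
`treescan.pipeline.default_config`:

* a pair-dating scenario — a taxon pair with a known split age plus an
  outgroup, many small windows, used to test that the dating chain recovers
  the configured split;
* an inversion scenario — one chromosome with an inversion interval whose
  genealogy predates the radiation, used to test breakpoint recovery and
  the inside/outside age contrast.

Window sizes here are 5 kb rather than the 50 kb production default: the
per-window divergences involved give ample signal at 5 kb and the scan's
logic is size-agnostic, so the scaled windows keep the verification runs
fast without changing what is being tested.
"""

from __future__ import annotations

import numpy as np

from .dating import DatingConfig, estimate_divergence
from .mafio import ScanConfig, filter_windows, partition_windows
from .simulate import (
    InversionRegion,
    SimulationConfig,
    demo_config,
    inversion_override_newick,
)
from .trees import WindowTree, infer_window

MA_IN_GENERATIONS = 1e7  # at 10 generations / year


def pair_dating_config(
    split_ma: float,
    n_windows: int = 300,
    window_size: int = 50_000,
    ne: float = 5_000.0,
    seed: int = 0,
    gens_per_year: float = 10.0,
) -> SimulationConfig:
    """Pair + outgroup with a split `split_ma` Ma ago.

    Windows stay at the production 50 kb here: per-window distances are
    counts over the window, so the median's granularity scales as 1/length,
    and at 5 kb the lattice would be coarser than the bootstrap CI of the
    median (degenerate intervals).  The 2% missing data matches the other
    scenarios and matters statistically too: it varies each window's
    shared-column denominator, so distances do not all sit on one lattice
    and the bootstrapped median is well behaved.  Ne is kept small (5,000
    haploids) so the coalescent excess above the split adds well under a
    branch's worth of bias to the pair distance; the residual upward bias
    (~Ne generations) is inherent to dating from sequence divergence.
    """
    t = split_ma * gens_per_year * 1e6
    og = 8.0 * gens_per_year * 1e6
    newick = f"((A:{t:g},B:{t:g}):{og - t:g},O:{og:g});"
    return SimulationConfig(
        species_newick=newick,
        chrom_lengths={"sim": n_windows * window_size},
        reference="A",
        outgroup="O",
        window_size=window_size,
        mu=1.1e-9,
        gens_per_year=gens_per_year,
        ne=ne,
        missing_data_rate=0.02,
        seed=seed,
    )


def pair_scan_config(window_size: int = 5_000) -> ScanConfig:
    return ScanConfig(
        focal="A",
        expected_sister="B",
        outgroup="O",
        window_size=window_size,
        min_informative_fraction=0.10,
    )


def inversion_scenario_config(
    seed: int = 0,
    chrom_length: int = 200_000,
    window_size: int = 5_000,
    inversion: tuple[int, int] = (50_000, 150_000),
) -> SimulationConfig:
    """One chromosome carrying an inversion whose genealogy predates the
    radiation (carriers: focal, sister and melas)."""
    return demo_config(
        seed=seed,
        chrom_lengths={"3L": chrom_length},
        window_size=window_size,
        missing_data_rate=0.02,
        introgression_events=[],
        inversion_regions=[
            InversionRegion("3L", inversion[0], inversion[1], inversion_override_newick())
        ],
    )


def complex_scan_config(window_size: int = 5_000) -> ScanConfig:
    return ScanConfig(
        focal="fontenillei",
        expected_sister="bwambae",
        outgroup="christyi",
        window_size=window_size,
        min_informative_fraction=0.10,
        clade_definitions={
            "GC": frozenset({"gambiae", "coluzzii"}),
            "A(GC)": frozenset({"arabiensis", "gambiae", "coluzzii"}),
        },
    )


def window_trees_for(
    config: SimulationConfig,
    scan_cfg: ScanConfig,
    n_boot: int = 1,
    seed: int = 0,
) -> tuple[list[WindowTree], list]:
    """simulate -> partition -> filter -> infer, in memory.

    Returns the window trees and the ground truth.  `n_boot` defaults to 1
    because the verification analyses consume topologies and patristic
    distances, not supports.
    """
    from .simulate import simulate_maf

    blocks, truth = simulate_maf(config)
    windows = partition_windows(blocks, scan_cfg)
    retained, _ = filter_windows(windows, scan_cfg)
    wtrees = []
    for i, win in enumerate(retained):
        wt, _ = infer_window(
            win, scan_cfg, n_boot=n_boot, seed=(seed * 1_000_003 + i) % (2**31)
        )
        if wt is not None:
            wtrees.append(wt)
    return wtrees, truth


def dating_recovery_replicate(
    split_ma: float, seed: int, n_windows: int = 300, n_boot: int = 1000
):
    """One replicate of the pair-dating recovery analysis.

    Returns (estimate, truth_age_ma, distances) for the configured split.
    """
    cfg = pair_dating_config(split_ma, n_windows=n_windows, seed=seed)
    scfg = pair_scan_config(cfg.window_size)
    wtrees, _ = window_trees_for(cfg, scfg, n_boot=1, seed=seed)
    dcfg = DatingConfig(
        mu=cfg.mu, gens_per_year=cfg.gens_per_year, n_boot=n_boot, flank=0, seed=seed
    )
    est = estimate_divergence(wtrees, ("A", "B"), dcfg)
    from .dating import collect_pair_distances

    distances = collect_pair_distances(wtrees, ("A", "B"))
    return est, split_ma, distances
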