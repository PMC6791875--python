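"""Pipeline orchestration: simulate -> window -> infer -> scan -> date,
driven by one flat YAML config, with per-stage outputs, a run manifest and
resume support.

Every stage is a plain function reading its inputs from `outdir` and
writing deterministic text outputs (MAF/TSV/BED/newick), so deleting
downstream outputs and resuming reproduces them byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import dating as dating_mod
from . import mafio, scan as scan_mod, simulate as sim_mod, trees as trees_mod
from .tree import Clade

logger = logging.getLogger(__name__)

STAGES = ("simulate", "windows", "trees", "scan", "date")


class StageDependencyError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def default_config(seed: int = 0) -> dict:
    """The shipped demo scenario: 2 chromosomes x 2 Mb, 9 taxa, one recent
    introgression pulse near a centromere-proximal region and one inversion
    whose genealogy predates the radiation."""
    return {
        "seed": seed,
        "simulation": {
            "species_newick": sim_mod.default_species_newick(),
            "chrom_lengths": {"2L": 2_000_000, "3L": 2_000_000},
            "reference": "gambiae",
            "outgroup": "christyi",
            "window_size": 50_000,
            "mu": 1.1e-9,
            "gens_per_year": 10,
            "ne": 50_000,
            "missing_data_rate": 0.02,
            "introgression": [
                {
                    "donor": "gambiae",
                    "recipient": "fontenillei",
                    "chrom": "2L",
                    "start": 0,
                    "end": 400_000,
                    "time": 50_000,
                    "probability": 1.0,
                }
            ],
            "inversions": [
                {
                    "chrom": "3L",
                    "start": 600_000,
                    "end": 1_400_000,
                    "override_newick": sim_mod.inversion_override_newick(),
                }
            ],
        },
        "scan": {
            "focal": "fontenillei",
            "expected_sister": "bwambae",
            "outgroup": "christyi",
            "window_size": 50_000,
            "min_informative_fraction": 0.10,
            "clades": {
                "GC": ["gambiae", "coluzzii"],
                "A(GC)": ["arabiensis", "gambiae", "coluzzii"],
                "QA": ["quadriannulatus", "arabiensis"],
            },
            "min_run": 1,
        },
        "trees": {"n_boot": 100},
        "dating": {
            "mu": 1.1e-9,
            "gens_per_year": 10,
            "n_boot": 1000,
            "flank": 100_000,
            "pairs": [["fontenillei", "bwambae"], ["gambiae", "coluzzii"]],
            "inversion_pair": ["fontenillei", "quadriannulatus"],
        },
        "regions": {
            "centromere": [["2L", 0, 400_000]],
        },
    }


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def validate_config(config: dict) -> list[str]:
    """Schema and cross-field checks; returns the list of violations
    (empty means the config is valid)."""
    errs: list[str] = []
    sim = config.get("simulation", {})
    scn = config.get("scan", {})
    try:
        tree = sim_mod.SpeciesTree.from_newick(
            sim["species_newick"], ne=sim.get("ne", 50_000)
        )
        taxa = set(tree.leaf_names())
    except (KeyError, ValueError) as exc:
        return [f"simulation.species_newick: {exc}"]
    if sim.get("mu", 1.1e-9) <= 0:
        errs.append("simulation.mu must be > 0")
    if sim.get("gens_per_year", 10) <= 0:
        errs.append("simulation.gens_per_year must be > 0")
    if not 0 <= sim.get("missing_data_rate", 0) <= 1:
        errs.append("simulation.missing_data_rate must lie in [0,1]")
    chrom_lengths = sim.get("chrom_lengths", {})
    for label in ("reference", "outgroup"):
        if sim.get(label) not in taxa:
            errs.append(f"simulation.{label} {sim.get(label)!r} not among taxa")
    for ev in sim.get("introgression", []):
        for who in (ev.get("donor"), ev.get("recipient")):
            if who not in taxa:
                errs.append(f"introgression taxon {who!r} not among taxa")
        if not 0 <= ev.get("probability", 1.0) <= 1:
            errs.append("introgression probability must lie in [0,1]")
        if not _in_bounds(ev, chrom_lengths):
            errs.append(f"introgression interval out of bounds: {ev}")
    for inv in sim.get("inversions", []):
        if not _in_bounds(inv, chrom_lengths):
            errs.append(f"inversion interval out of bounds: {inv}")
        try:
            over = sim_mod.SpeciesTree.from_newick(inv["override_newick"])
            if set(over.leaf_names()) != taxa:
                errs.append("inversion override tree has different taxa")
        except (KeyError, ValueError) as exc:
            errs.append(f"inversion override newick: {exc}")
    for label in ("focal", "expected_sister", "outgroup"):
        if scn.get(label) not in taxa:
            errs.append(f"scan.{label} {scn.get(label)!r} not among taxa")
    for name, members in scn.get("clades", {}).items():
        if not set(members) <= taxa:
            errs.append(f"clade {name!r} contains unknown taxa")
    if scn.get("window_size", 50_000) <= 0:
        errs.append("scan.window_size must be > 0")
    if not 0 < scn.get("min_informative_fraction", 0.1) <= 1:
        errs.append("scan.min_informative_fraction must lie in (0,1]")
    dat = config.get("dating", {})
    if dat.get("mu", 1.1e-9) <= 0:
        errs.append("dating.mu must be > 0")
    if dat.get("flank", 0) < 0:
        errs.append("dating.flank must be >= 0")
    regions = config.get("regions", {})
    flat = [
        (name, c, s, e) for name, ivs in regions.items() for c, s, e in ivs
    ]
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            if (
                flat[i][1] == flat[j][1]
                and flat[i][2] < flat[j][3]
                and flat[j][2] < flat[i][3]
            ):
                errs.append(
                    f"overlapping regions {flat[i][0]} and {flat[j][0]}"
                )
    for name, c, s, e in flat:
        if c in chrom_lengths and not (0 <= s < e <= chrom_lengths[c]):
            errs.append(f"region {name} out of bounds on {c}")
    return errs


def _in_bounds(iv: dict, chrom_lengths: dict) -> bool:
    c = iv.get("chrom")
    return (
        c in chrom_lengths
        and 0 <= iv.get("start", -1) < iv.get("end", -1) <= chrom_lengths[c]
    )


def _simulation_config(config: dict) -> sim_mod.SimulationConfig:
    sim = config["simulation"]
    return sim_mod.SimulationConfig(
        species_newick=sim["species_newick"],
        chrom_lengths=dict(sim["chrom_lengths"]),
        reference=sim["reference"],
        outgroup=sim["outgroup"],
        window_size=int(sim.get("window_size", 50_000)),
        mu=float(sim.get("mu", 1.1e-9)),
        gens_per_year=float(sim.get("gens_per_year", 10)),
        ne=float(sim.get("ne", 50_000)),
        missing_data_rate=float(sim.get("missing_data_rate", 0.0)),
        introgression_events=[
            sim_mod.IntrogressionEvent(
                donor=ev["donor"],
                recipient=ev["recipient"],
                chrom=ev["chrom"],
                start=int(ev["start"]),
                end=int(ev["end"]),
                time=float(ev["time"]),
                probability=float(ev.get("probability", 1.0)),
            )
            for ev in sim.get("introgression", [])
        ],
        inversion_regions=[
            sim_mod.InversionRegion(
                chrom=inv["chrom"],
                start=int(inv["start"]),
                end=int(inv["end"]),
                override_newick=inv["override_newick"],
            )
            for inv in sim.get("inversions", [])
        ],
        seed=int(config.get("seed", 0)),
    )


def scan_config(config: dict) -> mafio.ScanConfig:
    scn = config["scan"]
    return mafio.ScanConfig(
        focal=scn["focal"],
        expected_sister=scn["expected_sister"],
        outgroup=scn["outgroup"],
        window_size=int(scn.get("window_size", 50_000)),
        min_informative_fraction=float(scn.get("min_informative_fraction", 0.10)),
        clade_definitions={
            k: frozenset(v) for k, v in scn.get("clades", {}).items()
        },
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _require(path: Path, stage: str, needed_by: str):
    if not path.exists():
        raise StageDependencyError(
            f"stage '{needed_by}' requires output {path.name} of stage "
            f"'{stage}'; run that stage first"
        )


def stage_simulate(config: dict, outdir: Path) -> dict:
    cfg = _simulation_config(config)
    blocks, truth = sim_mod.simulate_maf(cfg)
    outdir.mkdir(parents=True, exist_ok=True)
    mafio.write_maf(blocks, outdir / "alignment.maf")
    with open(outdir / "truth.bed", "w") as fh:
        for w in truth.windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.label}\n")
    with open(outdir / "truth_breakpoints.bed", "w") as fh:
        for chrom, pos, kind in truth.breakpoints:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{kind}\n")
    taxa = sorted(truth.trees["species"].leaf_names())
    with open(outdir / "truth_split_ages.tsv", "w") as fh:
        fh.write("label\ttaxon_a\ttaxon_b\tsplit_generations\n")
        for label, tree in sorted(truth.trees.items()):
            for i in range(len(taxa)):
                for j in range(i + 1, len(taxa)):
                    fh.write(
                        f"{label}\t{taxa[i]}\t{taxa[j]}\t"
                        f"{tree.mrca_age(taxa[i], taxa[j]):.6g}\n"
                    )
    return {"n_blocks": len(blocks)}


def stage_windows(config: dict, outdir: Path) -> dict:
    maf_path = outdir / "alignment.maf"
    _require(maf_path, "simulate", "windows")
    scfg = scan_config(config)
    blocks = mafio.read_maf(maf_path)
    windows = mafio.partition_windows(blocks, scfg)
    retained, excluded = mafio.filter_windows(windows, scfg)
    with open(outdir / "windows.tsv", "w") as fh:
        fh.write("# coordinates are 0-based half-open (BED convention)\n")
        fh.write("chrom\tstart\tend\tinformative\tretained\n")
        kept_ids = {w.window_id for w in retained}
        for w in windows:
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{w.informative_count}\t"
                f"{int(w.window_id in kept_ids)}\n"
            )
    with open(outdir / "windows_excluded.log", "w") as fh:
        for w, reason in excluded:
            fh.write(f"{w.window_id}\t{reason}\n")
    return {"n_windows": len(windows), "n_retained": len(retained)}


def _retained_windows(config: dict, outdir: Path) -> list[mafio.AlignmentWindow]:
    maf_path = outdir / "alignment.maf"
    scfg = scan_config(config)
    blocks = mafio.read_maf(maf_path)
    windows = mafio.partition_windows(blocks, scfg)
    retained, _ = mafio.filter_windows(windows, scfg)
    return retained


def stage_trees(config: dict, outdir: Path) -> dict:
    _require(outdir / "windows.tsv", "windows", "trees")
    scfg = scan_config(config)
    n_boot = int(config.get("trees", {}).get("n_boot", 1000))
    seed = int(config.get("seed", 0))
    retained = _retained_windows(config, outdir)
    rows = []
    skips = []
    for i, win in enumerate(retained):
        wseed = (seed * 1_000_003 + 7919 * i) % (2**31)
        wtree, reason = trees_mod.infer_window(win, scfg, n_boot, wseed)
        if wtree is None:
            skips.append((win.window_id, reason))
            continue
        rows.append(
            (win.window_id, win.chrom, win.start, win.end, wtree.newick())
        )
    with open(outdir / "trees.tsv", "w") as fh:
        fh.write("window_id\tchrom\tstart\tend\tnewick\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    with open(outdir / "trees_skipped.log", "w") as fh:
        for wid, reason in skips:
            fh.write(f"{wid}\t{reason}\n")
    return {"n_trees": len(rows), "n_skipped": len(skips)}


def load_window_trees(outdir: Path) -> list[trees_mod.WindowTree]:
    path = Path(outdir) / "trees.tsv"
    _require(path, "trees", "scan/date")
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        tree = Clade.from_newick(row["newick"])
        out.append(
            trees_mod.WindowTree(
                window_id=row["window_id"],
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                tree=tree,
                taxa=sorted(tree.leaf_names()),
            )
        )
    return out


def stage_scan(config: dict, outdir: Path) -> dict:
    wtrees = load_window_trees(outdir)
    scfg = scan_config(config)
    min_run = int(config.get("scan", {}).get("min_run", 1))
    calls = []
    skipped = []
    for wt in wtrees:
        try:
            calls.append(scan_mod.classify_window(wt, scfg))
        except KeyError as exc:
            skipped.append((wt.window_id, str(exc)))
    with open(outdir / "calls.tsv", "w") as fh:
        fh.write(
            "window_id\tchrom\tstart\tend\tsister_ok\tlabel\tambiguous\ttopology\n"
        )
        for c in calls:
            fh.write(
                f"{c.window_id}\t{c.chrom}\t{c.start}\t{c.end}\t"
                f"{int(c.sister_ok)}\t{c.class_label}\t{int(c.ambiguous)}\t"
                f"{c.canonical}\n"
            )
    tally = scan_mod.tally_topologies(calls)
    tally.to_csv(outdir / "tally.tsv", sep="\t", index=False)
    blocks = scan_mod.segment_blocks(calls, min_run=min_run)
    with open(outdir / "blocks.bed", "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.label}\t{b.n_windows}\n")
    regions = {
        name: [tuple(iv) for iv in ivs]
        for name, ivs in config.get("regions", {}).items()
    }
    if regions and calls:
        contrast = scan_mod.region_contrast(
            calls, regions, seed=int(config.get("seed", 0))
        )
        contrast.counts.to_csv(outdir / "region_counts.tsv", sep="\t")
    with open(outdir / "scan_skipped.log", "w") as fh:
        for wid, reason in skipped:
            fh.write(f"{wid}\t{reason}\n")
    return {"n_calls": len(calls), "n_blocks": len(blocks)}


def stage_date(config: dict, outdir: Path) -> dict:
    wtrees = load_window_trees(outdir)
    dat = config.get("dating", {})
    dcfg = dating_mod.DatingConfig(
        mu=float(dat.get("mu", 1.1e-9)),
        gens_per_year=float(dat.get("gens_per_year", 10)),
        n_boot=int(dat.get("n_boot", 1000)),
        flank=int(dat.get("flank", 500_000)),
        seed=int(config.get("seed", 0)),
    )
    estimates = []
    for pair in dat.get("pairs", []):
        estimates.append(dating_mod.estimate_divergence(wtrees, tuple(pair), dcfg))
    inv_pair = dat.get("inversion_pair")
    inversions = config.get("simulation", {}).get("inversions", [])
    if inv_pair and inversions:
        region = [
            (inv["chrom"], int(inv["start"]), int(inv["end"]))
            for inv in inversions
        ]
        for side in ("inside", "outside"):
            estimates.append(
                dating_mod.estimate_divergence(
                    wtrees, tuple(inv_pair), dcfg, region=region, side=side
                )
            )
    with open(outdir / "dating.tsv", "w") as fh:
        fh.write(
            f"# mu={dcfg.mu:g} gens_per_year={dcfg.gens_per_year:g} "
            f"n_boot={dcfg.n_boot} flank={dcfg.flank}\n"
        )
        fh.write(
            "taxon_a\ttaxon_b\tregion\tn_windows\tmedian_d\td_ci_low\t"
            "d_ci_high\td_sd\tage_ma\tage_ci_low\tage_ci_high\n"
        )
        for e in estimates:
            fh.write(
                f"{e.pair[0]}\t{e.pair[1]}\t{e.region}\t{e.n_windows}\t"
                f"{e.median_distance:.6g}\t{e.distance_ci[0]:.6g}\t"
                f"{e.distance_ci[1]:.6g}\t{e.distance_sd:.6g}\t"
                f"{e.age_ma:.4g}\t{e.age_ci[0]:.4g}\t{e.age_ci[1]:.4g}\n"
            )
    return {"n_estimates": len(estimates)}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "windows": stage_windows,
    "trees": stage_trees,
    "scan": stage_scan,
    "date": stage_date,
}


def run_pipeline(
    config: dict,
    outdir,
    stages: Optional[list[str]] = None,
) -> dict:
    """Run (a subset of) the pipeline and write the run manifest.

    Raises ValueError before any compute when the config is invalid, and
    StageDependencyError when a resumed stage is missing upstream output.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    counters: dict[str, dict] = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("running stage %s", stage)
        counters[stage] = _STAGE_FUNCS[stage](config, outdir)
    manifest = {
        "config_hash": config_hash(config),
        "seed": int(config.get("seed", 0)),
        "stages": counters,
        "outdir": str(outdir),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
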