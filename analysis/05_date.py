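#!/usr/bin/env python
"""Date divergences from per-window patristic distances: the focal pair and
the reference pair genome-wide, and the inversion pair inside vs outside
the inverted region (flanks excluded)."""

from pathlib import Path

from treescan import pipeline

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "demo"


def main() -> None:
    config = pipeline.load_config(OUTDIR / "config.yaml")
    counts = pipeline.stage_date(config, OUTDIR)
    print(f"{counts['n_estimates']} divergence estimates -> {OUTDIR / 'dating.tsv'}")
    for line in (OUTDIR / "dating.tsv").read_text().splitlines():
        if line.startswith("#"):
            continue
        print("  " + line)


if __name__ == "__main__":
    main()
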