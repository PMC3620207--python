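#!/usr/bin/env python
"""Predict novel hairpin miRNAs from unannotated uniquely mapped tags.

Prints the candidate summary (count, energies, mature length mode, 5'
nucleotide composition) and whether the planted hairpins were recovered.
"""

import argparse
import json
import shutil
from pathlib import Path

import pandas as pd

from mirmet.config import RunConfig
from mirmet.pipeline import run_all


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--run-dir", default="scratch/run")
    args = ap.parse_args()
    cfg = RunConfig(seed=args.seed, out_dir=args.run_dir, log_level="WARNING")
    run_dir = run_all(cfg, stages=("novel",))
    stats = json.loads((run_dir / "novel" / "stats.json").read_text())
    print("candidate summary:", json.dumps(stats, indent=2))
    cands = pd.read_csv(run_dir / "novel" / "candidates.tsv", sep="\t")
    truth = pd.read_csv(run_dir / "reference" / "novel_loci.tsv", sep="\t")
    rec = sum(((cands["contig"] == h.contig) & (cands["start"] < h.end)
               & (cands["end"] > h.start)).any() for h in truth.itertuples())
    print(f"planted hairpins recovered: {rec}/{len(truth)}")
    shutil.copy(run_dir / "novel" / "candidates.tsv",
                Path("results") / "novel_candidates.tsv")


if __name__ == "__main__":
    main()
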