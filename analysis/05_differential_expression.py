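#!/usr/bin/env python
"""Call differential expression between the BM and NM libraries.

Per-million normalisation, both-below-1 filtering with the 0.01 zero
floor, log2 fold change and the Audic–Claverie exact test; up/down at
|log2 FC| > 2 and p < 0.05.  Prints the significant table and compares
calls against the planted truth.
"""

import argparse
import shutil
from pathlib import Path

import pandas as pd

from mirmet.config import RunConfig
from mirmet.pipeline import evaluate_against_truth, run_all


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--run-dir", default="scratch/run")
    args = ap.parse_args()
    cfg = RunConfig(seed=args.seed, out_dir=args.run_dir, log_level="WARNING")
    run_dir = run_all(cfg, stages=("de",))
    table = pd.read_csv(run_dir / "de" / "de_table.tsv", sep="\t")
    print(table.to_string(index=False))
    up = (table["Status"] == "up-regulated").sum()
    down = (table["Status"] == "down-regulated").sum()
    print(f"{up} up-regulated, {down} down-regulated of {len(table)} significant")
    ev = evaluate_against_truth(run_dir)
    print(f"planted effects called with correct direction: "
          f"{ev['n_correct_direction']}/{ev['n_planted_effects']}")
    shutil.copy(run_dir / "de" / "de_table.tsv", Path("results") / "de_table.tsv")


if __name__ == "__main__":
    main()
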