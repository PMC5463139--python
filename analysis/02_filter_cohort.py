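#!/usr/bin/env python
"""Run the filtering pipeline over the simulated cohort and summarise it.

Reads the config written by 01_simulate_cohort.py, runs ingest ->
segregation filters -> rarity/deleteriousness cascade -> panel scan ->
consanguinity for every family, and prints the per-child count ladder
(total variants, SNPs, indels, recessive homozygotes, then the rare /
nonsynonymous / deleterious survivors) plus the per-category panel-candidate
counts.  Full reports land under results/run/<family>/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from triokin.pipeline import run_pipeline, validate_config

CONFIG = ROOT / "results" / "cohort" / "config.yaml"


def main() -> None:
    if not CONFIG.exists():
        sys.exit(f"run analysis/01_simulate_cohort.py first ({CONFIG} missing)")
    out = run_pipeline(validate_config(CONFIG))
    summary = json.loads((out / "summary.json").read_text())

    rows = []
    for fam in summary["families"]:
        row = {"family": fam["family_id"], **fam["cascade"]}
        row.pop("rarity_threshold")
        rows.append(row)
    table = pd.DataFrame(rows).set_index("family")
    print("per-child filter cascade (counts):")
    print(table.to_string())
    print("\ncohort means:",
          {k: round(v, 1) for k, v in summary["mean_child_counts"].items()})

    print("\npanel candidates per category:")
    for fam in summary["families"]:
        nonzero = {c: n for c, n in fam["panel_counts"].items() if n}
        print(f"  {fam['family_id']}: {nonzero or 'none'}")
    print(f"\nreports in {out}")


if __name__ == "__main__":
    main()
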