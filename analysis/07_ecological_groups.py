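#!/usr/bin/env python
"""Classify OTUs as sensitive / opportunistic / tolerant per treatment.

One-sided phase contrasts on size-factor-normalized counts with joint
Benjamini-Hochberg control (alpha 0.05): sensitive taxa peak in phase 1,
opportunistic in phase 2, tolerant in phase 3.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from micasm import ecogroups, io
from micasm.copynum import PhaseAssignment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--phases", type=Path, default=Path("results/phases.json"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    table = io.read_community(args.data / "counts.tsv",
                              args.data / "metadata.tsv")
    phases = PhaseAssignment(json.loads(args.phases.read_text()))
    args.outdir.mkdir(parents=True, exist_ok=True)

    all_calls, summary = [], {}
    for trt in sorted(set(table.metadata["treatment"]) - {"Control"}):
        calls = ecogroups.classify_otus(table, phases, trt,
                                        alpha=args.alpha, pseudocount=0.5)
        all_calls.append(calls)
        counts = ecogroups.category_counts(calls)
        summary[trt] = counts.to_dict()
        print(f"{trt}: " + ", ".join(f"{k}={v}" for k, v in counts.items()))

    pd.concat(all_calls).to_csv(args.outdir / "ecological_groups.tsv",
                                sep="\t", index=False)
    pd.DataFrame(summary).T.to_csv(args.outdir / "group_counts.tsv",
                                   sep="\t", index_label="treatment")


if __name__ == "__main__":
    main()
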