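#!/usr/bin/env python
"""Dissimilarity-overlap analysis within each treatment over time.

Per within-treatment sample pair: overlap (shared-taxon abundance mass)
and root Jensen-Shannon dissimilarity of the renormalized shared
fractions; a linear slope above the median-overlap cutoff; and the
fraction of sample-bootstrap refits with a negative slope.
"""

import argparse
from pathlib import Path

import pandas as pd

from micasm import doc, io
from micasm.errors import DegenerateDataError


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--n-boot", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    table = io.read_community(args.data / "counts.tsv",
                              args.data / "metadata.tsv")
    args.outdir.mkdir(parents=True, exist_ok=True)

    summary, points = [], []
    for i, trt in enumerate(sorted(set(table.metadata["treatment"]))):
        try:
            res = doc.doc_analysis(table, trt, n_boot=args.n_boot,
                                   seed=args.seed + i)
        except DegenerateDataError as exc:
            print(f"{trt}: degenerate ({exc})")
            continue
        summary.append((trt, len(res.points), res.cutoff, res.slope,
                        res.fraction_negative))
        points.append(res.points.assign(treatment=trt))
        print(f"{trt}: {len(res.points)} pairs, cutoff {res.cutoff:.3f}, "
              f"slope {res.slope:+.3f}, "
              f"fraction of negative bootstrap slopes "
              f"{res.fraction_negative:.3f}")

    pd.concat(points).to_csv(args.outdir / "doc_points.tsv", sep="\t",
                             index=False)
    pd.DataFrame(summary, columns=["treatment", "n_points", "cutoff",
                                   "slope", "fraction_negative"]).to_csv(
        args.outdir / "doc_summary.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
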