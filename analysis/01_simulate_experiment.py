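#!/usr/bin/env python
"""Simulate the reference serial-transfer experiment and write its
artifacts (counts, metadata, tree, chemistry, copy numbers, truth).

Design: 5 arms (Control, BPA, TCS, MI, MII) x 3 replicates x 7 batches
of 5 days, 10% transfer, chemistry at days 0/2/5, one sequencing sample
per bottle per batch.
"""

import argparse
from pathlib import Path

import numpy as np

from micasm import io, synthio
from micasm.pipeline import _sim_tree_seed


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    cfg = synthio.SimConfig(seed=args.seed)
    table, chem, truth = synthio.simulate_experiment(cfg)
    tree = synthio.simulate_tree(cfg.n_otus, _sim_tree_seed(cfg))
    cn_seed = int(np.random.SeedSequence(args.seed + 500)
                  .generate_state(1)[0] % (2 ** 31))
    cn = synthio.simulate_copy_numbers(tree, cn_seed,
                                       unassigned_fraction=0.05)

    args.outdir.mkdir(parents=True, exist_ok=True)
    io.write_community(table, args.outdir / "counts.tsv",
                       args.outdir / "metadata.tsv")
    io.write_chem(chem, args.outdir / "chemistry.tsv")
    io.write_tree(tree, args.outdir / "tree.nwk")
    io.write_copy_numbers(cn, args.outdir / "copy_numbers.tsv")
    truth.to_json(args.outdir / "truth.json")

    rich = (table.counts > 0).sum(axis=1)
    print(f"wrote {len(table.sample_ids)} samples "
          f"({cfg.n_otus} OTUs, depth {cfg.sequencing_depth}) to {args.outdir}")
    print(f"per-sample richness: min {rich.min()}, median "
          f"{int(rich.median())}, max {rich.max()}")


if __name__ == "__main__":
    main()
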