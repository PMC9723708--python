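#!/usr/bin/env python
"""Micropollutant removal per batch, with the nonparametric contracts:
rank-sum tests between consecutive batches per compound, and a
Kruskal-Wallis comparison of compounds within each mixture arm.
"""

import argparse
from pathlib import Path

from micasm import community, io


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    chem = io.read_chem(args.data / "chemistry.tsv")
    removal = community.removal_rate(chem)
    removal["treatment"] = removal["microcosm_id"].str.rsplit(
        "_r", n=1).str[0]
    args.outdir.mkdir(parents=True, exist_ok=True)
    removal.to_csv(args.outdir / "removal_rates.tsv", sep="\t", index=False)

    print("mean removal (%) by arm and compound:")
    summary = removal.groupby(["treatment", "compound"])["removal_percent"] \
        .agg(["mean", "std"]).round(2)
    print(summary.to_string())

    print("\nconsecutive-batch rank-sum p-values (single-compound arms):")
    for arm in ("BPA", "TCS"):
        grp = removal[(removal["treatment"] == arm)
                      & (removal["compound"] == arm)]
        batches = io.sort_batches(grp["batch"])
        ps = []
        for b1, b2 in zip(batches, batches[1:]):
            a = grp.loc[grp["batch"] == b1, "removal_percent"]
            b = grp.loc[grp["batch"] == b2, "removal_percent"]
            _, p = community.rank_sum_test(a, b)
            ps.append(f"{b1}-{b2}: {p:.3f}")
        print(f"  {arm}: " + ", ".join(ps))

    for arm in ("MI", "MII"):
        grp = removal[removal["treatment"] == arm]
        groups = [g["removal_percent"].to_numpy()
                  for _, g in grp.groupby("compound")]
        h, p = community.kruskal_wallis(groups)
        print(f"Kruskal-Wallis between compounds in {arm}: "
              f"H={h:.2f}, p={p:.4f}")


if __name__ == "__main__":
    main()
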