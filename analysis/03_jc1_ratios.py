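#!/usr/bin/env python
"""JC-1 red/green ratios of polarized vs depolarized cells.

Simulates 50 cells per group, measures per-cell mean red / mean green
ratios through the mask-based pipeline, and runs the two-sample t-test.
Depolarized (senescent-like) cells should show a significantly lower
ratio.
"""

import argparse
from pathlib import Path

import pandas as pd

from senometrix.jc1 import compare_ratios, per_cell_ratio
from senometrix.synthetic import Jc1SimConfig, simulate_jc1_pair


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/jc1"))
    parser.add_argument("--cells-per-group", type=int, default=50)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = Jc1SimConfig(n_cells_per_group=args.cells_per_group, seed=args.seed)
    red, green, mask, truth = simulate_jc1_pair(cfg)
    records = per_cell_ratio(red, green, mask, groups=list(truth["group"]))
    records.to_csv(args.out / "cells.tsv", sep="\t", index=False)

    pol = records.loc[records.group == "polarized", "ratio"]
    dep = records.loc[records.group == "depolarized", "ratio"]
    res = compare_ratios(pol, dep, group_a="polarized", group_b="depolarized")
    pd.DataFrame([res.__dict__]).to_csv(args.out / "comparison.tsv", sep="\t",
                                        index=False)

    print(f"mean ratio polarized:   {pol.mean():.3f} (n={len(pol)})")
    print(f"mean ratio depolarized: {dep.mean():.3f} (n={len(dep)})")
    print(f"t = {res.statistic:.2f}, two-sided p = {res.p_two_sided:.3g} "
          f"({res.method})")
    print("=> depolarized cells show the expected drop in red/green ratio."
          if dep.mean() < pol.mean() else "=> unexpected ordering!")


if __name__ == "__main__":
    main()
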