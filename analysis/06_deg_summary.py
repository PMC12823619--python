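#!/usr/bin/env python
"""Differential-expression count arithmetic for the two senescence contrasts.

Summarises the published up/down-regulated gene counts of senescent
(SEN) and engulfing senescent (SEN/ENG) MCF7 cells versus control into
totals and integer percentages.
"""

import argparse
from pathlib import Path

from senometrix.experiments import deg_summary_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)  # unused; uniform CLI
    parser.add_argument("--out", type=Path, default=Path("results/deg"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = deg_summary_table()
    table.to_csv(args.out / "deg_counts.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    for _, r in table.iterrows():
        print(f"=> {r.comparison}: {r.total} DEGs, {r.pct_up}% up / "
              f"{r.pct_down}% down")


if __name__ == "__main__":
    main()
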