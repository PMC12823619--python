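#!/usr/bin/env python
"""Aggregation Index of punctate vs dispersed autofluorescence.

Simulates a control-like group (punctate cofactor signal) and a
senescent-like group (signal dispersed over the cytosol) at equal
per-cell photon counts, runs the full preprocessing + metric pipeline,
and compares the groups. Expected outcome, mirroring the biology: the
dispersed group covers a larger fraction of the cell area and has a
significantly lower Aggregation Index.
"""

import argparse
from pathlib import Path

from senometrix.synthetic import TpefSimConfig, simulate_tpef_image
from senometrix.tpef import run_tpef_pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/tpef"))
    parser.add_argument("--cells-per-group", type=int, default=20)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    triples = []
    for label, aggregation, seed in [
        ("control", 1.0, args.seed),
        ("senescent", 0.2, args.seed + 1),
    ]:
        cfg = TpefSimConfig(image_size=(420, 420), n_cells=args.cells_per_group,
                            aggregation=aggregation, seed=seed)
        image, mask, _ = simulate_tpef_image(cfg)
        triples.append((image, mask, label))

    records, comparisons, log = run_tpef_pipeline(triples)
    records.to_csv(args.out / "cells.tsv", sep="\t", index=False)
    comparisons.to_csv(args.out / "comparisons.tsv", sep="\t", index=False)
    (args.out / "pipeline_log.txt").write_text("\n".join(log) + "\n")

    med = records.groupby("group")[["aggregation_index",
                                    "area_fraction_pct"]].median()
    print("median per group:")
    print(med.to_string(float_format="%.4f"))
    for _, row in comparisons.iterrows():
        print(f"{row.metric}: {row.group_a} vs {row.group_b} "
              f"U={row.U:.1f} p={row.p_two_sided:.3g} ({row.method})")
    ai = med["aggregation_index"]
    verdict = "lower" if ai["senescent"] < ai["control"] else "NOT lower"
    print(f"=> Aggregation Index of the dispersed (senescent-like) group is "
          f"{verdict} than the punctate control group.")


if __name__ == "__main__":
    main()
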