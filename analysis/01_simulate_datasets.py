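#!/usr/bin/env python
"""Generate the synthetic datasets used by the downstream analyses.

Writes one punctate (control-like) and one dispersed (senescent-like)
TPEF field with masks and ground truth, a JC-1 red/green channel pair,
and the three-group lipid spectra with their manifest. Later scripts can
regenerate everything in memory; the on-disk copies exist for
inspection.
"""

import argparse
from pathlib import Path

import tifffile

from senometrix.synthetic import (
    Jc1SimConfig,
    SpectraSimConfig,
    TpefSimConfig,
    simulate_jc1_pair,
    simulate_spectra,
    simulate_tpef_image,
    write_spectra,
    write_tpef_dataset,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("scratch/simulated"))
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    for label, aggregation in [("control", 1.0), ("senescent", 0.2)]:
        cfg = TpefSimConfig(aggregation=aggregation, seed=args.seed)
        image, mask, truth = simulate_tpef_image(cfg)
        write_tpef_dataset(out, image, mask, truth, stem=f"tpef_{label}")
        print(f"TPEF {label}: {cfg.n_cells} cells, aggregation {aggregation}, "
              f"{len(truth['outliers'])} cosmic-ray pixels, "
              f"serpentine shift {truth['serpentine_shift']} px")

    jc1_cfg = Jc1SimConfig(seed=args.seed)
    red, green, mask, truth = simulate_jc1_pair(jc1_cfg)
    tifffile.imwrite(out / "jc1_red.tif", red.astype("float32"))
    tifffile.imwrite(out / "jc1_green.tif", green.astype("float32"))
    tifffile.imwrite(out / "jc1_mask.tif", mask.labels.astype("uint16"))
    truth.to_csv(out / "jc1_truth.tsv", sep="\t", index=False)
    print(f"JC-1: {2 * jc1_cfg.n_cells_per_group} cells, true ratios "
          f"{jc1_cfg.polarized_ratio_mean} (polarized) vs "
          f"{jc1_cfg.depolarized_ratio_mean} (depolarized)")

    spec_cfg = SpectraSimConfig(seed=args.seed)
    spectra, effects = simulate_spectra(spec_cfg)
    manifest = write_spectra(out / "spectra", spectra)
    effects.to_csv(out / "spectra_true_effects.tsv", sep="\t", index=False)
    print(f"Spectra: {len(spectra)} spectra in groups {spectra.groups}, "
          f"manifest at {manifest}")


if __name__ == "__main__":
    main()
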