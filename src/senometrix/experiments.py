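"""Reproducible desk-scale experiments over the synthetic generators.

Each function runs one end-to-end recovery experiment — simulate data
with known ground truth, push it through the corresponding pipeline,
and measure how well the pipeline recovers what was injected. These are
the computations behind the analysis drivers and the acceptance script;
keeping them here makes them importable from tests.

All seeds are plain integers; sub-seeds are derived with
``numpy.random.SeedSequence`` and kept below 2**31.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import maldi, plsa, stats, tpef
from .containers import CellLabelMask
from .synthetic import (
    Jc1SimConfig,
    SpectraSimConfig,
    TpefSimConfig,
    simulate_jc1_pair,
    simulate_spectra,
    simulate_tpef_image,
)

__all__ = [
    "subseeds",
    "ai_recovery",
    "serpentine_recovery",
    "outlier_detection_eval",
    "top_decile_check",
    "jc1_group_experiment",
    "region_effect_recovery",
    "plsa_discrimination_experiment",
    "mwu_type1_error",
    "deg_summary_table",
]


def subseeds(seed: int, n: int) -> List[int]:
    """Derive ``n`` independent integer seeds (< 2**31) from one seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# TPEF
# ---------------------------------------------------------------------------


def ai_recovery(
    seed: int,
    n_seeds: int = 20,
    n_cells: int = 20,
    aggregation_high: float = 1.0,
    aggregation_low: float = 0.2,
    image_size: Tuple[int, int] = (420, 420),
) -> pd.DataFrame:
    """Aggregated vs dispersed cells: does the pipeline order their AI?

    For each of ``n_seeds`` replicate runs, simulates one image of
    punctate cells (aggregation_high) and one of dispersed cells
    (aggregation_low) with noise, outliers and serpentine distortion
    switched on, runs the full pipeline, and records the per-group
    median Aggregation Index plus the Mann–Whitney p-value.
    """
    rows = []
    for run, s in enumerate(subseeds(seed, n_seeds)):
        cfg_hi = TpefSimConfig(
            image_size=image_size, n_cells=n_cells,
            aggregation=aggregation_high, seed=s,
        )
        cfg_lo = TpefSimConfig(
            image_size=image_size, n_cells=n_cells,
            aggregation=aggregation_low, seed=s + 1,
        )
        img_hi, mask_hi, _ = simulate_tpef_image(cfg_hi)
        img_lo, mask_lo, _ = simulate_tpef_image(cfg_lo)
        records, comps, _ = tpef.run_tpef_pipeline(
            [(img_hi, mask_hi, "aggregated"), (img_lo, mask_lo, "dispersed")]
        )
        med = records.groupby("group")["aggregation_index"].median()
        ai_comp = comps[comps["metric"] == "aggregation_index"].iloc[0]
        rows.append(
            {
                "run": run,
                "seed": s,
                "median_ai_aggregated": med["aggregated"],
                "median_ai_dispersed": med["dispersed"],
                "ordered": med["aggregated"] > med["dispersed"],
                "p_two_sided": ai_comp["p_two_sided"],
            }
        )
    return pd.DataFrame(rows)


def serpentine_recovery(
    seed: int, shifts: Sequence[int] = tuple(range(-5, 6))
) -> pd.DataFrame:
    """Inject each shift into a noiseless field and re-estimate it."""
    cfg = TpefSimConfig(
        n_cells=6, background_sd=0.0, n_outliers=0, serpentine_shift=0,
        seed=seed,
    )
    image, _, _ = simulate_tpef_image(cfg)
    base = image["tpef"]
    rows = []
    for s0 in shifts:
        distorted = base.copy()
        distorted[1::2] = np.roll(distorted[1::2], s0, axis=1)
        res = tpef.deskew_serpentine(distorted, max_shift=8)
        rows.append(
            {
                "injected": s0,
                "estimated": res.shift,
                "recovered": res.shift == -s0
                and np.array_equal(res.image, base),
            }
        )
    return pd.DataFrame(rows)


def outlier_detection_eval(seed: int, n_outliers: int = 30) -> Dict[str, float]:
    """Sensitivity and structure-preservation of the cosmic-ray filter.

    On a noiseless field with injected 1-pixel extrema: fraction of
    injected pixels flagged (sensitivity) and number of non-injected
    pixels altered by the filter (should be zero).
    """
    cfg = TpefSimConfig(
        n_cells=8, background_sd=0.0, serpentine_shift=0,
        n_outliers=n_outliers, seed=seed,
    )
    image, _, truth = simulate_tpef_image(cfg)
    arr = image["tpef"]
    flags = tpef.detect_outliers(arr)
    cleaned = tpef.remove_outliers(arr)
    injected = np.zeros(arr.shape, dtype=bool)
    for o in truth["outliers"]:
        injected[o["row"], o["col"]] = True
    sensitivity = float(flags[injected].mean())
    altered = (cleaned != arr) & ~injected
    return {
        "sensitivity": sensitivity,
        "n_structure_pixels_altered": int(altered.sum()),
        "n_injected": int(injected.sum()),
    }


def top_decile_check(seed: int, n_cells: int = 100) -> float:
    """Max |max_tpef − sort-based oracle| over random cells."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cells):
        n = int(rng.integers(10, 2000))
        values = rng.gamma(2.0, 1.0, n)
        k = int(np.ceil(0.10 * n))
        oracle = float(np.mean(sorted(values)[-k:]))
        worst = max(worst, abs(tpef.max_tpef(values) - oracle))
    return worst


# ---------------------------------------------------------------------------
# JC-1
# ---------------------------------------------------------------------------


def jc1_group_experiment(seed: int, n: int = 50) -> Dict[str, float]:
    """Polarized vs depolarized JC-1 ratios through the ratio pipeline."""
    from .jc1 import compare_ratios, per_cell_ratio

    cfg = Jc1SimConfig(n_cells_per_group=n, seed=seed)
    red, green, mask, truth = simulate_jc1_pair(cfg)
    records = per_cell_ratio(red, green, mask, groups=list(truth["group"]))
    pol = records.loc[records["group"] == "polarized", "ratio"].to_numpy()
    dep = records.loc[records["group"] == "depolarized", "ratio"].to_numpy()
    comp = compare_ratios(pol, dep, group_a="polarized", group_b="depolarized")
    return {
        "mean_ratio_polarized": float(pol.mean()),
        "mean_ratio_depolarized": float(dep.mean()),
        "t": comp.statistic,
        "p_two_sided": comp.p_two_sided,
    }


# ---------------------------------------------------------------------------
# MALDI
# ---------------------------------------------------------------------------


def region_effect_recovery(
    seed: int,
    effect: float = 2.0,
    n_per_group: int = 30,
    peak_mz: float = 773.0,
) -> Dict[str, float]:
    """Recover an injected multiplicative Region-3 and single-peak effect.

    Two groups: control and an 'effect' group whose Region-3 peaks and
    the ``peak_mz`` peak are scaled by ``effect``. Reports the
    pre-normalization Region-3 intensity ratio (noiseless oracle check
    happens in tests; here noise is on) and the TIC-normalized
    per-spectrum peak comparison.
    """
    cfg = SpectraSimConfig(
        group_effects={"control": {}, "senescent": {"region3": effect,
                                                    peak_mz: effect}},
        n_spectra_per_group=n_per_group,
        seed=seed,
    )
    spectra, _ = simulate_spectra(cfg)
    region_by_group: Dict[str, List[float]] = {}
    for s in spectra:
        region_by_group.setdefault(s.group, []).append(
            maldi.region_intensity(s)["region3"]
        )
    ratio = float(
        np.mean(region_by_group["senescent"]) / np.mean(region_by_group["control"])
    )
    _, comps = maldi.peak_group_summary(spectra, [peak_mz],
                                        control_group="control")
    row = comps.iloc[0]
    return {
        "region3_ratio": ratio,
        "peak_mz": peak_mz,
        "peak_p_two_sided": float(row["p_two_sided"]),
        "peak_direction_up": bool(row["direction"] == "up"),
    }


# ---------------------------------------------------------------------------
# pLSA
# ---------------------------------------------------------------------------


def plsa_discrimination_experiment(
    seed: int,
    n_seeds: int = 20,
    n_per_group: int = 20,
    noise_cv: float = 0.1,
    k: int = 3,
    bin_width: float = 1.0,
    restarts: int = 3,
) -> pd.DataFrame:
    """Nearest-centroid accuracy of pLSA topic loadings on 3-group spectra.

    Injected per-group effects are >= 1.5-fold on at least one region,
    emulating the senescence-associated lipid signatures; per run the
    topic model (which never sees the labels) is fitted and documents
    are assigned to label centroids in topic space.
    """
    rows = []
    for run, s in enumerate(subseeds(seed, n_seeds)):
        cfg = SpectraSimConfig(
            group_effects={
                "control": {},
                "doxo": {"region1": 1.5, "region3": 2.0, 797.67: 0.5},
                "radio": {"region1": 0.6, "region2": 1.8, "region3": 1.5},
            },
            n_spectra_per_group=n_per_group,
            noise_cv=noise_cv,
            seed=s,
        )
        spectra, _ = simulate_spectra(cfg)
        dtm = plsa.bin_spectra(spectra, bin_width=bin_width)
        model = plsa.fit(dtm, k=k, seed=s, restarts=restarts)
        labels = [sp.group for sp in spectra]
        report = plsa.discriminate(model, labels)
        rows.append({"run": run, "seed": s,
                     "accuracy": report["accuracy"],
                     "silhouette": report["silhouette"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def mwu_type1_error(
    seed: int, n_sim: int = 1000, n_per_group: int = 50, alpha: float = 0.05
) -> float:
    """Monte-Carlo type-I error rate of the MWU kernel under the null."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sim):
        x = rng.normal(size=n_per_group)
        y = rng.normal(size=n_per_group)
        if stats.mann_whitney_u(x, y).p_two_sided < alpha:
            hits += 1
    return hits / n_sim


def deg_summary_table() -> pd.DataFrame:
    """Up/down DEG arithmetic for the two printed senescence contrasts.

    Inputs are the published per-contrast up/down gene counts for
    senescent (SEN) and engulfing senescent (SEN/ENG) MCF7 cells vs
    control.
    """
    comparisons = [("MCF7-SEN_vs_control", 791, 593),
                   ("MCF7-SEN-ENG_vs_control", 675, 391)]
    rows = []
    for name, up, down in comparisons:
        d = stats.summarize_deg_counts(up, down, name=name)
        rows.append({"comparison": d.comparison, "n_up": d.n_up,
                     "n_down": d.n_down, "total": d.total,
                     "pct_up": d.pct_up, "pct_down": d.pct_down})
    return pd.DataFrame(rows)
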