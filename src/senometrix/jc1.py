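"""JC-1 mitochondrial membrane-potential ratiometry.

JC-1 aggregates into red-fluorescent dimers inside polarized
mitochondria and stays as green monomers in the cytosol when the
membrane is depolarized, so the per-cell mean red / mean green intensity
ratio drops with mitochondrial dysfunction. This module computes the
per-cell ratio from a red/green channel pair and a label mask, and
compares group ratios with a two-sample t-test (Student by default,
Welch by flag).
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .containers import CellLabelMask
from .stats import GroupComparison, two_sample_t

__all__ = ["per_cell_ratio", "compare_ratios"]


def per_cell_ratio(
    red: np.ndarray,
    green: np.ndarray,
    mask: CellLabelMask,
    groups: Sequence[str] | None = None,
    bg_subtract: bool = False,
) -> pd.DataFrame:
    """Per-cell red/green mean-intensity ratios.

    ``groups`` optionally assigns a group label per cell (index = cell_id
    - 1). With ``bg_subtract`` the per-channel median of unlabeled
    pixels is subtracted from both means. Cells whose (corrected) green
    mean is non-positive are flagged ``bad_denominator`` and carry NaN
    ratios instead of infinities.
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if red.shape != green.shape or red.shape != mask.labels.shape:
        raise ValueError("red, green and mask must share a shape")
    if mask.n_cells == 0:
        raise ValueError("mask contains no cells")
    if groups is not None and len(groups) != mask.n_cells:
        raise ValueError("one group label per cell required")

    bg_red = bg_green = 0.0
    if bg_subtract:
        outside = mask.labels == 0
        if outside.any():
            bg_red = float(np.median(red[outside]))
            bg_green = float(np.median(green[outside]))

    rows = []
    for cid in mask.cell_ids():
        inside = mask.pixels(cid)
        if not inside.any():
            raise ValueError(f"cell {cid} has no pixels")
        mean_red = float(red[inside].mean()) - bg_red
        mean_green = float(green[inside].mean()) - bg_green
        flag = "" if mean_green > 0 else "bad_denominator"
        rows.append(
            {
                "cell_id": cid,
                "group": groups[cid - 1] if groups is not None else "",
                "mean_red": mean_red,
                "mean_green": mean_green,
                "ratio": mean_red / mean_green if mean_green > 0 else np.nan,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def compare_ratios(
    ratios_a: Sequence[float],
    ratios_b: Sequence[float],
    variant: Literal["student", "welch"] = "student",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-sided t-test on two groups of per-cell red/green ratios."""
    return two_sample_t(
        ratios_a, ratios_b, variant=variant,
        metric="jc1_red_green_ratio", group_a=group_a, group_b=group_b,
    )
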