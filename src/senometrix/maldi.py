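"""MALDI lipid-spectrum preprocessing, region scheme and peak analysis.

Spectra are TIC-normalized (total ion count scaled to 1), optionally
averaged across replicates on a common m/z grid, split into the three
diagnostic m/z regions used for differential lipid analysis —
Region 1 [600, 825) mixed phosphatides, Region 2 [825, 950) mostly
phosphatidylinositols, Region 3 [1300, 1500) cardiolipins — and probed
at annotated peak positions. The default peak tolerance of +/-0.2 Da
follows from a TOF resolving power of ~5000 at m/z 885.56
(FWHM ~ 885.56/5000 ~ 0.18 Da).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .containers import Spectrum, SpectrumSet
from .stats import GroupComparison, mann_whitney_u

__all__ = [
    "RegionScheme",
    "DEFAULT_REGIONS",
    "LipidAnnotation",
    "DEFAULT_ANNOTATIONS",
    "DEFAULT_PEAK_TOL_DA",
    "tic_normalize",
    "average_spectra",
    "region_intensity",
    "extract_peak",
    "annotate",
    "peak_group_summary",
    "read_spectra",
    "read_imzml",
]

DEFAULT_PEAK_TOL_DA = 0.2


@dataclass(frozen=True)
class RegionScheme:
    """Ordered, non-overlapping half-open m/z regions [lower, upper)."""

    regions: Tuple[Tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for name, lo, hi in self.regions:
            if hi <= lo:
                raise ValueError(f"region {name}: upper must exceed lower")
            if lo < prev_hi:
                raise ValueError("regions must be sorted and non-overlapping")
            prev_hi = hi

    def locate(self, mz: float) -> Optional[str]:
        for name, lo, hi in self.regions:
            if lo <= mz < hi:
                return name
        return None


DEFAULT_REGIONS = RegionScheme(
    (
        ("region1", 600.0, 825.0),
        ("region2", 825.0, 950.0),
        ("region3", 1300.0, 1500.0),
    )
)


@dataclass(frozen=True)
class LipidAnnotation:
    mz: float
    species: str
    lipid_class: str


#: Diagnostic assignments; Region 3 peaks additionally map to class CL.
DEFAULT_ANNOTATIONS: Tuple[LipidAnnotation, ...] = (
    LipidAnnotation(616.47, "CerP (d16:1/18:0)", "CerP"),
    LipidAnnotation(773.0, "PG (18:1/18:1)", "PG"),
    LipidAnnotation(797.67, "SM (d18:1/24:1)", "SM"),
    LipidAnnotation(819.0, "PG (18:1/22:6)", "PG"),
)


def tic_normalize(s: Spectrum) -> Spectrum:
    """Scale intensities so the total ion count is 1; m/z unchanged."""
    total = s.intensity.sum()
    if total <= 0:
        raise ValueError("cannot TIC-normalize an all-zero spectrum")
    return Spectrum(
        mz=s.mz, intensity=s.intensity / total,
        sample=s.sample, replicate=s.replicate, group=s.group,
    )


def average_spectra(
    spectra: Union[SpectrumSet, Sequence[Spectrum]],
    grid: Optional[np.ndarray] = None,
) -> Spectrum:
    """Average spectra pointwise after linear interpolation onto a grid.

    Without an explicit grid, the overlap of all input ranges is sampled
    at the median step of the first spectrum. Disjoint ranges are an
    error.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    lo = max(s.mz[0] for s in spectra)
    hi = min(s.mz[-1] for s in spectra)
    if hi <= lo:
        raise ValueError("spectra have disjoint m/z ranges")
    if grid is None:
        step = float(np.median(np.diff(spectra[0].mz)))
        grid = np.arange(lo, hi + step / 2, step)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid[0] < lo or grid[-1] > hi:
            raise ValueError("grid extends outside the common m/z overlap")
    acc = np.zeros_like(grid)
    for s in spectra:
        acc += np.interp(grid, s.mz, s.intensity)
    group = spectra[0].group if len({s.group for s in spectra}) == 1 else ""
    return Spectrum(mz=grid, intensity=acc / len(spectra), group=group,
                    sample="average")


def region_intensity(
    s: Spectrum, scheme: RegionScheme = DEFAULT_REGIONS
) -> Dict[str, float]:
    """Trapezoidal integral of intensity per half-open region [lo, hi)."""
    out: Dict[str, float] = {}
    for name, lo, hi in scheme.regions:
        sel = (s.mz >= lo) & (s.mz < hi)
        if sel.sum() < 2:
            warnings.warn(f"region {name} outside spectrum range; integral 0")
            out[name] = 0.0
            continue
        out[name] = float(np.trapezoid(s.intensity[sel], s.mz[sel]))
    return out


def extract_peak(
    s: Spectrum,
    target_mz: float,
    tol: float = DEFAULT_PEAK_TOL_DA,
    mode: str = "max",
) -> float:
    """Peak intensity near ``target_mz``: windowed max (default) or integral."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    sel = (s.mz >= target_mz - tol) & (s.mz <= target_mz + tol)
    if not sel.any():
        raise ValueError(f"no m/z grid points within {tol} Da of {target_mz}")
    if mode == "max":
        return float(s.intensity[sel].max())
    if mode == "integral":
        if sel.sum() < 2:
            return 0.0
        return float(np.trapezoid(s.intensity[sel], s.mz[sel]))
    raise ValueError(f"unknown mode {mode!r}")


def annotate(
    target_mz: float,
    table: Sequence[LipidAnnotation] = DEFAULT_ANNOTATIONS,
    tol: float = 0.5,
    regions: RegionScheme = DEFAULT_REGIONS,
) -> Optional[LipidAnnotation]:
    """Nearest annotated species within ``tol`` Da, else a class-level
    cardiolipin call in Region 3, else None."""
    best = None
    best_d = tol
    for ann in table:
        d = abs(ann.mz - target_mz)
        if d <= best_d:
            best, best_d = ann, d
    if best is not None:
        return best
    if regions.locate(target_mz) == "region3":
        return LipidAnnotation(target_mz, "CL (unassigned species)", "CL")
    return None


def peak_group_summary(
    spectra: SpectrumSet,
    peaks: Sequence[float],
    control_group: Optional[str] = None,
    tol: float = DEFAULT_PEAK_TOL_DA,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-spectrum TIC-normalized peak intensities plus group tests.

    Returns (long, comparisons): ``long`` has one row per (spectrum,
    peak) with columns sample, group, mz, intensity; ``comparisons``
    holds two-sided Mann–Whitney U tests of every non-control group
    against ``control_group`` (default: the first group) per peak, with
    the direction of the median shift.
    """
    groups = spectra.groups
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    control = control_group if control_group is not None else groups[0]
    if control not in groups:
        raise ValueError(f"unknown control group {control!r}")

    rows = []
    for s in spectra:
        sn = tic_normalize(s)
        for mz0 in peaks:
            try:
                val = extract_peak(sn, mz0, tol=tol)
            except ValueError:
                warnings.warn(f"peak {mz0} outside spectrum {s.sample}; skipped")
                continue
            rows.append({"sample": s.sample, "group": s.group,
                         "mz": mz0, "intensity": val})
    long = pd.DataFrame(rows)

    comps = []
    for mz0 in peaks:
        sub = long[long["mz"] == mz0]
        if sub.empty:
            warnings.warn(f"peak {mz0} absent from all spectra; skipped")
            continue
        ctrl = sub.loc[sub["group"] == control, "intensity"].to_numpy()
        for g in groups:
            if g == control:
                continue
            other = sub.loc[sub["group"] == g, "intensity"].to_numpy()
            res = mann_whitney_u(other, ctrl, metric=f"peak_{mz0}",
                                 group_a=g, group_b=control)
            direction = "up" if np.median(other) > np.median(ctrl) else "down"
            comps.append({"mz": mz0, "group": g, "control": control,
                          "U": res.statistic, "p_two_sided": res.p_two_sided,
                          "method": res.method, "direction": direction,
                          "n_group": res.n_a, "n_control": res.n_b})
    return long, pd.DataFrame(comps)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_spectra(manifest: Union[str, Path]) -> SpectrumSet:
    """Load spectra from a manifest TSV (columns: file, replicate, group).

    Each referenced file is a CSV with columns mz, intensity, resolved
    relative to the manifest's directory.
    """
    manifest = Path(manifest)
    table = pd.read_csv(manifest, sep="\t")
    spectra = []
    for _, row in table.iterrows():
        df = pd.read_csv(manifest.parent / row["file"])
        spectra.append(
            Spectrum(
                mz=df["mz"].to_numpy(), intensity=df["intensity"].to_numpy(),
                sample=Path(row["file"]).stem,
                replicate=str(row.get("replicate", "")),
                group=str(row.get("group", "")),
            )
        )
    return SpectrumSet(spectra)


def read_imzml(path: Union[str, Path], group: str = "") -> SpectrumSet:
    """Read spectra from an imzML file (continuous or processed mode)."""
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    spectra = []
    for i, coords in enumerate(parser.coordinates):
        mz, intensity = parser.getspectrum(i)
        spectra.append(
            Spectrum(
                mz=np.asarray(mz, dtype=float),
                intensity=np.asarray(intensity, dtype=float),
                sample=f"pixel_{coords[0]}_{coords[1]}",
                replicate=str(i), group=group,
            )
        )
    return SpectrumSet(spectra)
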