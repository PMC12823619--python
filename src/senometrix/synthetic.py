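"""Synthetic microscopy images and lipid mass spectra with known ground truth.

Three generators emulate the raw data the downstream metrics consume:

* :func:`simulate_tpef_image` — autofluorescence fields of cells whose
  cofactor signal is either punctate (aggregated mitochondria) or
  dispersed over the cytosol, with the two acquisition artifacts the
  preprocessing must undo: 1-pixel cosmic-ray extrema and a serpentine
  row shift from the raster stage.
* :func:`simulate_jc1_pair` — red/green ratiometric channel pairs with
  group-specific membrane-potential ratios.
* :func:`simulate_spectra` — negative-ion lipid spectra as sums of
  Gaussian peaks with per-group multiplicative effects, log-normal peak
  noise and total-ion-count jitter.

All randomness flows from the single integer ``seed`` of each config
through one ``numpy.random.Generator``; identical config + seed gives
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from .containers import (
    CellLabelMask,
    MultiChannelImage,
    PlacementError,
    Spectrum,
    SpectrumSet,
)

__all__ = [
    "TpefSimConfig",
    "Jc1SimConfig",
    "SpectraSimConfig",
    "simulate_tpef_image",
    "simulate_jc1_pair",
    "simulate_spectra",
    "DEFAULT_PEAK_TABLE",
    "DEFAULT_GROUP_EFFECTS",
    "write_tpef_dataset",
    "write_spectra",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class TpefSimConfig:
    """Parameters of the synthetic autofluorescence field.

    ``aggregation`` interpolates between a fully punctate signal (1.0:
    all photons in Gaussian spots of width ``spot_sigma``) and a fully
    dispersed one (0.0: photons spread uniformly over the cell). The
    total injected photon count per cell is held fixed at
    ``peak_amplitude * 2*pi*spot_sigma**2 * spots_per_cell`` regardless
    of ``aggregation``, so the two regimes differ in distribution, not
    brightness.
    """

    image_size: Tuple[int, int] = (320, 320)
    n_cells: int = 10
    spots_per_cell: int = 5
    spot_sigma: float = 2.0
    aggregation: float = 1.0
    peak_amplitude: float = 3.0
    background_sd: float = 0.05
    n_outliers: int = 10
    serpentine_shift: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.aggregation <= 1.0):
            raise ValueError("aggregation must lie in [0,1]")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be positive")
        if abs(self.serpentine_shift) > self.image_size[1] // 4:
            raise ValueError("serpentine_shift must be within +/- W/4")
        if self.background_sd < 0 or self.peak_amplitude <= 0:
            raise ValueError("amplitudes/noise must be nonnegative")
        if self.n_cells < 1 or self.spots_per_cell < 1 or self.n_outliers < 0:
            raise ValueError("counts out of range")


@dataclass
class Jc1SimConfig:
    """Parameters of the synthetic JC-1 red/green channel pair."""

    n_cells_per_group: int = 50
    polarized_ratio_mean: float = 2.0
    depolarized_ratio_mean: float = 0.8
    ratio_sd: float = 0.3
    green_level: float = 100.0
    image_size: Tuple[int, int] = (512, 512)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.polarized_ratio_mean <= 0 or self.depolarized_ratio_mean <= 0:
            raise ValueError("ratio means must be positive")
        if self.ratio_sd < 0:
            raise ValueError("ratio_sd must be nonnegative")


#: Diagnostic lipid species and supporting peaks used as the default
#: synthetic peak table (m/z in Da, base intensity in a.u.). The four
#: annotated diagnostic species (CerP 616.47, PG 773, SM 797.67, PG 819)
#: sit in Region 1; PI species populate Region 2 (including the 885.56
#: resolving-power anchor) and cardiolipins Region 3.
DEFAULT_PEAK_TABLE: Tuple[Tuple[float, float], ...] = (
    (616.47, 40.0),   # CerP (d16:1/18:0)
    (722.51, 60.0),   # PE species
    (747.52, 55.0),   # PG species
    (773.0, 70.0),    # PG (18:1/18:1)
    (797.67, 65.0),   # SM (d18:1/24:1)
    (819.0, 50.0),    # PG (18:1/22:6)
    (835.53, 45.0),   # PI (34:1)
    (857.52, 40.0),   # PI (36:2)
    (885.56, 80.0),   # PI (38:4)
    (909.55, 30.0),   # PI (40:6)
    (1375.9, 20.0),   # CL (68:4)
    (1399.9, 25.0),   # CL (70:6)
    (1447.96, 35.0),  # CL (72:8)
    (1475.97, 18.0),  # CL (74:9)
)

#: Default per-group effects: multiplicative factors keyed either by a
#: region name ("region1"/"region2"/"region3") or by a specific peak m/z
#: (a float key, matched to the nearest peak). Mirrors the reported
#: direction of change: cardiolipins up in both senescence models, PG
#: 773/819 up everywhere, SM 797.67 down under doxorubicin, CerP 616.47
#: up, PI region down under doxorubicin in the cell line emulated here.
DEFAULT_GROUP_EFFECTS: Mapping[str, Mapping[Union[str, float], float]] = {
    "control": {},
    "doxo": {
        "region1": 1.3,
        "region2": 0.7,
        "region3": 1.8,
        616.47: 1.8,
        773.0: 2.0,
        797.67: 0.6,
        819.0: 2.0,
    },
    "radio": {
        "region1": 1.5,
        "region2": 1.2,
        "region3": 1.6,
        616.47: 1.8,
        773.0: 2.0,
        819.0: 2.0,
    },
}

_REGION_BOUNDS = {"region1": (600.0, 825.0), "region2": (825.0, 950.0),
                  "region3": (1300.0, 1500.0)}


@dataclass
class SpectraSimConfig:
    """Parameters of the synthetic lipid spectra.

    Each spectrum is a sum of Gaussian peaks at ``peak_table`` positions
    whose amplitudes are scaled by the group's effect factor, perturbed
    by log-normal noise with coefficient of variation ``noise_cv``, and
    finally multiplied by a per-spectrum TIC jitter drawn uniformly from
    ``[1/tic_jitter, tic_jitter]``.
    """

    peak_table: Sequence[Tuple[float, float]] = DEFAULT_PEAK_TABLE
    group_effects: Mapping[str, Mapping[Union[str, float], float]] = field(
        default_factory=lambda: DEFAULT_GROUP_EFFECTS
    )
    mz_start: float = 600.0
    mz_stop: float = 1500.0
    mz_step: float = 0.05
    peak_width_fwhm: float = 0.18
    noise_cv: float = 0.1
    tic_jitter: float = 1.2
    n_spectra_per_group: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mz_step <= 0 or self.mz_stop <= self.mz_start:
            raise ValueError("m/z grid must be strictly increasing")
        if self.peak_width_fwhm <= 0:
            raise ValueError("FWHM must be positive")
        if self.noise_cv < 0 or self.tic_jitter < 1.0:
            raise ValueError("noise_cv >= 0 and tic_jitter >= 1 required")
        for mz, amp in self.peak_table:
            if not (self.mz_start <= mz <= self.mz_stop):
                raise ValueError(f"peak at m/z {mz} outside the grid")
            if amp < 0:
                raise ValueError("base intensities must be nonnegative")

    def mz_grid(self) -> np.ndarray:
        n = int(round((self.mz_stop - self.mz_start) / self.mz_step)) + 1
        return self.mz_start + self.mz_step * np.arange(n)


# ---------------------------------------------------------------------------
# TPEF generator
# ---------------------------------------------------------------------------


def _place_cells(
    rng: np.random.Generator,
    shape: Tuple[int, int],
    n_cells: int,
    axis_major: Tuple[float, float] = (12.0, 18.0),
    axis_minor: Tuple[float, float] = (8.0, 13.0),
    gap: int = 3,
    max_tries: int = 4000,
) -> Tuple[np.ndarray, List[dict]]:
    """Paint non-overlapping ellipses; returns (labels, cell geometry)."""
    h, w = shape
    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)  # cells dilated by `gap`
    cells: List[dict] = []
    for k in range(1, n_cells + 1):
        for _ in range(max_tries):
            a = rng.uniform(*axis_major)
            b = rng.uniform(*axis_minor)
            theta = rng.uniform(0, np.pi)
            margin = int(np.ceil(max(a, b))) + gap + 1
            if 2 * margin >= min(h, w):
                raise PlacementError("cells too large for the image")
            r0 = rng.uniform(margin, h - margin)
            c0 = rng.uniform(margin, w - margin)
            rr_big, cc_big = _draw_ellipse(
                r0, c0, a + gap, b + gap, shape=shape, rotation=theta
            )
            if occupied[rr_big, cc_big].any():
                continue
            rr, cc = _draw_ellipse(r0, c0, a, b, shape=shape, rotation=theta)
            labels[rr, cc] = k
            occupied[rr_big, cc_big] = True
            cells.append(
                {"cell_id": k, "center": (float(r0), float(c0)),
                 "axes": (float(a), float(b)), "rotation": float(theta)}
            )
            break
        else:
            raise PlacementError(
                f"could not place cell {k} of {n_cells} after {max_tries} tries"
            )
    return labels, cells


def _spot_centers_in_cell(
    rng: np.random.Generator, cell: dict, n_spots: int, margin: float
) -> np.ndarray:
    """Sample spot centers inside the cell ellipse shrunk by ``margin``."""
    a = max(cell["axes"][0] - margin, 1.0)
    b = max(cell["axes"][1] - margin, 1.0)
    theta = cell["rotation"]
    r0, c0 = cell["center"]
    # Uniform in the unit disc, mapped through the ellipse axes.
    radii = np.sqrt(rng.uniform(0, 1, n_spots))
    angles = rng.uniform(0, 2 * np.pi, n_spots)
    u = radii * np.cos(angles) * a
    v = radii * np.sin(angles) * b
    # skimage's ellipse rotation convention: rows = r0 + u*cos(t) + v*sin(t)
    rows = r0 + u * np.cos(theta) + v * np.sin(theta)
    cols = c0 - u * np.sin(theta) + v * np.cos(theta)
    return np.column_stack([rows, cols])


def _add_gaussian_spot(
    field: np.ndarray, row: float, col: float, sigma: float, amplitude: float
) -> None:
    """Accumulate an isotropic Gaussian into ``field`` within a 5-sigma box."""
    h, w = field.shape
    half = int(np.ceil(5 * sigma))
    r_lo, r_hi = max(0, int(row) - half), min(h, int(row) + half + 1)
    c_lo, c_hi = max(0, int(col) - half), min(w, int(col) + half + 1)
    rr = np.arange(r_lo, r_hi)[:, None]
    cc = np.arange(c_lo, c_hi)[None, :]
    d2 = (rr - row) ** 2 + (cc - col) ** 2
    field[r_lo:r_hi, c_lo:c_hi] += amplitude * np.exp(-d2 / (2 * sigma**2))


def _is_single_pixel_extremum(
    field: np.ndarray, r: int, c: int, value: float, k: float = 5.0
) -> bool:
    """Would setting (r, c) to ``value`` create an isolated 1-pixel extremum?

    Mirrors the detection criterion of the preprocessing filter: strict
    unique window extremum with |value - median| > k * window MAD.
    """
    window = field[r - 1:r + 2, c - 1:c + 2].copy()
    window[1, 1] = value
    flat = window.ravel()
    others = np.delete(flat, 4)
    if not (value > others.max() or value < others.min()):
        return False
    med = np.median(flat)
    mad = np.median(np.abs(flat - med))
    return abs(value - med) > k * mad


def _apply_serpentine(img: np.ndarray, shift: int) -> np.ndarray:
    """Circularly shift odd rows (0-based rows 1, 3, ...) by ``shift``."""
    out = img.copy()
    if shift:
        out[1::2] = np.roll(out[1::2], shift, axis=1)
    return out


def simulate_tpef_image(
    cfg: TpefSimConfig,
) -> Tuple[MultiChannelImage, CellLabelMask, dict]:
    """Generate a TPEF field, its cell mask, and a ground-truth record.

    The returned ground truth records per-cell spot centers, the
    aggregation level, the injected outlier pixels (positions and kind)
    and the serpentine shift actually applied. The label mask refers to
    the undistorted field; the image carries the artifacts.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    labels, cells = _place_cells(rng, (h, w), cfg.n_cells)

    sigma = cfg.spot_sigma
    photons_per_cell = cfg.peak_amplitude * 2 * np.pi * sigma**2 * cfg.spots_per_cell
    field = np.zeros((h, w), dtype=np.float64)
    margin = 3.0 * sigma
    truth_cells = []
    for cell in cells:
        centers = _spot_centers_in_cell(rng, cell, cfg.spots_per_cell, margin)
        if cfg.aggregation > 0:
            for row, col in centers:
                _add_gaussian_spot(
                    field, row, col, sigma, cfg.aggregation * cfg.peak_amplitude
                )
        if cfg.aggregation < 1:
            inside = labels == cell["cell_id"]
            area = int(inside.sum())
            field[inside] += (1 - cfg.aggregation) * photons_per_cell / area
        truth_cells.append(
            {**cell, "spot_centers": centers.tolist(),
             "aggregation": cfg.aggregation,
             "photons": float(photons_per_cell)}
        )

    if cfg.background_sd > 0:
        field = np.clip(field + rng.normal(0, cfg.background_sd, field.shape), 0, None)

    # Stage distortion first, cosmic rays second: the rays hit the
    # detector after the raster, so preprocessing must remove them
    # before deskewing.
    field = _apply_serpentine(field, cfg.serpentine_shift)

    outliers: List[dict] = []
    if cfg.n_outliers:
        taken = np.zeros((h, w), dtype=bool)
        bright_value = 10.0 * (field.max() + 1.0)
        attempts = 0
        while len(outliers) < cfg.n_outliers and attempts < 200_000:
            attempts += 1
            r = int(rng.integers(1, h - 1))
            c = int(rng.integers(1, w - 1))
            if taken[max(0, r - 3):r + 4, max(0, c - 3):c + 4].any():
                continue
            want_dark = (len(outliers) % 2 == 1)
            value = 0.0 if want_dark else bright_value
            # Only keep positions where the event actually registers as
            # an isolated single-pixel extremum: a dark pixel inside a
            # dim or steeply varying neighborhood is not an outlier in
            # any observable sense.
            if not _is_single_pixel_extremum(field, r, c, value):
                continue
            field[r, c] = value
            taken[r, c] = True
            outliers.append(
                {"row": r, "col": c, "kind": "dark" if want_dark else "bright"}
            )
        if len(outliers) < cfg.n_outliers:
            raise PlacementError("could not place the requested outliers")

    image = MultiChannelImage({"tpef": field})
    truth = {
        "cells": truth_cells,
        "outliers": outliers,
        "serpentine_shift": cfg.serpentine_shift,
        "aggregation": cfg.aggregation,
    }
    return image, CellLabelMask(labels), truth


# ---------------------------------------------------------------------------
# JC-1 generator
# ---------------------------------------------------------------------------


def simulate_jc1_pair(
    cfg: Jc1SimConfig,
) -> Tuple[np.ndarray, np.ndarray, CellLabelMask, pd.DataFrame]:
    """Generate red/green channel images for polarized vs depolarized cells.

    Each cell is filled with a constant green level and a red level equal
    to its drawn true ratio times the green level, so the per-cell mean
    red / mean green recovers the drawn ratio exactly. Returns
    (red, green, mask, truth) where truth has columns
    cell_id, group, true_ratio. Non-positive draws are resampled.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells_per_group
    labels, _ = _place_cells(rng, cfg.image_size, 2 * n)

    groups = ["polarized"] * n + ["depolarized"] * n
    means = {"polarized": cfg.polarized_ratio_mean,
             "depolarized": cfg.depolarized_ratio_mean}
    red = np.zeros(cfg.image_size, dtype=np.float64)
    green = np.zeros(cfg.image_size, dtype=np.float64)
    rows = []
    for cell_id, group in zip(range(1, 2 * n + 1), groups):
        ratio = -1.0
        for _ in range(1000):
            ratio = rng.normal(means[group], cfg.ratio_sd)
            if ratio > 0:
                break
        if ratio <= 0:
            raise ValueError("could not draw a positive ratio; lower ratio_sd")
        inside = labels == cell_id
        green[inside] = cfg.green_level
        red[inside] = ratio * cfg.green_level
        rows.append({"cell_id": cell_id, "group": group, "true_ratio": ratio})
    return red, green, CellLabelMask(labels), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spectra generator
# ---------------------------------------------------------------------------


def _effect_for_peak(
    effects: Mapping[Union[str, float], float], mz: float
) -> float:
    """Resolve a peak's multiplicative effect: specific m/z beats region."""
    best_key, best_dist = None, np.inf
    for key in effects:
        if isinstance(key, (int, float)):
            d = abs(float(key) - mz)
            if d < 0.5 and d < best_dist:
                best_key, best_dist = key, d
    if best_key is not None:
        return float(effects[best_key])
    for name, (lo, hi) in _REGION_BOUNDS.items():
        if name in effects and lo <= mz < hi:
            return float(effects[name])
    return 1.0


def simulate_spectra(cfg: SpectraSimConfig) -> Tuple[SpectrumSet, pd.DataFrame]:
    """Generate grouped lipid spectra plus the true effect table.

    Returns (spectra, effects) where ``effects`` is a long table with
    columns group, mz, base_intensity, effect — the multiplicative
    factor actually applied to each peak in each group.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.mz_grid()
    sigma = cfg.peak_width_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    # log-normal with mean 1 and the requested CV
    ln_sigma = np.sqrt(np.log(1.0 + cfg.noise_cv**2)) if cfg.noise_cv > 0 else 0.0

    # Precompute each peak's unit profile on the grid (sparse window).
    profiles = []
    for mz0, base in cfg.peak_table:
        lo = np.searchsorted(grid, mz0 - 6 * sigma)
        hi = np.searchsorted(grid, mz0 + 6 * sigma)
        prof = np.exp(-((grid[lo:hi] - mz0) ** 2) / (2 * sigma**2))
        profiles.append((mz0, base, lo, hi, prof))

    effect_rows = []
    spectra: List[Spectrum] = []
    for group, effects in cfg.group_effects.items():
        peak_factors = np.array(
            [_effect_for_peak(effects, mz0) for mz0, _ in cfg.peak_table]
        )
        for j, (mz0, base) in enumerate(cfg.peak_table):
            effect_rows.append(
                {"group": group, "mz": mz0, "base_intensity": base,
                 "effect": peak_factors[j]}
            )
        for i in range(cfg.n_spectra_per_group):
            intensity = np.zeros_like(grid)
            for j, (mz0, base, lo, hi, prof) in enumerate(profiles):
                amp = base * peak_factors[j]
                if ln_sigma > 0:
                    amp *= rng.lognormal(-0.5 * ln_sigma**2, ln_sigma)
                intensity[lo:hi] += amp * prof
            if cfg.tic_jitter > 1.0:
                intensity *= rng.uniform(1.0 / cfg.tic_jitter, cfg.tic_jitter)
            spectra.append(
                Spectrum(
                    mz=grid.copy(), intensity=intensity,
                    sample=f"{group}_{i:03d}", replicate=str(i), group=group,
                )
            )
    return SpectrumSet(spectra), pd.DataFrame(effect_rows)


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------


def write_tpef_dataset(
    out_dir: Union[str, Path],
    image: MultiChannelImage,
    mask: CellLabelMask,
    truth: dict,
    stem: str = "tpef",
) -> None:
    """Write image (float32 multi-page TIFF), mask (uint16 TIFF), truth JSON."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pages = np.stack([image.channels[k].astype(np.float32) for k in image.channels])
    tifffile.imwrite(out / f"{stem}_image.tif", pages, metadata={
        "channels": list(image.channels)})
    tifffile.imwrite(out / f"{stem}_mask.tif", mask.labels.astype(np.uint16))
    (out / f"{stem}_truth.json").write_text(json.dumps(truth, indent=1))


def write_spectra(out_dir: Union[str, Path], spectra: SpectrumSet) -> Path:
    """Write one CSV per spectrum plus a manifest TSV; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in spectra:
        fname = f"{s.sample}.csv"
        pd.DataFrame({"mz": s.mz, "intensity": s.intensity}).to_csv(
            out / fname, index=False
        )
        rows.append({"file": fname, "replicate": s.replicate, "group": s.group})
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
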