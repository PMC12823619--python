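"""Shared in-memory containers for images, label masks and spectra.

Images are plain float arrays in arbitrary fluorescence units (a.u.),
0-based, row-major. A :class:`MultiChannelImage` groups channels by role
("tpef", "transmission", "red", "green", ...); a :class:`CellLabelMask`
is an integer segmentation aligned to an image (0 = background, k = cell
k, labels contiguous from 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np


class PlacementError(RuntimeError):
    """Raised when synthetic cells cannot be placed without overlap."""


@dataclass
class MultiChannelImage:
    """A set of equally shaped 2-D channels keyed by role."""

    channels: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        for name, ch in self.channels.items():
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"channel {name!r} contains non-finite values")

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def map(self, fn: Callable[[np.ndarray], np.ndarray]) -> "MultiChannelImage":
        """Apply ``fn`` to every channel, returning a new image."""
        return MultiChannelImage({k: fn(v) for k, v in self.channels.items()})

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]


@dataclass
class CellLabelMask:
    """Integer per-pixel cell labels; 0 is background."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if np.issubdtype(self.labels.dtype, np.floating):
            raise ValueError("label mask must be integer-typed")
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size and not np.array_equal(present, np.arange(1, present.size + 1)):
            raise ValueError("cell labels must be contiguous from 1")

    @property
    def n_cells(self) -> int:
        return int(self.labels.max(initial=0))

    def cell_ids(self) -> range:
        return range(1, self.n_cells + 1)

    def pixels(self, cell_id: int) -> np.ndarray:
        """Boolean mask of pixels belonging to ``cell_id``."""
        if cell_id < 1 or cell_id > self.n_cells:
            raise KeyError(f"no cell {cell_id}")
        return self.labels == cell_id


@dataclass
class Spectrum:
    """A single mass spectrum: strictly increasing m/z with intensities.

    ``sample``/``replicate``/``group`` identify the spectrum inside a
    :class:`SpectrumSet`; they are carried through preprocessing.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample: str = ""
    replicate: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and nonnegative")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class SpectrumSet:
    """A collection of spectra with replicate and group labels."""

    spectra: List[Spectrum] = field(default_factory=list)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def groups(self) -> List[str]:
        seen: List[str] = []
        for s in self.spectra:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def by_group(self, group: str) -> "SpectrumSet":
        return SpectrumSet([s for s in self.spectra if s.group == group])
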