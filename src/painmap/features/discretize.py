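"""Fixed-bin-width gray-level discretization of an ROI.

All texture families operate on integer gray levels rather than raw HU.
Levels are assigned as ``level(x) = floor((x - min) / bin_width) + 1``,
re-anchored at the ROI minimum, so an additive HU shift of the whole ROI
leaves the level image (and hence every discretized-texture feature)
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizedROI", "discretize"]


@dataclass
class DiscretizedROI:
    """Integer gray levels over the masked voxels of a volume.

    ``levels`` is co-shaped with the mask and holds consecutive integers
    starting at 1 inside the mask and 0 outside.
    """

    levels: np.ndarray        # int array, 0 outside mask
    mask: np.ndarray          # bool
    n_levels: int
    bin_width_hu: float
    min_hu: float

    def level_edges(self, level: int) -> tuple[float, float]:
        """HU half-open range ``[lo, hi)`` mapped to ``level``."""
        lo = self.min_hu + (level - 1) * self.bin_width_hu
        return lo, lo + self.bin_width_hu

    def histogram(self) -> np.ndarray:
        """Probability of each level (length ``n_levels``)."""
        counts = np.bincount(self.levels[self.mask], minlength=self.n_levels + 1)[1:]
        return counts / counts.sum()


def discretize(values: np.ndarray, mask: np.ndarray, bin_width_hu: float = 25.0) -> DiscretizedROI:
    """Discretize the masked voxels of ``values`` with a fixed bin width."""
    if bin_width_hu <= 0:
        raise ValueError("bin_width_hu must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    x = np.asarray(values, dtype=float)
    mn = x[mask].min()
    levels = np.zeros(mask.shape, dtype=np.int32)
    levels[mask] = np.floor((x[mask] - mn) / bin_width_hu).astype(np.int32) + 1
    return DiscretizedROI(
        levels=levels,
        mask=mask,
        n_levels=int(levels.max()),
        bin_width_hu=float(bin_width_hu),
        min_hu=float(mn),
    )
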