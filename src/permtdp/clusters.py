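"""Supra-threshold cluster formation on the 3D mask grid.

Clusters are connected components of ``{|z| > z_thresh}`` within the mask,
under face (6), edge (18) or vertex (26) adjacency, discarding components
below a minimum size.  Positive- and negative-tail voxels are clustered
separately by default — a mixed-sign "cluster" has no physiological
interpretation — with a flag to merge the tails.

Cluster voxel indices are 0-based positions in the C-order scan of the
mask's nonzero voxels, matching the column order of the permutation
engine, so clusters plug directly into the TDP bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .tdp import VoxelSet

__all__ = ["StatVolume", "threshold_clusters"]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class StatVolume:
    """A 3D statistic map with its binary analysis mask."""

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("statistic volume and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite statistics inside the mask")


def threshold_clusters(
    vol: StatVolume,
    z_thresh: float = 3.0,
    min_size: int = 150,
    connectivity: int = 26,
    separate_signs: bool = True,
) -> list[VoxelSet]:
    """Connected components of ``{|z| > z_thresh}`` within the mask.

    Components smaller than ``min_size`` voxels are discarded; survivors
    are labelled by descending size (ties by first voxel in scan order).
    Returns an empty list when nothing survives.
    """
    if z_thresh <= 0:
        raise ValueError("z threshold must be positive")
    if min_size < 1:
        raise ValueError("minimum cluster size must be >= 1")
    try:
        structure = _STRUCTURES[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None

    # column index of every mask voxel in C scan order, for index lookup
    column_of = np.full(vol.mask.shape, -1, dtype=np.intp)
    column_of[vol.mask] = np.arange(int(vol.mask.sum()))

    if separate_signs:
        tails = [vol.values > z_thresh, vol.values < -z_thresh]
        signs = ["+", "-"]
    else:
        tails = [np.abs(vol.values) > z_thresh]
        signs = ["+/-"]

    found: list[tuple[np.ndarray, str]] = []
    for tail, sign in zip(tails, signs):
        labels, n_comp = ndimage.label(tail & vol.mask, structure=structure)
        for comp in range(1, n_comp + 1):
            cols = column_of[labels == comp]
            if cols.size >= min_size:
                found.append((np.sort(cols), sign))

    found.sort(key=lambda item: (-item[0].size, item[0][0]))
    return [
        VoxelSet(
            indices=cols,
            label=f"cluster {rank} ({sign}, |z|>{z_thresh:g}, n={cols.size})",
        )
        for rank, (cols, sign) in enumerate(found, start=1)
    ]
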