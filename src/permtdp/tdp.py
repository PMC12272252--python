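"""True discovery proportion bounds over arbitrary voxel sets.

From a calibrated critical vector ``l`` the simultaneous lower confidence
bound on the number of true discoveries in a voxel set ``S`` is

    a_bar(S) = max over u in 1..min(|S|, L) of  1 - u + #{i in S : p_i <= l_u}

floored at 0, where ``L`` is the vector's effective length (``m`` for the
shifted-Simes family, ``kmax`` for learned templates, whose constant-1 tail
carries no valid information).  The bound holds simultaneously over all
subsets S at confidence 1 - alpha, so sets may be chosen post hoc —
clusters, anatomical ROIs, drill-downs — without invalidating coverage.

Also here: the largest region reaching a fixed TDP level (over nested sets
of smallest p-values), the relative-size comparison metric between two
methods, and per-cluster report tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationResult
from .families import CriticalVector

__all__ = [
    "VoxelSet",
    "true_discovery_bound",
    "tdp_lower_bound",
    "largest_region_at_tdp",
    "percent_variation",
    "cluster_tdp_table",
]


@dataclass
class VoxelSet:
    """A subset of mask voxels, by 0-based column index, with provenance."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp).ravel()
        if idx.size == 0:
            raise ValueError("empty voxel set")
        if np.unique(idx).size != idx.size:
            raise ValueError("voxel indices must be unique")
        if idx.min() < 0:
            raise ValueError("voxel indices must be non-negative")
        self.indices = idx

    @property
    def size(self) -> int:
        return self.indices.size


def true_discovery_bound(pvals_in_S: np.ndarray, critvec: CriticalVector) -> int:
    """Lower confidence bound on the number of truly active voxels in S.

    Evaluates ``max_u (1 - u + #{p <= l_u})`` over usable ranks
    ``u <= min(|S|, effective_length)``, floored at 0.
    """
    p = np.asarray(pvals_in_S, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError("empty voxel set")
    u_max = min(p.size, critvec.effective_length)
    p_sorted = np.sort(p)
    thresholds = critvec.values[:u_max]
    counts = np.searchsorted(p_sorted, thresholds, side="right")
    u = np.arange(1, u_max + 1)
    return int(max(0, (1 - u + counts).max()))


def tdp_lower_bound(
    S: VoxelSet, identity_pvalues: np.ndarray, critvec: CriticalVector
) -> float:
    """Lower confidence bound on the TDP of S: a_bar(S) / |S|."""
    p = np.asarray(identity_pvalues, dtype=np.float64)
    a_bar = true_discovery_bound(p[S.indices], critvec)
    return a_bar / S.size


def largest_region_at_tdp(
    identity_pvalues: np.ndarray, critvec: CriticalVector, threshold: float
) -> tuple[int, VoxelSet | None]:
    """Largest k such that the k smallest p-values have TDP bound >= threshold.

    Scans every k exhaustively (the bound over nested smallest-p sets need
    not be monotone in k) but in O(m log m): for the set of the k smallest
    p-values, #{p <= l_u} = min(C_u, k) where C_u counts all p-values <=
    l_u, so the inner max splits at the first rank with C_u >= k.  Ties
    among p-values are broken by voxel scan order (stable argsort), so the
    returned set is reproducible.

    Returns ``(0, None)`` if no k qualifies.
    """
    if not 0 < threshold <= 1:
        raise ValueError("TDP threshold must lie in (0, 1]")
    p = np.asarray(identity_pvalues, dtype=np.float64).ravel()
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]

    L = min(m, critvec.effective_length)
    thresholds = critvec.values[:L]
    C = np.searchsorted(p_sorted, thresholds, side="right")  # non-decreasing
    T = 1 - np.arange(1, L + 1) + C
    prefix_max_T = np.maximum.accumulate(T)

    best_k = 0
    for k in range(1, m + 1):
        u_lim = min(k, L)
        # first 1-based rank u with C_u >= k (all-p count saturates at k there)
        u_sat = int(np.searchsorted(C, k, side="left")) + 1
        a_bar = 0
        if u_sat > 1:
            a_bar = max(a_bar, int(prefix_max_T[min(u_sat - 1, u_lim) - 1]))
        if u_sat <= u_lim:
            a_bar = max(a_bar, k + 1 - u_sat)
        if a_bar >= threshold * k:
            best_k = k
    if best_k == 0:
        return 0, None
    return best_k, VoxelSet(
        indices=order[:best_k], label=f"largest region at TDP>={threshold}"
    )


def percent_variation(size_a: int, size_b: int) -> float:
    """Relative size difference ``(|S|_a - |S|_b) / |S|_b``.

    Negative values mean method b found the larger region.  Undefined for
    ``size_b = 0`` (raises; callers flag such records instead of averaging
    them).
    """
    if size_b <= 0:
        raise ValueError("reference region size is 0: percent variation undefined")
    return (size_a - size_b) / size_b


def cluster_tdp_table(
    identity_pvalues: np.ndarray,
    clusters: list[VoxelSet],
    calibrations: dict[str, CalibrationResult],
) -> pd.DataFrame:
    """Per-cluster, per-method TDP report (one row per cluster x method).

    Columns: cluster_id, size, method, alpha, a_bar, tdp, best (the
    per-cluster maximum TDP across methods, computed on unrounded values).
    TDP is rounded only at presentation.
    """
    p = np.asarray(identity_pvalues, dtype=np.float64)
    m = p.size
    for name, cal in calibrations.items():
        if cal.critical_vector.m != m:
            raise ValueError(
                f"calibration {name!r} built for m={cal.critical_vector.m}, "
                f"p-value vector has m={m}"
            )
    rows = []
    for ci, cluster in enumerate(clusters):
        label = cluster.label or f"cluster {ci + 1}"
        for name, cal in calibrations.items():
            a_bar = true_discovery_bound(p[cluster.indices], cal.critical_vector)
            rows.append(
                {
                    "cluster_id": label,
                    "size": cluster.size,
                    "method": name,
                    "alpha": cal.alpha,
                    "a_bar": a_bar,
                    "tdp": a_bar / cluster.size,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["best"] = table.groupby("cluster_id")["tdp"].transform(
            lambda s: s == s.max()
        )
    return table
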