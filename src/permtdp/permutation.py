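"""Sign-flipping permutation engine for one-sample multi-subject contrast maps.

Turns an ``n_subjects x m_voxels`` matrix of contrast values into a
``w x m`` matrix of p-values, one row per data transformation.  Row 0 is
always the identity transformation (the observed data); the remaining
``w - 1`` rows apply independent random subject-level sign flips, which
preserve the null distribution of the one-sample t statistic when subject
errors are symmetric about zero.  Flipping whole subject maps (rather than
individual voxels) preserves the spatial correlation structure, which is
what the downstream lambda-calibration exploits.

Voxel columns follow a fixed row-major (C-order) scan over the nonzero
mask voxels, so column indices are stable across runs and I/O round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "SubjectMaps",
    "StatMatrix",
    "PermutationPValueMatrix",
    "load_subject_maps",
    "sign_flip_statistics",
    "statistics_to_pvalues",
    "sorted_pvalue_curves",
]

_P_FLOOR = np.finfo(np.float64).tiny  # p-values live in (0, 1]


@dataclass
class SubjectMaps:
    """Per-subject contrast values restricted to the voxels of a brain mask.

    Parameters
    ----------
    data:
        ``(n_subjects, m_voxels)`` array of contrast values.
    mask:
        3D boolean array; ``data`` columns correspond to ``True`` voxels in
        C (row-major) scan order.
    affine:
        Optional 4x4 voxel-to-world transform carried along for I/O.
    """

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("data must be 2D (n_subjects x m_voxels)")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.m_voxels < 1 or self.m_voxels != int(self.mask.sum()):
            raise ValueError(
                f"data has {self.m_voxels} columns but mask has "
                f"{int(self.mask.sum())} nonzero voxels"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def m_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def mask_shape(self) -> tuple[int, ...]:
        return self.mask.shape

    @property
    def voxel_coords(self) -> np.ndarray:
        """``(m_voxels, 3)`` grid coordinates of each column, C scan order."""
        return np.argwhere(self.mask)

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a length-``m`` vector back onto the 3D grid."""
        vol = np.full(self.mask.shape, fill, dtype=np.float64)
        vol[self.mask] = values
        return vol


@dataclass
class StatMatrix:
    """``w x m`` one-sample t statistics under sign-flip transformations."""

    values: np.ndarray
    transform_codes: np.ndarray  # (w, n_subjects) entries in {-1, +1}
    identity_row: int = 0

    def __post_init__(self) -> None:
        if not np.all(self.transform_codes[self.identity_row] == 1):
            raise ValueError("identity row must carry the all-+1 sign vector")
        if self.values.shape[0] < 2:
            raise ValueError("need w >= 2 transformations")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite test statistics")

    @property
    def w(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.transform_codes.shape[1]


@dataclass
class PermutationPValueMatrix:
    """``w x m`` p-values in (0, 1], one row per data transformation."""

    pvalues: np.ndarray
    identity_row: int = 0
    sorted_curves: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.pvalues, dtype=np.float64)
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        self.pvalues = p

    @property
    def w(self) -> int:
        return self.pvalues.shape[0]

    @property
    def m(self) -> int:
        return self.pvalues.shape[1]

    @property
    def identity_pvalues(self) -> np.ndarray:
        """The observed-data (untransformed) p-values."""
        return self.pvalues[self.identity_row]


def load_subject_maps(map_paths, mask_path) -> SubjectMaps:
    """Read per-subject NIfTI contrast volumes restricted to a binary mask.

    ``map_paths`` may be a list of 3D volumes (one per subject) or a single
    4D volume whose last axis indexes subjects.
    """
    import nibabel as nib

    mask_img = nib.load(str(mask_path))
    mask_data = np.asanyarray(mask_img.dataobj)
    uniq = np.unique(mask_data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask is not binary (values other than 0/1 found)")
    mask = mask_data.astype(bool)
    if not mask.any():
        raise ValueError("empty mask: no nonzero voxels")

    if isinstance(map_paths, (str, bytes)) or hasattr(map_paths, "__fspath__"):
        map_paths = [map_paths]
    volumes = []
    for path in map_paths:
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj, dtype=np.float64)
        if arr.ndim == 4:
            if arr.shape[:3] != mask.shape:
                raise ValueError(
                    f"volume grid {arr.shape[:3]} does not match mask {mask.shape}"
                )
            volumes.extend(arr[..., t] for t in range(arr.shape[3]))
        elif arr.ndim == 3:
            if arr.shape != mask.shape:
                raise ValueError(
                    f"volume grid {arr.shape} does not match mask {mask.shape}"
                )
            volumes.append(arr)
        else:
            raise ValueError(f"expected 3D or 4D volume, got {arr.ndim}D")
    data = np.stack([v[mask] for v in volumes], axis=0)
    return SubjectMaps(data=data, mask=mask, affine=np.asarray(mask_img.affine))


def sign_flip_statistics(maps: SubjectMaps, w: int, seed: int) -> StatMatrix:
    """One-sample t statistics under ``w`` sign-flip transformations.

    Row 0 is the identity (all-+1 signs); the other ``w - 1`` rows draw
    sign vectors i.i.d. uniform over {-1, +1}^n and flip whole subject maps.
    Deterministic given ``seed``.
    """
    if w < 2:
        raise ValueError("need w >= 2 transformations (identity plus at least one)")
    data = maps.data
    n = maps.n_subjects

    sd0 = data.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(sd0 == 0)
    if zero_var.size:
        raise ValueError(
            f"zero-variance voxel(s) at column index {zero_var[:10].tolist()}"
        )

    rng = np.random.default_rng(seed)
    signs = np.ones((w, n), dtype=np.int8)
    signs[1:] = rng.choice(np.array([-1, 1], dtype=np.int8), size=(w - 1, n))

    # Sum of squares is invariant under sign flips, so only the mean moves.
    means = (signs.astype(np.float64) @ data) / n
    ssq = np.einsum("ij,ij->j", data, data)
    var = (ssq - n * means**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    if not np.all(np.isfinite(t)):
        bad = np.argwhere(~np.isfinite(t))
        raise ValueError(
            f"degenerate (zero-variance) flipped sample at (row, voxel) {bad[0].tolist()}"
        )
    return StatMatrix(values=t, transform_codes=signs, identity_row=0)


def statistics_to_pvalues(
    stats: StatMatrix,
    df: int | None = None,
    alternative: str = "one-sided-upper",
) -> PermutationPValueMatrix:
    """Map t statistics to Student-t tail p-values, row by row.

    The same monotone transform is applied to every row, which is all the
    calibration step requires.  ``df`` defaults to ``n_subjects - 1``.
    """
    if df is None:
        df = stats.n_subjects - 1
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    if alternative == "one-sided-upper":
        p = _sps.t.sf(stats.values, df)
    elif alternative == "two-sided":
        p = 2.0 * _sps.t.sf(np.abs(stats.values), df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = np.clip(p, _P_FLOOR, 1.0)
    return PermutationPValueMatrix(pvalues=p, identity_row=stats.identity_row)


def sorted_pvalue_curves(pmat: PermutationPValueMatrix) -> PermutationPValueMatrix:
    """Fill ``sorted_curves`` with each row sorted ascending. Idempotent."""
    if pmat.sorted_curves is None:
        pmat.sorted_curves = np.sort(pmat.pvalues, axis=1)
    return pmat


def save_pvalue_matrix(pmat: PermutationPValueMatrix, prefix, **metadata) -> None:
    """Persist the matrix as a .npy array plus a JSON sidecar (shape,
    identity row, caller-supplied metadata such as seed or mask checksum)."""
    import json
    from pathlib import Path

    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), pmat.pvalues)
    sidecar = {
        "shape": list(pmat.pvalues.shape),
        "identity_row": pmat.identity_row,
        **metadata,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def load_pvalue_matrix(prefix) -> PermutationPValueMatrix:
    import json
    from pathlib import Path

    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    pvalues = np.load(prefix.with_suffix(".npy"))
    if list(pvalues.shape) != sidecar["shape"]:
        raise ValueError("sidecar shape does not match stored array")
    return PermutationPValueMatrix(
        pvalues=pvalues, identity_row=sidecar["identity_row"]
    )
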