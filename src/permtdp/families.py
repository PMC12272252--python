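"""Candidate critical-vector families for ordered p-values.

A critical vector is a non-decreasing vector ``l = (l_1, ..., l_m)`` of
thresholds for sorted p-values.  Each family is a one-parameter collection
``l(lambda)``, non-decreasing in rank and, pointwise, in lambda:

* **Shifted Simes** (pARI): ``l_i(lambda) = (i - delta) * lambda / (m - delta)``
  with an integer shift ``delta`` in ``{0, ..., m-1}``.  ``delta = 0`` is the
  classical Simes line ``i * lambda / m``; ``delta > 0`` sacrifices all power
  on voxel sets of size <= delta in exchange for power on large clusters.
* **Learned template** (Notip): ``l_i(lambda)`` is the lambda-quantile of the
  rank-i sorted p-values over ``w_tilde`` reference permutations, truncated
  to 1 above a rank bound ``kmax``; concretely the ``floor(lambda * w_tilde)``-th
  smallest reference value at each rank.

Each family also induces, for a sorted p-value curve, the *lambda statistic*:
the supremum of lambda at which the curve still lies strictly above
``l(lambda)`` at every usable rank.  Calibration takes per-curve lambda
statistics over permutation curves and picks the largest lambda that at
least ``(1 - alpha) * w`` of them exceed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

__all__ = [
    "SimesFamily",
    "LearnedTemplateFamily",
    "CriticalVector",
    "simes_vector",
    "simes_curve_lambda",
    "build_learned_family",
    "learned_vector",
    "learned_curve_lambda",
    "save_family",
    "load_family",
]

DEFAULT_DELTA = 27  # recommended shift for large-cluster fMRI inference (3^3)
DEFAULT_KMAX = 1000  # recommended truncation rank for learned templates


@dataclass
class CriticalVector:
    """A realized non-decreasing threshold vector for sorted p-values.

    ``effective_length`` is the largest rank usable in the true-discovery
    bound: ``m`` for Simes vectors, ``kmax`` for learned templates (whose
    tail is the unusable constant 1).
    """

    values: np.ndarray
    effective_length: int
    lambda_star: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(np.diff(self.values) < 0):
            raise ValueError("critical vector must be non-decreasing")
        if not 0 < self.effective_length <= self.values.size:
            raise ValueError("effective_length out of range")

    @property
    def m(self) -> int:
        return self.values.size


@dataclass
class SimesFamily:
    """Shifted-Simes family ``l_i(lambda) = (i - delta) * lambda / (m - delta)``."""

    m: int
    delta: int = DEFAULT_DELTA

    def __post_init__(self) -> None:
        if not 0 <= self.delta <= self.m - 1:
            raise ValueError(f"delta must lie in [0, m-1], got {self.delta} (m={self.m})")

    @property
    def name(self) -> str:
        return f"simes(delta={self.delta})"

    @property
    def effective_length(self) -> int:
        return self.m

    def vector(self, lam: float) -> CriticalVector:
        if not 0 <= lam <= 1:
            raise ValueError("lambda must lie in [0, 1]")
        ranks = np.arange(1, self.m + 1, dtype=np.float64)
        values = (ranks - self.delta) * lam / (self.m - self.delta)
        # ranks below the shift get a negative threshold; clamp to 0 — no
        # p-value in (0, 1] can sit at or below either, and clamping keeps
        # the vector pointwise non-decreasing in lambda
        np.maximum(values, 0.0, out=values)
        return CriticalVector(values=values, effective_length=self.m, lambda_star=lam)

    def curve_lambda(self, sorted_curve: np.ndarray) -> float:
        return float(self.curve_lambdas(np.asarray(sorted_curve)[None, :])[0])

    def curve_lambdas(self, sorted_curves: np.ndarray) -> np.ndarray:
        """Vectorized lambda statistic, one per row of sorted p-values.

        min over ranks i > delta of ``p_(i) * (m - delta) / (i - delta)``.
        """
        sorted_curves = np.asarray(sorted_curves, dtype=np.float64)
        m = sorted_curves.shape[1]
        if m != self.m:
            raise ValueError(f"curve length {m} != family m {self.m}")
        ranks = np.arange(self.delta + 1, m + 1, dtype=np.float64)
        ratios = sorted_curves[:, self.delta:] * (m - self.delta) / (ranks - self.delta)
        return np.minimum(ratios.min(axis=1), 1.0)


@dataclass
class LearnedTemplateFamily:
    """Rank-wise quantile templates learned from reference permutation curves.

    ``reference_quantiles`` has shape ``(kmax, w_tilde)``; entry ``(i, t)``
    (0-based) is the (t+1)-th smallest value among the rank-(i+1) sorted
    p-values over the reference transformations.  Rows are non-decreasing
    left to right (sorted), columns non-decreasing top to bottom (curves
    were sorted by rank).
    """

    reference_quantiles: np.ndarray
    m: int
    kmax: int = field(default=DEFAULT_KMAX)

    def __post_init__(self) -> None:
        q = np.asarray(self.reference_quantiles, dtype=np.float64)
        if q.ndim != 2 or q.shape[0] != self.kmax:
            raise ValueError("reference_quantiles must be (kmax, w_tilde)")
        if not 1 <= self.kmax <= self.m:
            raise ValueError(f"kmax must lie in [1, m], got {self.kmax}")
        if np.any(np.diff(q, axis=1) < 0):
            raise ValueError("reference_quantiles rows must be non-decreasing")
        if np.any(np.diff(q, axis=0) < 0):
            raise ValueError("reference_quantiles columns must be non-decreasing")
        self.reference_quantiles = q

    @property
    def w_tilde(self) -> int:
        return self.reference_quantiles.shape[1]

    @property
    def name(self) -> str:
        return f"learned(kmax={self.kmax}, w_tilde={self.w_tilde})"

    @property
    def effective_length(self) -> int:
        return self.kmax

    def vector(self, lam: float) -> CriticalVector:
        """Critical vector at lambda: the floor(lambda * w_tilde)-th smallest
        reference value at each rank <= kmax, constant 1 above kmax.

        lambda below 1/w_tilde has no quantile to point at; the all-zero
        vector is returned so calibration degrades gracefully.
        """
        if not 0 <= lam <= 1:
            raise ValueError("lambda must lie in [0, 1]")
        # nudge guards floor() against 0.999... representations of grid values
        j = int(np.floor(lam * self.w_tilde + 1e-9))
        values = np.ones(self.m, dtype=np.float64)
        if j < 1:
            values[:] = 0.0
        else:
            values[: self.kmax] = self.reference_quantiles[:, j - 1]
        return CriticalVector(
            values=values, effective_length=self.kmax, lambda_star=lam
        )

    def curve_lambda(self, sorted_curve: np.ndarray) -> float:
        return float(self.curve_lambdas(np.asarray(sorted_curve)[None, :])[0])

    def curve_lambdas(self, sorted_curves: np.ndarray) -> np.ndarray:
        """Grid lambda statistic per row: ``min_i h_i / w_tilde`` where
        ``h_i`` counts reference values at rank i strictly below ``p_(i)``."""
        sorted_curves = np.asarray(sorted_curves, dtype=np.float64)
        if sorted_curves.shape[1] != self.m:
            raise ValueError(
                f"curve length {sorted_curves.shape[1]} != family m {self.m}"
            )
        n_curves = sorted_curves.shape[0]
        h_min = np.full(n_curves, self.w_tilde, dtype=np.int64)
        for i in range(self.kmax):
            h_i = np.searchsorted(
                self.reference_quantiles[i], sorted_curves[:, i], side="left"
            )
            np.minimum(h_min, h_i, out=h_min)
        return h_min / self.w_tilde


def build_learned_family(
    reference_sorted_curves: np.ndarray, kmax: int = DEFAULT_KMAX
) -> LearnedTemplateFamily:
    """Build a learned-template family from row-sorted reference p-value curves.

    ``reference_sorted_curves`` is ``(w_tilde, m)``, each row the ascending
    sorted p-values of one reference transformation.  Row i of the family's
    quantile table is the ascending sort of column i, truncated at ``kmax``.
    """
    curves = np.asarray(reference_sorted_curves, dtype=np.float64)
    if curves.ndim != 2:
        raise ValueError("reference curves must be a 2D (w_tilde, m) array")
    if np.any(np.diff(curves, axis=1) < 0):
        raise ValueError("reference curves must be row-sorted ascending")
    m = curves.shape[1]
    if not 1 <= kmax <= m:
        raise ValueError(f"kmax must lie in [1, m={m}], got {kmax}")
    quantiles = np.sort(curves[:, :kmax], axis=0).T  # (kmax, w_tilde)
    return LearnedTemplateFamily(reference_quantiles=quantiles, m=m, kmax=kmax)


# -- thin functional wrappers over the family methods ------------------------

def simes_vector(family: SimesFamily, lam: float) -> CriticalVector:
    return family.vector(lam)


def simes_curve_lambda(family: SimesFamily, sorted_curve: np.ndarray) -> float:
    return family.curve_lambda(sorted_curve)


def learned_vector(family: LearnedTemplateFamily, lam: float) -> CriticalVector:
    return family.vector(lam)


def learned_curve_lambda(family: LearnedTemplateFamily, sorted_curve: np.ndarray) -> float:
    return family.curve_lambda(sorted_curve)


def save_family(family, prefix) -> None:
    """Serialize a family as a JSON parameter file plus a .npy array."""
    prefix = Path(prefix)
    if isinstance(family, SimesFamily):
        meta = {"kind": "simes", "m": family.m, "delta": family.delta}
    elif isinstance(family, LearnedTemplateFamily):
        meta = {"kind": "learned", "m": family.m, "kmax": family.kmax}
        np.save(prefix.with_suffix(".npy"), family.reference_quantiles)
    else:
        raise TypeError(f"cannot serialize {type(family).__name__}")
    prefix.with_suffix(".json").write_text(json.dumps(meta))


def load_family(prefix):
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    if meta["kind"] == "simes":
        return SimesFamily(m=meta["m"], delta=meta["delta"])
    quantiles = np.load(prefix.with_suffix(".npy"))
    return LearnedTemplateFamily(
        reference_quantiles=quantiles, m=meta["m"], kmax=meta["kmax"]
    )
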