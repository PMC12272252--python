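"""Lambda-calibration of a critical-vector family against permutation curves.

Given ``w`` sorted p-value curves (one per data transformation, the
identity among them) and a family ``l(lambda)``, calibration selects the
largest lambda such that at least ``(1 - alpha) * w`` of the curves lie
*strictly* above ``l(lambda)`` at every usable rank.  Because the count of
dominating curves only changes at the per-curve lambda statistics, the
maximization scans exactly those candidates (plus 0) and evaluates the
count directly — exact under ties, no order-statistic index arithmetic.

The identity transformation participates like any other row; its presence
among the ``w`` transformations is what makes the joint error rate control
exact at level alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .families import CriticalVector
from .permutation import PermutationPValueMatrix, sorted_pvalue_curves

__all__ = ["CalibrationResult", "calibrate", "calibrated_bound_pipeline"]


@dataclass
class CalibrationResult:
    """Outcome of lambda-calibration.

    Attributes
    ----------
    lambda_star:
        The calibrated lambda (0 if no candidate satisfies the count).
    lambda_stats:
        The ``w`` per-transformation lambda statistics.
    alpha:
        Target joint error rate.
    w:
        Number of transformations (identity included).
    family_ref:
        Human-readable identifier of the calibrated family.
    critical_vector:
        The family evaluated at ``lambda_star``.
    """

    lambda_star: float
    lambda_stats: np.ndarray
    alpha: float
    w: int
    family_ref: str
    critical_vector: CriticalVector

    def to_dict(self) -> dict:
        return {
            "lambda_star": self.lambda_star,
            "alpha": self.alpha,
            "w": self.w,
            "family": self.family_ref,
            "effective_length": self.critical_vector.effective_length,
        }


def _count_above(lambda_stats: np.ndarray, lam: float) -> int:
    """Number of curves strictly dominating l(lam), i.e. with stat > lam."""
    return int(np.sum(lambda_stats > lam))


def calibrate(family, curves: np.ndarray, alpha: float) -> CalibrationResult:
    """Select the largest lambda whose critical vector is dominated by at
    least ``(1 - alpha) * w`` of the ``w`` sorted permutation curves.

    Parameters
    ----------
    family:
        A ``SimesFamily`` or ``LearnedTemplateFamily``.
    curves:
        ``(w, m)`` matrix of row-sorted p-values, identity row included.
    alpha:
        Joint error rate in (0, 1); requires ``w * alpha >= 1``.
    """
    curves = np.asarray(curves, dtype=np.float64)
    if curves.ndim != 2:
        raise ValueError("curves must be a 2D (w, m) matrix")
    w = curves.shape[0]
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if w * alpha < 1:
        raise ValueError(
            f"w * alpha = {w * alpha:.3g} < 1: calibration would be forced to "
            "lambda* = 0; raise the number of transformations w or alpha"
        )

    lambda_stats = np.asarray(family.curve_lambdas(curves), dtype=np.float64)
    # compared as a real number (count is an integer); the epsilon absorbs
    # binary representation error of decimal alphas, e.g. (1-0.95)*20 != 1.0
    need = (1.0 - alpha) * w - 1e-9
    lambda_star = 0.0
    for cand in np.unique(lambda_stats)[::-1]:
        if _count_above(lambda_stats, cand) >= need:
            lambda_star = float(cand)
            break
    return CalibrationResult(
        lambda_star=lambda_star,
        lambda_stats=lambda_stats,
        alpha=alpha,
        w=w,
        family_ref=family.name,
        critical_vector=family.vector(lambda_star),
    )


def calibrated_bound_pipeline(
    pmat: PermutationPValueMatrix, family, alpha: float
) -> CalibrationResult:
    """Convenience composition: sort curves, then calibrate."""
    pmat = sorted_pvalue_curves(pmat)
    return calibrate(family, pmat.sorted_curves, alpha)
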