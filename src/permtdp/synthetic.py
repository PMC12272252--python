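"""Synthetic inputs with the statistical structure the methods assume.

The generator emulates multi-subject contrast maps: per subject, a white
Gaussian field on a 3D grid is convolved with a Gaussian kernel of a given
FWHM (voxel units) and rescaled to exact unit voxel variance, then a fixed
mean shift (``effect_size``, in noise-sd units) is added on an optional
planted active set.  Smoothing induces the positive local spatial
correlation that calibration is designed to exploit; subject maps are
independent (contrasts are already time-collapsed, so no temporal
structure is modelled).  The kernel is truncated at the grid boundary with
per-voxel renormalization, so variance is exactly 1 everywhere.

Also here: exchangeable uniform p-value matrices for calibration unit
tests, and the two headline simulation experiments — joint-error-rate
coverage under the global null, and recovery of lambda* ~ alpha for the
classical Simes family under independence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import CalibrationResult, calibrate
from .families import SimesFamily, build_learned_family
from .permutation import (
    PermutationPValueMatrix,
    SubjectMaps,
    sign_flip_statistics,
    sorted_pvalue_curves,
    statistics_to_pvalues,
)
from .tdp import VoxelSet

__all__ = [
    "GroundTruth",
    "generate_maps",
    "generate_uniform_pvalue_matrix",
    "CoverageResult",
    "coverage_experiment",
    "lambda_recovery_experiment",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class GroundTruth:
    """Configuration of one synthetic dataset, with known active set."""

    n_subjects: int
    grid_shape: tuple[int, int, int]
    smoothing_fwhm: float = 0.0
    active_set: VoxelSet | None = None
    effect_size: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smoothing_fwhm < 0:
            raise ValueError("FWHM must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect size must be non-negative")
        m = int(np.prod(self.grid_shape))
        if self.active_set is not None and self.active_set.indices.max() >= m:
            raise ValueError("active set extends beyond the grid")

    @property
    def m_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


def _gaussian_weights(fwhm: float) -> np.ndarray:
    sigma = fwhm * _FWHM_TO_SIGMA
    radius = max(1, int(4.0 * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def _smooth_unit_variance(white: np.ndarray, fwhm: float) -> np.ndarray:
    """Convolve a white field with a separable Gaussian, truncated at the
    boundary, then rescale so every voxel has variance exactly 1.

    For white noise, Var of the smoothed field at voxel v is the sum of the
    squared effective kernel weights; separability makes that sum a product
    of per-axis 1D correlations of a ones-vector with the squared weights.
    """
    if fwhm == 0:
        return white
    w = _gaussian_weights(fwhm)
    smoothed = white
    sd_axes = []
    for axis in range(white.ndim):
        smoothed = ndimage.correlate1d(smoothed, w, axis=axis, mode="constant")
        ones = np.ones(white.shape[axis])
        ssq = ndimage.correlate1d(ones, w**2, mode="constant")
        sd_axes.append(np.sqrt(ssq))
    sd = sd_axes[0][:, None, None] * sd_axes[1][None, :, None] * sd_axes[2][None, None, :]
    return smoothed / sd


def generate_maps(truth: GroundTruth, rng: np.random.Generator | None = None) -> SubjectMaps:
    """Draw one synthetic multi-subject dataset; deterministic given the seed.

    An explicit ``rng`` (used by the experiment drivers) overrides
    ``truth.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    shape = tuple(truth.grid_shape)
    data = np.empty((truth.n_subjects, truth.m_voxels))
    shift = np.zeros(truth.m_voxels)
    if truth.active_set is not None and truth.effect_size > 0:
        shift[truth.active_set.indices] = truth.effect_size
    for s in range(truth.n_subjects):
        white = rng.standard_normal(shape)
        data[s] = _smooth_unit_variance(white, truth.smoothing_fwhm).ravel() + shift
    mask = np.ones(shape, dtype=bool)
    return SubjectMaps(data=data, mask=mask)


def generate_uniform_pvalue_matrix(w: int, m: int, seed: int) -> PermutationPValueMatrix:
    """i.i.d. Uniform(0, 1) p-values, w rows (row 0 designated identity).

    Models the exchangeable independent-null setting used by the
    calibration unit tests and the lambda-recovery experiment.
    """
    if w < 2:
        raise ValueError("need w >= 2 rows")
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=(w, m))
    p[p == 0] = np.finfo(np.float64).tiny
    return PermutationPValueMatrix(pvalues=p, identity_row=0)


@dataclass
class CoverageResult:
    """Empirical joint-error-rate estimate from a null simulation."""

    violation_rate: float
    standard_error: float
    n_reps: int
    n_violations: int
    per_family: dict = field(default_factory=dict)


def _violates(sorted_identity_curve: np.ndarray, critvec) -> bool:
    """True if the observed sorted curve touches or crosses below the
    critical vector at any usable rank (the joint-error-rate event)."""
    L = min(sorted_identity_curve.size, critvec.effective_length)
    return bool(np.any(sorted_identity_curve[:L] <= critvec.values[:L]))


def coverage_experiment(
    truth: GroundTruth,
    alpha: float,
    w: int,
    n_reps: int,
    seed: int,
    families: dict | None = None,
    learned_w_tilde: int | None = None,
    learned_kmax: int | None = None,
    fixed_vector=None,
) -> dict[str, CoverageResult]:
    """Estimate the joint error rate under the global null by simulation.

    For each replicate: draw null subject maps, compute ``w`` sign-flip
    p-value curves (identity included), calibrate each family at ``alpha``,
    and record whether the observed sorted curve falls at or below the
    calibrated critical vector at any usable rank.  Under the global null
    every voxel is inactive, so this is exactly the event whose probability
    the calibration bounds by ``alpha``.

    ``families`` maps names to family objects or factories ``m -> family``;
    default is Simes with delta=0.  If ``learned_w_tilde`` is given, a
    learned-template family is additionally built once from an independent
    synthetic null reference dataset of the same geometry.  A
    ``fixed_vector`` bypasses calibration entirely (diagnostic use).

    Returns one ``CoverageResult`` per family, with a binomial standard
    error; all replicates share the same data, so the per-family rates are
    paired.
    """
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    root = np.random.SeedSequence(seed)
    ref_seq, rep_seq = root.spawn(2)
    m = truth.m_voxels

    if families is None:
        families = {"simes(delta=0)": SimesFamily(m=m, delta=0)}
    realized = {
        name: (fam(m) if callable(fam) else fam) for name, fam in families.items()
    }
    if learned_w_tilde is not None:
        kmax = min(learned_kmax or m, m)
        ref_rng = np.random.default_rng(ref_seq)
        ref_maps = generate_maps(truth, rng=ref_rng)
        ref_stats = sign_flip_statistics(
            ref_maps, w=learned_w_tilde, seed=int(ref_seq.generate_state(1)[0] >> 1)
        )
        ref_pmat = sorted_pvalue_curves(statistics_to_pvalues(ref_stats))
        realized[f"learned(kmax={kmax})"] = build_learned_family(
            ref_pmat.sorted_curves, kmax=kmax
        )

    violations = {name: 0 for name in realized}
    for child in rep_seq.spawn(n_reps):
        rep_rng = np.random.default_rng(child)
        maps = generate_maps(truth, rng=rep_rng)
        stats = sign_flip_statistics(
            maps, w=w, seed=int(child.generate_state(1)[0] >> 1)
        )
        pmat = sorted_pvalue_curves(statistics_to_pvalues(stats))
        identity_curve = pmat.sorted_curves[pmat.identity_row]
        for name, fam in realized.items():
            if fixed_vector is not None:
                vec = fixed_vector
            else:
                vec = calibrate(fam, pmat.sorted_curves, alpha).critical_vector
            violations[name] += _violates(identity_curve, vec)

    results = {}
    for name, v in violations.items():
        rate = v / n_reps
        results[name] = CoverageResult(
            violation_rate=rate,
            standard_error=float(np.sqrt(rate * (1 - rate) / n_reps)),
            n_reps=n_reps,
            n_violations=v,
        )
    return results


def lambda_recovery_experiment(
    m: int, w: int, n_reps: int, alpha: float, seed: int
) -> dict[str, float]:
    """Mean and sd of the calibrated lambda* for classical Simes (delta=0)
    on independent uniform p-values.

    Under independence the Simes inequality is an equality, so the lambda
    statistic of each curve is itself Uniform(0, 1) and lambda* is the
    empirical alpha-quantile of w uniforms: the mean of lambda* over
    replicates concentrates near alpha.
    """
    family = SimesFamily(m=m, delta=0)
    root = np.random.SeedSequence(seed)
    stars = []
    for child in root.spawn(n_reps):
        pmat = generate_uniform_pvalue_matrix(
            w=w, m=m, seed=int(child.generate_state(1)[0] >> 1)
        )
        curves = np.sort(pmat.pvalues, axis=1)
        stars.append(calibrate(family, curves, alpha).lambda_star)
    stars = np.asarray(stars)
    return {
        "mean_lambda_star": float(stars.mean()),
        "sd_lambda_star": float(stars.std(ddof=1)) if n_reps > 1 else 0.0,
        "n_reps": n_reps,
    }
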