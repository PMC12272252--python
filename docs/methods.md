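# Methods

## Model and guarantee

For m voxels with p-values p₁, …, p_m and unknown active set A, the package
computes lower (1 − α)-confidence bounds a̅(S) on |A ∩ S| that hold
simultaneously over all subsets S. Validity rests on a single condition on
the critical vector ℓ: the sorted p-values q₍₁₎ ≤ … ≤ q₍|N|₎ of the
*inactive* voxels N = B \ A must lie entirely above ℓ with probability at
least 1 − α (the joint error rate, JER). Given that event, the bound

    a̅(S) = max_{1 ≤ u ≤ min(|S|, L)} ( 1 − u + #{ i ∈ S : pᵢ ≤ ℓᵤ } ),

floored at 0, never overcounts discoveries, for every S at once. L is the
vector's *effective length*: the largest rank whose threshold is below 1
and therefore informative (see "Truncation" below).

## Calibration

The JER condition is enforced nonparametrically. Under the one-sample
symmetric-error model, multiplying all of a subject's voxels by a random
±1 sign preserves the null distribution of the one-sample t statistic while
keeping the spatial correlation intact. The engine computes w statistic
rows — the identity (observed data) plus w − 1 independent sign-flip rows —
and maps them to p-values with the same monotone Student-t tail transform
per row. Including the identity among the w transformations is what makes
the control exact rather than approximate.

Each family induces, per sorted curve, a λ statistic: the supremum of λ at
which the curve stays strictly above ℓ(λ) at every usable rank (for the
learned family this lives on the grid {j/w̃}). Calibration returns the
largest candidate λ — candidates are exactly the w per-curve statistics,
plus 0 — such that the number of curves with statistic strictly greater
than λ is at least (1 − α)·w. Ties are handled by evaluating the count
directly, never by order-statistic index arithmetic, so equal λ statistics
cannot silently overshoot the level. The count is compared against
(1 − α)·w as a real number, with a 1e-9 epsilon absorbing the binary
representation error of decimal α (e.g. (1 − 0.95)·20 ≠ 1.0 in floats).
Calibration requires w·α ≥ 1; below that no candidate can pass and the
procedure refuses rather than silently returning λ* = 0.

## Families and their parameters

**Shifted Simes** ℓᵢ(λ) = (i − δ)λ/(m − δ), δ ∈ {0, …, m−1}, default 27.
δ is the size of the voxel sets entirely sacrificed: any S with |S| ≤ δ has
a̅(S) = 0 because its usable thresholds are ≤ 0. In exchange every rank
above δ gets a steeper threshold, which raises the calibrated λ*
dramatically (in the worked examples, from ≈ 0.06 at δ = 0 to ≈ 0.7 at
δ = 27) and with it the bounds on large clusters. Ranks below the shift
formally get negative thresholds; they are clamped to 0, which changes
nothing (no p-value in (0, 1] can fall at or below either) and keeps
vectors pointwise non-decreasing in λ.

**Learned templates**: from w̃ reference sorted curves, row i of the family
is the ascending sort of the rank-i values; ℓᵢ(λ) indexes the
⌊λw̃⌋-th smallest of them. λ below 1/w̃ has no quantile to point at and
evaluates to the all-zero vector, so a calibration that finds no usable
grid point degrades to a powerless — never invalid — bound. kmax (default
1000) truncates the family: ranks above kmax are 1. The reference curves
must have exactly m columns; cross-resolution templates are not
implemented. The reference count w̃ matters more than it may appear: the
calibrated grid index ⌊λ*w̃⌋ is typically small (single digits per
thousand), so w̃ in the thousands is needed for the index to resolve at
all — with w̃ of a few hundred the index pins at 1 and the method is
reduced to the pointwise minimum of the reference curves.

**Truncation and the bound.** The constant-1 tail above kmax is excluded
from the max in a̅(S) (effective_length = kmax). Taking u with ℓᵤ = 1
literally would claim at least |S| − kmax discoveries in *any* set, which
the JER condition cannot support; ignoring all p-values beyond the kmax-th
is the intended semantics of the truncation.

## Test sidedness

P-values default to one-sided upper-tail (activation > 0), matching
standard contrast inference; a two-sided option is exposed. Cluster
formation, by contrast, always uses |z| so both activation and
deactivation clusters are reported (sign-homogeneous by default, since a
mixed-sign component has no interpretation; a flag merges the tails).

## Largest region at a TDP level

The comparison metric between methods is the size of the largest set of
smallest p-values whose TDP bound still reaches a threshold t
(t ∈ {0.8, 0.9, 0.95} by convention), with the relative difference
(|S|ₐ − |S|_b)/|S|_b summarizing two methods. The scan over k is
exhaustive — the bound over nested smallest-p sets is not monotone in k —
but runs in O(m log m): for the k smallest p-values the inner count is
min(C_u, k) with C_u the count over all voxels, so the inner max splits at
the first rank where C_u ≥ k, and both branches are prefix-computable.
Equality with the naive per-k evaluation is asserted in the tests. Ties
among p-values are broken by voxel scan order (stable sort), so reported
regions are reproducible.

## Synthetic data

The generator emulates multi-subject contrast maps: per subject an
independent white Gaussian field on the grid, convolved with a separable
Gaussian kernel of given FWHM (voxels), truncated at the grid boundary with
exact per-voxel variance renormalization (for white noise the smoothed
variance is the product over axes of 1D correlations of a ones-vector with
the squared kernel weights), then a constant effect (in noise-sd units)
added on the planted active set. Defaults used by the experiments: n = 20
subjects, 12×12×12 grid (m = 1728), FWHM 2 voxels, w = 200
transformations — a desk-scale stand-in for real acquisitions, chosen so
the full 500-replicate coverage experiment completes in about a minute.

What the generator does *not* emulate: non-stationary smoothness,
anatomical masks with irregular topology, between-subject variance
heterogeneity, and the heavy preprocessing of real pipelines. Passing
coverage on it therefore demonstrates the correctness of the calibration
machinery under the model's assumptions (exchangeable sign-symmetric
subject errors, stationary smooth noise), not robustness to their
violation — which is the methods' own stated scope.

Scale effects worth knowing when extrapolating to real maps (m ≈ 5·10⁴,
clusters of 10³–10⁴ voxels): at m = 1728 the default kmax = 1000 truncates
very little, and δ = 27 is a larger fraction of realistic cluster sizes
than it would be at full resolution, so the shifted family's advantage
appears at moderate effect sizes and large planted regions, and reverses
(as it must) when nearly every p-value in a set is tiny, where
a̅ saturates near |S| − δ versus |S|.

## Experiments

- **Coverage**: replicate global-null datasets; per replicate, calibrate
  each family and record whether the observed sorted curve touches or
  crosses ℓ at any usable rank. Under the global null every voxel is
  inactive, so this is exactly the JER event; the empirical rate must stay
  at or below α up to binomial noise. All families share each replicate's
  data, making the per-family rates paired. The learned family's reference
  curves come from an additional independent null dataset.
- **λ recovery**: on i.i.d. uniform p-values the Simes inequality is an
  equality, so each curve's δ = 0 λ statistic is itself Uniform(0, 1) and
  λ* — essentially the empirical α-quantile of w uniforms — concentrates
  near α. Run at m = 500, w = 2000, 20 replicates.

## Numerical choices and degenerate inputs

- p-values are clipped below at the smallest positive double so the (0, 1]
  invariant survives extreme statistics.
- Zero-variance voxels under the identity are an error (reported with
  index); a zero-variance *flipped* sample (possible only for adversarial
  tiny-n data) is also an error rather than an infinite statistic.
- Sign vectors are drawn i.i.d. uniform without deduplication; the
  identity is forced as row 0 and never sampled away.
- The bound's optimized evaluation (sort + vectorized searchsorted) is
  checked for exact integer equality against a naive double loop over
  1000 random instances.
- The learned-family quantile index uses ⌊λw̃⌋ with a 1e-9 nudge so grid
  values reconstructed from h/w̃ arithmetic do not floor one step down.

## Known limitations

- One-sample (sign-flip) designs only; two-sample group comparisons must
  be reduced upstream to per-subject difference maps.
- No step-down refinement of the shifted-Simes procedure (single-step
  only).
- Learned templates require the reference resolution to equal the analysis
  resolution exactly.
- The largest-region search considers nested smallest-p sets only, the
  standard convention for this metric.
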