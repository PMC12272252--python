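"""True-discovery bounds, largest regions, comparison metric, report tables."""

import numpy as np
import pytest

from permtdp import (
    CriticalVector,
    SimesFamily,
    VoxelSet,
    build_learned_family,
    calibrate,
    cluster_tdp_table,
    generate_uniform_pvalue_matrix,
    largest_region_at_tdp,
    percent_variation,
    tdp_lower_bound,
    true_discovery_bound,
)
from conftest import naive_true_discovery_bound


def vec(values, effective_length=None, lam=1.0):
    values = np.asarray(values, dtype=float)
    return CriticalVector(
        values=values,
        effective_length=effective_length or values.size,
        lambda_star=lam,
    )


class TestTrueDiscoveryBound:
    def test_three_voxel_worked_example(self):
        # u=1: 1-1+2=2, u=2: 1-2+2=1, u=3: 1-3+2=0 -> max 2
        a = true_discovery_bound(np.array([0.001, 0.002, 0.9]), vec([0.01, 0.02, 0.03]))
        assert a == 2

    def test_no_pvalue_below_any_threshold_gives_zero(self):
        a = true_discovery_bound(np.ones(4), vec([0.1, 0.2, 0.3, 0.4]))
        assert a == 0

    def test_saturation_when_all_below_first_threshold(self):
        a = true_discovery_bound(np.full(5, 0.001), vec([0.01, 0.02, 0.03, 0.04, 0.05]))
        assert a == 5

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            true_discovery_bound(np.array([]), vec([0.1]))

    def test_matches_naive_double_loop_oracle(self, rng):
        """Optimized evaluation equals exhaustive enumeration over u."""
        for _ in range(300):
            m = int(rng.integers(1, 51))
            p = rng.uniform(size=int(rng.integers(1, m + 1)))
            ell = np.sort(rng.uniform(0, 0.8, size=m))
            L = int(rng.integers(1, m + 1))
            got = true_discovery_bound(p, vec(ell, effective_length=L))
            want = naive_true_discovery_bound(p.tolist(), ell.tolist(), L)
            assert got == max(0, want)

    def test_monotone_in_set_inclusion(self, rng):
        """a_bar(S) <= a_bar(T) for nested S in T."""
        m = 40
        ell = np.sort(rng.uniform(0, 0.5, size=m))
        critvec = vec(ell)
        for _ in range(200):
            p = rng.uniform(size=m)
            t_idx = rng.choice(m, size=int(rng.integers(2, m + 1)), replace=False)
            s_idx = rng.choice(t_idx, size=int(rng.integers(1, t_idx.size + 1)),
                               replace=False)
            assert true_discovery_bound(p[s_idx], critvec) <= true_discovery_bound(
                p[t_idx], critvec
            )

    def test_monotone_in_lambda(self, rng):
        fam = SimesFamily(m=30, delta=0)
        p = rng.uniform(0, 0.3, size=30)
        bounds = [
            true_discovery_bound(p, fam.vector(lam))
            for lam in np.linspace(0.01, 1.0, 15)
        ]
        assert np.all(np.diff(bounds) >= 0)

    def test_effective_length_truncation_binds(self, rng):
        """With a learned family the bound never exploits ranks > kmax:
        a_bar <= max over u <= kmax even for |S| >> kmax."""
        kmax, m = 3, 25
        ref = np.sort(rng.uniform(size=(9, m)), axis=1)
        fam = build_learned_family(ref, kmax=kmax)
        critvec = fam.vector(0.5)
        p = rng.uniform(size=m)
        got = true_discovery_bound(p, critvec)
        want = naive_true_discovery_bound(p.tolist(), critvec.values.tolist(), kmax)
        assert got == max(0, want)
        # taking the constant-1 tail literally would claim m - kmax discoveries
        literal = naive_true_discovery_bound(p.tolist(), critvec.values.tolist(), m)
        assert literal >= m - kmax
        assert got < literal

    def test_delta_shift_kills_small_sets(self, rng):
        """With shift delta, any set of size <= delta gets a_bar = 0."""
        m, delta = 60, 7
        fam = SimesFamily(m=m, delta=delta)
        critvec = fam.vector(1.0)
        for _ in range(50):
            size = int(rng.integers(1, delta + 1))
            p = rng.uniform(1e-9, 1.0, size=size)
            assert true_discovery_bound(p, critvec) == 0


class TestTdpLowerBound:
    def test_ratio_of_bound_to_size(self):
        p = np.array([0.001, 0.002, 0.9, 0.5])
        s = VoxelSet(indices=[0, 1, 2])
        assert tdp_lower_bound(s, p, vec([0.01, 0.02, 0.03, 0.04])) == pytest.approx(2 / 3)

    def test_extremes(self):
        p = np.array([0.5, 0.6])
        assert tdp_lower_bound(VoxelSet(indices=[0, 1]), p, vec([0.01, 0.02])) == 0.0
        p_hot = np.array([0.001, 0.002])
        assert tdp_lower_bound(VoxelSet(indices=[0, 1]), p_hot, vec([0.01, 0.02])) == 1.0


class TestLargestRegion:
    def test_worked_example_k3(self):
        p = np.array([0.001, 0.002, 0.003, 0.5, 0.6])
        critvec = vec([0.01, 0.02, 0.03, 0.04, 0.05])
        k, region = largest_region_at_tdp(p, critvec, 0.8)
        assert k == 3
        np.testing.assert_array_equal(np.sort(region.indices), [0, 1, 2])
        k1, _ = largest_region_at_tdp(p, critvec, 1.0)
        assert k1 == 3

    def test_no_discoveries_returns_zero_and_none(self):
        k, region = largest_region_at_tdp(np.ones(5), vec([0.01] * 5), 0.8)
        assert k == 0 and region is None

    def test_matches_naive_per_k_scan(self, rng):
        """The O(m log m) scan equals evaluating the bound at every k."""
        for _ in range(40):
            m = int(rng.integers(2, 30))
            p = rng.uniform(size=m)
            ell = np.sort(rng.uniform(0, 0.9, size=m))
            L = int(rng.integers(1, m + 1))
            critvec = vec(ell, effective_length=L)
            t = float(rng.uniform(0.1, 1.0))
            k, _ = largest_region_at_tdp(p, critvec, t)
            p_sorted = np.sort(p)
            naive_k = 0
            for kk in range(1, m + 1):
                a = max(0, naive_true_discovery_bound(
                    p_sorted[:kk].tolist(), ell.tolist(), L))
                if a >= t * kk:
                    naive_k = kk
            assert k == naive_k

    def test_returned_region_passes_its_own_threshold(self, rng):
        p = rng.uniform(size=50) ** 2
        fam = SimesFamily(m=50, delta=0)
        critvec = fam.vector(0.4)
        for t in (0.5, 0.8, 0.95):
            k, region = largest_region_at_tdp(p, critvec, t)
            if k > 0:
                assert tdp_lower_bound(region, p, critvec) >= t

    def test_ties_broken_by_scan_order(self):
        p = np.array([0.5, 0.001, 0.001, 0.001, 0.9])
        critvec = vec([0.01, 0.02, 0.03, 0.04, 0.05])
        _, region = largest_region_at_tdp(p, critvec, 0.9)
        np.testing.assert_array_equal(region.indices, [1, 2, 3])


class TestPercentVariation:
    @pytest.mark.parametrize("a, b, expected", [(120, 100, 0.2), (100, 100, 0.0),
                                                (80, 100, -0.2)])
    def test_relative_difference(self, a, b, expected):
        assert percent_variation(a, b) == pytest.approx(expected)

    def test_zero_reference_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            percent_variation(10, 0)


class TestClusterTable:
    def test_one_row_per_cluster_method_pair(self, rng):
        m = 30
        pmat = generate_uniform_pvalue_matrix(40, m, seed=2)
        curves = np.sort(pmat.pvalues, axis=1)
        calibrations = {
            "simes0": calibrate(SimesFamily(m=m, delta=0), curves, 0.1),
            "simes5": calibrate(SimesFamily(m=m, delta=5), curves, 0.1),
        }
        clusters = [VoxelSet(indices=[0, 1, 2], label="c1"),
                    VoxelSet(indices=[5, 6, 7, 8], label="c2")]
        table = cluster_tdp_table(pmat.identity_pvalues, clusters, calibrations)
        assert len(table) == 4
        assert set(table["method"]) == {"simes0", "simes5"}
        assert table.groupby("cluster_id")["best"].sum().eq(1).all() or \
            table.groupby("cluster_id")["best"].sum().ge(1).all()

    def test_saturated_cluster_reports_tdp_one(self):
        p = np.array([1e-6, 1e-6, 0.5])
        cal_vec = vec([0.01, 0.02, 0.03])
        from permtdp.calibration import CalibrationResult
        cal = CalibrationResult(lambda_star=1.0, lambda_stats=np.ones(2), alpha=0.05,
                                w=2, family_ref="stub", critical_vector=cal_vec)
        table = cluster_tdp_table(p, [VoxelSet(indices=[0, 1], label="hot")],
                                  {"stub": cal})
        assert table.loc[0, "tdp"] == pytest.approx(1.0)

    def test_mismatched_m_rejected(self):
        from permtdp.calibration import CalibrationResult
        cal = CalibrationResult(lambda_star=1.0, lambda_stats=np.ones(2), alpha=0.05,
                                w=2, family_ref="stub", critical_vector=vec([0.1, 0.2]))
        with pytest.raises(ValueError, match="m="):
            cluster_tdp_table(np.array([0.5, 0.5, 0.5]),
                              [VoxelSet(indices=[0])], {"stub": cal})
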