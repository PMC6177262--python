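import itertools
import math

import numpy as np
import pytest

from bgscan.sfs_toolkit import (SFSVector, normalize_sfs, project_sfs,
                                read_fastsimcoal_sfs, sfs_distance,
                                sfs_permutation_test, unfolded_sfs,
                                write_fastsimcoal_sfs)


def enumerate_projection(n: int, f: int, m: int) -> np.ndarray:
    """Oracle: probability of each derived count 0..m in a subsample of m
    haploids, by exhaustive enumeration of all C(n, m) subsamples."""
    hap = np.zeros(n, dtype=int)
    hap[:f] = 1
    out = np.zeros(m + 1)
    total = 0
    for comb in itertools.combinations(range(n), m):
        out[hap[list(comb)].sum()] += 1
        total += 1
    return out / total


class TestUnfoldedSfs:
    def test_basic_counts(self):
        sfs = unfolded_sfs([1, 1, 2, 3], n_diploids=2)
        assert sfs.m == 4
        assert sfs.xi.tolist() == [2, 1, 1]

    def test_monomorphic_skipped_and_counted(self):
        sfs = unfolded_sfs([0, 1, 4, 2], n_diploids=2)
        assert sfs.xi.tolist() == [1, 1, 0]
        assert sfs.n_skipped == 2

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            unfolded_sfs([], 2)

    def test_site_order_invariance(self, rng):
        totals = rng.integers(1, 8, size=50)
        a = unfolded_sfs(totals, 4)
        b = unfolded_sfs(rng.permutation(totals), 4)
        assert a == b


class TestNormalize:
    def test_stationary_shape_maps_to_unity(self):
        eta = normalize_sfs(SFSVector(4, [6, 3, 2]))
        assert np.allclose(eta.xi, 1.0)

    def test_singletons_only(self):
        eta = normalize_sfs(SFSVector(4, [4, 0, 0]))
        assert np.allclose(eta.xi, [11 / 6, 0, 0])

    def test_scale_invariance(self, rng):
        xi = rng.uniform(0.1, 5, size=9)
        a = normalize_sfs(SFSVector(10, xi))
        b = normalize_sfs(SFSVector(10, 7.3 * xi))
        assert np.allclose(a.xi, b.xi)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            normalize_sfs(SFSVector(4, [0, 0, 0]))


class TestProjection:
    def test_worked_example_n6_f3_m4(self):
        proj = project_sfs([(6, 3)], 4)
        assert np.allclose(proj.xi, [3 / 15, 9 / 15, 3 / 15])

    def test_singleton_mass_loss(self):
        proj = project_sfs([(6, 1)], 4)
        assert proj.xi[0] == pytest.approx(10 / 15)
        assert proj.s == pytest.approx(10 / 15)   # 1/3 lost to monomorphic

    def test_identity_projection(self, rng):
        xi = rng.integers(0, 20, size=7).astype(float)
        xi[0] += 1
        sfs = SFSVector(8, xi)
        assert np.allclose(project_sfs(sfs, 8).xi, xi)

    def test_matches_exhaustive_enumeration(self):
        # every (n <= 8, f, m_target) against the subsample-enumeration oracle
        for n in range(3, 9):
            for m in range(2, n + 1):
                for f in range(1, n):
                    expected = enumerate_projection(n, f, m)[1:m]
                    got = project_sfs([(n, f)], m).xi
                    assert np.allclose(got, expected, atol=1e-12), (n, f, m)

    def test_per_site_mass_conservation(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 30))
            f = int(rng.integers(1, n))
            m = int(rng.integers(2, n + 1))
            from scipy.stats import hypergeom
            full = hypergeom.pmf(np.arange(0, m + 1), n, f, m)
            assert full.sum() == pytest.approx(1.0)
            assert project_sfs([(n, f)], m).s == \
                pytest.approx(full[1:m].sum())

    def test_linearity(self, rng):
        sites_a = [(10, int(f)) for f in rng.integers(1, 10, size=15)]
        sites_b = [(10, int(f)) for f in rng.integers(1, 10, size=9)]
        lhs = project_sfs(sites_a + sites_b, 6).xi
        rhs = project_sfs(sites_a, 6).xi + project_sfs(sites_b, 6).xi
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_double_projection_consistency(self, rng):
        xi = rng.uniform(0, 10, size=11)
        sfs = SFSVector(12, xi)
        via8 = project_sfs(project_sfs(sfs, 8), 4)
        direct = project_sfs(sfs, 4)
        assert np.allclose(via8.xi, direct.xi, atol=1e-9)

    def test_invalid_f_errors(self):
        with pytest.raises(ValueError):
            project_sfs([(6, 0)], 4)
        with pytest.raises(ValueError):
            project_sfs([(6, 6)], 4)


class TestDistance:
    def test_identity_and_symmetry(self, rng):
        a = SFSVector(6, rng.uniform(0.1, 3, size=5))
        b = SFSVector(6, rng.uniform(0.1, 3, size=5))
        assert sfs_distance(a, a) == 0
        assert sfs_distance(a, b) == pytest.approx(sfs_distance(b, a))

    def test_worked_example(self):
        a = SFSVector(4, [1, 1, 0])
        b = SFSVector(4, [2, 0, 0])
        assert sfs_distance(a, b) == pytest.approx(0.5)

    def test_unequal_m_errors(self):
        with pytest.raises(ValueError, match="differ"):
            sfs_distance(SFSVector(4, [1, 1, 1]), SFSVector(6, [1] * 5))


class TestPermutationTest:
    def test_identical_sets(self):
        sites = [1, 2, 3, 2, 1]
        res = sfs_permutation_test(sites, sites, 2, n_perm=99, seed=0)
        assert res.d_obs == 0
        assert res.p == 1.0

    def test_three_vs_three_exact(self):
        # 3 singletons vs 3 doubletons: of the C(6,3)=20 re-splits exactly 2
        # (the original and its mirror) reach D >= D_obs
        res = sfs_permutation_test([1, 1, 1], [2, 2, 2], 2, exact=True)
        assert res.exact and res.n_perm == 20
        assert res.p == pytest.approx(2 / 20)

    def test_monte_carlo_converges_to_exact(self):
        res = sfs_permutation_test([1, 1, 1], [2, 2, 2], 2, n_perm=4000,
                                   seed=7)
        assert res.p == pytest.approx(0.1, abs=0.02)

    def test_p_estimator_invariant(self):
        res = sfs_permutation_test([1, 1, 1], [2, 2, 2], 2, n_perm=200,
                                   seed=3)
        ge = int(np.count_nonzero(res.d_perm >= res.d_obs - 1e-15))
        assert res.p == (1 + ge) / (1 + 200)

    def test_shared_sites_stay_fixed(self):
        # with ids, the overlap is held out of the permutation pool
        a = [1, 1, 2, 3]
        b = [1, 1, 2, 2]
        res = sfs_permutation_test(a, b, 2, n_perm=50, seed=0,
                                   ids_a=[0, 1, 2, 3], ids_b=[0, 1, 2, 9])
        assert res.n_perm == 50

    def test_nested_mode_requires_subset(self):
        with pytest.raises(ValueError, match="nested"):
            sfs_permutation_test([3, 3, 3], [1, 1, 2, 2], 2, mode="nested")

    def test_nested_mode_runs(self, rng):
        b = rng.integers(1, 4, size=40)
        a = rng.choice(b, size=10, replace=False)
        res = sfs_permutation_test(a, b, 2, mode="nested", n_perm=99, seed=1)
        assert 0 < res.p <= 1

    def test_null_rejection_rate_small(self, rng):
        # light null calibration; the full 500-replicate version runs in the
        # acceptance suite
        rejections = 0
        n_data = 60
        for i in range(n_data):
            pool = rng.integers(1, 10, size=400)
            res = sfs_permutation_test(pool[:200], pool[200:], 5,
                                       n_perm=99, seed=int(i))
            rejections += res.p <= 0.05
        rate = rejections / n_data
        assert rate <= 0.18    # generous 3-sigma-ish bound at n=60


class TestFastsimcoalExport:
    def test_round_trip(self, tmp_path, rng):
        sfs = unfolded_sfs(rng.integers(1, 20, size=200), 10)
        path = tmp_path / "x_DAFpop0.obs"
        write_fastsimcoal_sfs(sfs, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("1 observations")
        assert len(lines[1].split()) == 21        # m = 20 -> entries 0..20
        back = read_fastsimcoal_sfs(path)
        assert back == sfs
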