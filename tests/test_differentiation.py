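import numpy as np
import pandas as pd
import pytest
from scipy import stats

from landrace_popgen import differentiation as diff

from conftest import make_panel


class TestHudsonComponents:
    def test_no_differentiation_limit(self):
        num, den = diff.hudson_components(0.4, 10_000, 0.4, 10_000)
        assert abs(num) < 1e-4
        assert num / den == pytest.approx(0.0, abs=1e-3)

    def test_fixed_difference(self):
        num, den = diff.hudson_components(1.0, 1000, 0.0, 1000)
        assert num / den == pytest.approx(1.0)

    def test_ten_site_manual_oracle(self, rng):
        p1 = rng.uniform(0, 1, 10)
        p2 = rng.uniform(0, 1, 10)
        n1 = rng.integers(4, 40, 10)
        n2 = rng.integers(4, 40, 10)
        num, den = diff.hudson_components(p1, n1, p2, n2)
        for k in range(10):
            # longhand Bhatia/Hudson evaluation
            en = (
                (p1[k] - p2[k]) ** 2
                - p1[k] * (1 - p1[k]) / (n1[k] - 1)
                - p2[k] * (1 - p2[k]) / (n2[k] - 1)
            )
            ed = p1[k] * (1 - p2[k]) + p2[k] * (1 - p1[k])
            assert num[k] == pytest.approx(en, rel=1e-12)
            assert den[k] == pytest.approx(ed, rel=1e-12)

    def test_low_count_sites_skipped(self):
        num, den = diff.hudson_components([0.5], [1], [0.5], [10])
        assert np.isnan(num[0]) and np.isnan(den[0])


class TestBlockwiseFst:
    def test_single_block_has_no_se(self, rng):
        nums = rng.uniform(0, 0.1, 50)
        dens = rng.uniform(0.2, 0.5, 50)
        fst, se = diff.blockwise_fst(nums, dens, block_size=100)
        assert fst == pytest.approx(nums.sum() / dens.sum())
        assert np.isnan(se)

    def test_jackknife_matches_explicit_leave_one_out(self, rng):
        nums = np.concatenate(
            [rng.uniform(0, 0.05, 30), rng.uniform(0.1, 0.3, 30),
             rng.uniform(0, 0.01, 30)]
        )
        dens = rng.uniform(0.2, 0.6, 90)
        fst, se = diff.blockwise_fst(nums, dens, block_size=30)
        loo = []
        for b in range(3):
            mask = np.ones(90, bool)
            mask[b * 30:(b + 1) * 30] = False
            loo.append(nums[mask].sum() / dens[mask].sum())
        loo = np.array(loo)
        expected_se = np.sqrt(2 / 3 * ((loo - loo.mean()) ** 2).sum())
        assert se == pytest.approx(expected_se, rel=1e-12)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        # constructed counterexample where the two differ materially
        nums = np.array([0.9, 0.01])
        dens = np.array([1.0, 0.01])
        fst, _ = diff.blockwise_fst(nums, dens, block_size=1)
        assert fst == pytest.approx(0.91 / 1.01)
        assert fst != pytest.approx(np.mean(nums / dens))

    def test_zero_denominator_is_missing(self):
        fst, se = diff.blockwise_fst([0.0], [0.0], block_size=10)
        assert np.isnan(fst)


class TestSlatkin:
    def test_closed_forms(self):
        assert diff.slatkin_linearized(0.0) == 0.0
        assert diff.slatkin_linearized(0.5) == pytest.approx(1.0)
        assert np.isnan(diff.slatkin_linearized(1.0))

    def test_matrix_level_rho_identical(self, rng):
        # Spearman with geography is blind to the monotone linearization
        k = 8
        fst = np.zeros((k, k))
        geo = np.zeros((k, k))
        iu = np.triu_indices(k, 1)
        fst[iu] = rng.uniform(0.01, 0.6, iu[0].size)
        geo[iu] = rng.uniform(10, 2000, iu[0].size)
        fst += fst.T
        geo += geo.T
        lin = fst / (1 - fst)
        r1, _ = diff.ibd_test(fst, geo)
        r2, _ = diff.ibd_test(lin, geo)
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestSelfFst:
    def test_population_with_itself_is_zero(self, rng):
        # same allele counts on both sides -> numerator only finite-sample noise
        dosage = rng.integers(0, 3, size=(12, 300)).astype(np.int8)
        panel = make_panel(dosage, pops=["p1"] * 6 + ["p2"] * 6)
        # make p2 an exact copy of p1: num = -2pq/(n-1), den = 2pq, so the
        # ratio of sums is exactly the finite-sample bias -1/(n-1)
        panel.dosage[6:] = panel.dosage[:6]
        fm = diff.pairwise_fst(panel, block_size=50)
        assert fm.fst[0, 1] == pytest.approx(-1 / 11, rel=1e-9)


class TestEnvironmentalDistance:
    def test_identical_environments_zero(self):
        bc = pd.DataFrame(
            {"population": ["A", "B"], "bio1": [3.0, 3.0], "bio2": [1.0, 2.0]}
        )
        d = diff.environmental_distance(bc)
        # bio1 dropped (zero variance), bio2 scaled to +-1 -> distance 2
        assert d[0, 1] == pytest.approx(2.0)

    def test_single_variable_scaled_pair(self):
        bc = pd.DataFrame({"population": ["A", "B"], "bio1": [-10.0, 30.0]})
        d = diff.environmental_distance(bc)
        assert d[0, 1] == pytest.approx(2.0)  # values are ±1 after scaling

    def test_brute_force_oracle_5x19(self, rng):
        pops = list("ABCDE")
        data = {"population": pops}
        for i in range(1, 20):
            data[f"bio{i}"] = rng.normal(size=5) * rng.uniform(0.5, 50)
        bc = pd.DataFrame(data)
        d = diff.environmental_distance(bc)
        X = bc.drop(columns="population").to_numpy()
        Xs = (X - X.mean(0)) / X.std(0)
        for i in range(5):
            for j in range(5):
                expected = np.sqrt(((Xs[i] - Xs[j]) ** 2).sum())
                assert d[i, j] == pytest.approx(expected, rel=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        pops = list("ABCDEF")
        bc = pd.DataFrame(
            {"population": pops, "bio1": rng.normal(size=6),
             "bio2": rng.normal(size=6)}
        )
        d1 = diff.environmental_distance(bc)
        bc2 = bc.copy()
        bc2["bio1"] = 42.0 + 1000.0 * bc2["bio1"]
        d2 = diff.environmental_distance(bc2)
        np.testing.assert_allclose(d1, d2, rtol=1e-9)


class TestIbdTest:
    def test_monotone_relationship_rho_one(self):
        k = 6
        geo = np.zeros((k, k))
        iu = np.triu_indices(k, 1)
        geo[iu] = np.arange(1, iu[0].size + 1)
        geo += geo.T
        fst = np.sqrt(geo)  # strictly increasing function of distance
        rho, p = diff.ibd_test(fst, geo)
        assert rho == pytest.approx(1.0)

    def test_too_few_pairs_raises(self):
        m = np.zeros((2, 2))
        with pytest.raises(ValueError):
            diff.ibd_test(m, m)

    def test_null_rejection_rate_near_nominal(self):
        # permuted population labels break any genuine association; the
        # observed rate is recorded in the assertion message
        rng = np.random.default_rng(11)
        k = 10
        coords = rng.uniform(0, 50, size=(k, 2))
        geo = np.sqrt(
            ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        )
        base = rng.uniform(0.01, 0.5, size=(k, k))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 0)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            perm = rng.permutation(k)
            fst = base[np.ix_(perm, perm)]
            _, p = diff.ibd_test(fst, geo)
            rejections += p < 0.05
        rate = rejections / n_sim
        assert rate <= 0.10, f"observed null rejection rate {rate:.3f}"

    def test_cluster_subsets_partition_pairs(self, rng):
        k = 6
        pops = [f"P{i}" for i in range(k)]
        clusters = {p: ("W" if i < 3 else "E") for i, p in enumerate(pops)}
        m = rng.uniform(0, 1, (k, k))
        m = (m + m.T) / 2
        w = diff._pair_subset_mask(pops, clusters, "within-cluster")
        b = diff._pair_subset_mask(pops, clusters, "between-cluster")
        assert w.sum() + b.sum() == k * (k - 1) // 2
        assert w.sum() == 6  # C(3,2) twice


class TestClusterContrast:
    def _matrix(self, within, between):
        pops = ["A", "B", "C", "D"]
        clusters = {"A": "W", "B": "W", "C": "E", "D": "E"}
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = within[0]
        m[2, 3] = m[3, 2] = within[1]
        vals = iter(between)
        for i in (0, 1):
            for j in (2, 3):
                m[i, j] = m[j, i] = next(vals)
        return m, pops, clusters

    def test_identical_distributions_ks_zero(self):
        m, pops, clusters = self._matrix([0.2, 0.2], [0.2, 0.2, 0.2, 0.2])
        res = diff.cluster_contrast(m, pops, clusters)
        assert res["ks_statistic"] == 0.0

    def test_disjoint_supports_ks_one(self):
        m, pops, clusters = self._matrix([0.1, 0.12], [0.4, 0.5, 0.6, 0.45])
        res = diff.cluster_contrast(m, pops, clusters)
        assert res["ks_statistic"] == 1.0

    def test_matches_brute_force_cdf_scan(self, rng):
        k = 6
        pops = [f"P{i}" for i in range(k)]
        clusters = {p: ("W" if i < 3 else "E") for i, p in enumerate(pops)}
        m = rng.uniform(0, 1, (k, k))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        res = diff.cluster_contrast(m, pops, clusters)
        within = m[diff._pair_subset_mask(pops, clusters, "within-cluster")]
        between = m[diff._pair_subset_mask(pops, clusters, "between-cluster")]
        grid = np.sort(np.concatenate([within, between]))
        gap = max(
            abs((within <= t).mean() - (between <= t).mean()) for t in grid
        )
        assert res["ks_statistic"] == pytest.approx(gap, rel=1e-12)

    def test_single_population_cluster_raises(self):
        m = np.zeros((3, 3))
        pops = ["A", "B", "C"]
        clusters = {"A": "W", "B": "E", "C": "E"}
        with pytest.raises(ValueError):
            diff.cluster_contrast(m, pops, clusters)
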