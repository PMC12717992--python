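from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from landrace_popgen import sweep_scan
from landrace_popgen.panel import HaplotypePanel

from conftest import make_panel


def hap_panel(H, spacing=100, chrom="1"):
    H = np.asarray(H, dtype=np.uint8)
    return HaplotypePanel(
        line_ids=[f"l{i}" for i in range(H.shape[0])],
        sites=pd.DataFrame(
            {"chrom": chrom, "pos": 1 + spacing * np.arange(H.shape[1])}
        ),
        H=H,
    )


def ehh_oracle(H, core, allele, direction):
    """All-pairs prefix-identity count, O(n^2 * L)."""
    carriers = [i for i in range(H.shape[0]) if H[i, core] == allele]
    n = len(carriers)
    span = (
        range(core + 1, H.shape[1]) if direction == "right"
        else range(core - 1, -1, -1)
    )
    out = [1.0]
    sofar = [core]
    for x in span:
        sofar.append(x)
        ident = sum(
            all(H[a, s] == H[b, s] for s in sofar)
            for a, b in combinations(carriers, 2)
        )
        out.append(ident / (n * (n - 1) / 2))
    return out


class TestEhh:
    def test_identical_carriers_stay_at_one(self):
        H = np.tile([1, 0, 1, 1, 0], (4, 1))
        panel = hap_panel(H)
        pos, curve = sweep_scan.ehh(panel, 0, 1, "right", ehh_cutoff=0.0)
        np.testing.assert_allclose(curve, 1.0)

    def test_two_group_split_counting(self):
        # 4 carriers split into two internally identical pairs at the
        # first flank: EHH = 2*C(2,2)/C(4,2) = 1/3
        H = np.array([[1, 0], [1, 0], [1, 1], [1, 1]])
        panel = hap_panel(H)
        _, curve = sweep_scan.ehh(panel, 0, 1, "right", ehh_cutoff=0.0)
        assert curve[1] == pytest.approx(1 / 3)

    def test_monotone_nonincreasing_and_core_one(self, rng):
        H = rng.integers(0, 2, size=(8, 20))
        panel = hap_panel(H)
        for direction in ("left", "right"):
            _, curve = sweep_scan.ehh(panel, 10, 1, direction, ehh_cutoff=0.0)
            assert curve[0] == 1.0
            assert np.all(np.diff(curve) <= 1e-12)

    def test_matches_all_pairs_oracle(self, rng):
        H = rng.integers(0, 2, size=(6, 15))
        panel = hap_panel(H)
        for core in (0, 7, 14):
            for allele in (0, 1):
                if np.sum(H[:, core] == allele) < 2:
                    continue
                for direction in ("left", "right"):
                    _, curve = sweep_scan.ehh(
                        panel, core, allele, direction, ehh_cutoff=0.0
                    )
                    expected = ehh_oracle(H, core, allele, direction)
                    np.testing.assert_allclose(curve, expected, atol=1e-12)

    def test_fewer_than_two_carriers_raises(self):
        H = np.array([[1, 0], [0, 0], [0, 1]])
        with pytest.raises(ValueError):
            sweep_scan.ehh(hap_panel(H), 0, 1, "right")


class TestIhh:
    def test_rectangle(self):
        pos = np.array([0, 5000, 10_000])
        curve = np.array([1.0, 1.0, 1.0])
        assert sweep_scan.ihh(pos, curve, ehh_cutoff=0.05) == pytest.approx(10_000)

    def test_triangle(self):
        pos = np.linspace(0, 10_000, 11)
        curve = np.linspace(1, 0, 11)
        assert sweep_scan.ihh(pos, curve, ehh_cutoff=0.0) == pytest.approx(5000)

    def test_truncates_below_cutoff(self):
        pos = np.array([0, 1000, 2000, 3000])
        curve = np.array([1.0, 1.0, 0.01, 0.01])
        # last point >= cutoff is index 1 -> only the first interval counts
        assert sweep_scan.ihh(pos, curve, ehh_cutoff=0.05) == pytest.approx(1000)

    def test_gap_capping(self):
        pos = np.array([0, 500_000])
        curve = np.array([1.0, 1.0])
        assert sweep_scan.ihh(pos, curve, max_gap=200_000) == pytest.approx(200_000)

    def test_matches_riemann_oracle(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 50_000), size=30, replace=False))
        curve = np.sort(rng.uniform(0.2, 1, size=30))[::-1]
        got = sweep_scan.ihh(pos, curve, ehh_cutoff=0.0, max_gap=10**9)
        # fine-grained Riemann sum over the linear interpolant
        grid = np.linspace(pos[0], pos[-1], 2_000_001)
        vals = np.interp(grid, pos, curve)
        expected = np.sum((vals[:-1] + vals[1:]) / 2) * (grid[1] - grid[0])
        assert got == pytest.approx(expected, rel=1e-6)


class TestIhsScan:
    def test_symmetric_alleles_give_zero_raw(self):
        # carriers of 1 and of 0 have identical internal flank structure
        H = np.array(
            [
                [1, 0, 0, 1], [1, 0, 0, 1], [1, 1, 1, 0],
                [0, 0, 0, 1], [0, 0, 0, 1], [0, 1, 1, 0],
            ]
        )
        panel = hap_panel(H)
        d, _ = sweep_scan._site_ihh(panel, 0, 1, 0.0, 10**9)
        a, _ = sweep_scan._site_ihh(panel, 0, 0, 0.0, 10**9)
        assert d == pytest.approx(a)

    def test_antisymmetric_under_label_swap(self, rng):
        H = rng.integers(0, 2, size=(10, 21))
        core = 10
        if not (2 <= H[:, core].sum() <= 8):
            H[:5, core], H[5:, core] = 1, 0
        panel = hap_panel(H)
        d, _ = sweep_scan._site_ihh(panel, core, 1, 0.0, 10**9)
        a, _ = sweep_scan._site_ihh(panel, core, 0, 0.0, 10**9)
        swapped = hap_panel(np.where(np.arange(21) == core, 1 - H, H))
        d2, _ = sweep_scan._site_ihh(swapped, core, 1, 0.0, 10**9)
        a2, _ = sweep_scan._site_ihh(swapped, core, 0, 0.0, 10**9)
        assert d == pytest.approx(a2) and a == pytest.approx(d2)

    def test_sign_convention_long_derived_haplotypes(self, rng):
        # derived carriers share one haplotype -> iHH_D >> iHH_A -> raw < 0
        n, L = 40, 41
        H = rng.integers(0, 2, size=(n, L)).astype(np.uint8)
        core = 20
        H[:, core] = 0
        H[:20] = 0  # identical derived haplotype block
        H[:20, core] = 1
        panel = hap_panel(H)
        res = sweep_scan.ihs_scan(panel, n_bins=5)
        row = res[res["pos"] == panel.sites["pos"].iloc[core]].iloc[0]
        assert row["ihs_raw"] < 0

    def test_bin_standardization_mean_zero_sd_one(self, rng):
        H = rng.integers(0, 2, size=(30, 120)).astype(np.uint8)
        panel = hap_panel(H)
        res = sweep_scan.ihs_scan(panel, n_bins=4)
        edges = np.linspace(0, 1, 5)
        bins = np.clip(np.digitize(res["daf"], edges) - 1, 0, 3)
        for b in np.unique(bins):
            vals = res.loc[(bins == b) & res["ihs_std"].notna(), "ihs_std"]
            if len(vals) >= 2:
                assert vals.mean() == pytest.approx(0, abs=1e-9)
                assert vals.std(ddof=0) == pytest.approx(1, abs=1e-9)


class TestEmpiricalClassify:
    def _results(self, z):
        return pd.DataFrame(
            {"chrom": "1", "pos": np.arange(1, len(z) + 1), "daf": 0.5,
             "ihs_std": z}
        )

    def test_rank_one_of_hundred(self, rng):
        z = rng.normal(size=100)
        z[42] = 10.0
        res = sweep_scan.empirical_classify(self._results(z))
        assert res.loc[42, "emp_p"] == pytest.approx(0.01)

    def test_dual_threshold_rule(self):
        z = np.concatenate([[2.5, 1.5], np.linspace(0.1, 1.0, 48)])
        res = sweep_scan.empirical_classify(self._results(z))
        assert bool(res.loc[0, "significant"])       # emp_p 0.02, |z| 2.5
        assert not bool(res.loc[1, "significant"])   # emp_p 0.04, |z| 1.5

    def test_emp_p_forms_uniform_grid(self, rng):
        z = rng.normal(size=50)
        res = sweep_scan.empirical_classify(self._results(z))
        np.testing.assert_allclose(
            np.sort(res["emp_p"]), np.arange(1, 51) / 50, atol=1e-12
        )


class TestNearestGene:
    def _genes(self):
        return pd.DataFrame(
            {"chrom": ["1", "1", "1"], "start": [100, 1000, 5000],
             "end": [200, 1200, 5500], "gene_id": ["g1", "g2", "g3"]}
        )

    def test_inside_gene_distance_zero(self):
        sites = pd.DataFrame({"chrom": ["1"], "pos": [1100]})
        res = sweep_scan.nearest_gene(sites, self._genes())
        assert res.loc[0, "gene_id"] == "g2"
        assert res.loc[0, "distance"] == 0

    def test_equidistant_tie_goes_upstream(self):
        sites = pd.DataFrame({"chrom": ["1"], "pos": [600]})
        res = sweep_scan.nearest_gene(sites, self._genes())
        # 400 bp from g1's end and from g2's start -> lower-coordinate g1
        assert res.loc[0, "gene_id"] == "g1"
        assert res.loc[0, "distance"] == 400

    def test_unplaced_chromosome(self):
        sites = pd.DataFrame({"chrom": ["7"], "pos": [50]})
        res = sweep_scan.nearest_gene(sites, self._genes())
        assert res.loc[0, "side"] == "unplaced"

    def test_matches_exhaustive_scan(self, rng):
        starts = np.sort(rng.choice(np.arange(1, 100_000), 20, replace=False))
        genes = pd.DataFrame(
            {"chrom": "1", "start": starts, "end": starts + 500,
             "gene_id": [f"g{i}" for i in range(20)]}
        )
        sites = pd.DataFrame(
            {"chrom": "1",
             "pos": rng.choice(np.arange(1, 100_000), 100, replace=False)}
        )
        res = sweep_scan.nearest_gene(sites, genes)
        for k, site in sites.iterrows():
            best_d, best_g = None, None
            for _, g in genes.iterrows():
                if g["start"] <= site["pos"] <= g["end"]:
                    d = 0
                elif site["pos"] < g["start"]:
                    d = g["start"] - site["pos"]
                else:
                    d = site["pos"] - g["end"]
                if best_d is None or d < best_d or (
                    d == best_d and g["start"] < best_g["start"]
                ):
                    best_d, best_g = d, g
            assert res.loc[k, "gene_id"] == best_g["gene_id"]
            assert abs(res.loc[k, "distance"]) == best_d


class TestDhHaplotypes:
    def test_heterozygote_rejected(self):
        panel = make_panel([[0, 1], [2, 0]], coding="derived")
        with pytest.raises(ValueError, match="heterozygous"):
            sweep_scan.dh_haplotypes(panel, "pop1")

    def test_collapse_and_missing_drop(self):
        panel = make_panel([[0, 2, -1], [2, 0, 2]], coding="derived")
        hap = sweep_scan.dh_haplotypes(panel, "pop1")
        assert hap.n_sites == 2
        np.testing.assert_array_equal(hap.H, [[0, 1], [1, 0]])

    def test_unpolarized_panel_rejected(self):
        panel = make_panel([[0, 2], [2, 0]])
        with pytest.raises(ValueError, match="polarized"):
            sweep_scan.dh_haplotypes(panel, "pop1")
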