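import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.interpolate import interp1d

from admixscan.ehh import (classify_outlier_windows, ehh_at, ehhs_at,
                           integrate_ihh, integrate_ies, ihs_scan,
                           neglog10_two_sided, relaxed_replication_preset,
                           rsb_scan, site_ies_table, xpehh_scan)
from admixscan.panel import build_window_grid

from _oracles import ehh_pair_brute
from conftest import make_hap_panel, near_core


class TestEhhDecay:
    def test_focal_ehh_is_one_per_class(self):
        rng = np.random.default_rng(0)
        p = make_hap_panel(rng.integers(0, 2, (8, 20)))
        for cls in ("ancestral", "derived"):
            arms = ehh_at(p, 10, cls)
            if arms is not None:
                assert arms["left"][1][0] == 1.0
                assert arms["right"][1][0] == 1.0
        arms = ehhs_at(p, 10)
        assert arms["right"][1][0] == pytest.approx(1.0)

    def test_two_plus_two_split_gives_one_third(self):
        # 4 derived carriers split 2+2 at the next SNP: 2 identical pairs of 6
        alleles = np.array([
            [1, 0], [1, 0], [1, 1], [1, 1],  # derived carriers
            [0, 0], [0, 0]])                 # ancestral carriers
        p = make_hap_panel(alleles, pos=[1000, 2000])
        arms = ehh_at(p, 0, "derived")
        idx, e = arms["right"]
        assert e[1] == pytest.approx(1 / 3)

    def test_walk_truncates_before_large_gap(self):
        alleles = np.tile(np.array([[0], [0], [1], [1]]), (1, 5))
        pos = [1_000, 2_000, 3_000, 603_001, 604_000]  # 600-kb gap after 3 kb
        p = make_hap_panel(alleles, pos=pos)
        arms = ehh_at(p, 0, "all")
        idx, _ = arms["right"]
        assert list(idx) == [0, 1, 2]  # stops at the SNP before the gap

    def test_monotone_non_increasing_and_bounded(self):
        rng = np.random.default_rng(1)
        p = make_hap_panel(rng.integers(0, 2, (10, 60)))
        for focal in (0, 25, 59):
            for cls in ("ancestral", "derived", "all"):
                arms = ehh_at(p, focal, cls, ehh_floor=0.0)
                if arms is None:
                    continue
                for side in ("left", "right"):
                    e = arms[side][1]
                    assert (np.diff(e) <= 1e-12).all()
                    assert (e >= 0).all() and (e <= 1 + 1e-12).all()

    @pytest.mark.parametrize("cls", ["ancestral", "derived", "all"])
    def test_matches_exhaustive_pair_enumeration(self, cls):
        """On <= 8 haplotypes, EHH equals brute-force pair counting."""
        rng = np.random.default_rng(2)
        for trial in range(5):
            alleles = rng.integers(0, 2, (8, 30))
            p = make_hap_panel(alleles)
            focal = int(rng.integers(5, 25))
            arms = ehh_at(p, focal, cls, ehh_floor=0.0)
            if arms is None:
                continue
            allele_col = alleles[:, focal]
            if cls == "ancestral":
                rows = np.nonzero(allele_col == 0)[0]
            elif cls == "derived":
                rows = np.nonzero(allele_col == 1)[0]
            else:
                rows = np.arange(8)
            h0 = ehh_pair_brute(alleles, rows, focal, focal)
            for side in ("left", "right"):
                idx, e = arms[side]
                for k, j in enumerate(idx):
                    expect = ehh_pair_brute(alleles, rows, focal, int(j))
                    if cls == "all":
                        expect /= h0
                    assert e[k] == pytest.approx(expect, abs=1e-12)


class TestIntegration:
    def test_rectangle(self):
        arms = {"left": (np.array([5]), np.array([1.0])),
                "right": (np.array([5, 6]), np.array([1.0, 1.0]))}
        pos = np.array([0, 0, 0, 0, 0, 0, 10_000])
        assert integrate_ihh(arms, pos, 5) == pytest.approx(10_000)

    def test_triangle(self):
        arms = {"left": (np.array([5]), np.array([1.0])),
                "right": (np.array([5, 6]), np.array([1.0, 0.0]))}
        pos = np.array([0, 0, 0, 0, 0, 0, 10_000])
        assert integrate_ihh(arms, pos, 5) == pytest.approx(5_000)

    def test_matches_independent_quadrature(self):
        rng = np.random.default_rng(3)
        d = np.sort(rng.choice(50_000, 20, replace=False)).astype(float)
        d[0] = 0.0
        e = np.minimum.accumulate(rng.uniform(0.05, 1.0, 20))
        e[0] = 1.0
        pos = (1_000_000 + d).astype(np.int64)
        arms = {"left": (np.array([0]), np.array([1.0])),
                "right": (np.arange(20), e)}
        got = integrate_ihh(arms, pos, 0)
        f = interp1d(d, e)
        expect = sum(quad(f, d[i], d[i + 1], epsabs=1e-12)[0]
                     for i in range(19))
        assert got == pytest.approx(expect, rel=1e-9)

    def test_flat_ehhs_integral(self):
        # all haplotypes identical over a 10-kb arm, then chromosome end
        alleles = np.tile(np.array([[0], [0], [1], [1]]), (1, 3))
        p = make_hap_panel(alleles, pos=[1000, 6000, 11_000])
        assert integrate_ies(p, 0) == pytest.approx(10_000)


class TestPTransform:
    def test_zero_score_maps_to_zero(self):
        assert neglog10_two_sided(0.0) == 0.0

    def test_threshold_quantile(self):
        assert float(neglog10_two_sided(4.8916)) == pytest.approx(6.00, abs=0.01)

    def test_monotone_in_absolute_score(self):
        s = np.linspace(-10, 10, 401)
        p = neglog10_two_sided(s)
        assert (np.diff(p[s >= 0]) > 0).all()
        np.testing.assert_allclose(p, neglog10_two_sided(-s), atol=1e-12)


class TestScans:
    def test_ihs_skips_monomorphic_with_reason(self):
        rng = np.random.default_rng(4)
        alleles = rng.integers(0, 2, (12, 40))
        alleles[:, 7] = 0
        tab = ihs_scan(make_hap_panel(alleles))
        assert tab["reason"].iloc[7] == "monomorphic"
        assert np.isnan(tab["std"].iloc[7])

    def test_identical_panels_give_zero_raw(self):
        rng = np.random.default_rng(5)
        p = make_hap_panel(rng.integers(0, 2, (8, 50)))
        for scan in (rsb_scan, xpehh_scan):
            tab = scan(p, p)
            ok = ~np.isnan(tab["raw"])
            assert ok.any()
            assert (tab["raw"][ok] == 0).all()

    @pytest.mark.parametrize("framing", ["site", "derived"])
    def test_antisymmetric_under_population_swap(self, framing):
        rng = np.random.default_rng(6)
        a = make_hap_panel(rng.integers(0, 2, (10, 80)))
        b = make_hap_panel(rng.integers(0, 2, (8, 80)))
        t1 = xpehh_scan(a, b, framing=framing)
        t2 = xpehh_scan(b, a, framing=framing)
        np.testing.assert_allclose(t1["raw"], -t2["raw"], atol=1e-12)
        r1 = rsb_scan(a, b)
        r2 = rsb_scan(b, a)
        np.testing.assert_allclose(r1["raw"], -r2["raw"], atol=1e-12)

    def test_sweep_core_rsb_positive_and_top_percent(self, sweep_scan):
        tab = sweep_scan.scores["Rsb_vs_EUT"]
        core = ((tab["chrom"] == "1")
                & (np.abs(tab["pos"] - 12_500_000) < 250_000))
        core_max = np.nanmax(tab.loc[core, "std"])
        assert core_max > 0
        cut = np.nanquantile(tab["std"], 0.99)
        assert core_max >= cut


class TestOutlierWindows:
    def _scores(self, pos_p):
        return pd.DataFrame({
            "chrom": "1", "pos": [p for p, _ in pos_p],
            "std": [5.0] * len(pos_p),
            "neglog10p": [v for _, v in pos_p]})

    def test_five_outliers_flag_window(self):
        scores = self._scores([(100_000 + i * 1000, 6.5) for i in range(5)])
        grid = build_window_grid({"1": 1_000_000}, 500_000)
        calls = classify_outlier_windows(scores, grid)
        assert calls["flagged"].tolist() == [True, False]
        assert calls["sign"].iloc[0] == 5.0

    def test_four_outliers_do_not(self):
        scores = self._scores([(100_000 + i * 1000, 6.5) for i in range(4)])
        grid = build_window_grid({"1": 1_000_000}, 500_000)
        calls = classify_outlier_windows(scores, grid)
        assert not calls["flagged"].any()

    def test_scattered_singletons_never_flag(self):
        scores = self._scores([(i * 500_000 + 1000, 7.0) for i in range(10)])
        grid = build_window_grid({"1": 5_000_000}, 500_000)
        calls = classify_outlier_windows(scores, grid)
        assert not calls["flagged"].any()
        assert calls["n_outliers"].sum() == 10

    def test_relaxed_preset(self):
        preset = relaxed_replication_preset({"1": 3_000_000})
        assert preset["p_threshold"] == 4.0 and preset["min_snps"] == 1
        grid = preset["grid"]
        assert grid.width == 1_000_000 and grid.step == 500_000
        scores = self._scores([(1_200_000, 4.5)])
        calls = classify_outlier_windows(scores, grid, preset["p_threshold"],
                                         preset["min_snps"])
        # one outlier flags every sliding window containing it
        flagged = calls[calls["flagged"]]
        assert len(flagged) == 2
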