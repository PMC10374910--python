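import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from admixscan.filters import (apply_variant_filters, assign_ancestral_alleles,
                               derived_allele_frequency, hwe_exact_test,
                               ld_prune, pihat_relatedness,
                               prune_related_samples)
from admixscan.panel import GenotypePanel, make_variant_table

from _oracles import hwe_exact_brute


def make_geno(genotypes, qual=None):
    genotypes = np.asarray(genotypes, np.int8)
    variants = make_variant_table("1", np.arange(1, genotypes.shape[1] + 1) * 1000,
                                  qual=qual)
    return GenotypePanel(variants, genotypes,
                         [f"s{i}" for i in range(genotypes.shape[0])])


class TestHwe:
    def test_monomorphic_site(self):
        assert hwe_exact_test(25, 0, 0) == 1.0

    def test_matches_enumeration_oracle(self):
        assert hwe_exact_test(5, 10, 5) == pytest.approx(
            hwe_exact_brute(5, 10, 5), rel=1e-9)

    def test_extreme_heterozygote_excess_fails_filter(self):
        assert hwe_exact_test(0, 100, 0) < 0.01

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_brute_force(self, rr, ra, aa):
        if rr + ra + aa == 0:
            return
        assert hwe_exact_test(rr, ra, aa) == pytest.approx(
            hwe_exact_brute(rr, ra, aa), rel=1e-9, abs=1e-12)


class TestVariantFilters:
    def test_maf_threshold(self):
        # MAF 0.05, 0.2, 0.5 with 10 diploids
        g = np.zeros((10, 3), np.int8)
        g[0, 0] = 1          # alt freq 0.05
        g[:4, 1] = 1         # alt freq 0.2
        g[:5, 2] = 2         # alt freq 0.5
        out, rep = apply_variant_filters(make_geno(g), hwe_p_min=0.0,
                                         qual_min=0)
        assert out.n_variants == 2 and rep.removed_maf == 1

    def test_missingness(self):
        g = np.tile(np.array([[0], [1], [2], [1]], np.int8), (5, 4))
        g[:3, 2] = -1  # 15% missing at third variant
        out, rep = apply_variant_filters(make_geno(g), maf_min=0,
                                         hwe_p_min=0, qual_min=0)
        assert rep.removed_missing == 1
        assert 3000 not in set(out.variants["pos"])

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        g = make_geno(rng.integers(0, 3, size=(30, 200)))
        once, _ = apply_variant_filters(g)
        twice, rep2 = apply_variant_filters(once)
        assert twice.variants.equals(once.variants)
        assert rep2.n_kept == once.n_variants

    def test_retained_set_matches_per_variant_recheck(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, size=(40, 300)).astype(np.int8)
        miss = rng.random((40, 300)) < 0.05
        g[miss] = -1
        panel = make_geno(g, qual=rng.uniform(50, 200, 300))
        out, _ = apply_variant_filters(panel)
        kept = set(out.variants["pos"])
        for j in range(panel.n_variants):
            col = panel.genotypes[:, j]
            obs = col[col != -1]
            f = obs.sum() / (2 * len(obs))
            maf = min(f, 1 - f)
            ok = (maf >= 0.1 and (col == -1).mean() <= 0.1
                  and hwe_exact_brute(int((obs == 0).sum()),
                                      int((obs == 1).sum()),
                                      int((obs == 2).sum())) >= 0.01
                  and panel.variants["qual"].iloc[j] >= 100)
            assert (panel.variants["pos"].iloc[j] in kept) == ok


class TestLdPrune:
    def test_perfectly_correlated_pair(self):
        col = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 1], np.int8)
        g = make_geno(np.stack([col, col], axis=1))
        kept = ld_prune(g, r2_max=0.6)
        assert len(kept) == 1

    def test_independent_variants_survive(self):
        rng = np.random.default_rng(0)
        g = make_geno(rng.integers(0, 3, size=(200, 30)))
        kept = ld_prune(g, r2_max=0.99)
        assert len(kept) == 30

    def test_no_surviving_pair_exceeds_threshold(self):
        # LD block structure: pairs within blocks are highly correlated
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, size=(60, 10)).astype(np.int8)
        g = np.repeat(base, 5, axis=1)  # 50 variants in 10 identical blocks
        flip = rng.random(g.shape) < 0.05
        g = np.where(flip, rng.integers(0, 3, size=g.shape), g).astype(np.int8)
        panel = make_geno(g)
        kept = ld_prune(panel, window_snps=20, step_snps=4, r2_max=0.6)
        x = panel.genotypes[:, kept].astype(float)
        # exhaustive pair recheck within every sliding window position
        for w0 in range(0, len(kept), 1):
            win = [k for k in range(len(kept))
                   if kept[w0] <= kept[k] < kept[w0] + 20]
            for ai in range(len(win)):
                for bi in range(ai + 1, len(win)):
                    r = np.corrcoef(x[:, win[ai]], x[:, win[bi]])[0, 1]
                    if np.isfinite(r):
                        assert r * r <= 0.6 + 1e-9

    def test_fewer_than_two_variants_unchanged(self):
        g = make_geno(np.array([[0], [1]], np.int8))
        assert list(ld_prune(g, r2_max=0.5)) == [0]


class TestPihat:
    def test_duplicated_sample_is_identical(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, size=(1, 2000))
        g = make_geno(np.vstack([col, col, rng.integers(0, 3, (1, 2000))]))
        est = pihat_relatedness(g, "s0", "s1")
        assert est.pihat == pytest.approx(1.0, abs=0.05)

    def test_unrelated_samples_near_zero(self):
        rng = np.random.default_rng(3)
        n_sites = 10_000
        p = rng.uniform(0.1, 0.9, n_sites)
        g = (rng.random((20, n_sites)) < p).astype(np.int8) + \
            (rng.random((20, n_sites)) < p).astype(np.int8)
        est = pihat_relatedness(make_geno(g), "s0", "s1")
        assert abs(est.pihat) < 0.05

    def test_parent_offspring_half(self):
        rng = np.random.default_rng(4)
        n_sites = 10_000
        p = rng.uniform(0.1, 0.9, n_sites)
        hap = lambda: (rng.random(n_sites) < p).astype(np.int8)
        pa, pb = hap(), hap()
        parent = pa + pb
        child = pa + hap()  # inherits haplotype pa
        others = np.stack([hap() + hap() for _ in range(10)])
        g = make_geno(np.vstack([parent, child, others]))
        est = pihat_relatedness(g, "s0", "s1")
        assert est.pihat == pytest.approx(0.5, abs=0.05)

    def test_symmetric(self):
        rng = np.random.default_rng(9)
        g = make_geno(rng.integers(0, 3, size=(6, 500)))
        a = pihat_relatedness(g, "s1", "s4").pihat
        b = pihat_relatedness(g, "s4", "s1").pihat
        assert a == pytest.approx(b, abs=1e-12)

    def test_related_pair_pruned(self):
        rng = np.random.default_rng(10)
        n_sites = 12_000  # PI_HAT noise must sit well below the 0.05 cut
        p = rng.uniform(0.1, 0.9, n_sites)
        draw = lambda: ((rng.random(n_sites) < p).astype(np.int8)
                        + (rng.random(n_sites) < p).astype(np.int8))
        dup = draw()
        g = make_geno(np.vstack([dup, dup] + [draw() for _ in range(3)]))
        kept, _ = prune_related_samples(g, pihat_max=0.05)
        assert len(kept) == 4
        assert not {"s0", "s1"} <= set(kept)


class TestAncestralAlleles:
    def test_majority_and_tie_rules(self):
        g = np.array([[2, 2, 1], [2, 1, 1], [1, 0, 0], [2, 0, 0]], np.int8)
        # alt freqs: 7/8, 3/8, 2/8 -> ancestral alt, ref, ref
        out = assign_ancestral_alleles(make_geno(g))
        assert list(out.variants["ancestral_is_alt"]) == [True, False, False]
        tie = np.array([[1], [1]], np.int8)  # alt freq exactly 0.5
        out = assign_ancestral_alleles(make_geno(tie))
        assert not out.variants["ancestral_is_alt"].iloc[0]

    def test_daf_recomputation(self):
        rng = np.random.default_rng(11)
        g = make_geno(rng.integers(0, 3, size=(50, 100)))
        out = assign_ancestral_alleles(g)
        f_alt = out.alt_frequency()
        daf = derived_allele_frequency(out.variants, f_alt)
        f_anc = np.where(out.variants["ancestral_is_alt"], f_alt, 1 - f_alt)
        np.testing.assert_allclose(daf, 1 - f_anc, atol=1e-12)
        assert (daf <= 0.5 + 1e-12).all()  # ancestral is the majority allele
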