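"""Diversity indices, HWE/linkage tests, EM null alleles, Weir–Cockerham FST,
AMOVA, and Mantel isolation-by-distance."""
import numpy as np
import pytest

from conftest import amova_brute, toy_two_pop_genotypes, wc_theta_brute
from seascapegen.popgen import (
    GenotypeMatrix,
    amova_three_level,
    bonferroni,
    compare_fst_paired_t,
    estimate_null_alleles_em,
    haversine_km,
    hwe_exact_enumeration,
    hwe_exact_test,
    linkage_permutation_test,
    mantel_ibd,
    summarize_loci,
    wc_fst,
)
from seascapegen.synthetic_data import GenotypeSimConfig, simulate_genotypes


def make_g(calls, pops, groups=None, loci=None):
    calls = np.asarray(calls, dtype=int)
    if calls.ndim == 2:
        calls = calls[:, None, :]
    n, L, _ = calls.shape
    groups = groups or {p: "g" for p in set(pops)}
    return GenotypeMatrix(
        individuals=[f"i{k}" for k in range(n)],
        loci=loci or [f"L{j}" for j in range(L)],
        calls=calls,
        population=list(pops),
        group=groups,
    )


class TestSummarizeLoci:
    def test_monomorphic(self):
        g = make_g([(1, 1)] * 8, ["A"] * 8)
        (s_a, s_all) = summarize_loci(g)
        assert s_a.na == 1 and s_a.ho == 0 and s_a.he == 0
        assert s_a.pic == 0 and s_a.ar == 1.0

    def test_biallelic_all_het_closed_forms(self):
        """p = q = 0.5, 10 fully heterozygous individuals:
        Ho = 1, He = (20/19)(1 - 0.5) = 0.526316, PIC = 1 - 0.5 - 2(0.25·0.25) = 0.375."""
        g = make_g([(1, 2)] * 10, ["A"] * 10)
        s = summarize_loci(g)[0]
        assert s.ho == 1.0
        assert s.he == pytest.approx(20 / 19 * 0.5, abs=1e-12)
        assert s.pic == pytest.approx(0.375, abs=1e-12)

    def test_rarefaction_identity(self):
        """AR at rarefaction_n = 2N equals the raw allele count."""
        rng = np.random.default_rng(0)
        calls = rng.integers(1, 5, size=(12, 1, 2))
        g = make_g(calls, ["A"] * 12)
        s = summarize_loci(g, rarefaction_n=24)[0]
        assert s.ar == pytest.approx(s.na, abs=1e-12)

    def test_ar_monotone_in_rarefaction_n(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(1, 7, size=(15, 1, 2))
        g = make_g(calls, ["A"] * 15)
        ars = [summarize_loci(g, rarefaction_n=n)[0].ar for n in (2, 6, 12, 24, 30)]
        assert all(b >= a - 1e-12 for a, b in zip(ars, ars[1:]))

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(1, 5, size=(20, 1, 2))
        g1 = make_g(calls, ["A"] * 20)
        relabel = {1: 9, 2: 4, 3: 7, 4: 1}
        calls2 = np.vectorize(relabel.get)(calls)
        g2 = make_g(calls2, ["A"] * 20)
        s1, s2 = summarize_loci(g1)[0], summarize_loci(g2)[0]
        for attr in ("he", "pic", "ho", "na", "ar"):
            assert getattr(s1, attr) == pytest.approx(getattr(s2, attr), abs=1e-12)


class TestHweExactTest:
    def test_matches_enumeration_tiny_n(self):
        """Monte-Carlo p agrees with exhaustive enumeration for n <= 8."""
        cases = [
            [(1, 1)] * 3 + [(1, 2)] * 2 + [(2, 2)] * 2,
            [(1, 2)] * 6,
            [(1, 1)] * 4 + [(2, 2)] * 3,
            [(1, 2), (1, 3), (2, 3), (1, 1), (2, 2), (3, 3)],
        ]
        for pairs in cases:
            exact = hwe_exact_enumeration(np.array(pairs))
            g = make_g(pairs, ["A"] * len(pairs))
            mc = hwe_exact_test(g, "L0", "A", n_reps=20000, seed=0)
            se = np.sqrt(max(exact * (1 - exact), 0.0) / 20000)
            assert abs(mc - exact) < 4 * se + 2e-3

    def test_all_heterozygotes_rejected(self):
        g = make_g([(1, 2)] * 50, ["A"] * 50)
        p = hwe_exact_test(g, "L0", "A", n_reps=5000, seed=1)
        assert p < 0.01

    def test_determinism(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(1, 4, size=(30, 1, 2))
        g = make_g(calls, ["A"] * 30)
        p1 = hwe_exact_test(g, "L0", "A", n_reps=2000, seed=11)
        p2 = hwe_exact_test(g, "L0", "A", n_reps=2000, seed=11)
        assert p1 == p2

    def test_monomorphic_signaled(self):
        g = make_g([(1, 1)] * 10, ["A"] * 10)
        with pytest.raises(ValueError, match="monomorphic"):
            hwe_exact_test(g, "L0", "A")


class TestLinkage:
    def test_duplicated_locus_maximal_association(self):
        rng = np.random.default_rng(4)
        col = rng.integers(1, 4, size=(40, 1, 2))
        calls = np.concatenate([col, col], axis=1)
        g = make_g(calls, ["A"] * 40)
        p = linkage_permutation_test(g, "L0", "L1", n_reps=500, seed=0)
        assert p <= 2 / 501

    def test_determinism(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(1, 4, size=(40, 2, 2))
        g = make_g(calls, ["A"] * 40)
        assert linkage_permutation_test(g, "L0", "L1", 300, seed=9) == \
            linkage_permutation_test(g, "L0", "L1", 300, seed=9)

    def test_monomorphic_rejected(self):
        calls = np.concatenate(
            [np.full((10, 1, 2), 1), np.random.default_rng(0).integers(1, 3, (10, 1, 2))],
            axis=1,
        )
        g = make_g(calls, ["A"] * 10)
        with pytest.raises(ValueError, match="polymorphic"):
            linkage_permutation_test(g, "L0", "L1")


class TestBonferroni:
    @pytest.mark.parametrize(
        "pvals,alpha,expected",
        [
            ([0.04], 0.05, [True]),
            ([0.003, 0.01, 0.2], 0.05, [True, True, False]),  # threshold 0.0167
            ([1.0, 1.0, 1.0], 0.05, [False, False, False]),
        ],
    )
    def test_flags(self, pvals, alpha, expected):
        assert bonferroni(pvals, alpha).tolist() == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([])


class TestNullAlleleEM:
    def test_hwe_sample_no_null(self):
        """Genotypes drawn in exact HWE proportions show ~zero null frequency."""
        # p = (0.5, 0.3, 0.2), n = 100 in perfect proportions
        pairs = (
            [(1, 1)] * 25 + [(2, 2)] * 9 + [(3, 3)] * 4
            + [(1, 2)] * 30 + [(1, 3)] * 20 + [(2, 3)] * 12
        )
        g = make_g(pairs, ["A"] * 100)
        est = estimate_null_alleles_em(g, "L0", "A")
        assert est.null_freq < 0.01
        assert est.null_freq + sum(est.visible_freqs.values()) == pytest.approx(1.0)

    def test_all_heterozygotes_zero_null(self):
        g = make_g([(1, 2)] * 30, ["A"] * 30)
        est = estimate_null_alleles_em(g, "L0", "A")
        assert est.null_freq < 1e-6

    def test_parameter_recovery(self):
        cfg = GenotypeSimConfig(
            n_groups=2, pops_per_group=1, individuals_per_pop=200, n_loci=1,
            alleles_per_locus=(8, 8), null_allele_freq=0.2, seed=5,
        )
        g = simulate_genotypes(cfg)
        est = estimate_null_alleles_em(g, "locus1", g.populations[0])
        assert est.null_freq == pytest.approx(0.2, abs=0.05)

    def test_missing_variant_flag(self):
        pairs = [(1, 1)] * 20 + [(1, 2)] * 5 + [(2, 2)] * 10 + [(0, 0)] * 5
        g = make_g(pairs, ["A"] * 40)
        a = estimate_null_alleles_em(g, "L0", "A", missing_as_null=True)
        b = estimate_null_alleles_em(g, "L0", "A", missing_as_null=False)
        assert a.null_freq > b.null_freq  # blanks counted as null homozygotes


class TestWcFst:
    def test_toy_matches_brute_force(self):
        g = toy_two_pop_genotypes()
        res = wc_fst(g, scope="pairwise", n_boot=0)
        calls_by_pop = [
            g.calls[g.pop_indices("A"), 0, :],
            g.calls[g.pop_indices("B"), 0, :],
        ]
        assert res.theta[0, 1] == pytest.approx(wc_theta_brute(calls_by_pop), abs=1e-12)

    def test_fixed_alternate_alleles(self):
        calls = np.zeros((20, 2, 2), int)
        calls[:10], calls[10:] = 1, 2
        g = make_g(calls, ["A"] * 10 + ["B"] * 10)
        res = wc_fst(g, scope="pairwise", n_boot=0)
        assert res.theta[0, 1] == pytest.approx(1.0)

    def test_panmixia_ci_covers_zero(self):
        rng = np.random.default_rng(6)
        p = rng.dirichlet(np.ones(6))
        calls = rng.choice(6, size=(200, 10, 2), p=p) + 1
        g = make_g(calls, ["A"] * 100 + ["B"] * 100)
        res = wc_fst(g, scope="pairwise", n_boot=500, seed=0)
        lo, hi = res.bootstrap_ci[0, 1]
        assert lo <= 0.0 <= hi or abs(res.theta[0, 1]) < 0.005

    def test_relabel_and_pop_order_invariance(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(1, 5, size=(60, 4, 2))
        pops = ["A"] * 20 + ["B"] * 20 + ["C"] * 20
        g1 = make_g(calls, pops)
        relabel = {1: 3, 2: 1, 3: 4, 4: 2}
        g2 = make_g(np.vectorize(relabel.get)(calls), pops)
        idx = np.concatenate([np.arange(40, 60), np.arange(20, 40), np.arange(0, 20)])
        g3 = make_g(calls[idx], ["C"] * 20 + ["B"] * 20 + ["A"] * 20)
        t1 = wc_fst(g1, n_boot=0).theta
        t2 = wc_fst(g2, n_boot=0).theta
        t3 = wc_fst(g3, n_boot=0)
        assert np.allclose(t1, t2, atol=1e-12)
        k = {p: i for i, p in enumerate(t3.populations)}
        for i, a in enumerate(["A", "B", "C"]):
            for j, b in enumerate(["A", "B", "C"]):
                assert t1[i, j] == pytest.approx(t3.theta[k[a], k[b]], abs=1e-12)

    def test_ena_equals_uncorrected_without_nulls(self):
        """With every locus fully heterozygous (no homozygote excess possible),
        EM nulls converge to 0 and the ENA θ matches the uncorrected θ."""
        rng = np.random.default_rng(8)
        n = 40
        calls = np.zeros((n, 3, 2), int)
        for l in range(3):
            for i in range(n):
                a, b = rng.choice(6, size=2, replace=False) + 1
                calls[i, l] = (a, b)
        g = make_g(calls, ["A"] * 20 + ["B"] * 20)
        res = wc_fst(g, ena=True, n_boot=0)
        assert res.theta_ena[0, 1] == pytest.approx(res.theta[0, 1], abs=1e-3)

    def test_bootstrap_determinism(self):
        g = simulate_genotypes(GenotypeSimConfig(
            n_groups=2, pops_per_group=1, individuals_per_pop=20, n_loci=6, seed=1))
        a = wc_fst(g, n_boot=100, seed=3)
        b = wc_fst(g, n_boot=100, seed=3)
        assert np.array_equal(a.bootstrap_ci, b.bootstrap_ci)


class TestComparePairedT:
    def test_identical(self):
        m = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        t, p = compare_fst_paired_t(m, m)
        assert t == 0.0 and p == 1.0

    def test_constant_offset_significant(self):
        m = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        t, p = compare_fst_paired_t(m, m + 0.01)
        assert p < 0.05

    def test_mean_zero_noise_not_significant(self):
        rng = np.random.default_rng(9)
        m = np.zeros((6, 6))
        iu = np.triu_indices(6, 1)
        vals = rng.uniform(0.0, 0.2, len(iu[0]))
        m[iu] = vals
        m += m.T
        noise = np.zeros_like(m)
        nz = rng.normal(0, 0.005, len(iu[0]))
        nz -= nz.mean()  # exactly mean-zero differences
        noise[iu] = nz
        noise += noise.T
        t, p = compare_fst_paired_t(m, m + noise)
        assert p > 0.5

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="pairs"):
            compare_fst_paired_t(np.zeros((2, 2)), np.zeros((2, 2)))


class TestAmova:
    def test_matches_brute_force_toy(self):
        rng = np.random.default_rng(10)
        calls = rng.integers(1, 4, size=(18, 2, 2))
        g = make_g(
            calls, ["A"] * 6 + ["B"] * 6 + ["C"] * 6,
            groups={"A": "g1", "B": "g1", "C": "g2"},
        )
        res = amova_three_level(g, n_perm=0)
        ba, bb, bc = amova_brute(g)
        assert res.sigma2["among_groups"] == pytest.approx(ba, abs=1e-10)
        assert res.sigma2["among_pops_within_groups"] == pytest.approx(bb, abs=1e-10)
        assert res.sigma2["within_pops"] == pytest.approx(bc, abs=1e-10)
        assert sum(res.pct_variation.values()) == pytest.approx(100.0, abs=1e-6)

    def test_df_partition(self):
        rng = np.random.default_rng(11)
        calls = rng.integers(1, 4, size=(20, 2, 2))
        g = make_g(
            calls, ["A"] * 5 + ["B"] * 5 + ["C"] * 5 + ["D"] * 5,
            groups={"A": "g1", "B": "g1", "C": "g2", "D": "g2"},
        )
        res = amova_three_level(g, n_perm=0)
        assert sum(res.df.values()) == 2 * 20 - 1

    def test_fixed_groups_full_partition(self):
        calls = np.zeros((30, 2, 2), int)
        calls[:10], calls[10:20], calls[20:] = 1, 2, 3
        g = make_g(
            calls,
            ["A"] * 5 + ["B"] * 5 + ["C"] * 5 + ["D"] * 5 + ["E"] * 5 + ["F"] * 5,
            groups={"A": "g1", "B": "g1", "C": "g2", "D": "g2", "E": "g3", "F": "g3"},
        )
        res = amova_three_level(g, n_perm=0)
        assert res.pct_variation["among_groups"] == pytest.approx(100.0, abs=1e-6)

    def test_null_data_nonsignificant(self):
        g = simulate_genotypes(GenotypeSimConfig(
            n_groups=1, pops_per_group=6, individuals_per_pop=12, n_loci=8,
            fst_within_groups=0.005, seed=12))
        # relabel the 6 panmictic-ish pops into 3 arbitrary "groups"
        grouping = {p: f"g{(i // 2) + 1}" for i, p in enumerate(g.populations)}
        res = amova_three_level(g, grouping=grouping, n_perm=100, seed=0)
        assert res.p_values["F_CT"] > 0.01

    def test_permutation_determinism(self):
        rng = np.random.default_rng(13)
        calls = rng.integers(1, 4, size=(18, 2, 2))
        g = make_g(
            calls, ["A"] * 6 + ["B"] * 6 + ["C"] * 6,
            groups={"A": "g1", "B": "g1", "C": "g2"},
        )
        r1 = amova_three_level(g, n_perm=50, seed=5)
        r2 = amova_three_level(g, n_perm=50, seed=5)
        assert r1.p_values == r2.p_values


class TestMantel:
    def coords_line(self, n):
        return {i: (30.0 + i * 2.0, -30.0 + i * 1.5) for i in range(n)}

    def test_perfect_linear_relation(self):
        n = 6
        coords = self.coords_line(n)
        geo = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                geo[i, j] = haversine_km(*coords[i], *coords[j])
        # construct theta so that fst/(1-fst) = geo * 1e-5  =>  perfect IBD
        lin = geo * 1e-5
        theta = lin / (1 + lin)
        res = mantel_ibd(theta, coords=coords, n_perm=200, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p <= 2 / 201

    def test_determinism(self):
        rng = np.random.default_rng(14)
        n = 6
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        m[iu] = rng.uniform(0, 0.2, len(iu[0]))
        m += m.T
        r1 = mantel_ibd(m, coords=self.coords_line(n), n_perm=300, seed=21)
        r2 = mantel_ibd(m, coords=self.coords_line(n), n_perm=300, seed=21)
        assert (r1.r, r1.p) == (r2.r, r2.p)

    def test_negative_theta_clamped(self):
        n = 5
        m = np.full((n, n), 0.1)
        np.fill_diagonal(m, 0)
        m[0, 1] = m[1, 0] = -0.02  # slightly negative estimate
        res = mantel_ibd(m, coords=self.coords_line(n), n_perm=100, seed=0)
        assert np.isfinite(res.r)

    def test_too_few_populations(self):
        with pytest.raises(ValueError, match=">= 4"):
            mantel_ibd(np.zeros((3, 3)), coords=self.coords_line(3))


class TestHaversine:
    def test_quarter_meridian(self):
        # pole to equator along a meridian = 1/4 of the great circle
        assert haversine_km(0, 0, 0, 90) == pytest.approx(np.pi / 2 * 6371.0, rel=1e-9)
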