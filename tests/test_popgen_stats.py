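import numpy as np
import pytest

from consgen.popgen_stats import (
    amova,
    amova_from_distance,
    codominant_distance,
    diversity,
    fst_prime,
    hwe_test,
    pcoa,
    rst_permutation_test,
    wright_fst,
)
from consgen.synthetic_data import SynthSpec, balding_nichols_table

from conftest import make_table


class TestDiversity:
    def test_monomorphic_locus(self):
        t = make_table([[[7, 7]], [[7, 7]]], pops=["A", "A"])
        rep = diversity(t, by="total")
        row = rep.per_locus.loc[("total", "L1")]
        assert row["Na"] == 1 and row["Ne"] == 1
        assert row["He"] == 0 and row["Ho"] == 0
        assert np.isnan(row["FIS"])

    def test_all_heterozygous_symmetric(self):
        t = make_table(
            [[[100, 102]], [[100, 102]], [[100, 102]]], pops=["A"] * 3
        )
        row = diversity(t).per_locus.loc[("total", "L1")]
        assert row["Ho"] == 1.0
        assert row["He"] == pytest.approx(0.5)
        assert row["FIS"] == pytest.approx(-1.0)

    def test_hand_computed_two_individuals(self):
        """p(100) = 3/4: He = 0.375, Ho = 0.5, Ne = 1.6, FIS = −1/3."""
        t = make_table([[[100, 102]], [[100, 100]]], pops=["A", "A"])
        row = diversity(t).per_locus.loc[("total", "L1")]
        assert row["He"] == pytest.approx(0.375, abs=1e-12)
        assert row["Ho"] == pytest.approx(0.5)
        assert row["Ne"] == pytest.approx(1.6, abs=1e-12)
        assert row["FIS"] == pytest.approx(-1 / 3, abs=1e-12)

    def test_all_missing_locus_is_nan_not_zero(self):
        t = make_table(
            [[[5, 5], [1, 1]], [[5, 6], [1, 1]]],
            pops=["A", "A"],
            missing=[[False, True], [False, True]],
        )
        row = diversity(t).per_locus.loc[("total", "L2")]
        assert row.isna().all()

    def test_bounds_and_na_ge_ne(self, random_table):
        rep = diversity(random_table, by="pop")
        ok = rep.per_locus.dropna()
        assert ((ok["Ho"] >= 0) & (ok["Ho"] <= 1)).all()
        assert ((ok["He"] >= 0) & (ok["He"] <= 1)).all()
        assert (ok["Ne"] >= 1 - 1e-12).all()
        assert (ok["Na"] >= ok["Ne"] - 1e-12).all()


class TestHweTest:
    def test_extreme_heterozygote_deficit(self):
        """50 individuals, all homozygous at p = 0.5: p-value ≤ 0.001."""
        alleles = [[[1, 1]]] * 25 + [[[2, 2]]] * 25
        t = make_table(alleles, pops=["A"] * 50)
        p = hwe_test(t, 0, "A", n_perm=5000, seed=1)
        assert p <= 0.001

    def test_null_calibration(self):
        """Data drawn in Hardy–Weinberg proportions rarely give small p."""
        rng = np.random.default_rng(7)
        small = 0
        n_sets = 60
        for k in range(n_sets):
            genos = rng.integers(1, 3, size=(100, 1, 2))
            t = make_table(genos, pops=["A"] * 100)
            if hwe_test(t, 0, "A", n_perm=400, seed=k) <= 0.05:
                small += 1
        assert small <= 0.05 * n_sets + 3

    def test_monomorphic_flagged(self):
        t = make_table([[[3, 3]], [[3, 3]]], pops=["A", "A"])
        with pytest.warns(UserWarning, match="monomorphic"):
            assert hwe_test(t, 0, "A", n_perm=10, seed=0) == 1.0

    def test_zero_permutations_rejected(self, two_pop_table):
        with pytest.raises(ValueError):
            hwe_test(two_pop_table, 0, "A", n_perm=0)


def naive_ss(d2, idx):
    s = 0.0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            s += d2[idx[a], idx[b]]
    return s / len(idx)


class TestAmova:
    def test_fixed_differences_give_fst_one(self):
        t = make_table(
            [[[1, 1], [5, 5]]] * 3 + [[[2, 2], [6, 6]]] * 3,
            pops=["A"] * 3 + ["B"] * 3,
        )
        res = amova(t, strata="pop", n_perm=99, seed=0)
        assert res.indices["FST"] == pytest.approx(1.0)
        assert res.percent["among"] == pytest.approx(100.0)

    def test_random_labels_give_null(self):
        rng = np.random.default_rng(2)
        t = balding_nichols_table(
            SynthSpec(n_ind_per_group=(40, 40), target_fst=0.0, seed=3)
        )
        res = amova(t, strata="group", n_perm=199, seed=5)
        assert abs(res.indices["FST"]) < 0.05
        assert res.p_values["FST"] > 0.01

    def test_percentages_sum_to_100(self, random_table):
        res = amova(random_table, strata="pop", n_perm=9, seed=1)
        assert sum(res.percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_three_level_matches_naive_decomposition(self):
        """Hand-built 2 groups × 2 pops × 4 individuals: components equal a
        brute-force sums-of-squares decomposition."""
        rng = np.random.default_rng(11)
        alleles = rng.integers(10, 16, size=(16, 3, 2))
        pops = [f"p{k}" for k in range(4) for _ in range(4)]
        groups = ["g1"] * 8 + ["g2"] * 8
        t = make_table(alleles, pops=pops, groups=groups)
        d2 = codominant_distance(t)
        res = amova(t, strata=("group", "pop"), n_perm=9, seed=0)

        # naive decomposition with explicit loops
        n, P, G = 16, 4, 2
        pop_idx = [list(range(4 * k, 4 * k + 4)) for k in range(4)]
        grp_idx = [list(range(0, 8)), list(range(8, 16))]
        ss_wp = sum(naive_ss(d2, ix) for ix in pop_idx)
        ss_g = sum(naive_ss(d2, ix) for ix in grp_idx)
        ss_tot = naive_ss(d2, list(range(n)))
        ms_wp = ss_wp / (n - P)
        ms_ap = (ss_g - ss_wp) / (P - G)
        ms_ag = (ss_tot - ss_g) / (G - 1)
        # balanced design: n' = 4, n'' = 4, n''' = 8
        sigma_c = ms_wp
        sigma_b = (ms_ap - sigma_c) / 4
        sigma_a = (ms_ag - sigma_c - 4 * sigma_b) / 8
        assert res.components["within_pops"] == pytest.approx(sigma_c, abs=1e-9)
        assert res.components["among_pops_within_groups"] == pytest.approx(
            sigma_b, abs=1e-9
        )
        assert res.components["among_groups"] == pytest.approx(
            sigma_a, abs=1e-9
        )
        assert sum(res.percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_singleton_stratum_rejected(self):
        t = make_table(
            [[[1, 2]], [[1, 2]], [[2, 2]]], pops=["A", "A", "B"]
        )
        with pytest.raises(ValueError, match="B"):
            amova(t, strata="pop", n_perm=9, seed=0)


class TestFstPrime:
    def test_private_alleles_give_prime_one(self):
        """Groups sharing no alleles: recoding is the identity and
        F'_ST = F_ST / F_ST = 1."""
        t = make_table(
            [[[1, 2], [5, 5]]] * 4 + [[[3, 4], [6, 7]]] * 4,
            pops=["A"] * 4 + ["B"] * 4,
            groups=["w"] * 4 + ["e"] * 4,
        )
        res = fst_prime(t, grouping="group")
        assert res.fst_prime == pytest.approx(1.0, abs=1e-9)

    def test_identical_groups_give_prime_near_zero(self):
        """Duplicating one group's genotypes as the other group: F_ST and
        F'_ST sit at (slightly below, by the estimator's finite-sample
        bias) zero."""
        rng = np.random.default_rng(8)
        block = rng.integers(10, 16, size=(60, 3, 2))
        t = make_table(
            np.concatenate([block, block]),
            pops=["A"] * 60 + ["B"] * 60,
            groups=["w"] * 60 + ["e"] * 60,
        )
        res = fst_prime(t, grouping="group")
        assert abs(res.fst) < 0.02
        assert abs(res.fst_prime) < 0.1

    def test_prime_dominates_fst_on_random_tables(self):
        for seed in range(15):
            t = balding_nichols_table(
                SynthSpec(
                    n_ind_per_group=(25, 25),
                    n_loci=4,
                    target_fst=0.2,
                    seed=seed,
                )
            )
            res = fst_prime(t, grouping="group")
            assert res.fst_prime >= res.fst - 1e-9


class TestRst:
    def test_fixed_size_difference_gives_one(self):
        t = make_table(
            [[[100, 100]]] * 4 + [[[120, 120]]] * 4,
            pops=["A"] * 4 + ["B"] * 4,
            groups=["w"] * 4 + ["e"] * 4,
        )
        res = rst_permutation_test(t, n_perm=99, seed=0)
        assert res.rst == pytest.approx(1.0)

    def test_monomorphic_locus_excluded_with_warning(self):
        t = make_table(
            [[[100, 100], [7, 7]]] * 3 + [[[120, 120], [7, 7]]] * 3,
            pops=["A"] * 3 + ["B"] * 3,
            groups=["w"] * 3 + ["e"] * 3,
        )
        with pytest.warns(UserWarning, match="single allele"):
            res = rst_permutation_test(t, n_perm=99, seed=0)
        assert res.rst == pytest.approx(1.0)

    def test_stepwise_divergence_detected(self):
        """Under stepwise divergence R_ST exceeds its size-permutation null
        (p < 0.05) in the majority of replicates."""
        from consgen.coalescent_sim import DVM, MutationModel
        from consgen.synthetic_data import coalescent_table

        model = DVM(500, 500, 2000, 8000, 0.0, 0.0)
        hits = 0
        n_rep = 12
        for i in range(n_rep):
            t = coalescent_table(
                model, MutationModel(), [20, 20], n_loci=8, seed=100 + i
            )
            res = rst_permutation_test(t, n_perm=199, seed=i)
            if res.p_value < 0.05 and res.rst > res.p_rst:
                hits += 1
        assert hits > n_rep / 2


class TestPcoa:
    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords, eig = pcoa(d)
        got = []
        for i in range(3):
            for j in range(i + 1, 3):
                got.append(np.linalg.norm(coords[i] - coords[j]))
        assert np.allclose(got, 1.0, atol=1e-8)
        assert np.all(np.diff(eig) <= 1e-12)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords, _eig = pcoa(d)
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(d, d2, atol=1e-8)

    def test_zero_matrix(self):
        coords, eig = pcoa(np.zeros((4, 4)))
        assert np.allclose(coords, 0.0) and np.allclose(eig, 0.0)

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(d)


def test_wright_fst_recovers_target_in_expectation():
    """Allele-level F_ST on F-model tables is unbiased for the target
    (modest table size, many replicates)."""
    vals = np.array(
        [
            wright_fst(
                balding_nichols_table(
                    SynthSpec(
                        n_ind_per_group=(50, 50),
                        n_loci=8,
                        target_fst=0.11,
                        seed=i,
                    )
                )
            )
            for i in range(200)
        ]
    )
    se = vals.std(ddof=1) / np.sqrt(vals.size)
    assert abs(vals.mean() - 0.11) < 2 * se + 0.005


class TestSequentialBonferroni:
    def test_holm_ordering(self):
        from consgen.popgen_stats import sequential_bonferroni

        p = [0.001, 0.04, 0.012, 0.9]
        rej = sequential_bonferroni(p, alpha=0.05)
        # 0.001 <= 0.05/4, 0.012 <= 0.05/3, but 0.04 > 0.05/2 stops the run
        assert rej.tolist() == [True, False, True, False]

    def test_no_rejections(self):
        from consgen.popgen_stats import sequential_bonferroni

        assert not sequential_bonferroni([0.2, 0.5, 0.9]).any()
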