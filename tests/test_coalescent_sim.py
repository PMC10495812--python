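import numpy as np
import pytest

from consgen.coalescent_sim import (
    DVM,
    PGM,
    SNM,
    SRM,
    Genealogy,
    MutationModel,
    overlay_gsm,
    simulate_genealogy,
    simulate_msat_dataset,
)


class TestModelValidation:
    def test_srm_requires_decline(self):
        with pytest.raises(ValueError, match="N < Nb"):
            SRM(N=1000, Nb=500, t1=100)

    def test_pgm_ancestral_size(self):
        m = PGM(N=1000, G=0.001, t=500)
        assert m.ancestral_size == pytest.approx(1000 * np.exp(-0.5))

    def test_migration_bounds(self):
        with pytest.raises(ValueError, match="migration"):
            DVM(100, 100, 200, 10, m12=1.5)


class TestGenealogyStructure:
    @pytest.mark.parametrize(
        "model,cfg",
        [
            (SNM(N=200), [12]),
            (PGM(N=400, G=0.002, t=800), [10]),
            (SRM(N=200, Nb=2000, t1=300), [10]),
            (DVM(300, 300, 600, 500, 0.001, 0.001), [6, 6]),
        ],
    )
    def test_binary_ultrametric_times_increase_rootward(self, model, cfg):
        gen = simulate_genealogy(model, cfg, seed=42)
        n = sum(cfg)
        assert gen.parent.size == 2 * n - 1
        assert np.sum(gen.parent < 0) == 1  # single root
        assert np.all(gen.time[:n] == 0.0)  # tips at present
        has_parent = gen.parent >= 0
        assert np.all(
            gen.time[gen.parent[has_parent]] > gen.time[has_parent]
        )
        # every internal node has exactly two children
        counts = np.bincount(gen.parent[has_parent], minlength=2 * n - 1)
        assert np.all(counts[n:] == 2)

    def test_determinism(self):
        a = simulate_genealogy(SNM(N=100), [8], seed=7)
        b = simulate_genealogy(SNM(N=100), [8], seed=7)
        assert np.array_equal(a.parent, b.parent)
        assert np.array_equal(a.time, b.time)

    def test_no_cross_deme_coalescence_without_migration(self):
        """With m = 0 lineages from different demes can only meet in the
        ancestral population, i.e. at or after the split time T."""
        model = DVM(200, 200, 400, 1500, 0.0, 0.0)
        for seed in range(20):
            gen = simulate_genealogy(model, [5, 5], seed=seed)
            n = gen.n_tips
            demes_below = [
                {int(gen.tip_demes[i])} for i in range(n)
            ] + [set() for _ in range(n - 1)]
            order = np.argsort(gen.time)
            for node in order:
                p = gen.parent[node]
                if p >= 0:
                    demes_below[p] |= demes_below[node]
            for node in range(n, 2 * n - 1):
                if len(demes_below[node]) > 1:
                    assert gen.time[node] >= model.T

    def test_zero_lineages_rejected(self):
        with pytest.raises(ValueError):
            simulate_genealogy(SNM(N=100), [0], seed=0)


class TestCoalescenceTimes:
    def test_pairwise_time_snm(self):
        """E[T2] = 2N generations for two lineages in a diploid deme."""
        N = 500
        times = [
            simulate_genealogy(SNM(N=N), [2], seed=i).tmrca
            for i in range(800)
        ]
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(np.mean(times) - 2 * N) < 3 * se

    def test_tmrca_snm(self):
        """E[TMRCA] = 4N(1 − 1/n)."""
        N, n = 500, 10
        times = [
            simulate_genealogy(SNM(N=N), [n], seed=i).tmrca
            for i in range(800)
        ]
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(np.mean(times) - 4 * N * (1 - 1 / n)) < 3 * se

    def test_growth_shortens_tmrca(self):
        """A forward-growing population (small ancestral size) coalesces
        faster than a constant one of the current size."""
        snm = [
            simulate_genealogy(SNM(N=2000), [8], seed=i).tmrca
            for i in range(300)
        ]
        pgm = [
            simulate_genealogy(
                PGM(N=2000, G=0.01, t=600), [8], seed=i
            ).tmrca
            for i in range(300)
        ]
        assert np.mean(pgm) < np.mean(snm)

    def test_matches_msprime_divergence_model(self):
        """Cross-check against an independent coalescent implementation:
        mean TMRCA under a symmetric divergence model."""
        msprime = pytest.importorskip("msprime")
        N1 = N2 = 400
        N_anc, T, m = 800, 1000, 0.002
        model = DVM(N1, N2, N_anc, T, m, m)
        ours = np.array(
            [
                simulate_genealogy(model, [8, 8], seed=i).tmrca
                for i in range(400)
            ]
        )
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=N1)
        dem.add_population(name="B", initial_size=N2)
        dem.add_population(name="C", initial_size=N_anc)
        dem.set_symmetric_migration_rate(["A", "B"], m)
        dem.add_population_split(time=T, derived=["A", "B"], ancestral="C")
        theirs = []
        for ts in msprime.sim_ancestry(
            samples={"A": 4, "B": 4},
            demography=dem,
            ploidy=2,
            num_replicates=400,
            random_seed=99,
        ):
            theirs.append(ts.max_root_time)
        theirs = np.array(theirs)
        se = np.sqrt(
            ours.var(ddof=1) / ours.size + theirs.var(ddof=1) / theirs.size
        )
        assert abs(ours.mean() - theirs.mean()) < 4 * se


class TestGsmOverlay:
    def _two_tip_tree(self, depth):
        return Genealogy(
            parent=np.array([2, 2, -1]),
            time=np.array([0.0, 0.0, depth]),
            n_tips=2,
            tip_demes=np.zeros(2, dtype=np.int64),
        )

    def test_zero_rate_keeps_root_size(self):
        gen = simulate_genealogy(SNM(N=100), [6], seed=3)
        tips = overlay_gsm(gen, 0.0, 0.0, root_size=25, seed=1)
        assert np.all(tips == 25)

    def test_step_variance_scales_with_geometric_moment(self):
        """Tip difference variance = 2·λ·E[k²] on a two-tip tree of branch
        length B with λ = μB mutations per branch; E[k²] = (1+P)/(1−P)²."""
        depth, mu = 1000.0, 0.05
        lam = mu * depth
        rng = np.random.default_rng(0)
        for p, ek2 in [(0.0, 1.0), (0.5, 6.0)]:
            diffs = []
            for i in range(500):
                tips = overlay_gsm(
                    self._two_tip_tree(depth), mu, p, rng=rng
                )
                diffs.append(tips[0] - tips[1])
            var = np.var(diffs, ddof=1)
            expected = 2 * lam * ek2
            assert abs(var - expected) / expected < 0.25

    def test_strict_smm_steps_are_unit(self):
        """P_GSM = 0: every mutation is ±1, so with exactly one expected
        mutation regime the support stays tight around the root size."""
        gen = self._two_tip_tree(10.0)
        seen = set()
        rng = np.random.default_rng(1)
        for _ in range(300):
            tips = overlay_gsm(gen, 0.05, 0.0, root_size=100, rng=rng)
            seen.update(np.abs(np.diff(tips)).tolist())
        # differences are sums of unit steps; jumps beyond the mutation
        # count never occur (no multi-step mutations)
        assert max(seen) <= 8

    def test_negative_rate_rejected(self):
        gen = self._two_tip_tree(1.0)
        with pytest.raises(ValueError):
            overlay_gsm(gen, -1.0, 0.0)


class TestDatasetSimulation:
    def test_seed_determinism(self):
        m = DVM(300, 300, 600, 400, 0.0, 0.01)
        a = simulate_msat_dataset(m, MutationModel(), 4, [8, 8], seed=5)
        b = simulate_msat_dataset(m, MutationModel(), 4, [8, 8], seed=5)
        assert np.array_equal(a.alleles, b.alleles)
        assert a.equals(b)

    def test_smm_equilibrium_heterozygosity(self):
        """Strict SMM at equilibrium: He = 1 − 1/sqrt(1+8Nμ)."""
        N, mu = 1000, 5e-4  # theta = 4Nmu = 2
        mut = MutationModel(
            mu_mean=mu, gamma_shape=1e6, gamma_rate=1e6, p_gsm=0.0
        )
        hes = []
        for i in range(400):
            t = simulate_msat_dataset(SNM(N=N), mut, 1, [25], seed=i)
            copies = t.alleles[:, 0, :].ravel()
            _v, c = np.unique(copies, return_counts=True)
            p = c / c.sum()
            hes.append(1 - np.sum(p**2))
        expected = 1 - 1 / np.sqrt(1 + 8 * N * mu)
        se = np.std(hes, ddof=1) / np.sqrt(len(hes))
        assert abs(np.mean(hes) - expected) < 3 * se + 0.01

    def test_deep_isolation_gives_high_differentiation(self):
        from consgen.popgen_stats import wright_fst

        m = DVM(400, 400, 800, 40_000, 0.0, 0.0)
        t = simulate_msat_dataset(m, MutationModel(), 6, [15, 15], seed=9)
        assert wright_fst(t) > 0.3

    def test_group_labels_and_shapes(self):
        m = DVM(300, 300, 600, 400, 0.0, 0.0)
        t = simulate_msat_dataset(m, MutationModel(), 3, [5, 7], seed=2)
        assert t.n_individuals == 12 and t.n_loci == 3
        assert t.groups() == ["group1", "group2"]
        assert np.sum(t.group_labels == "group1") == 5
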