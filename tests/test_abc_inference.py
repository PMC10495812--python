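import numpy as np
import pandas as pd
import pytest

from consgen.abc_inference import (
    ModelChoiceResult,
    Prior,
    ReferenceTable,
    build_reference_table,
    dvm_spec,
    estimate_posterior,
    goodness_of_fit,
    pair_stat_names,
    rf_model_choice,
    snm_spec,
    srm_spec,
    summarize,
)
from consgen.coalescent_sim import DVM, SNM, MutationModel, simulate_msat_dataset

from conftest import make_table


class TestPriors:
    def test_families_and_bounds(self):
        rng = np.random.default_rng(0)
        u = Prior("uniform", 2.0, 4.0)
        lu = Prior("loguniform", 1e-3, 1e-1)
        f = Prior("fixed", 7.0)
        for _ in range(50):
            assert 2.0 <= u.draw(rng) <= 4.0
            assert 1e-3 <= lu.draw(rng) <= 1e-1
        assert f.draw(rng) == 7.0
        with pytest.raises(ValueError):
            Prior("uniform", 3.0, 1.0)
        with pytest.raises(ValueError):
            Prior("loguniform", -1.0, 1.0)


class TestSummarize:
    def test_monomorphic_table(self):
        t = make_table([[[5, 5]] * 3] * 4, pops=["A"] * 4)
        v = summarize(t, "single")
        assert v.tolist() == [1.0, 0.0, 0.0, 0.0, 0.0, 0.0]

    def test_hand_computed_vector(self):
        """Two loci: allele counts (2, 3), He (0.5, 0.625), ranges (2, 4)."""
        t = make_table(
            [
                [[10, 12], [20, 24]],
                [[10, 12], [22, 22]],
            ],
            pops=["A", "A"],
        )
        v = summarize(t, "single")
        A = np.array([2.0, 3.0])
        He = np.array([0.5, 1 - (0.25 ** 2 * 2 + 0.5 ** 2)])
        R = np.array([2.0, 4.0])
        expected = [
            A.mean(), A.std(ddof=1), He.mean(), He.std(ddof=1),
            R.mean(), R.std(ddof=1),
        ]
        assert np.allclose(v, expected, atol=1e-12)

    def test_pair_mode_identical_groups_gst_zero(self):
        rng = np.random.default_rng(1)
        block = rng.integers(10, 14, size=(20, 3, 2))
        t = make_table(
            np.concatenate([block, block]),
            pops=["A"] * 20 + ["B"] * 20,
            groups=["w"] * 20 + ["e"] * 20,
        )
        v = summarize(t, "pair")
        assert v.size == 14
        assert v[-1] == pytest.approx(0.0, abs=1e-12)  # G_ST

    def test_pair_mode_requires_two_groups(self):
        t = make_table([[[1, 2]]] * 4, pops=["A"] * 4, groups=["w"] * 4)
        with pytest.raises(ValueError, match="2 groups"):
            summarize(t, "pair")


class TestReferenceTable:
    def test_equal_allocation(self):
        specs = [
            snm_spec(), srm_spec(),
            snm_spec(),  # three entries -> 2 rows each at n_sims=6
        ]
        specs[2].name = "SNM2"
        ref = build_reference_table(specs, 6, [6], n_loci=2, seed=1)
        labels, counts = np.unique(ref.model_labels, return_counts=True)
        assert counts.tolist() == [2, 2, 2]

    def test_determinism(self):
        a = build_reference_table([snm_spec()], 5, [6], n_loci=2, seed=3)
        b = build_reference_table([snm_spec()], 5, [6], n_loci=2, seed=3)
        assert np.allclose(a.stats, b.stats)
        assert a.params.equals(b.params)

    def test_snm_rows_track_equilibrium_heterozygosity(self):
        """At a fixed N the simulated mean He clusters around the stepwise
        equilibrium value (GSM steps raise it above the strict-SMM form)."""
        N, mu = 1000, 5e-4
        spec = snm_spec(n_prior=Prior("fixed", N))
        spec.priors["p_gsm"] = Prior("fixed", 0.0)
        spec.priors["shape"] = Prior("fixed", 1e6)
        ref = build_reference_table([spec], 60, [25], n_loci=4, seed=4)
        he = ref.stats[:, 2]
        expected = 1 - 1 / np.sqrt(1 + 8 * N * mu)
        assert abs(he.mean() - expected) < 0.05


def _gaussian_reference(seed, n=400, sep=8.0):
    """Synthetic two-model reference table with controllable separation."""
    rng = np.random.default_rng(seed)
    sa = rng.normal(0.0, 1.0, size=(n, 4))
    sb = rng.normal(sep, 1.0, size=(n, 4))
    stats = np.vstack([sa, sb])
    labels = np.array(["A"] * n + ["B"] * n)
    params = pd.DataFrame({"x": rng.uniform(0, 1, size=2 * n)})
    return ReferenceTable(
        model_labels=labels, params=params, stats=stats,
        stat_names=[f"s{i}" for i in range(4)],
    )


class TestModelChoice:
    def test_disjoint_supports(self):
        """Fully separable models: OOB error ≈ 0, posterior prob ≈ 1."""
        ref = _gaussian_reference(0, sep=8.0)
        res = rf_model_choice(ref, np.full(4, 8.0), n_trees=300, seed=1)
        assert res.selected == "B"
        assert res.oob_error_mean < 0.02
        assert res.posterior_probability > 0.95
        assert sum(res.votes.values()) == 300

    def test_identical_models_are_chance_level(self):
        ref = _gaussian_reference(2, sep=0.0)
        res = rf_model_choice(ref, np.zeros(4), n_trees=300, seed=3)
        assert 0.35 < res.oob_error_mean < 0.65
        assert 0.3 < res.posterior_probability < 0.7

    def test_single_model_rejected(self):
        ref = _gaussian_reference(1).subset_model("A")
        with pytest.raises(ValueError, match="2 models"):
            rf_model_choice(ref, np.zeros(4), n_trees=10)


class TestEstimatePosterior:
    def _dvm_reference(self, n=300, seed=0):
        specs = [dvm_spec(600, 400, flow="2to1")]
        return build_reference_table(specs, n, [10, 10], n_loci=4, seed=seed)

    def test_rejection_tolerance_one_returns_prior(self):
        ref = self._dvm_reference()
        obs = ref.stats.mean(axis=0)
        post = estimate_posterior(
            ref, obs, tolerance=1.0, method="rejection", seed=1
        )
        assert len(post.draws) == ref.n_rows
        assert np.allclose(
            np.sort(post.draws["T"].to_numpy()),
            np.sort(ref.params["T"].to_numpy()),
        )

    def test_retention_count_is_ceiling(self):
        ref = self._dvm_reference()
        post = estimate_posterior(
            ref, ref.stats[0], tolerance=0.333, method="rejection", seed=1
        )
        assert len(post.draws) == int(np.ceil(0.333 * ref.n_rows))

    def test_too_few_draws_rejected(self):
        ref = self._dvm_reference(n=100)
        with pytest.raises(ValueError, match="increase n_sims"):
            estimate_posterior(ref, ref.stats[0], tolerance=0.01)

    def test_degenerate_stats_warn_and_fall_back(self):
        ref = self._dvm_reference(n=120)
        ref.stats = np.ones_like(ref.stats)
        with pytest.warns(UserWarning, match="degenerate"):
            post = estimate_posterior(
                ref, ref.stats[0], tolerance=1.0, method="loclinear", seed=2
            )
        assert post.method == "rejection"

    def test_hpd_is_narrowest_and_contains_mode(self):
        ref = self._dvm_reference()
        post = estimate_posterior(
            ref, ref.stats.mean(axis=0), tolerance=0.5, seed=3
        )
        for p, (lo, hi) in post.hpd.items():
            draws = post.draws[p].to_numpy()
            inside = np.mean((draws >= lo) & (draws <= hi))
            assert inside >= 0.95 - 1e-9
            assert lo - 1e-9 <= post.modes[p] <= hi + 1e-9

    def test_adjusted_draws_respect_prior_bounds(self):
        ref = self._dvm_reference()
        post = estimate_posterior(
            ref, ref.stats[0], tolerance=0.5, method="loclinear", seed=4
        )
        for p, (lo, hi) in (ref.param_bounds or {}).items():
            if p in post.draws:
                assert post.draws[p].min() >= lo - 1e-9
                assert post.draws[p].max() <= hi + 1e-9


class TestGoodnessOfFit:
    def test_zero_ppc_rejected(self):
        ref = build_reference_table([snm_spec()], 60, [8], n_loci=2, seed=0)
        post = estimate_posterior(ref, ref.stats[0], tolerance=1.0,
                                  method="rejection", seed=1)
        with pytest.raises(ValueError):
            goodness_of_fit(snm_spec(), post, ref.stats[0], 0, [8])

    def test_self_consistency_and_contrast(self):
        """Observations drawn from the fitted model are not flagged;
        observations from a grossly different demography are."""
        spec = snm_spec(n_prior=Prior("uniform", 500, 5000))
        ref = build_reference_table([spec], 400, [15], n_loci=4, seed=5)
        # self-consistent observation
        obs_tab = simulate_msat_dataset(
            SNM(N=2000), MutationModel(gamma_shape=2, gamma_rate=2,
                                       p_gsm=0.3),
            4, [15], seed=77,
        )
        obs = summarize(obs_tab, "single")
        post = estimate_posterior(ref, obs, tolerance=0.25, seed=6)
        gof = goodness_of_fit(spec, post, obs, 150, [15], n_loci=4, seed=7)
        assert gof["n_flagged"] <= 1
        # grossly different observation: deep-split two-deme data pooled
        far_tab = simulate_msat_dataset(
            DVM(5000, 5000, 10_000, 100_000, 0.0, 0.0),
            MutationModel(p_gsm=0.9), 4, [8, 7], seed=88,
        )
        far = summarize(far_tab, "single")
        post_far = estimate_posterior(ref, far, tolerance=0.25, seed=8)
        gof_far = goodness_of_fit(
            spec, post_far, far, 150, [15], n_loci=4, seed=9
        )
        assert gof_far["n_flagged"] >= 1


class TestPersistence:
    def test_reference_table_tsv_round_trip(self, tmp_path):
        from consgen.abc_inference import (
            load_reference_table,
            save_reference_table,
        )

        ref = build_reference_table(
            [snm_spec(), srm_spec()], 10, [6], n_loci=2, seed=9
        )
        p = tmp_path / "ref.tsv"
        save_reference_table(ref, p)
        back = load_reference_table(p)
        assert list(back.model_labels) == list(ref.model_labels)
        assert np.allclose(back.stats, ref.stats)
        assert back.param_bounds == ref.param_bounds
        assert list(back.params.columns) == list(ref.params.columns)
        assert np.allclose(
            back.params.fillna(-1).to_numpy(dtype=float),
            ref.params.fillna(-1).to_numpy(dtype=float),
        )
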