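import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from blastocomp import (
    ExpressionMatrix,
    degradation_lrt,
    estimate_noise,
    fit_rate,
    fit_shared_rate,
    rate_vs_expression_divergence,
)
from blastocomp.datatypes import DegradationOptions
from blastocomp.simulate import decay_gene_data, decay_noise_estimate, simulate_maternal_decay


class TestEstimateNoise:
    @staticmethod
    def _setup(values):
        samples = pd.DataFrame(
            {
                "sample_id": ["e1", "e2", "m1", "m2"],
                "species": "sp1",
                "stage": ["egg", "egg", "embryo", "embryo"],
                "sex": ["na", "na", "female", "female"],
                "replicate": [1, 2, 1, 2],
            }
        )
        m = ExpressionMatrix(
            pd.DataFrame([values], index=["g1"], columns=samples["sample_id"])
        )
        return m, samples

    def test_replicates_nine_eleven_contribute_variance_two(self):
        m, samples = self._setup([9.0, 11.0, 5.0, 5.0])
        # conditions: egg var 2, embryo var 0 -> mean 1
        assert estimate_noise(m, samples) == pytest.approx(1.0)

    def test_noiseless_input_rejected(self):
        m, samples = self._setup([5.0, 5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="zero"):
            estimate_noise(m, samples)

    def test_matches_two_pass_oracle(self, rng):
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "species": "sp1",
                "stage": ["egg"] * 3 + ["embryo"] * 3,
                "sex": ["na"] * 3 + ["male"] * 3,
                "replicate": [1, 2, 3, 1, 2, 3],
            }
        )
        values = rng.lognormal(1, 1, size=(40, 6))
        m = ExpressionMatrix(
            pd.DataFrame(values, index=[f"g{i}" for i in range(40)], columns=samples["sample_id"])
        )
        sigma2 = estimate_noise(m, samples)
        hand = []
        for row in values:
            for block in (row[:3], row[3:]):
                mean = sum(block) / 3
                hand.append(sum((x - mean) ** 2 for x in block) / 2)
        assert sigma2 == pytest.approx(np.mean(hand))

    def test_single_replicate_conditions_rejected(self):
        samples = pd.DataFrame(
            {
                "sample_id": ["e1", "m1"],
                "species": "sp1",
                "stage": ["egg", "embryo"],
                "sex": ["na", "male"],
                "replicate": [1, 1],
            }
        )
        m = ExpressionMatrix(pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["e1", "m1"]))
        with pytest.raises(ValueError, match="replicates"):
            estimate_noise(m, samples)


class TestFitRate:
    def test_exact_half_degradation(self):
        fit = fit_rate([10.0, 10.0, 10.0], [5.0, 5.0, 5.0])
        assert fit["r"] == pytest.approx(0.5)
        assert fit["rss"] == pytest.approx(0.0, abs=1e-9)

    def test_no_degradation(self):
        fit = fit_rate([4.0, 4.0], [4.0, 4.0])
        assert fit["r"] == pytest.approx(0.0)

    def test_matches_grid_search_minimizer(self, rng):
        egg = rng.lognormal(2, 0.2, 3)
        embryo = 0.6 * egg.mean() * rng.lognormal(0, 0.1, 3)
        fit = fit_rate(egg, embryo)
        grid = np.arange(0.0, 1.0 + 1e-6, 1e-6)
        a = 1.0 - grid
        ss = (
            len(embryo) * np.sum(egg**2) * a**2
            - 2 * a * np.sum(egg) * np.sum(embryo)
            + len(egg) * np.sum(embryo**2)
        )
        assert fit["r"] == pytest.approx(grid[np.argmin(ss)], abs=1e-5)

    def test_all_zero_eggs_rejected(self):
        with pytest.raises(ValueError, match="egg"):
            fit_rate([0.0, 0.0], [1.0])

    def test_bounds_clipping_flagged(self):
        fit = fit_rate([10.0], [20.0])  # embryo above egg -> r < 0, clipped
        assert fit["r"] == 0.0 and fit["at_boundary"]


class TestSharedRate:
    def test_identical_species_match_per_species_fit(self):
        data = {sp: ([10.0, 9.0], [4.0, 5.0]) for sp in ("a", "b", "c", "d")}
        shared = fit_shared_rate(data)
        single = fit_rate([10.0, 9.0], [4.0, 5.0])
        assert shared["r"] == pytest.approx(single["r"])

    def test_two_species_pooled_closed_form(self):
        data = {"a": ([10.0], [8.0]), "b": ([10.0], [2.0])}  # rates 0.2 and 0.8
        shared = fit_shared_rate(data)
        assert shared["r"] == pytest.approx(0.5)

    def test_pooled_objective_identity(self, rng):
        data = {
            sp: (rng.lognormal(2, 0.3, 3), rng.lognormal(1.5, 0.3, 3))
            for sp in ("a", "b", "c", "d")
        }
        shared = fit_shared_rate(data)
        a = 1.0 - shared["r"]
        total = 0.0
        for egg, embryo in data.values():
            total += sum((m - a * e) ** 2 for e in egg for m in embryo)
        assert shared["rss"] == pytest.approx(total)


class TestLRT:
    @staticmethod
    def _gene_data(rng, n_genes=30, specific=False):
        sim = simulate_maternal_decay(
            n_genes=n_genes,
            n_egg=1,
            noise_model="additive",
            prop_specific=1.0 if specific else 0.0,
            seed=int(rng.integers(1_000_000)),
        )
        return decay_gene_data(sim), decay_noise_estimate(sim), sim

    def test_identical_rates_not_significant(self):
        data = {f"g{i}": {sp: ([10.0], [5.0, 5.1, 4.9]) for sp in "abcd"} for i in range(12)}
        fits = degradation_lrt(data, sigma2=1.0)
        assert (fits["lrt_stat"] < 1.0).all()
        assert not fits["species_specific"].any()

    def test_nested_model_dominance(self, rng):
        data, sigma2, _ = self._gene_data(rng, specific=True)
        fits = degradation_lrt(data, sigma2)
        assert (fits["loglik_specific"] >= fits["loglik_common"] - 1e-9).all()
        assert (fits["lrt_stat"] >= 0).all()

    def test_bh_step_up_hand_example(self):
        # p-vector (0.01, 0.02, 0.03, 0.04) -> all q-values 0.04
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, 0.04)

    def test_flagging_monotone_in_alpha_and_fold(self, rng):
        data, sigma2, _ = self._gene_data(rng, n_genes=60, specific=True)
        loose = degradation_lrt(data, sigma2, DegradationOptions(alpha=0.01, fold_threshold=1.5))
        tight_alpha = degradation_lrt(data, sigma2, DegradationOptions(alpha=0.0001, fold_threshold=1.5))
        tight_fold = degradation_lrt(data, sigma2, DegradationOptions(alpha=0.01, fold_threshold=4.0))
        assert set(tight_alpha.index[tight_alpha["species_specific"]]) <= set(
            loose.index[loose["species_specific"]]
        )
        assert set(tight_fold.index[tight_fold["species_specific"]]) <= set(
            loose.index[loose["species_specific"]]
        )

    def test_missing_species_rejected(self):
        data = {"g1": {"a": ([1.0], [1.0])}, "g2": {"a": ([1.0], [1.0]), "b": ([1.0], [1.0])}}
        with pytest.raises(ValueError, match="missing species"):
            degradation_lrt(data, sigma2=1.0)


class TestRateVsExpression:
    def test_matches_rank_correlation_oracle(self, rng):
        sim = simulate_maternal_decay(
            n_genes=120, n_egg=1, noise_model="additive", prop_specific=0.8, seed=9
        )
        fits = degradation_lrt(decay_gene_data(sim), decay_noise_estimate(sim))
        truth = sim["truth"]
        emb = np.log10(
            pd.DataFrame({sp: truth[f"embryo_level_{sp}"] for sp in sim["species"]}) + 1
        )
        out = rate_vs_expression_divergence(fits, emb)
        from scipy.stats import spearmanr

        flagged = fits[fits["species_specific"]]
        a, b = sim["species"][0], sim["species"][1]
        dr = flagged[f"r_{a}"] - flagged[f"r_{b}"]
        de = emb.loc[flagged.index, a] - emb.loc[flagged.index, b]
        expected = spearmanr(dr, de)[0]
        row = out[(out["species_a"] == a) & (out["species_b"] == b)].iloc[0]
        assert row["rho_embryo"] == pytest.approx(expected)

    def test_too_few_flagged_genes_gives_empty(self):
        fits = pd.DataFrame(
            {"species_specific": [False] * 5, "r_a": 0.5, "r_b": 0.5},
            index=[f"g{i}" for i in range(5)],
        )
        out = rate_vs_expression_divergence(fits, pd.DataFrame())
        assert out.empty
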