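import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blastocomp import (
    ExpressionMatrix,
    attribute_bias_direction,
    chromosome_enrichment,
    compute_sex_ratio,
    cross_species_sets,
    rank_and_classify,
    sex_bias_analysis,
    top_k_distribution,
)


def _one_species_matrix(female, male, species="sp1"):
    female = np.asarray(female, dtype=float)
    male = np.asarray(male, dtype=float)
    genes = [f"g{i}" for i in range(len(female))]
    data = pd.DataFrame(
        {"f1": female, "f2": female, "m1": male, "m2": male}, index=genes
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["f1", "f2", "m1", "m2"],
            "species": species,
            "stage": "embryo",
            "sex": ["female", "female", "male", "male"],
            "replicate": [1, 2, 1, 2],
        }
    )
    return ExpressionMatrix(data), samples


class TestSexRatio:
    def test_fourfold_difference(self):
        m, s = _one_species_matrix([8.0, 4.0, 4.0], [2.0, 4.0, 4.0])
        t = compute_sex_ratio(m, s, "sp1")
        assert t.loc["g0", "log2_ratio"] == pytest.approx(2.0)
        assert t.loc["g1", "log2_ratio"] == pytest.approx(0.0)

    def test_zero_male_mean_not_evaluated(self):
        m, s = _one_species_matrix([4.0, 4.0], [0.0, 4.0])
        t = compute_sex_ratio(m, s, "sp1")
        assert not t.loc["g0", "evaluated"]
        assert np.isnan(t.loc["g0", "log2_ratio"])  # no division performed

    def test_no_male_samples_rejected(self):
        m, s = _one_species_matrix([1.0], [1.0])
        s = s[s["sex"] == "female"]
        with pytest.raises(ValueError, match="male"):
            compute_sex_ratio(m, s, "sp1")


class TestRankAndClassify:
    def test_ten_gene_example(self):
        ratios = pd.Series(np.arange(1.0, 11.0), index=[f"g{i}" for i in range(1, 11)])
        out = rank_and_classify(ratios)
        assert set(out.index[out["bias_class"] == "female"]) == {"g9", "g10"}
        assert set(out.index[out["bias_class"] == "male"]) == {"g1", "g2"}
        assert set(out.index[out["bias_class"] == "unbiased"]) == {"g5", "g6"}

    def test_all_ties_unbiased(self):
        ratios = pd.Series(np.ones(12), index=[f"g{i}" for i in range(12)])
        out = rank_and_classify(ratios)
        assert (out["quantile_rank"] == 0.5).all()
        assert (out["bias_class"] == "unbiased").all()

    def test_matches_sort_oracle(self, rng):
        ratios = pd.Series(rng.normal(size=1000), index=[f"g{i}" for i in range(1000)])
        out = rank_and_classify(ratios, top_q=0.2, bottom_q=0.2, unbiased_window=(0.4, 0.6))
        # independent sort-based oracle (no ties almost surely)
        order = ratios.sort_values().index
        n = len(ratios)
        for pos, gene in enumerate(order, start=1):
            rank = pos / (n + 1)
            if rank >= 0.8:
                expected = "female"
            elif rank <= 0.2:
                expected = "male"
            elif 0.4 <= rank <= 0.6:
                expected = "unbiased"
            else:
                expected = "intermediate"
            assert out.loc[gene, "bias_class"] == expected

    def test_biased_counts_near_quantile(self, rng):
        ratios = pd.Series(rng.normal(size=501), index=[f"g{i}" for i in range(501)])
        out = rank_and_classify(ratios)
        n = len(ratios)
        for cls in ("female", "male"):
            assert abs((out["bias_class"] == cls).sum() - round(0.2 * n)) <= 1

    def test_overlapping_windows_rejected(self):
        ratios = pd.Series(np.arange(20.0))
        with pytest.raises(ValueError, match="overlap"):
            rank_and_classify(ratios, top_q=0.6, bottom_q=0.6)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            rank_and_classify(pd.Series(np.arange(5.0)))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_classification_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    ratios = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
    base = rank_and_classify(ratios)
    for transform in (lambda x: 3 * x + 1, np.exp, lambda x: x**3):
        out = rank_and_classify(transform(ratios))
        assert (out["bias_class"] == base["bias_class"]).all()


def _call_table(classes, ranks=None):
    idx = [f"g{i}" for i in range(len(classes))]
    if ranks is None:
        ranks = {"female": 0.9, "male": 0.1, "unbiased": 0.5, "intermediate": 0.3,
                 "not_evaluated": np.nan}
        ranks = [ranks[c] for c in classes]
    return pd.DataFrame({"bias_class": classes, "quantile_rank": ranks}, index=idx)


class TestCrossSpeciesSets:
    def test_conserved_and_specific_membership(self):
        tables = {
            "sp1": _call_table(["female", "female", "female", "unbiased"]),
            "sp2": _call_table(["female", "unbiased", "intermediate", "unbiased"]),
            "sp3": _call_table(["female", "unbiased", "unbiased", "unbiased"]),
            "sp4": _call_table(["female", "unbiased", "unbiased", "unbiased"]),
        }
        sets = cross_species_sets(tables)
        assert "g0" in sets["biased_all_female"]
        assert "g1" in sets["specific"]["sp1"]["female"]
        # intermediate in one species -> in no set
        assert all("g2" not in s for s in [sets["biased_all_female"],
                                           sets["specific"]["sp1"]["female"]])

    def test_not_evaluated_excluded_everywhere(self):
        tables = {
            "sp1": _call_table(["female", "female"]),
            "sp2": _call_table(["female", "not_evaluated"]),
            "sp3": _call_table(["female", "female"]),
            "sp4": _call_table(["female", "female"]),
        }
        sets = cross_species_sets(tables)
        assert sets["biased_all_female"] == {"g0"}

    def test_nonbiased_sides_use_sixty_percent_rule(self):
        tables = {
            sp: _call_table(
                ["unbiased", "intermediate"], ranks=[0.5, 0.35]
            )
            for sp in ("sp1", "sp2", "sp3", "sp4")
        }
        sets = cross_species_sets(tables)
        # both genes ranked <= 0.6 everywhere: never female-biased
        assert sets["nonbiased_all_female_side"] == {"g0", "g1"}
        # g1 at rank 0.35 is below 0.4: not in the never-male-biased set
        assert sets["nonbiased_all_male_side"] == {"g0"}


class TestChromosomeEnrichment:
    def test_proportional_set_null(self):
        elements = pd.Series(
            ["A"] * 40 + ["B"] * 60, index=[f"g{i}" for i in range(100)]
        )
        gene_set = [f"g{i}" for i in range(0, 20)] + [f"g{i}" for i in range(40, 70)]
        out = chromosome_enrichment(gene_set, elements)  # 20/30 vs 40/60
        row = out[out["muller_element"] == "global"].iloc[0]
        assert row["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_value"] == pytest.approx(1.0)

    def test_two_element_closed_form(self):
        elements = pd.Series(
            ["A"] * 50 + ["B"] * 50, index=[f"g{i}" for i in range(100)]
        )
        gene_set = [f"g{i}" for i in range(20)] + [f"g{i}" for i in range(50, 60)]
        out = chromosome_enrichment(gene_set, elements)
        row = out[out["muller_element"] == "global"].iloc[0]
        assert row["chi2"] == pytest.approx(10.0 / 3.0)
        a = out[out["muller_element"] == "A"].iloc[0]
        assert a["expected"] == pytest.approx(15.0)

    def test_expected_counts_sum_to_set_size(self, rng):
        elements = pd.Series(
            rng.choice(list("ABCDE"), size=300), index=[f"g{i}" for i in range(300)]
        )
        gene_set = list(rng.choice(elements.index, size=80, replace=False))
        out = chromosome_enrichment(gene_set, elements)
        per_element = out[out["muller_element"] != "global"]
        assert per_element["expected"].sum() == pytest.approx(len(gene_set))

    def test_tiny_element_excluded(self):
        elements = pd.Series(
            ["A"] * 50 + ["B"] * 50 + ["F"] * 5, index=[f"g{i}" for i in range(105)]
        )
        out = chromosome_enrichment([f"g{i}" for i in range(30)], elements)
        assert "F" not in set(out["muller_element"])

    def test_gene_outside_universe_rejected(self):
        elements = pd.Series(["A"] * 30, index=[f"g{i}" for i in range(30)])
        with pytest.raises(ValueError, match="outside"):
            chromosome_enrichment(["nope"], elements)


class TestTopK:
    @staticmethod
    def _table(ratios, evaluated=None):
        idx = [f"g{i}" for i in range(len(ratios))]
        return pd.DataFrame(
            {
                "log2_ratio": ratios,
                "evaluated": evaluated if evaluated is not None else [True] * len(ratios),
            },
            index=idx,
        )

    def test_k_equals_gene_count_recovers_full_proportions(self, rng):
        ratios = rng.normal(size=60)
        elements = pd.Series(rng.choice(["A", "B"], 60), index=[f"g{i}" for i in range(60)])
        out = top_k_distribution(self._table(ratios), elements, k=60)
        for _, row in out.iterrows():
            on = elements == row["muller_element"]
            assert row["n_female"] == (ratios[on.to_numpy()] > 0).sum()

    def test_constructed_x_dominance(self):
        ratios = np.r_[np.full(10, 5.0), np.full(40, 0.1)]
        elements = pd.Series(
            ["A"] * 10 + ["B"] * 40, index=[f"g{i}" for i in range(50)]
        )
        out = top_k_distribution(self._table(ratios), elements, k=10)
        a = out[out["muller_element"] == "A"].iloc[0]
        assert a["prop_female"] == pytest.approx(1.0)

    def test_matches_sort_oracle(self, rng):
        ratios = rng.normal(size=100)
        elements = pd.Series(rng.choice(list("ABC"), 100), index=[f"g{i}" for i in range(100)])
        out = top_k_distribution(self._table(ratios), elements, k=30)
        top_idx = np.argsort(-np.abs(ratios), kind="stable")[:30]
        for el in "ABC":
            on_top = [i for i in top_idx if elements.iloc[i] == el]
            row = out[out["muller_element"] == el].iloc[0]
            assert row["n_top"] == len(on_top)

    def test_k_too_large_rejected(self, rng):
        ratios = rng.normal(size=20)
        elements = pd.Series(["A"] * 20, index=[f"g{i}" for i in range(20)])
        with pytest.raises(ValueError, match="exceeds"):
            top_k_distribution(self._table(ratios), elements, k=21)


class TestAttribution:
    @staticmethod
    def _tables(f_sp1, m_sp1, f_sp2, m_sp2):
        idx = [f"g{i}" for i in range(len(f_sp1))]
        t1 = pd.DataFrame({"female_mean": f_sp1, "male_mean": m_sp1}, index=idx)
        t2 = pd.DataFrame({"female_mean": f_sp2, "male_mean": m_sp2}, index=idx)
        return {"sp1": t1, "sp2": t2}

    def test_all_male_driven_binomial(self):
        n = 8
        tables = self._tables([2.0] * n, [1.0] * n, [2.0] * n, [2.0] * n)
        sets = {"sp1": {"female": set(tables["sp1"].index)}}
        out = attribute_bias_direction(sets, tables)
        row = out.iloc[0]
        assert row["n_male_driven"] == n
        assert row["binomial_p"] == pytest.approx(2 * 0.5**8)

    def test_even_split_p_one(self):
        f1 = [4.0] * 4 + [2.0] * 4
        m1 = [1.0] * 8
        f2 = [2.0] * 8
        m2 = [1.0] * 4 + [2.0] * 4
        tables = self._tables(f1, m1, f2, m2)
        sets = {"sp1": {"female": set(tables["sp1"].index)}}
        out = attribute_bias_direction(sets, tables)
        row = out.iloc[0]
        assert row["n_female_driven"] == 4 and row["n_male_driven"] == 4
        assert row["binomial_p"] == pytest.approx(1.0)

    def test_empty_set_no_rows(self):
        tables = self._tables([1.0], [1.0], [1.0], [1.0])
        out = attribute_bias_direction({"sp1": {"female": set()}}, tables)
        assert out.empty


class TestFullStage:
    def test_class_partition_covers_all_genes(self, small_prepared):
        res = sex_bias_analysis(
            small_prepared["normalized"],
            small_prepared["bundle"].samples,
            small_prepared["bundle"].annotation,
        )
        for table in res.tables.values():
            counts = table["bias_class"].value_counts()
            assert counts.sum() == len(table)
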