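"""Rank-based sex-bias classification and chromosomal enrichment.

Per species, each gene's female:male ratio (computed on non-log, normalized
levels) is converted to a fractional rank; genes in the top ``top_q`` of the
ranking are called female-biased, those in the bottom ``bottom_q``
male-biased, and those inside a central quantile window unbiased. Because the
calls are rank-based they are invariant under any strictly monotone transform
of the ratios. Genes whose replicate-mean level falls below an expression
floor in either sex of any species are not evaluated (low-abundance
transcripts produce unstable ratios). Cross-species set operations,
chi-squared chromosomal enrichment against a gene-content expectation, the
top-|k| most-biased distribution, and a sign-test attribution of
lineage-specific bias to a female increase versus a male decrease complete
the stage.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, SexBiasOptions
from .normalize import condition_means

logger = logging.getLogger(__name__)

BIAS_CLASSES = ("female", "male", "unbiased", "intermediate", "not_evaluated")


def sex_means(matrix, samples: pd.DataFrame, species: str) -> pd.DataFrame:
    """Replicate-mean female and male embryo levels for one species."""
    means = condition_means(matrix, samples)
    for cond in ("female", "male"):
        if (species, cond) not in means.columns:
            raise ValueError(f"no {cond} embryo samples for species {species!r}")
    return pd.DataFrame(
        {"female_mean": means[(species, "female")], "male_mean": means[(species, "male")]}
    )


def evaluate_floor(
    matrix: ExpressionMatrix, samples: pd.DataFrame, floor_log2: float = 0.33
) -> pd.Series:
    """Boolean mask: both sex means exceed the expression floor in every species.

    The floor is expressed on a log2 scale; a gene is evaluated only if its
    replicate-mean FPKM is above ``2**floor_log2`` for females and males in
    all species, which keeps ratios away from the unstable low-abundance
    regime. No ratio is computed for genes failing the floor.
    """
    if matrix.transform != "raw":
        raise ValueError("sex ratios are computed on non-log transformed levels")
    floor = 2.0**floor_log2
    means = condition_means(matrix, samples)
    embryo = means.loc[:, means.columns.get_level_values("condition").isin(["female", "male"])]
    return (embryo > floor).all(axis=1)


def compute_sex_ratio(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    species: str,
    evaluated: pd.Series | None = None,
    floor_log2: float = 0.33,
) -> pd.DataFrame:
    """Per-gene log2(female/male) for one species.

    Returns a frame with ``female_mean``, ``male_mean``, ``log2_ratio`` and
    ``evaluated``; the ratio is NaN (never computed) for non-evaluated genes.
    If ``evaluated`` is not supplied the floor is applied to this species
    alone; the pipeline passes the all-species mask from
    :func:`evaluate_floor`.
    """
    table = sex_means(matrix, samples, species)
    if evaluated is None:
        floor = 2.0**floor_log2
        evaluated = (table["female_mean"] > floor) & (table["male_mean"] > floor)
    table["evaluated"] = evaluated.reindex(table.index).fillna(False).astype(bool)
    ratio = np.full(len(table), np.nan)
    mask = table["evaluated"].to_numpy()
    ratio[mask] = np.log2(
        table.loc[mask, "female_mean"].to_numpy() / table.loc[mask, "male_mean"].to_numpy()
    )
    table["log2_ratio"] = ratio
    return table


def rank_and_classify(
    ratios: pd.Series,
    top_q: float = 0.20,
    bottom_q: float = 0.20,
    unbiased_window: tuple[float, float] = (0.40, 0.60),
) -> pd.DataFrame:
    """Fractional ranks and bias classes for a vector of evaluated ratios.

    Quantile rank is average-rank / (n + 1), strictly inside (0, 1); the
    female call is rank >= 1 - top_q, male is rank <= bottom_q, unbiased is
    rank inside the window, anything else is intermediate.
    """
    if top_q + bottom_q >= 1:
        raise ValueError("top_q + bottom_q must be < 1 (windows overlap)")
    ratios = ratios.dropna()
    n = len(ratios)
    if n < 10:
        raise ValueError(f"need at least 10 evaluated genes, got {n}")
    rank = ratios.rank(method="average") / (n + 1)
    lo, hi = unbiased_window
    bias = np.where(
        rank >= 1 - top_q,
        "female",
        np.where(rank <= bottom_q, "male", np.where((rank >= lo) & (rank <= hi), "unbiased", "intermediate")),
    )
    return pd.DataFrame({"quantile_rank": rank, "bias_class": bias}, index=ratios.index)


def sex_bias_table(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    species: str,
    evaluated: pd.Series,
    options: SexBiasOptions,
) -> pd.DataFrame:
    """Full per-species record: means, ratio, rank and class for every gene."""
    table = compute_sex_ratio(matrix, samples, species, evaluated=evaluated)
    ranked = rank_and_classify(
        table["log2_ratio"],
        top_q=options.top_q,
        bottom_q=options.bottom_q,
        unbiased_window=options.unbiased_window,
    )
    table["quantile_rank"] = ranked["quantile_rank"].reindex(table.index)
    table["bias_class"] = ranked["bias_class"].reindex(table.index).fillna("not_evaluated")
    table["species"] = species
    return table


def cross_species_sets(tables: dict[str, pd.DataFrame]) -> dict:
    """Cross-species bias sets from per-species classification tables.

    Returns the four-species conserved sets (biased in all four; never
    female-/male-biased in any, i.e. ranked in the bottom/top 60%) and the
    lineage-specific sets (biased in exactly one species, unbiased — inside
    the central window — in the other three). Genes not evaluated in any
    species are excluded from every set.
    """
    species = sorted(tables)
    if len(species) < 2:
        raise ValueError("need tables for at least two species")
    index = tables[species[0]].index
    for sp in species[1:]:
        if not tables[sp].index.equals(index):
            raise ValueError("species tables must cover the same orthogroups")
    cls = pd.DataFrame({sp: tables[sp]["bias_class"] for sp in species})
    rank = pd.DataFrame({sp: tables[sp]["quantile_rank"] for sp in species})
    ok = (cls != "not_evaluated").all(axis=1)

    sets = {
        "biased_all_female": set(index[ok & (cls == "female").all(axis=1)]),
        "biased_all_male": set(index[ok & (cls == "male").all(axis=1)]),
        # never female-biased: ranked in the bottom 60% in every species
        "nonbiased_all_female_side": set(index[ok & (rank <= 0.60).all(axis=1)]),
        # never male-biased: ranked in the top 60% in every species
        "nonbiased_all_male_side": set(index[ok & (rank >= 0.40).all(axis=1)]),
        "specific": {},
    }
    for sp in species:
        others = [t for t in species if t != sp]
        unb_others = (cls[others] == "unbiased").all(axis=1)
        sets["specific"][sp] = {
            sex: set(index[ok & (cls[sp] == sex) & unb_others]) for sex in ("female", "male")
        }
    return sets


def chromosome_enrichment(
    gene_set,
    elements: pd.Series,
    min_element_genes: int = 20,
) -> pd.DataFrame:
    """Chi-squared test of a gene set's chromosomal distribution.

    ``elements`` maps every gene of the evaluated universe to its Müller
    element; expected counts are proportional to element gene content.
    Elements with fewer than ``min_element_genes`` genes in the universe
    (the tiny Müller F dot chromosome) are excluded for chi-squared validity.
    Rows: one per element with a 1-df element-vs-rest test, plus a ``global``
    row with the (k-1)-df omnibus test.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    stray = gene_set - set(elements.index)
    if stray:
        raise ValueError(f"genes outside the annotated universe: {sorted(stray)[:5]}")
    sizes = elements.value_counts()
    small = sizes[sizes < min_element_genes].index.tolist()
    if small:
        logger.info("excluding element(s) %s with < %d genes from enrichment", small, min_element_genes)
    keep_elements = sorted(sizes[sizes >= min_element_genes].index)
    universe = elements[elements.isin(keep_elements)]
    members = universe.loc[universe.index.isin(gene_set)]
    n, total = len(members), len(universe)
    if n == 0:
        raise ValueError("gene set has no members on testable elements")
    rows = []
    observed = members.value_counts().reindex(keep_elements, fill_value=0)
    expected = sizes.loc[keep_elements] / total * n
    for element in keep_elements:
        obs, exp = observed[element], expected[element]
        chi2 = (obs - exp) ** 2 / exp + ((n - obs) - (n - exp)) ** 2 / (n - exp)
        rows.append(
            {
                "muller_element": element,
                "observed": int(obs),
                "expected": float(exp),
                "chi2": float(chi2),
                "df": 1,
                "p_value": float(stats.chi2.sf(chi2, 1)),
            }
        )
    chi2_global = float(((observed - expected) ** 2 / expected).sum())
    df_global = len(keep_elements) - 1
    rows.append(
        {
            "muller_element": "global",
            "observed": int(n),
            "expected": float(n),
            "chi2": chi2_global,
            "df": df_global,
            "p_value": float(stats.chi2.sf(chi2_global, df_global)),
        }
    )
    return pd.DataFrame(rows)


def top_k_distribution(
    ratio_table: pd.DataFrame, elements: pd.Series, k: int = 200
) -> pd.DataFrame:
    """Chromosomal distribution of the top-|k| absolute-ratio genes.

    Genes are ordered by decreasing |log2 ratio| (ties at the k-th position
    broken by gene id order); per element the proportion of its evaluated
    genes that land in the top k is reported, split by sign of the bias.
    """
    evaluated = ratio_table.loc[ratio_table["evaluated"].astype(bool), "log2_ratio"].dropna()
    if k > len(evaluated):
        raise ValueError(f"k={k} exceeds {len(evaluated)} evaluated genes")
    order = (
        pd.DataFrame({"abs_ratio": evaluated.abs(), "gene": evaluated.index})
        .sort_values(["abs_ratio", "gene"], ascending=[False, True], kind="mergesort")
        .index[:k]
    )
    top = evaluated.loc[order]
    el = elements.reindex(evaluated.index)
    rows = []
    for element in sorted(el.dropna().unique()):
        genes_on = el.index[el == element]
        on_top = top.loc[top.index.intersection(genes_on)]
        n_el = len(genes_on)
        rows.append(
            {
                "muller_element": element,
                "n_genes": n_el,
                "n_top": len(on_top),
                "n_female": int((on_top > 0).sum()),
                "n_male": int((on_top < 0).sum()),
                "prop_female": float((on_top > 0).sum() / n_el),
                "prop_male": float((on_top < 0).sum() / n_el),
            }
        )
    return pd.DataFrame(rows)


def attribute_bias_direction(
    specific_sets: dict, tables: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Attribute lineage-specific bias to a female or male expression change.

    For a gene biased only in species ``s``, compared against species ``t``,
    the question is whether the bias arose by an expression increase in the
    favored sex or a decrease in the other sex. A female-biased gene is
    called male-driven when its male level is lower in ``s`` than in ``t``
    (the bias involves a male decrease) and female-driven otherwise (the
    bias requires a female increase); male-biased genes symmetrically
    (female-driven when the female level decreased). A two-sided exact
    binomial test against a 50/50 split is reported per (s, sex, t)
    comparison; empty sets yield no row.
    """
    rows = []
    species = sorted(tables)
    for sp in species:
        for sex in ("female", "male"):
            genes = sorted(specific_sets.get(sp, {}).get(sex, set()))
            if not genes:
                continue
            for other in species:
                if other == sp:
                    continue
                d_f = np.log2(
                    tables[sp].loc[genes, "female_mean"].to_numpy()
                    / tables[other].loc[genes, "female_mean"].to_numpy()
                )
                d_m = np.log2(
                    tables[sp].loc[genes, "male_mean"].to_numpy()
                    / tables[other].loc[genes, "male_mean"].to_numpy()
                )
                if sex == "female":
                    female_driven = d_m >= 0  # no male decrease: bias needs a female increase
                else:
                    female_driven = d_f < 0  # female decrease created the male bias
                n_f = int(female_driven.sum())
                n_m = len(genes) - n_f
                p = stats.binomtest(n_f, len(genes), 0.5).pvalue
                rows.append(
                    {
                        "species": sp,
                        "sex": sex,
                        "versus": other,
                        "n_genes": len(genes),
                        "n_female_driven": n_f,
                        "n_male_driven": n_m,
                        "binomial_p": float(p),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "sex",
            "versus",
            "n_genes",
            "n_female_driven",
            "n_male_driven",
            "binomial_p",
        ],
    )


@dataclass
class SexBiasResults:
    tables: dict[str, pd.DataFrame]
    sets: dict
    enrichment: pd.DataFrame
    top_k: dict[str, pd.DataFrame]
    attribution: pd.DataFrame


def sex_bias_analysis(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    annotation: pd.DataFrame,
    options: SexBiasOptions | None = None,
) -> SexBiasResults:
    """Run the full sex-bias stage on a normalized raw-scale matrix."""
    options = options or SexBiasOptions()
    elements = annotation.set_index("orthogroup_id")["muller_element"]
    evaluated = evaluate_floor(matrix, samples, options.floor_log2)
    species = sorted(samples.loc[samples["stage"] == "embryo", "species"].unique())
    tables = {
        sp: sex_bias_table(matrix, samples, sp, evaluated, options) for sp in species
    }
    sets = cross_species_sets(tables)
    universe = elements.reindex(matrix.gene_ids[evaluated.reindex(matrix.gene_ids).fillna(False)]).dropna()
    enrich_rows = []
    for name in ("biased_all_female", "biased_all_male", "nonbiased_all_female_side", "nonbiased_all_male_side"):
        if sets[name]:
            table = chromosome_enrichment(sets[name], universe, options.min_element_genes)
            table.insert(0, "gene_set", name)
            enrich_rows.append(table)
    for sp in species:
        for sex in ("female", "male"):
            genes = sets["specific"][sp][sex]
            if genes:
                table = chromosome_enrichment(genes, universe, options.min_element_genes)
                table.insert(0, "gene_set", f"specific_{sp}_{sex}")
                enrich_rows.append(table)
    enrichment = pd.concat(enrich_rows, ignore_index=True) if enrich_rows else pd.DataFrame()
    top_k = {
        sp: top_k_distribution(tables[sp], elements, k=min(options.top_k, int(evaluated.sum())))
        for sp in species
    }
    attribution = attribute_bias_direction(sets["specific"], tables)
    return SexBiasResults(tables, sets, enrichment, top_k, attribution)
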