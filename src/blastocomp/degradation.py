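"""Maternal mRNA decay kinetics and species-specific rate detection.

For genes whose blastoderm transcripts are purely maternal, the embryo level
is the deposited egg level times the surviving fraction:

    mRNA[embryo] = mRNA[egg] * (1 - r) + epsilon

with r the egg-to-blastoderm degraded fraction and epsilon Gaussian with a
plug-in variance (the average within-condition replicate variance of the
dataset, on non-log values). Per gene, a species-common rate and four
species-specific rates are fitted by least squares over all egg x embryo
replicate pairings; the nested models are compared by a likelihood-ratio
test (chi-squared, 4 df by convention although the models differ by 3
parameters), Benjamini-Hochberg corrected, and the species-specific calls
are further required to show a > 2-fold rate difference between some pair of
species.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import DegradationOptions, ExpressionMatrix

logger = logging.getLogger(__name__)


def estimate_noise(
    matrix, samples: pd.DataFrame, genes=None, min_replicates: int = 2
) -> float:
    """Plug-in residual variance: mean within-condition replicate variance.

    Conditions are (species, stage, sex) sample groups with at least
    ``min_replicates`` replicates; the variance (ddof=1) of non-log values is
    averaged over genes and conditions. Zero variance (noiseless input) is
    degenerate for the Gaussian likelihood and raises.
    """
    data = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    if isinstance(matrix, ExpressionMatrix) and matrix.transform != "raw":
        raise ValueError("noise is estimated on non-log values")
    if genes is not None:
        data = data.loc[list(genes)]
    variances = []
    for _, group in samples.groupby(["species", "stage", "sex"], sort=True):
        ids = group["sample_id"].tolist()
        if len(ids) < min_replicates:
            continue
        variances.append(data[ids].var(axis=1, ddof=1).to_numpy())
    if not variances:
        raise ValueError("no condition has enough replicates to estimate noise")
    sigma2 = float(np.mean(np.concatenate(variances)))
    if sigma2 <= 0:
        raise ValueError("estimated noise variance is zero; set a floor explicitly")
    return sigma2


def _pair_sums(egg: np.ndarray, embryo: np.ndarray, pairing: str) -> tuple[float, float, float, int]:
    """(S_ee, S_em, S_mm, n_pairs) for the pairing objective.

    With ``pairing="pairs"`` the objective sums over every (egg replicate,
    embryo replicate) combination; with ``"mean_egg"`` each embryo replicate
    is paired with the egg replicate mean.
    """
    egg = np.asarray(egg, dtype=float)
    embryo = np.asarray(embryo, dtype=float)
    if egg.size == 0 or embryo.size == 0:
        raise ValueError("need at least one egg and one embryo replicate")
    if pairing == "mean_egg":
        egg = np.array([egg.mean()])
    n_pairs = egg.size * embryo.size
    s_ee = embryo.size * float(np.sum(egg**2))
    s_em = float(np.sum(egg) * np.sum(embryo))
    s_mm = egg.size * float(np.sum(embryo**2))
    return s_ee, s_em, s_mm, n_pairs


def fit_rate(
    egg, embryo, bounds: tuple[float, float] = (0.0, 1.0), pairing: str = "pairs"
) -> dict:
    """Least-squares degradation rate for one gene in one species.

    The inner solution is closed-form: with a = 1 - r, the sum of squares
    over pairings is minimized at a* = S_em / S_ee, i.e.
    r* = 1 - S_em / S_ee, clipped to ``bounds``.
    """
    s_ee, s_em, s_mm, n_pairs = _pair_sums(egg, embryo, pairing)
    if s_ee <= 0:
        raise ValueError("all egg values are zero; rate is unidentifiable")
    r = 1.0 - s_em / s_ee
    lo, hi = bounds
    r_clipped = float(np.clip(r, lo, hi))
    a = 1.0 - r_clipped
    rss = s_mm - 2.0 * a * s_em + a**2 * s_ee
    return {
        "r": r_clipped,
        "rss": max(float(rss), 0.0),
        "n_pairs": n_pairs,
        "at_boundary": bool(r != r_clipped or r_clipped in (lo, hi)),
    }


def fit_shared_rate(
    per_species: dict[str, tuple[np.ndarray, np.ndarray]],
    bounds: tuple[float, float] = (0.0, 1.0),
    pairing: str = "pairs",
) -> dict:
    """Single rate minimizing the pooled pairing objective across species."""
    if not per_species:
        raise ValueError("no species data supplied")
    tot_ee = tot_em = tot_mm = 0.0
    n_pairs = 0
    for species, (egg, embryo) in per_species.items():
        s_ee, s_em, s_mm, n = _pair_sums(egg, embryo, pairing)
        tot_ee += s_ee
        tot_em += s_em
        tot_mm += s_mm
        n_pairs += n
    if tot_ee <= 0:
        raise ValueError("all egg values are zero; rate is unidentifiable")
    r = 1.0 - tot_em / tot_ee
    lo, hi = bounds
    r_clipped = float(np.clip(r, lo, hi))
    a = 1.0 - r_clipped
    rss = tot_mm - 2.0 * a * tot_em + a**2 * tot_ee
    return {"r": r_clipped, "rss": max(float(rss), 0.0), "n_pairs": n_pairs}


def degradation_lrt(
    gene_data: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]],
    sigma2: float,
    options: DegradationOptions | None = None,
) -> pd.DataFrame:
    """Fit both nested models per gene and flag species-specific rates.

    ``gene_data`` maps gene -> species -> (egg replicates, embryo replicates)
    on non-log values. Log-likelihoods use the shared plug-in ``sigma2``;
    the LRT statistic 2*(ll_specific - ll_common) = (RSS_common -
    RSS_specific)/sigma2 is referred to a chi-squared with ``options.df``
    degrees of freedom, BH-corrected across genes. A gene is flagged
    species-specific when q < alpha and the fitted rates (floored at
    ``rate_floor``) differ more than ``fold_threshold``-fold between some
    species pair.
    """
    options = options or DegradationOptions()
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    species = sorted({sp for data in gene_data.values() for sp in data})
    rows = []
    for gene, data in gene_data.items():
        missing = set(species) - set(data)
        if missing:
            raise ValueError(f"gene {gene!r} missing species {sorted(missing)}")
        shared = fit_shared_rate(data, bounds=options.rate_bounds, pairing=options.pairing)
        rss_specific = 0.0
        r_by_species = {}
        boundary = False
        for sp in species:
            fit = fit_rate(*data[sp], bounds=options.rate_bounds, pairing=options.pairing)
            rss_specific += fit["rss"]
            r_by_species[sp] = fit["r"]
            boundary |= fit["at_boundary"]
        n_pairs = shared["n_pairs"]
        ll_const = -0.5 * n_pairs * np.log(2.0 * np.pi * sigma2)
        ll_common = ll_const - shared["rss"] / (2.0 * sigma2)
        ll_specific = ll_const - rss_specific / (2.0 * sigma2)
        lrt = max(2.0 * (ll_specific - ll_common), 0.0)
        floored = np.maximum(list(r_by_species.values()), options.rate_floor)
        fold = float(floored.max() / floored.min())
        rows.append(
            {
                "orthogroup_id": gene,
                "r_common": shared["r"],
                **{f"r_{sp}": r_by_species[sp] for sp in species},
                "loglik_common": ll_common,
                "loglik_specific": ll_specific,
                "lrt_stat": lrt,
                "fold_range": fold,
                "at_boundary": boundary,
            }
        )
    fits = pd.DataFrame(rows).set_index("orthogroup_id")
    fits["p_value"] = stats.chi2.sf(fits["lrt_stat"], options.df)
    fits["q_value"] = multipletests(fits["p_value"], method="fdr_bh")[1]
    fits["species_specific"] = (fits["q_value"] < options.alpha) & (
        fits["fold_range"] > options.fold_threshold
    )
    return fits


class MaternalDecayModel(BaseEstimator):
    """Estimator wrapper around the decay fit for a matrix + sample sheet.

    ``fit`` restricts the raw matrix to the supplied (conserved-maternal)
    gene set, estimates the plug-in noise variance, fits both nested rate
    models per gene and stores the result table in ``fits_``.
    """

    def __init__(
        self,
        rate_bounds: tuple[float, float] = (0.0, 1.0),
        df: int = 4,
        alpha: float = 0.001,
        fold_threshold: float = 2.0,
        rate_floor: float = 0.01,
        pairing: str = "pairs",
    ):
        self.rate_bounds = rate_bounds
        self.df = df
        self.alpha = alpha
        self.fold_threshold = fold_threshold
        self.rate_floor = rate_floor
        self.pairing = pairing

    def _options(self) -> DegradationOptions:
        return DegradationOptions(
            rate_bounds=tuple(self.rate_bounds),
            df=self.df,
            alpha=self.alpha,
            fold_threshold=self.fold_threshold,
            rate_floor=self.rate_floor,
            pairing=self.pairing,
        )

    def fit(self, matrix: ExpressionMatrix, samples: pd.DataFrame, genes=None):
        if matrix.transform != "raw":
            raise ValueError("decay rates are fitted on non-log values")
        genes = list(genes) if genes is not None else list(matrix.gene_ids)
        data = matrix.data.loc[genes]
        self.sigma2_ = estimate_noise(data, samples)
        species = sorted(samples["species"].unique())
        egg_ids = {
            sp: samples.loc[
                (samples["species"] == sp) & (samples["stage"] == "egg"), "sample_id"
            ].tolist()
            for sp in species
        }
        embryo_ids = {
            sp: samples.loc[
                (samples["species"] == sp) & (samples["stage"] == "embryo"), "sample_id"
            ].tolist()
            for sp in species
        }
        for sp in species:
            if not egg_ids[sp] or not embryo_ids[sp]:
                raise ValueError(f"species {sp!r} lacks egg or embryo samples")
        gene_data = {
            gene: {
                sp: (
                    data.loc[gene, egg_ids[sp]].to_numpy(dtype=float),
                    data.loc[gene, embryo_ids[sp]].to_numpy(dtype=float),
                )
                for sp in species
            }
            for gene in genes
        }
        self.species_ = species
        self.fits_ = degradation_lrt(gene_data, self.sigma2_, self._options())
        return self


def rate_vs_expression_divergence(
    fits: pd.DataFrame,
    log_levels_embryo: pd.DataFrame,
    log_levels_egg: pd.DataFrame | None = None,
    min_genes: int = 10,
) -> pd.DataFrame:
    """Correlate species differences in rate with differences in level.

    For flagged (species-specific) genes and every species pair, Spearman's
    rho between delta r and delta mean log embryo level (and, when egg levels
    are given, delta mean log egg level) is reported per pair plus pooled
    over all pairs. Higher degradation should deplete the embryo (negative
    rho) but not the egg.
    """
    flagged = fits[fits["species_specific"]] if "species_specific" in fits else fits
    if len(flagged) < min_genes:
        logger.warning("only %d flagged genes (< %d); no correlation computed", len(flagged), min_genes)
        return pd.DataFrame()
    species = sorted(c[2:] for c in flagged.columns if c.startswith("r_") and c != "r_common")
    genes = flagged.index.intersection(log_levels_embryo.index)
    rows = []
    pooled = {"dr": [], "d_embryo": [], "d_egg": []}
    for a, b in itertools.combinations(species, 2):
        dr = (flagged.loc[genes, f"r_{a}"] - flagged.loc[genes, f"r_{b}"]).to_numpy()
        d_emb = (log_levels_embryo.loc[genes, a] - log_levels_embryo.loc[genes, b]).to_numpy()
        row = {"species_a": a, "species_b": b, "n_genes": len(genes)}
        row["rho_embryo"] = float(stats.spearmanr(dr, d_emb)[0])
        pooled["dr"].append(dr)
        pooled["d_embryo"].append(d_emb)
        if log_levels_egg is not None:
            d_egg = (log_levels_egg.loc[genes, a] - log_levels_egg.loc[genes, b]).to_numpy()
            row["rho_egg"] = float(stats.spearmanr(dr, d_egg)[0])
            pooled["d_egg"].append(d_egg)
        rows.append(row)
    pooled_row = {"species_a": "all", "species_b": "all", "n_genes": len(genes) * len(rows)}
    dr = np.concatenate(pooled["dr"])
    pooled_row["rho_embryo"] = float(stats.spearmanr(dr, np.concatenate(pooled["d_embryo"]))[0])
    if log_levels_egg is not None:
        pooled_row["rho_egg"] = float(stats.spearmanr(dr, np.concatenate(pooled["d_egg"]))[0])
    rows.append(pooled_row)
    return pd.DataFrame(rows)
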