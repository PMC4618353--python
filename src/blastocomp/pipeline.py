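"""End-to-end orchestration of the analysis stages.

``run_pipeline`` takes a consistent input bundle (raw expression matrix,
sample sheet, annotation, tree, optional reference-species origin labels)
and an :class:`~blastocomp.datatypes.AnalysisConfig`, and produces every
stage's tables plus a manifest of the parameters actually applied. All
randomness flows from ``config.seed``; identical inputs and config give
identical outputs. Stages that require egg samples (origin classification,
maternal decay) are skipped with a logged warning when eggs are absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .datatypes import AnalysisConfig, ExpressionMatrix, muller_map, validate_annotation, validate_samples
from .degradation import MaternalDecayModel, rate_vs_expression_divergence
from .divergence import divergence_analysis
from .normalize import ExpressionNormalizer, condition_means, filter_expressed, log_transform
from .ordination import CorrespondenceAnalysis
from .origin import classify_origin, conserved_maternal_set, origin_conservation, origin_features, train_origin_classifier
from .sexbias import sex_bias_analysis

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    normalized: ExpressionMatrix
    log_matrix: ExpressionMatrix
    expressed_genes: pd.Index
    sexbias: object
    divergence: dict
    ordination: object
    origin_calls: dict | None
    origin_conservation: pd.DataFrame | None
    maternal_set: pd.Index | None
    degradation: pd.DataFrame | None
    rate_correlations: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    annotation: pd.DataFrame,
    tree,
    config: AnalysisConfig | None = None,
    origin_labels: pd.Series | None = None,
    reference_species: str | None = None,
    divergence_B: int | None = None,
) -> PipelineResult:
    config = config or AnalysisConfig()
    species = sorted(samples["species"].unique())
    samples = validate_samples(samples, species=species)
    annotation = validate_annotation(annotation, species=species)
    manifest = {"config": config.to_dict(), "species": species}

    # --- normalization and gene set -----------------------------------
    norm = ExpressionNormalizer(
        method=config.normalization.method,
        anchor_elements=config.normalization.anchor_elements,
        use_all_genes=config.normalization.use_all_genes,
    )
    normalized = norm.fit_transform(matrix, annotation=annotation)
    expressed = filter_expressed(normalized, samples, config.normalization.expression_threshold)
    manifest["n_expressed"] = len(expressed)
    normalized = normalized.subset_genes(expressed)
    log_matrix = log_transform(normalized)
    elements = muller_map(annotation).reindex(expressed)

    # --- sex bias ------------------------------------------------------
    sexbias = sex_bias_analysis(normalized, samples, annotation, config.sexbias)

    # --- divergence per condition -------------------------------------
    B = divergence_B if divergence_B is not None else config.divergence.n_bootstrap
    means = condition_means(log_matrix, samples)
    raw_means = condition_means(normalized, samples)
    divergence = {}
    for condition in ("female", "male", "egg"):
        cols = [c for c in means.columns if c[1] == condition]
        if len(cols) < len(species):
            logger.warning("condition %s missing in some species; divergence skipped", condition)
            continue
        levels = means[cols]
        levels.columns = [c[0] for c in cols]
        raw_lv = raw_means[cols]
        raw_lv.columns = [c[0] for c in cols]
        # restrict to genes detectably expressed in this condition somewhere
        cond_genes = levels.index[
            (raw_lv > config.normalization.expression_threshold).any(axis=1)
        ]
        divergence[condition] = divergence_analysis(
            levels.loc[cond_genes],
            tree,
            elements,
            B=B,
            seed=config.seed,
            anova_log_scale=config.divergence.anova_log_scale,
            support_rule=config.divergence.support_rule,
        )
    manifest["divergence_B"] = B

    # --- ordination ----------------------------------------------------
    ca = CorrespondenceAnalysis().fit(normalized)

    # --- origin + degradation (need eggs) -----------------------------
    origin_calls = conservation = maternal = fits = rate_corr = None
    have_eggs = set(samples.loc[samples["stage"] == "egg", "species"])
    if have_eggs.issuperset(species) and origin_labels is not None:
        reference = reference_species or species[0]
        feats = {sp: origin_features(log_matrix, samples, sp) for sp in species}
        model, report = train_origin_classifier(
            feats[reference],
            origin_labels.reindex(feats[reference].index).dropna(),
            options=config.origin,
            seed=config.seed,
            holdout=True,
        )
        manifest["origin_holdout"] = (
            {"recall": report["recall"], "n_test": report["n_test"]} if report else None
        )
        origin_calls = {
            sp: classify_origin(model, feats[sp], species=sp) for sp in species
        }
        conservation = origin_conservation(origin_calls)
        maternal = conserved_maternal_set(origin_calls)
        manifest["n_conserved_maternal"] = len(maternal)
        if len(maternal):
            decay = MaternalDecayModel(
                rate_bounds=config.degradation.rate_bounds,
                df=config.degradation.df,
                alpha=config.degradation.alpha,
                fold_threshold=config.degradation.fold_threshold,
                rate_floor=config.degradation.rate_floor,
                pairing=config.degradation.pairing,
            ).fit(normalized, samples, genes=maternal)
            fits = decay.fits_
            manifest["noise_sigma2"] = decay.sigma2_
            emb_cols = [c for c in means.columns if c[1] in ("female", "male")]
            embryo_levels = means[emb_cols].T.groupby(level="species").mean().T
            egg_cols = [c for c in means.columns if c[1] == "egg"]
            egg_levels = means[egg_cols]
            egg_levels.columns = [c[0] for c in egg_cols]
            rate_corr = rate_vs_expression_divergence(fits, embryo_levels, egg_levels)
    else:
        if not have_eggs.issuperset(species):
            logger.warning("egg samples missing for some species; origin and degradation stages skipped")
        elif origin_labels is None:
            logger.warning("no reference origin labels supplied; origin and degradation stages skipped")

    return PipelineResult(
        normalized=normalized,
        log_matrix=log_matrix,
        expressed_genes=expressed,
        sexbias=sexbias,
        divergence=divergence,
        ordination=ca,
        origin_calls=origin_calls,
        origin_conservation=conservation,
        maternal_set=maternal,
        degradation=fits,
        rate_correlations=rate_corr,
        manifest=manifest,
    )
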