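"""Between-sample normalization, log transform and the expression filter.

Six schemes are supported: ``none``, ``median``, ``p75``, ``p95`` (percentile
scaling on an anchor gene set, by default genes on the large autosomal Müller
elements B, C and E), ``tmm`` (trimmed mean of M-values) and ``quantile``.
Percentile methods rescale each sample so the chosen percentile of anchor-gene
values is identical across samples (equal to the geometric mean of the
per-sample percentiles, which makes the operation scale-balanced and
idempotent). The analyzed gene set is defined after normalization: a gene is
kept if its replicate-mean FPKM exceeds a threshold (default 1) in at least
one condition (egg, female embryo or male embryo) of at least one species.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import ExpressionMatrix, TRANSFORM_LOG, TRANSFORM_RAW, muller_map

logger = logging.getLogger(__name__)

PERCENTILES = {"median": 50.0, "p75": 75.0, "p95": 95.0}
METHODS = ("none", "median", "p75", "p95", "tmm", "quantile")


def _as_frame(matrix) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, ExpressionMatrix) else matrix


class ExpressionNormalizer(BaseEstimator, TransformerMixin):
    """Between-sample normalizer for raw FPKM matrices.

    Parameters
    ----------
    method : one of ``none``, ``median``, ``p75``, ``p95``, ``tmm``, ``quantile``.
    anchor_elements : Müller elements whose genes anchor the percentile methods.
    use_all_genes : ignore the anchor and use every gene (also the fallback
        when no annotation is supplied).
    tmm_trim_m, tmm_trim_a : total two-sided trim fractions on M and A values.

    Attributes
    ----------
    scale_factors_ : per-sample multiplicative factors (all methods except
        quantile, for which ``reference_distribution_`` is stored instead).
    """

    def __init__(
        self,
        method: str = "p75",
        anchor_elements: Sequence[str] = ("B", "C", "E"),
        use_all_genes: bool = False,
        tmm_trim_m: float = 0.30,
        tmm_trim_a: float = 0.05,
    ):
        self.method = method
        self.anchor_elements = anchor_elements
        self.use_all_genes = use_all_genes
        self.tmm_trim_m = tmm_trim_m
        self.tmm_trim_a = tmm_trim_a

    # ------------------------------------------------------------------
    def _anchor_genes(self, data: pd.DataFrame, annotation: pd.DataFrame | None) -> pd.Index:
        if self.use_all_genes or annotation is None:
            return data.index
        elements = muller_map(annotation)
        anchor = elements[elements.isin(list(self.anchor_elements))].index
        anchor = data.index.intersection(anchor)
        if len(anchor) == 0:
            raise ValueError("anchor element set selects zero genes")
        return anchor

    def fit(self, X, annotation: pd.DataFrame | None = None):
        if self.method not in METHODS:
            raise ValueError(f"unknown normalization method {self.method!r}")
        if isinstance(X, ExpressionMatrix) and X.transform != TRANSFORM_RAW:
            raise ValueError("normalization operates on raw (untransformed) matrices")
        data = _as_frame(X)
        if (data.sum(axis=0) <= 0).any():
            bad = data.columns[data.sum(axis=0) <= 0].tolist()
            raise ValueError(f"all-zero sample(s): {bad}")
        if self.method == "none":
            self.scale_factors_ = pd.Series(1.0, index=data.columns)
        elif self.method in PERCENTILES:
            anchor = self._anchor_genes(data, annotation)
            q = PERCENTILES[self.method]
            per_sample = data.loc[anchor].quantile(q / 100.0, interpolation="linear")
            if (per_sample <= 0).any():
                bad = per_sample.index[per_sample <= 0].tolist()
                raise ValueError(f"anchor percentile is zero for sample(s) {bad}")
            target = float(np.exp(np.log(per_sample).mean()))
            self.scale_factors_ = target / per_sample
            self.anchor_genes_ = anchor
            self.target_percentile_ = target
        elif self.method == "tmm":
            self.scale_factors_ = self._tmm_factors(data)
        elif self.method == "quantile":
            values = np.sort(data.to_numpy(), axis=0)
            self.reference_distribution_ = values.mean(axis=1)
            self.scale_factors_ = None
        self.n_features_in_ = data.shape[0]
        return self

    def transform(self, X) -> ExpressionMatrix:
        data = _as_frame(X)
        if self.method == "quantile":
            ref = self.reference_distribution_
            n = len(ref)
            if data.shape[0] != n:
                raise ValueError("quantile normalization requires the fitted gene set")
            ranks = data.rank(axis=0, method="average").to_numpy()
            out = np.empty_like(data.to_numpy(), dtype=float)
            positions = np.arange(1, n + 1, dtype=float)
            for j in range(data.shape[1]):
                # tied entries receive the mean of reference values at their tied ranks
                out[:, j] = np.interp(ranks[:, j], positions, ref)
            result = pd.DataFrame(out, index=data.index, columns=data.columns)
        else:
            result = data.mul(self.scale_factors_.reindex(data.columns), axis=1)
        return ExpressionMatrix(result, TRANSFORM_RAW)

    def fit_transform(self, X, annotation: pd.DataFrame | None = None, **kw) -> ExpressionMatrix:
        return self.fit(X, annotation=annotation).transform(X)

    # ------------------------------------------------------------------
    def _tmm_factors(self, data: pd.DataFrame) -> pd.Series:
        """Unweighted trimmed mean of M-values against a reference sample."""
        upper_q = data.quantile(0.75)
        ref_sample = (upper_q - upper_q.mean()).abs().idxmin()
        ref = data[ref_sample].to_numpy()
        log_factors = {}
        for sample in data.columns:
            obs = data[sample].to_numpy()
            keep = (obs > 0) & (ref > 0)
            if keep.sum() == 0:
                raise ValueError(f"no genes shared above zero with reference for {sample}")
            m = np.log2(obs[keep] / ref[keep])
            a = 0.5 * np.log2(obs[keep] * ref[keep])
            lo_m, hi_m = np.quantile(m, [self.tmm_trim_m / 2, 1 - self.tmm_trim_m / 2])
            lo_a, hi_a = np.quantile(a, [self.tmm_trim_a / 2, 1 - self.tmm_trim_a / 2])
            trimmed = m[(m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)]
            if trimmed.size == 0:
                trimmed = m
            log_factors[sample] = float(np.mean(trimmed))
        lf = pd.Series(log_factors)
        lf -= lf.mean()  # rescale so factors have geometric mean 1
        return 2.0 ** (-lf)


def normalize(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame | None = None,
    method: str = "p75",
    anchor_elements: Sequence[str] = ("B", "C", "E"),
    use_all_genes: bool = False,
) -> ExpressionMatrix:
    """Functional wrapper over :class:`ExpressionNormalizer`."""
    est = ExpressionNormalizer(
        method=method, anchor_elements=anchor_elements, use_all_genes=use_all_genes
    )
    return est.fit_transform(matrix, annotation=annotation)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Apply ``log10(x + 1)`` to a raw matrix."""
    if matrix.transform != TRANSFORM_RAW:
        raise ValueError("matrix is already log transformed")
    return ExpressionMatrix(np.log10(matrix.data + 1.0), TRANSFORM_LOG)


def condition_means(matrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean levels per (species, condition).

    Conditions are ``egg``, ``female`` (female embryos) and ``male`` (male
    embryos); columns are a (species, condition) MultiIndex.
    """
    data = _as_frame(matrix)
    cond = samples.copy()
    cond["condition"] = np.where(cond["stage"] == "egg", "egg", cond["sex"])
    groups = cond.groupby(["species", "condition"], sort=True)["sample_id"].apply(list)
    out = {}
    for (species, condition), ids in groups.items():
        out[(species, condition)] = data[ids].mean(axis=1)
    means = pd.DataFrame(out)
    means.columns = pd.MultiIndex.from_tuples(means.columns, names=["species", "condition"])
    return means


def filter_expressed(
    matrix: ExpressionMatrix, samples: pd.DataFrame, threshold: float = 1.0
) -> pd.Index:
    """Genes whose replicate-mean normalized FPKM exceeds ``threshold`` in at
    least one condition (egg, female embryo, male embryo) of any species."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if matrix.transform != TRANSFORM_RAW:
        raise ValueError("the expression filter applies before log transformation")
    means = condition_means(matrix, samples)
    keep = (means > threshold).any(axis=1)
    kept = matrix.gene_ids[keep.reindex(matrix.gene_ids).fillna(False)]
    logger.info("expression filter (> %g): kept %d / %d genes", threshold, len(kept), matrix.shape[0])
    return kept
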