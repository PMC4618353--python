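"""Correspondence analysis of egg/embryo expression profiles.

Classical CA on a non-negative genes x samples matrix: the matrix of
relative frequencies is centred by the outer product of its margins,
standardized by the square roots of the margins, and decomposed by SVD.
Eigenvalues (squared singular values) partition the total chi-squared
inertia; sample (column) coordinates are reported in principal scaling.
Supplementary profiles — e.g. pooled-embryo samples that must not influence
the axes — are projected with the transition formula (profile times standard
row coordinates), the standard diagnostic for pooling bias: a pool that is a
mixture of egg and embryo material lands between the egg and embryo clusters
on the dominant axis.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)


class CorrespondenceAnalysis(BaseEstimator):
    """Classical correspondence analysis with supplementary-point projection.

    Parameters
    ----------
    n_components : maximum number of axes kept (default: all with nonzero
        eigenvalue).
    eig_tol : eigenvalues below ``eig_tol * total_inertia`` are dropped.

    Attributes
    ----------
    eigenvalues_ : principal inertias per axis, decreasing.
    explained_inertia_ : eigenvalue / total inertia (sums to 1 given >= 1 axis).
    row_coordinates_, column_coordinates_ : principal coordinates.
    row_ids_, column_ids_ : active rows/columns (zero-sum ones are dropped).
    """

    def __init__(self, n_components: int | None = None, eig_tol: float = 1e-12):
        self.n_components = n_components
        self.eig_tol = eig_tol

    def fit(self, X):
        data = X.data if isinstance(X, ExpressionMatrix) else pd.DataFrame(X)
        values = data.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("correspondence analysis requires a non-negative matrix")
        grand = values.sum()
        if grand <= 0:
            raise ValueError("matrix grand total must be positive")
        row_ok = values.sum(axis=1) > 0
        col_ok = values.sum(axis=0) > 0
        if not row_ok.all():
            warnings.warn(f"dropping {int((~row_ok).sum())} zero-sum rows", stacklevel=2)
        if not col_ok.all():
            warnings.warn(f"dropping {int((~col_ok).sum())} zero-sum columns", stacklevel=2)
        data = data.loc[row_ok, col_ok]
        p = data.to_numpy(dtype=float) / grand
        r = p.sum(axis=1)
        c = p.sum(axis=0)
        s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        u, sv, vt = np.linalg.svd(s, full_matrices=False)
        eig = sv**2
        total = float(eig.sum())
        keep = eig > self.eig_tol * max(total, 1.0)
        u, sv, vt, eig = u[:, keep], sv[keep], vt[keep], eig[keep]
        if self.n_components is not None:
            u, sv, vt, eig = (
                u[:, : self.n_components],
                sv[: self.n_components],
                vt[: self.n_components],
                eig[: self.n_components],
            )
        # deterministic sign: largest-magnitude column loading positive per axis
        v = vt.T
        for k in range(v.shape[1]):
            j = int(np.argmax(np.abs(v[:, k])))
            if v[j, k] < 0:
                v[:, k] *= -1
                u[:, k] *= -1
        self.eigenvalues_ = eig
        self.total_inertia_ = total
        self.explained_inertia_ = eig / total if total > 0 else eig
        self.row_ids_ = data.index
        self.column_ids_ = data.columns
        self.row_weights_ = pd.Series(r, index=data.index)
        self.column_weights_ = pd.Series(c, index=data.columns)
        with np.errstate(divide="ignore", invalid="ignore"):
            row_std = u / np.sqrt(r)[:, None]
        self.row_standard_ = pd.DataFrame(
            row_std, index=data.index, columns=self._axes(len(eig))
        )
        self.row_coordinates_ = self.row_standard_ * sv
        self.column_coordinates_ = pd.DataFrame(
            (v / np.sqrt(c)[:, None]) * sv, index=data.columns, columns=self._axes(len(eig))
        )
        return self

    @staticmethod
    def _axes(k: int) -> list[str]:
        return [f"axis{i + 1}" for i in range(k)]

    def fit_transform(self, X):
        return self.fit(X).column_coordinates_

    def project_supplementary(self, profiles: pd.DataFrame) -> pd.DataFrame:
        """Project supplementary column profiles onto the fitted axes.

        ``profiles`` is genes x new-samples over the active gene set; each
        column is normalized to a profile and multiplied into the standard
        row coordinates (transition formula). Projecting an active sample's
        own profile reproduces its CA coordinates.
        """
        if not hasattr(self, "row_standard_"):
            raise ValueError("fit the analysis before projecting")
        if isinstance(profiles, pd.Series):
            profiles = profiles.to_frame()
        missing = self.row_ids_.difference(profiles.index)
        if len(missing):
            raise ValueError(f"profiles missing {len(missing)} active genes")
        aligned = profiles.reindex(self.row_ids_).to_numpy(dtype=float)
        if (aligned < 0).any():
            raise ValueError("supplementary profiles must be non-negative")
        totals = aligned.sum(axis=0)
        if (totals <= 0).any():
            bad = profiles.columns[totals <= 0].tolist()
            raise ValueError(f"zero-total supplementary profile(s): {bad}")
        prof = aligned / totals
        coords = prof.T @ self.row_standard_.to_numpy()
        return pd.DataFrame(coords, index=profiles.columns, columns=self._axes(coords.shape[1]))


def correspondence_analysis(matrix, n_components: int | None = None) -> CorrespondenceAnalysis:
    """Fit CA on a non-negative matrix (functional wrapper)."""
    return CorrespondenceAnalysis(n_components=n_components).fit(matrix)
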