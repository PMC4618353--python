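"""Phylogenetic expression divergence and faster-X tests.

The per-gene divergence statistic is the Brownian-motion rate (sigma^2) of
log expression along the species tree, estimated by REML through
phylogenetically independent contrasts: the pruning recursion yields n-1
standardized contrasts c_i and sigma^2 = sum(c_i^2) / (n - 1). For a fixed
tree the contrasts are a linear map of the tip values, so the operator is
built once and applied to a whole gene matrix.

Chromosome-level tests: one-way ANOVA of sigma^2 (optionally log-scale)
grouped by Müller element, per-element Spearman correlations of log levels
between species pairs (lower correlation = higher divergence), and a
within-element gene bootstrap measuring the support for Müller A (the X)
being the most divergent element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def pic_operator(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Standardized-contrast operator W of shape (n-1, n).

    Row k of W applied to a tip-value vector (ordered as ``taxa``) gives the
    k-th standardized independent contrast; sigma^2 = mean of squared rows of
    W @ x. Multifurcations are folded pairwise, which preserves the contrast
    count n - 1.
    """
    index = {label: i for i, label in enumerate(taxa)}
    n = len(taxa)
    contrasts: list[np.ndarray] = []

    def visit(node) -> tuple[np.ndarray, float]:
        if node.is_leaf():
            w = np.zeros(n)
            w[index[node.taxon.label]] = 1.0
            length = node.edge.length or 0.0
            if length < 0:
                raise ValueError("negative branch length")
            return w, float(length)
        children = [visit(child) for child in node.child_nodes()]
        w1, v1 = children[0]
        for w2, v2 in children[1:]:
            pooled = v1 + v2
            if pooled <= 0:
                raise ValueError("zero-length cherry: contrast variance is 0")
            contrasts.append((w1 - w2) / np.sqrt(pooled))
            w1 = (v2 * w1 + v1 * w2) / pooled
            v1 = v1 * v2 / pooled
        length = node.edge.length or 0.0
        return w1, v1 + float(length)

    visit(tree.seed_node)
    if not contrasts:
        raise ValueError("tree has fewer than two tips")
    return np.vstack(contrasts)


def bm_variance(tip_values, tree: dendropy.Tree) -> float:
    """REML Brownian-motion rate for one gene.

    ``tip_values`` maps species label -> (log) expression level; returns
    sigma^2 in squared trait units per unit branch length (0 iff all tips
    are equal).
    """
    tip_values = dict(tip_values)
    taxa = sorted(tip_values)
    tree_taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = tree_taxa - set(taxa)
    if missing:
        raise ValueError(f"missing tip values for {sorted(missing)}")
    w = pic_operator(tree, taxa)
    x = np.array([tip_values[t] for t in taxa], dtype=float)
    c = w @ x
    return float(np.mean(c**2))


def bm_variance_table(levels: pd.DataFrame, tree: dendropy.Tree) -> pd.Series:
    """Vectorized per-gene sigma^2 for a genes x species matrix of levels."""
    taxa = sorted(levels.columns)
    w = pic_operator(tree, taxa)
    c = levels[taxa].to_numpy() @ w.T
    return pd.Series(np.mean(c**2, axis=1), index=levels.index, name="bm_variance")


def chromosome_anova(
    variances: pd.Series,
    elements: pd.Series,
    log_scale: bool = False,
    log_eps: float = 1e-8,
) -> tuple[float, float]:
    """One-way ANOVA of BM variance grouped by Müller element -> (F, p)."""
    el = elements.reindex(variances.index)
    values = variances.copy()
    if log_scale:
        values = np.log10(values + log_eps)
    groups = [values[el == e].to_numpy() for e in sorted(el.dropna().unique())]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two elements with >= 2 genes")
    pooled = np.concatenate(groups)
    if np.allclose(pooled, pooled[0]):
        return 0.0, 1.0  # degenerate: no variance anywhere
    f, p = stats.f_oneway(*groups)
    if np.isnan(f):
        return 0.0, 1.0
    return float(f), float(p)


def chromosome_correlation(
    levels_a: pd.Series, levels_b: pd.Series, elements: pd.Series, min_genes: int = 3
) -> pd.Series:
    """Per-element Spearman correlation of log levels between two species."""
    shared = levels_a.index.intersection(levels_b.index)
    el = elements.reindex(shared)
    out = {}
    for element in sorted(el.dropna().unique()):
        genes = shared[el == element]
        if len(genes) < min_genes:
            continue
        a, b = levels_a.loc[genes], levels_b.loc[genes]
        if a.nunique() <= 1 or b.nunique() <= 1:
            logger.warning("constant expression vector on element %s; rho undefined", element)
            continue
        rho, _ = stats.spearmanr(a, b)
        out[element] = float(rho)
    return pd.Series(out, name="rho")


@dataclass
class BootstrapSupport:
    """Observed per-element rho plus bootstrap support for a more divergent X."""

    rho: pd.Series
    support: float
    B: int
    rule: str


def bootstrap_support(
    levels_a: pd.Series,
    levels_b: pd.Series,
    elements: pd.Series,
    B: int = 10_000,
    seed: int = 0,
    x_element: str = "A",
    rule: str = "all",
    min_genes: int = 3,
    exclude_elements: tuple = ("F",),
) -> BootstrapSupport:
    """Within-element gene bootstrap of Spearman correlations.

    Genes are resampled with replacement inside each element B times, each
    element drawing from its own seeded stream; the support for a more
    divergent X is the fraction of replicates in which Müller A's rho falls
    below every other element's rho (``rule="all"``) or below their median
    (``rule="median"``). The atypical dot chromosome (Müller F, tens of
    genes, unstable rho) is excluded from the X-versus-autosome comparison
    by default; its observed correlation is still reported.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if rule not in ("all", "median"):
        raise ValueError("rule must be 'all' or 'median'")
    observed = chromosome_correlation(levels_a, levels_b, elements, min_genes=min_genes)
    if x_element not in observed.index:
        raise ValueError(f"element {x_element!r} not testable (too few genes)")
    shared = levels_a.index.intersection(levels_b.index)
    el = elements.reindex(shared)
    order = [
        e for e in observed.index if e == x_element or e not in set(exclude_elements)
    ]
    root_ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = root_ss.spawn(len(order))
    reps = np.empty((B, len(order)))
    for j, element in enumerate(order):
        genes = shared[el == element]
        a = levels_a.loc[genes].to_numpy()
        b = levels_b.loc[genes].to_numpy()
        rng = np.random.default_rng(streams[j])
        n = len(genes)
        idx = rng.integers(0, n, size=(B, n))
        ra = np.apply_along_axis(stats.rankdata, 1, a[idx])
        rb = np.apply_along_axis(stats.rankdata, 1, b[idx])
        ra -= ra.mean(axis=1, keepdims=True)
        rb -= rb.mean(axis=1, keepdims=True)
        denom = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
        with np.errstate(invalid="ignore"):
            reps[:, j] = (ra * rb).sum(axis=1) / denom
    x_col = order.index(x_element)
    others = [j for j in range(len(order)) if j != x_col]
    if rule == "all":
        wins = (reps[:, [x_col]] < reps[:, others]).all(axis=1)
    else:
        wins = reps[:, x_col] < np.median(reps[:, others], axis=1)
    return BootstrapSupport(rho=observed, support=float(wins.mean()), B=B, rule=rule)


def divergence_analysis(
    log_levels: pd.DataFrame,
    tree: dendropy.Tree,
    elements: pd.Series,
    B: int = 10_000,
    seed: int = 0,
    anova_log_scale: bool = False,
    support_rule: str = "all",
) -> dict:
    """BM variances, chromosome ANOVA and pairwise bootstrap support for one
    condition's genes x species matrix of log levels."""
    variances = bm_variance_table(log_levels, tree)
    f, p = chromosome_anova(variances, elements, log_scale=anova_log_scale)
    species = sorted(log_levels.columns)
    pair_results = {}
    pair_streams = np.random.SeedSequence([seed, 1]).spawn(
        len(species) * (len(species) - 1) // 2
    )
    k = 0
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            pair_results[(a, b)] = bootstrap_support(
                log_levels[a], log_levels[b], elements, B=B, seed=pair_streams[k], rule=support_rule
            )
            k += 1
    return {"bm_variance": variances, "anova_F": f, "anova_p": p, "pairs": pair_results}
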