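"""Synthetic four-species egg/embryo expression datasets with ground truth.

The generator emulates the structure of a single-egg / single-embryo
comparative RNA-seq design: ~6,000 one-to-one orthologs across four species,
2-3 female and male blastoderm embryos and 1-2 unfertilized eggs per
species, Müller-element annotation including a neo-X (Müller D X-linked in
one species only), and a known truth record for every downstream stage.

Generative model per gene:

* an ancestral log10 deposited (egg) level and/or zygotic level, evolved
  along the species tree by Brownian motion with a per-gene, per-condition
  rate sigma^2 (optionally inflated on Müller A for the egg condition — the
  maternal faster-X scenario);
* origin class Mat / Zyg / MatZyg: maternal genes have no zygotic
  component, zygotic genes deposit nothing in the egg;
* the maternal pool decays between egg and blastoderm by a per-species
  degraded fraction r (a configured proportion of genes get species-specific
  rates with at least a two-fold spread);
* sex applies only to the zygotic component: X-linked genes (Müller A
  everywhere; Müller D in the neo-X species) are either dosage-compensated
  (female = male) or uncompensated (male = half the female level); Müller A
  genes are split 50/50, Müller D genes in the neo-X species are
  uncompensated, males having a single template;
* replicates receive multiplicative log-normal noise at a configured CV;
  eggs are sexless.

A second, focused generator (:func:`simulate_maternal_decay`) produces
conserved-maternal genes only, either with the same log-normal replicate
noise or with the additive homoscedastic embryo noise that the decay model
itself assumes (the configuration under which the likelihood-ratio test is
exactly calibrated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix
from .io import tree_from_newick

DEFAULT_SPECIES = ("melanogaster", "yakuba", "pseudoobscura", "virilis")
DEFAULT_TREE = (
    "((melanogaster:1.0,yakuba:1.0):1.0,pseudoobscura:1.0,virilis:1.0);"
)


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset."""

    n_genes: int = 6000
    species: tuple[str, ...] = DEFAULT_SPECIES
    neo_x_species: str = "pseudoobscura"
    tree_newick: str = DEFAULT_TREE
    replicates_female: int = 3
    replicates_male: int = 3
    replicates_egg: int = 2
    # proportions of the reference species' labeled set (maternal-only genes
    # dominate the blastoderm ortholog pool)
    class_proportions: dict = field(
        default_factory=lambda: {"Mat": 0.67, "Zyg": 0.18, "MatZyg": 0.15}
    )
    muller_proportions: dict = field(
        default_factory=lambda: {"A": 0.16, "B": 0.19, "C": 0.20, "D": 0.19, "E": 0.25, "F": 0.01}
    )
    prop_species_specific_r: float = 0.5
    dosage_compensated_fraction: float = 0.5
    noise_cv: float = 0.10
    ancestral_log10_mean: float = 1.3
    ancestral_log10_sd: float = 0.5
    bm_sigma2_median: float = 0.005
    bm_sigma2_log_sd: float = 1.0
    egg_x_sigma2_factor: float = 1.0
    r_range: tuple[float, float] = (0.1, 0.9)
    min_specific_fold: float = 2.0
    # dual-origin genes are re-transcribed at a level comparable to their
    # deposition (log10 ratio sd below); this produces the on-diagonal
    # Mat-Zyg cluster between the maternal and zygotic clouds
    matzyg_ratio_sd: float = 0.3
    # conserved gene-specific sex propensity of zygotic transcription
    # (log2 sd); makes sex-ratio ranks correlate across species as real
    # pairwise sex-ratio comparisons do
    sex_propensity_sd: float = 0.3
    # residual conserved sex propensity of predominantly-maternal genes
    # (low-level zygotic transcription below the labeling threshold)
    mat_propensity_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.n_genes < 100:
            raise ValueError("n_genes must be >= 100")
        if min(self.replicates_female, self.replicates_male, self.replicates_egg) < 1:
            raise ValueError("replicate counts must be >= 1")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if abs(sum(self.muller_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("Müller element proportions must sum to 1")
        if self.neo_x_species not in self.species:
            raise ValueError("neo-X species must be in the species set")
        if not 0 <= self.prop_species_specific_r <= 1:
            raise ValueError("prop_species_specific_r must lie in [0, 1]")


@dataclass
class SimulatedBundle:
    matrix: ExpressionMatrix
    samples: pd.DataFrame
    annotation: pd.DataFrame
    tree: object
    tree_newick: str
    truth: pd.DataFrame
    config: SimulationConfig


def _tree_covariance(tree, taxa: list[str]) -> np.ndarray:
    """Shared-path-length covariance matrix of tip values under unit-rate BM."""
    n = len(taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    depths = {}
    for node in tree.preorder_node_iter():
        parent_depth = depths.get(node.parent_node, 0.0)
        depths[node] = parent_depth + (node.edge.length or 0.0)
    pdm = tree.phylogenetic_distance_matrix()
    taxon_by_label = {t.label: t for t in tree.taxon_namespace}
    leaf_depth = {
        leaf.taxon.label: depths[leaf] for leaf in tree.leaf_node_iter()
    }
    cov = np.zeros((n, n))
    for a in taxa:
        for b in taxa:
            if a == b:
                cov[idx[a], idx[a]] = leaf_depth[a]
            else:
                d = pdm.patristic_distance(taxon_by_label[a], taxon_by_label[b])
                cov[idx[a], idx[b]] = 0.5 * (leaf_depth[a] + leaf_depth[b] - d)
    return cov


def _evolve_bm(
    ancestral: np.ndarray, sigma2: np.ndarray, chol: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Tip values for each gene: ancestral value + correlated BM increments."""
    n_genes, n_taxa = ancestral.shape[0], chol.shape[0]
    z = rng.standard_normal((n_genes, n_taxa))
    return ancestral[:, None] + np.sqrt(sigma2)[:, None] * (z @ chol.T)


def _draw_rates(
    rng: np.random.Generator,
    n: int,
    n_species: int,
    r_range: tuple[float, float],
    specific: np.ndarray,
    min_fold: float,
) -> np.ndarray:
    """Per-gene per-species degraded fractions.

    Genes not flagged species-specific share one rate; flagged genes draw
    independent per-species rates, redrawn until the max/min ratio reaches
    ``min_fold`` (rejection sampling, almost surely terminating).
    """
    lo, hi = r_range
    rates = np.repeat(rng.uniform(lo, hi, size=n)[:, None], n_species, axis=1)
    todo = np.flatnonzero(specific)
    while todo.size:
        draw = rng.uniform(lo, hi, size=(todo.size, n_species))
        ok = draw.max(axis=1) / draw.min(axis=1) >= min_fold
        rates[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return rates


def _lognormal_noise(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, size=shape))


def simulate_dataset(config: SimulationConfig | None = None, seed: int = 0) -> SimulatedBundle:
    """Generate the full input bundle plus the truth table."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2_0001]))
    n = config.n_genes
    species = list(config.species)
    tree = tree_from_newick(config.tree_newick, species)
    cov = _tree_covariance(tree, species)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(species)))

    genes = [f"OG{i:05d}" for i in range(1, n + 1)]
    elements = rng.choice(
        list(config.muller_proportions), size=n, p=list(config.muller_proportions.values())
    )
    classes = rng.choice(
        list(config.class_proportions), size=n, p=list(config.class_proportions.values())
    )
    has_maternal = classes != "Zyg"
    has_zygotic = classes != "Mat"

    # dosage status of the zygotic component where the gene is X-linked
    compensated = rng.random(n) < config.dosage_compensated_fraction
    sex_effect = np.full(n, "none", dtype=object)
    on_a = elements == "A"
    on_d = elements == "D"
    sex_effect[on_a & has_zygotic & compensated] = "compensated"
    sex_effect[on_a & has_zygotic & ~compensated] = "uncompensated"
    sex_effect[on_d & has_zygotic] = "uncompensated"  # neo-X males carry one template

    # per-gene BM rates per condition
    log_sd = config.bm_sigma2_log_sd
    sigma2_egg = config.bm_sigma2_median * np.exp(rng.normal(0.0, log_sd, size=n))
    sigma2_embryo = config.bm_sigma2_median * np.exp(rng.normal(0.0, log_sd, size=n))
    sigma2_egg[on_a] *= config.egg_x_sigma2_factor

    # maternal (egg) levels evolve along the tree; zygotic levels likewise
    anc_egg = rng.normal(config.ancestral_log10_mean, config.ancestral_log10_sd, size=n)
    anc_zyg = rng.normal(config.ancestral_log10_mean, config.ancestral_log10_sd, size=n)
    dual = classes == "MatZyg"
    anc_zyg[dual] = anc_egg[dual] + rng.normal(0.0, config.matzyg_ratio_sd, size=int(dual.sum()))
    egg_log = _evolve_bm(anc_egg, sigma2_egg, chol, rng)
    zyg_log = _evolve_bm(anc_zyg, sigma2_embryo, chol, rng)
    egg_fpkm = np.where(has_maternal[:, None], 10.0**egg_log, 0.0)
    zyg_fpkm = np.where(has_zygotic[:, None], 10.0**zyg_log, 0.0)

    specific = has_maternal & (rng.random(n) < config.prop_species_specific_r)
    rates = _draw_rates(
        rng, n, len(species), config.r_range, specific, config.min_specific_fold
    )
    maternal_embryo = egg_fpkm * (1.0 - rates)

    # zygotic component by sex: a conserved gene-specific propensity plus
    # the per-species dosage effect (X-linkage is per species)
    propensity = np.where(
        has_zygotic,
        rng.normal(0.0, config.sex_propensity_sd, size=n),
        rng.normal(0.0, config.mat_propensity_sd, size=n),
    )
    female_zyg = zyg_fpkm * 2.0 ** (propensity[:, None] / 2.0)
    male_zyg = zyg_fpkm * 2.0 ** (-propensity[:, None] / 2.0)
    for j, sp in enumerate(species):
        xlinked = on_a | (on_d & (sp == config.neo_x_species))
        halved = xlinked & (sex_effect == "uncompensated")
        male_zyg[halved, j] *= 0.5

    female_expected = maternal_embryo + female_zyg
    male_expected = maternal_embryo + male_zyg
    # purely maternal genes carry their residual propensity on the whole level
    only_mat = classes == "Mat"
    female_expected[only_mat] *= 2.0 ** (propensity[only_mat, None] / 2.0)
    male_expected[only_mat] *= 2.0 ** (-propensity[only_mat, None] / 2.0)

    columns, sample_rows, values = [], [], []
    for j, sp in enumerate(species):
        for rep in range(1, config.replicates_female + 1):
            sid = f"{sp}_embryo_female_{rep}"
            columns.append(sid)
            sample_rows.append((sid, sp, "embryo", "female", rep))
            values.append(female_expected[:, j] * _lognormal_noise(rng, n, config.noise_cv))
        for rep in range(1, config.replicates_male + 1):
            sid = f"{sp}_embryo_male_{rep}"
            columns.append(sid)
            sample_rows.append((sid, sp, "embryo", "male", rep))
            values.append(male_expected[:, j] * _lognormal_noise(rng, n, config.noise_cv))
        for rep in range(1, config.replicates_egg + 1):
            sid = f"{sp}_egg_{rep}"
            columns.append(sid)
            sample_rows.append((sid, sp, "egg", "na", rep))
            values.append(egg_fpkm[:, j] * _lognormal_noise(rng, n, config.noise_cv))

    matrix = ExpressionMatrix(
        pd.DataFrame(
            np.column_stack(values), index=pd.Index(genes, name="gene_id"), columns=columns
        ),
        transform="raw",
    )
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "species", "stage", "sex", "replicate"]
    )
    annotation = pd.DataFrame({"orthogroup_id": genes, "muller_element": elements})
    for sp in species:
        annotation[f"gene_id_{sp}"] = [f"{sp[:3]}_{g}" for g in genes]
        annotation[f"xlinked_{sp}"] = (elements == "A") | (
            (elements == "D") & (sp == config.neo_x_species)
        )

    truth = pd.DataFrame(
        {
            "orthogroup_id": genes,
            "origin_class": classes,
            "muller_element": elements,
            "sex_effect": sex_effect,
            "sex_propensity": propensity,
            "sigma2_egg": sigma2_egg,
            "sigma2_embryo": sigma2_embryo,
            "species_specific_r": specific,
        }
    )
    for j, sp in enumerate(species):
        truth[f"r_{sp}"] = np.where(has_maternal, rates[:, j], np.nan)
        truth[f"egg_level_{sp}"] = egg_fpkm[:, j]
    truth.loc[~has_maternal, "species_specific_r"] = False

    return SimulatedBundle(
        matrix=matrix,
        samples=samples,
        annotation=annotation,
        tree=tree,
        tree_newick=config.tree_newick,
        truth=truth.set_index("orthogroup_id"),
        config=config,
    )


def simulate_maternal_decay(
    n_genes: int = 1000,
    species: Sequence[str] = DEFAULT_SPECIES,
    n_egg: int = 3,
    n_embryo: int = 3,
    noise_cv: float = 0.10,
    noise_model: str = "lognormal",
    prop_specific: float = 0.5,
    r_range: tuple[float, float] = (0.1, 0.9),
    min_specific_fold: float = 2.0,
    egg_log10_mean: float = 1.2,
    egg_log10_sd: float = 0.25,
    egg_divergence_sd: float = 0.1,
    seed: int = 0,
) -> dict:
    """Conserved-maternal genes only, for decay-model studies.

    Egg levels are log-normal across genes with a small independent
    between-species spread (``egg_divergence_sd`` in log10 units, unrelated
    to the rates); embryo levels follow egg * (1 - r).

    ``noise_model="lognormal"`` applies multiplicative replicate noise at
    ``noise_cv`` to eggs and embryos alike. ``noise_model="additive"`` is
    the decay model's own idealization: egg replicates are exact and embryo
    replicates get homoscedastic Gaussian noise with standard deviation
    ``noise_cv`` times the mean embryo level (under which the LRT null is
    chi-squared distributed).

    Returns a dict with ``egg``/``embryo`` arrays per species (genes x
    replicates) and a ``truth`` frame of per-species rates.
    """
    if noise_model not in ("lognormal", "additive"):
        raise ValueError("noise_model must be 'lognormal' or 'additive'")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3_0001]))
    species = list(species)
    k = len(species)
    genes = [f"OG{i:05d}" for i in range(1, n_genes + 1)]
    base = rng.normal(egg_log10_mean, egg_log10_sd, size=n_genes)
    egg_log = base[:, None] + rng.normal(0.0, egg_divergence_sd, size=(n_genes, k))
    egg_level = 10.0**egg_log
    specific = rng.random(n_genes) < prop_specific
    rates = _draw_rates(rng, n_genes, k, r_range, specific, min_specific_fold)
    embryo_level = egg_level * (1.0 - rates)

    egg_reps, embryo_reps = {}, {}
    if noise_model == "lognormal":
        for j, sp in enumerate(species):
            egg_reps[sp] = egg_level[:, [j]] * _lognormal_noise(rng, (n_genes, n_egg), noise_cv)
            embryo_reps[sp] = embryo_level[:, [j]] * _lognormal_noise(
                rng, (n_genes, n_embryo), noise_cv
            )
        sigma_additive = None
    else:
        sigma_additive = noise_cv * float(embryo_level.mean())
        for j, sp in enumerate(species):
            egg_reps[sp] = np.repeat(egg_level[:, [j]], n_egg, axis=1)
            embryo_reps[sp] = embryo_level[:, [j]] + rng.normal(
                0.0, sigma_additive, size=(n_genes, n_embryo)
            )
    truth = pd.DataFrame(
        {"species_specific_r": specific, **{f"r_{sp}": rates[:, j] for j, sp in enumerate(species)}},
        index=pd.Index(genes, name="orthogroup_id"),
    )
    for j, sp in enumerate(species):
        truth[f"egg_level_{sp}"] = egg_level[:, j]
        truth[f"embryo_level_{sp}"] = embryo_level[:, j]
    return {
        "genes": genes,
        "species": species,
        "egg": egg_reps,
        "embryo": embryo_reps,
        "truth": truth,
        "sigma_additive": sigma_additive,
    }


def decay_gene_data(sim: dict) -> dict:
    """Re-shape a decay simulation into the mapping degradation_lrt expects."""
    return {
        gene: {
            sp: (sim["egg"][sp][i], sim["embryo"][sp][i]) for sp in sim["species"]
        }
        for i, gene in enumerate(sim["genes"])
    }


def decay_noise_estimate(sim: dict) -> float:
    """Plug-in sigma^2 for a decay simulation: mean within-condition variance
    over all conditions with >= 2 distinguishable replicates."""
    variances = []
    for sp in sim["species"]:
        for arr in (sim["egg"][sp], sim["embryo"][sp]):
            if arr.shape[1] >= 2:
                v = arr.var(axis=1, ddof=1)
                variances.append(v)
    pooled = np.concatenate(variances)
    sigma2 = float(pooled.mean())
    if sigma2 <= 0:
        raise ValueError("zero replicate variance; noiseless input is degenerate")
    return sigma2
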