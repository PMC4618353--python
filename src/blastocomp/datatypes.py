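"""Core domain types and configuration.

The package operates on four tables and a tree:

* an expression matrix (orthogroups x samples, FPKM or ``log10(FPKM+1)``),
* a sample sheet (species, stage ``egg``/``embryo``, sex, replicate),
* a gene annotation (orthogroup, per-species gene ids, Müller element A-F,
  per-species X-linkage, including a neo-X where Müller D is X-linked in a
  single lineage),
* a four-taxon phylogeny with branch lengths in substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

TRANSFORM_RAW = "raw"
TRANSFORM_LOG = "log10p1"
TRANSFORMS = (TRANSFORM_RAW, TRANSFORM_LOG)

MULLER_ELEMENTS = ("A", "B", "C", "D", "E", "F")
STAGES = ("egg", "embryo")
SEXES = ("female", "male", "na")

SAMPLE_COLUMNS = ("sample_id", "species", "stage", "sex", "replicate")


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with an explicit transform flag.

    ``data`` is indexed by gene (orthogroup) id with one column per sample.
    ``transform`` is ``"raw"`` (non-negative FPKM) or ``"log10p1"``.
    """

    data: pd.DataFrame
    transform: str = TRANSFORM_RAW

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        dup_genes = self.data.index[self.data.index.duplicated()].unique()
        if len(dup_genes):
            raise ValueError(f"duplicated gene ids: {', '.join(map(str, dup_genes[:5]))}")
        dup_samples = self.data.columns[self.data.columns.duplicated()].unique()
        if len(dup_samples):
            raise ValueError(f"duplicated sample ids: {', '.join(map(str, dup_samples[:5]))}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            self.data = self.data.astype(float)
            values = self.data.to_numpy()
        if np.isnan(values).any():
            gene = self.data.index[np.isnan(values).any(axis=1)][0]
            raise ValueError(f"missing value in row for gene {gene!r}; encode absence as 0.0")
        if self.transform == TRANSFORM_RAW and (values < 0).any():
            gene = self.data.index[(values < 0).any(axis=1)][0]
            raise ValueError(f"negative value in raw matrix (gene {gene!r})")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.transform)

    def subset_genes(self, genes: Sequence) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], self.transform)

    def subset_samples(self, samples: Sequence) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)], self.transform)


def validate_samples(samples: pd.DataFrame, species: Sequence[str] | None = None) -> pd.DataFrame:
    """Validate a sample sheet; returns it with canonical column order."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    samples = samples[list(SAMPLE_COLUMNS)].copy()
    if samples["sample_id"].duplicated().any():
        dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated sample ids: {dups}")
    bad_stage = set(samples["stage"]) - set(STAGES)
    if bad_stage:
        raise ValueError(f"unknown stage values: {sorted(bad_stage)}")
    bad_sex = set(samples["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex values: {sorted(bad_sex)}")
    eggs = samples[samples["stage"] == "egg"]
    if (eggs["sex"] != "na").any():
        raise ValueError("egg samples must have sex='na' (deposited before fertilization)")
    embryos = samples[samples["stage"] == "embryo"]
    if (~embryos["sex"].isin(["female", "male"])).any():
        raise ValueError("embryo samples must have sex 'female' or 'male'")
    if (samples["replicate"].astype(int) < 1).any():
        raise ValueError("replicate indices must be positive")
    if species is not None:
        extra = set(samples["species"]) - set(species)
        if extra:
            raise ValueError(f"samples from unknown species: {sorted(extra)}")
    return samples


def validate_annotation(annotation: pd.DataFrame, species: Sequence[str] | None = None) -> pd.DataFrame:
    """Validate a gene annotation table (one row per 1:1:1:1 orthogroup)."""
    for col in ("orthogroup_id", "muller_element"):
        if col not in annotation.columns:
            raise ValueError(f"annotation missing column {col!r}")
    if annotation["orthogroup_id"].duplicated().any():
        dups = annotation.loc[annotation["orthogroup_id"].duplicated(), "orthogroup_id"]
        raise ValueError(f"duplicated orthogroups in annotation: {dups.tolist()[:5]}")
    bad = set(annotation["muller_element"]) - set(MULLER_ELEMENTS)
    if bad:
        raise ValueError(f"unknown Müller elements: {sorted(bad)}")
    if species is not None:
        xcols = [f"xlinked_{sp}" for sp in species if f"xlinked_{sp}" in annotation.columns]
        for col in xcols:
            on_a = annotation["muller_element"] == "A"
            if not annotation.loc[on_a, col].astype(bool).all():
                raise ValueError(f"Müller A must be X-linked in every species ({col})")
    return annotation


def muller_map(annotation: pd.DataFrame) -> pd.Series:
    """Orthogroup -> Müller element lookup."""
    return annotation.set_index("orthogroup_id")["muller_element"]


# --------------------------------------------------------------------------
# configuration


@dataclass
class NormalizationOptions:
    method: str = "p75"
    anchor_elements: tuple[str, ...] = ("B", "C", "E")
    use_all_genes: bool = False
    expression_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in ("none", "median", "p75", "p95", "tmm", "quantile"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.expression_threshold < 0:
            raise ValueError("expression threshold must be >= 0")


@dataclass
class SexBiasOptions:
    top_q: float = 0.20
    bottom_q: float = 0.20
    unbiased_window: tuple[float, float] = (0.40, 0.60)
    floor_log2: float = 0.33
    top_k: int = 200
    min_element_genes: int = 20  # chi-squared validity; tiny Müller F is excluded below this

    def __post_init__(self) -> None:
        if not (0 < self.top_q < 0.5 and 0 < self.bottom_q < 0.5):
            raise ValueError("top_q and bottom_q must lie in (0, 0.5)")
        if self.top_q + self.bottom_q >= 1:
            raise ValueError("top_q + bottom_q must be < 1")
        lo, hi = self.unbiased_window
        if not (0 < lo < hi < 1):
            raise ValueError("unbiased window must be a sub-interval of (0, 1)")


@dataclass
class DivergenceOptions:
    n_bootstrap: int = 10_000
    support_rule: str = "all"  # Müller A rho below "all" autosomal rhos, or below their "median"
    anova_log_scale: bool = False
    anova_log_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("bootstrap count must be >= 1")
        if self.support_rule not in ("all", "median"):
            raise ValueError("support_rule must be 'all' or 'median'")


@dataclass
class OriginOptions:
    gamma: float = 0.01
    cost: float = 10.0
    thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"Mat": 0.8, "Zyg": 0.7, "MatZyg": 0.8}
    )
    holdout_fraction: float = 1 / 3

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.cost <= 0:
            raise ValueError("gamma and cost must be > 0")
        for cls, thr in self.thresholds.items():
            if not 0 < thr < 1:
                raise ValueError(f"threshold for {cls} must lie in (0, 1)")


@dataclass
class DegradationOptions:
    rate_bounds: tuple[float, float] = (0.0, 1.0)
    df: int = 4
    alpha: float = 0.001
    fold_threshold: float = 2.0
    rate_floor: float = 0.01
    pairing: str = "pairs"  # all egg x embryo replicate pairings, or "mean_egg"

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("LRT degrees of freedom must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fold_threshold < 1:
            raise ValueError("fold threshold must be >= 1")
        if self.pairing not in ("pairs", "mean_egg"):
            raise ValueError("pairing must be 'pairs' or 'mean_egg'")


@dataclass
class AnalysisConfig:
    """Bundle of all stage options plus the master seed."""

    normalization: NormalizationOptions = field(default_factory=NormalizationOptions)
    sexbias: SexBiasOptions = field(default_factory=SexBiasOptions)
    divergence: DivergenceOptions = field(default_factory=DivergenceOptions)
    origin: OriginOptions = field(default_factory=OriginOptions)
    degradation: DegradationOptions = field(default_factory=DegradationOptions)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        kwargs = {}
        for name, sub in (
            ("normalization", NormalizationOptions),
            ("sexbias", SexBiasOptions),
            ("divergence", DivergenceOptions),
            ("origin", OriginOptions),
            ("degradation", DegradationOptions),
        ):
            if name in d:
                section = dict(d.pop(name))
                for key, value in section.items():
                    if isinstance(value, list):
                        section[key] = tuple(value)
                kwargs[name] = sub(**section)
        if "seed" in d:
            kwargs["seed"] = int(d.pop("seed"))
        if d:
            raise ValueError(f"unknown config sections: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
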