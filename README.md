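# blastocomp

Comparative transcriptomics of *Drosophila* blastoderm embryos and
unfertilized eggs across four species (*D. melanogaster*, *D. yakuba*,
*D. pseudoobscura*, *D. virilis*).

The blastoderm (stage 5) embryo is a unique transcriptional environment:
canonical MSL-mediated X dosage compensation is not yet established, and
roughly half of the transcript pool is still maternally deposited mRNA in
the middle of being degraded. `blastocomp` is for researchers asking how
these two features shape the evolution of embryonic gene expression. From
FPKM matrices over 1:1:1:1 orthologs, a sample sheet, a Müller-element
annotation (A–F chromosome arms, including a neo-X where Müller D is
X-linked in one lineage) and a four-taxon phylogeny, it computes:

* **Normalization** — six schemes (none / median / p75 / p95 / TMM /
  quantile), percentile scaling anchored on autosomal genes (Müller
  B, C, E), `log10(FPKM+1)` transform and the expressed-gene filter.
* **Sex bias** — per-species log2(female/male) ratios on non-log levels,
  rank-quantile classification (top/bottom 20% biased, 40–60% window
  unbiased), cross-species conserved and lineage-specific sets,
  chi-squared chromosomal enrichment against gene-content expectations,
  the top-200 most-biased distribution, and a binomial sign test asking
  whether lineage-specific bias is driven by a female increase or a male
  decrease.
* **Faster-X** — per-gene Brownian-motion variance of log expression along
  the tree, `σ² = Σc²/(n−1)` from phylogenetically independent contrasts
  (REML), chromosome ANOVA, and per-chromosome Spearman correlations
  between species with a within-chromosome gene bootstrap measuring
  support for a more divergent X.
* **Transcript origin** — a radial-kernel SVM (gamma 0.01, cost 10, Platt
  probabilities) over (egg level, embryo level) features classifying genes
  as Mat / Zyg / Mat-Zyg, trained on a labeled reference species and
  transferred to the others; cross-species conservation of origin and the
  conserved high-confidence maternal set.
* **Maternal decay** — the kinetic model `mRNA[embryo] = mRNA[egg]·(1−r)`
  fitted per gene over all replicate pairings, species-common versus
  species-specific rates compared by likelihood-ratio test (chi-squared,
  BH-corrected q < 0.001, > 2-fold rate spread), and Spearman correlation
  of rate differences against embryo/egg level differences.
* **Ordination** — correspondence analysis of the egg/embryo samples with
  supplementary projection of pooled samples (the pooling-bias diagnostic:
  pools of mixed developmental content land between the egg and embryo
  clusters on the stage axis).
* **Synthetic data** — a generator producing the full input bundle with
  ground truth for every stage (origin classes, per-species decay rates,
  BM rates, dosage-compensation status, neo-X male halving).

See `docs/methods.md` for the models, estimators, defaults and their
rationale.

## Worked example

```python
from blastocomp import (
    ExpressionNormalizer, MaternalDecayModel, classify_origin,
    conserved_maternal_set, filter_expressed, log_transform,
    origin_features, sex_bias_analysis, train_origin_classifier,
)
from blastocomp.simulate import SimulationConfig, simulate_dataset

bundle = simulate_dataset(SimulationConfig(), seed=1)
normalized = ExpressionNormalizer(method="p75").fit_transform(
    bundle.matrix, annotation=bundle.annotation)
expressed = filter_expressed(normalized, bundle.samples)
normalized = normalized.subset_genes(expressed)
print(f"{len(expressed)} of {bundle.matrix.shape[0]} genes pass the expression filter")

res = sex_bias_analysis(normalized, bundle.samples, bundle.annotation)
enrich = res.enrichment
row = enrich[(enrich.gene_set == "biased_all_female")
             & (enrich.muller_element == "A")].iloc[0]
print(f"female-biased in all 4 species on Muller A: {row.observed} observed vs "
      f"{row.expected:.1f} expected (chi2 p = {row.p_value:.2e})")

log_matrix = log_transform(normalized)
feats = origin_features(log_matrix, bundle.samples, "melanogaster")
labels = bundle.truth["origin_class"].reindex(feats.index)
model, report = train_origin_classifier(feats, labels, seed=1, holdout=True)
print(f"origin SVM holdout recall: Mat {report['recall']['Mat']:.1%}, "
      f"Zyg {report['recall']['Zyg']:.1%}, MatZyg {report['recall']['MatZyg']:.1%}")

calls = {sp: classify_origin(model, origin_features(log_matrix, bundle.samples, sp),
                             species=sp)
         for sp in sorted(bundle.samples.species.unique())}
maternal = conserved_maternal_set(calls)
print(f"{len(maternal)} genes maternal with high confidence in all four species")

decay = MaternalDecayModel().fit(normalized, bundle.samples, genes=maternal)
n_flagged = int(decay.fits_["species_specific"].sum())
print(f"{n_flagged} / {len(decay.fits_)} maternal genes flagged with "
      "species-specific decay rates")
```

Output:

```
5984 of 6000 genes pass the expression filter
female-biased in all 4 species on Muller A: 158 observed vs 66.3 expected (chi2 p = 1.87e-34)
origin SVM holdout recall: Mat 99.7%, Zyg 100.0%, MatZyg 78.9%
3085 genes maternal with high confidence in all four species
779 / 3085 maternal genes flagged with species-specific decay rates
```

Reading the numbers: the X chromosome (Müller A) carries 2.4× the expected
number of genes female-biased in every species — the signature of
incomplete dosage compensation before MSL activation. The origin SVM is
near-perfect on purely maternal and purely zygotic genes and poor on the
dual-origin class, whose geometry overlaps both. About a quarter of the
conserved maternal genes are flagged with species-specific decay rates —
on this synthetic bundle half of them truly have diverged rates, and the
LRT plus fold filter recovers the strongly-powered portion.

## Command line

Each stage is also a subcommand over a directory of TSV inputs:

```sh
blastocomp --seed 17 --outdir run/ simulate --n-genes 6000
blastocomp --seed 17 --outdir run/ all --b 1000
```

Subcommands: `simulate`, `normalize`, `sexbias`, `divergence`,
`ordination`, `origin`, `degradation`, `all`; global flags `--config
<yaml>`, `--seed`, `--outdir`, `--log-level`. Formats: TSV for matrices
and tables, Newick for the tree, YAML for configuration.

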