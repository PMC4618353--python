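# Methods

`blastocomp` re-implements, as a tested pipeline, a comparative analysis of
gene expression in *Drosophila* blastoderm embryos and unfertilized eggs
across four species (*D. melanogaster*, *D. yakuba*, *D. pseudoobscura*,
*D. virilis*). The pipeline consumes FPKM matrices over 1:1:1:1 orthologs,
a sample sheet, a Müller-element annotation and a four-taxon phylogeny, and
produces: sex-bias calls with chromosomal enrichment, phylogenetic
expression-divergence (faster-X) tests, a maternal/zygotic transcript-origin
classification, a kinetic model of maternal mRNA decay with nested-model
selection, and a correspondence-analysis pooling diagnostic. A synthetic-data
generator with complete ground truth defines the study conditions under
which every stage is validated.

## Normalization and gene set

Six schemes are implemented: none, median, 75th- and 95th-percentile
scaling, TMM, and quantile normalization. Percentile methods rescale each
sample so that the chosen percentile of *anchor genes* (genes on the large
autosomal Müller elements B, C and E by default; X-linked genes are excluded
because their dosage differs by sex) is identical across samples. The common
target value is the geometric mean of the per-sample anchor percentiles,
which makes the operation symmetric in the samples and idempotent.
Percentiles use linear interpolation. TMM uses the standard recipe
(reference = sample whose upper quartile is closest to the mean upper
quartile; two-sided trims of 30% on M-values and 5% on A-values) with an
unweighted trimmed mean — the precision weights of count-based
implementations require library sizes that FPKM matrices do not carry.
Quantile normalization maps average ranks onto the mean sorted profile;
tied entries receive the mean of the reference values at their tied ranks.

After normalization, values are log-transformed as `log10(FPKM + 1)`, and
the analyzed gene set is fixed: genes whose replicate-mean normalized FPKM
exceeds 1 in at least one condition (egg, female embryo, male embryo) of at
least one species.

## Sex-bias calling

Sex ratios are computed on non-log levels as `log2(mean female / mean
male)`. Genes are *evaluated* only if both sex means exceed an expression
floor (`2**0.33` FPKM) in every species — low-abundance transcripts produce
unstable ratios; no ratio is computed below the floor. Evaluated genes
receive a fractional rank (average rank / (n+1), strictly inside (0,1));
the top 20% are female-biased, the bottom 20% male-biased, ranks within
[0.40, 0.60] unbiased, the remainder intermediate. Rank-based calls are
invariant under any strictly monotone transform of the ratios.

Cross-species sets: biased-in-all-four; never-female-biased (rank ≤ 0.6 in
every species) and never-male-biased (rank ≥ 0.4); lineage-specific (biased
in exactly one species and inside the unbiased window in the other three).
Chromosomal enrichment is tested by chi-squared against expectations
proportional to element gene content, both globally (k−1 df) and per
element (element-vs-rest, 1 df); elements with fewer than 20 genes in the
evaluated universe (the dot chromosome, Müller F) are excluded for test
validity. The top-|k| analysis ranks genes by |log2 ratio| (k = 200; ties
at the boundary broken by gene id) and reports, per element, the proportion
of its genes in the top set by bias direction.

Lineage-specific biases are attributed to a sex-specific expression change:
for a female-biased gene in species *s* compared with species *t*, the call
is *male-driven* when the male level is lower in *s* than in *t* (the bias
involves a male decrease) and *female-driven* otherwise (the bias requires
a female increase); male-biased genes symmetrically. The decrease takes
precedence because the question posed is whether lineage-specific bias
arises by loss in one sex — the dominant mode around the neo-X, where males
carry a single template. Counts are compared to a 50/50 null by a two-sided
exact binomial test, per (species, sex, comparison species).

## Phylogenetic expression divergence (faster-X)

Per-gene divergence is the Brownian-motion rate σ² of log expression along
the species tree, estimated by REML via phylogenetically independent
contrasts: the pruning recursion yields n−1 standardized contrasts c_i and
σ̂² = Σc²/(n−1). For a fixed tree the contrasts are a linear operator on the
tip values; the operator is built once and applied to whole gene matrices.
σ² scales inversely with branch-length units and is invariant to adding a
constant to all tips; identical tips give exactly 0. The estimator is
checked against an independent numeric maximizer of the restricted
likelihood built from the tree covariance matrix (agreement to 1e−6).

Chromosome effects are tested two ways. (1) One-way ANOVA of σ² grouped by
Müller element; because σ² estimates are strongly right-skewed, a
log10(σ²+ε) option exists and is used for calibration work (the F test is
then close to nominal size; on raw variances it is anticonservative).
Degenerate inputs (no variance anywhere) return p = 1. (2) Per-element
Spearman correlation of log levels between species pairs (lower correlation
= higher divergence), with a within-element gene bootstrap: the *support*
for a more divergent X is the fraction of replicates in which Müller A's
correlation is below that of every other element (a strict reading; a
"below the median" alternative is available). Each element draws from its
own seeded substream so that support values are reproducible and element
resamples are independent. The atypical dot chromosome (Müller F) is
excluded from the X-versus-autosome comparison by default: with only tens
of genes its correlation estimate is unstable and would dominate the
minimum under the strict rule (the same smallness that excludes it from
the chi-squared enrichment tests); its observed correlation is still
reported. Under exchangeable compared elements (equal sizes, identical
divergence) the support is 1/#compared elements in expectation — 1/5 for
Müller A against the four large autosomes; the calibration check uses
equal-size elements, where the exchangeability argument is exact.

Divergence is computed per condition (female embryos, male embryos, eggs)
on replicate-mean log levels, restricted to genes detectably expressed in
that condition (mean normalized FPKM > 1 in ≥ 1 species); without this
restriction the egg analysis would be dominated by zygotic-only genes that
are structurally absent from eggs.

## Transcript-origin classification

Features per gene and species: (mean egg log level, mean embryo log level),
embryo replicates pooled across sexes — maternal transcripts are sexless
and the class geometry is two-dimensional (maternal genes high in eggs,
zygotic genes near-zero in eggs and high in embryos, dual-origin genes
along the diagonal). The classifier is a radial-basis SVM
(C-classification, gamma = 0.01, cost = 10) with Platt-calibrated class
probabilities, trained on a labeled reference species and transferred to
the others. Predictions use the argmax of the calibrated probabilities so
that calls and probabilities are always consistent; a guard verifies the
probabilities sum to 1. Calls are high-confidence above class-specific
probability thresholds (defaults Mat 0.8, Zyg 0.7, MatZyg 0.8 — two
published variants of these thresholds disagree on the Zyg/MatZyg pair; the
Methods variant is the default and both are configurable). A holdout mode
reports a stratified 2/3–1/3 confusion matrix; the published
hyperparameters stand in for the repeated-split search that produced them
(an optional grid search would reproduce it, but its product is exactly
those values).

Cross-species conservation tabulates Mat↔Mat, Zyg↔Zyg, MatZyg↔MatZyg, and
Mat↔Zyg switches — the latter counted only when both calls are
high-confidence, everything else falling into "other". The conserved
maternal set (maternal with high confidence in all four species) feeds the
decay model; four-way intersection suppresses false "Mat" calls.

## Maternal decay kinetics

For conserved-maternal genes the embryo level is modeled as
`mRNA[embryo] = mRNA[egg] * (1 − r) + ε`, with r the egg-to-blastoderm
degraded fraction and ε Gaussian with a plug-in variance: the mean over
genes and conditions of the within-condition replicate variance of non-log
values (conditions with fewer than 2 replicates carry no variance
information and are skipped; exactly zero variance is degenerate and
raises). Replicates are used directly, not averaged: the objective sums
squared residuals over every (egg replicate, embryo replicate) pairing, for
which the minimizer is closed-form, r* = 1 − Σ(egg·embryo)/Σ(egg²) over
pairings, clipped to [0, 1] (r < 0 would imply zygotic transcription,
excluded by the conserved-maternal restriction; boundary hits are flagged).
A "mean-egg" pairing alternative is provided. The species-common rate
minimizes the pooled objective.

The nested models (one common r versus four species rates) are compared by
a likelihood-ratio statistic, 2Δll = (RSS_common − RSS_specific)/σ²,
referred to chi-squared with 4 df by convention — the models differ by 3
parameters, and the calibration suite documents that under the
model-faithful null the statistic follows chi-squared(3); with the
conventional 4 df the test is conservative. P-values are BH-corrected and
a gene is flagged species-specific when q < 0.001 and the fitted rates
differ more than 2-fold between some species pair (rates floored at 0.01
before the ratio, since a fold change is undefined at r = 0).

Two properties of the all-pairings objective matter for calibration. With
k egg replicates, each embryo residual enters k times, scaling the LRT by
roughly k; and the plug-in variance treats all genes as homoscedastic, so
under multiplicative noise high-expression genes have inflated statistics.
Both are faithful consequences of the stated procedure; the calibration
simulations therefore use the model's own idealization (a single exact egg
level per species, homoscedastic additive embryo noise), under which the
chi-squared(3) null is exact. Parameter recovery is measured separately
under multiplicative log-normal noise on all replicates.

For flagged genes, species differences in r are correlated (Spearman) with
species differences in mean log embryo and egg levels, per pair and pooled:
higher degradation should deplete the embryo (strongly negative rho) but
be unrelated to deposition (rho ≈ 0).

## Correspondence analysis

Classical CA of the non-negative genes × samples matrix: SVD of the
standardized residuals of the relative-frequency table. Zero-sum rows or
columns are dropped with a warning; eigenvalues below 1e−12 of the total
inertia are discarded; axis signs are fixed deterministically
(largest-magnitude column loading positive). Supplementary profiles are
projected by the transition formula (normalized profile × standard row
coordinates), which reproduces an active sample's coordinates when applied
to its own profile. CA runs on normalized untransformed FPKM — its
chi-squared geometry presumes count-like data — with the filtered gene set;
a log-scale input is accepted if explicitly constructed. The diagnostic
use: pooled samples that mix egg and embryo material project between the
egg and embryo clusters on the dominant (developmental-stage) axis,
monotonically in the mixing fraction.

## Synthetic data generator

The generator emulates the deposited study design: 6,000 orthologs × 4
species, 3 female + 3 male embryos and 2 eggs per species, Müller elements
in realistic gene-content proportions (A .16, B .19, C .20, D .19, E .25,
F .01), and a neo-X species in which Müller D is X-linked. Defaults, with
rationale:

* **Class proportions** Mat .67 / Zyg .18 / MatZyg .15 — the tallies of the
  reference species' labeled set (1211:320:268 in the published test
  split). This also reproduces the published error structure: the SVM is
  nearly perfect on Mat and Zyg and poor on MatZyg, which absorbs the
  boundary.
* **Levels** ancestral log10 level ~ N(1.3, 0.5) (FPKM ~1–500 for
  expressed genes); dual-origin genes are re-transcribed at a level
  comparable to their deposition (log10 ratio sd 0.3), producing the
  on-diagonal Mat-Zyg cluster of the egg-vs-embryo plane.
* **Divergence** per-gene, per-condition BM rates, log-normal around a
  median of 0.005 (sd 1 on the log), on the default unit-branch-length
  topology ((mel,yak),pse,vir). This yields cross-species rank correlations
  of replicate-mean levels of ~0.85–0.90, matching the conservation the
  study reports. The maternal faster-X scenario multiplies egg-condition
  rates on Müller A by a configurable factor (1 by default; 4 in the
  validation runs).
* **Decay** maternal pools decay by r ~ U(0.1, 0.9); half the maternal
  genes get independent per-species rates, redrawn until the spread exceeds
  2-fold.
* **Sex effects** apply only to the zygotic component (maternal reads are
  sexless). X-linked zygotic genes are 50/50 dosage-compensated
  (female = male) versus uncompensated (male = half), per the reference
  species' observation that roughly half of zygotic X genes are higher in
  females; Müller D genes in the neo-X species are uncompensated (males
  carry one template). In addition every gene carries a conserved
  gene-specific sex propensity (log2 sd 0.3 for zygotic-bearing genes,
  0.2 residual for predominantly-maternal genes, whose labels tolerate
  low-level zygotic transcription). Without a conserved component,
  sex-ratio ranks would be independent across species and lineage-specific
  sets would be nearly empty; real pairwise sex-ratio comparisons between
  species are visibly correlated.
* **Noise** multiplicative log-normal replicate noise at CV 0.10.

The focused decay generator produces conserved-maternal genes only, with
egg levels log-normal across genes (log10 sd 0.25 — conserved maternal
genes occupy a narrower dynamic range than the transcriptome at large; a
much wider range would starve low-expression genes of power under the
shared plug-in variance, a real limitation of the method) and a small
independent between-species egg spread (log10 sd 0.1) unrelated to the
rates. Its two noise modes are described above.

What the generator does **not** emulate: count overdispersion and
zero-inflation of real RNA-seq, annotation and mapping artifacts,
correlated noise between genes, unequal branch lengths, gene-length
effects, and any mechanistic model of dosage compensation. Passing tests
demonstrate that the implementations recover planted signals under the
stated generative assumptions — not that real data satisfy those
assumptions.

## Problem sizes used in validation

Parameter recovery uses 1,000 genes (3+3 replicates, 10% CV); LRT
calibration 2,000 null genes; model selection 1,000 genes with half
species-specific; the BM oracle 100 random four-taxon instances; faster-X
detection one 6,000-gene dataset at B = 1,000 with 20 equal-size null
datasets and 200 ANOVA null simulations at B = 200; sex-bias and origin
checks one 6,000-gene dataset at defaults. These sizes give Monte-Carlo
error comfortably below the asserted margins. Lineage-specific set sizes
are small (roughly 5–15 genes at these conditions), so the Müller-D
male-driven fraction is the one quantity with visible seed-to-seed
variability; the enrichment p-values and all other checks are stable.

## Known limitations

* The LRT's 4-df convention is conservative (3-parameter difference); both
  df values are configurable and the calibration documents the discrepancy.
* The plug-in shared variance makes decay-model power depend on absolute
  expression level; a per-gene variance model would be more powerful but is
  not what the procedure specifies.
* The bootstrap "support" criterion is one strict reading ("below all
  other elements"); the median alternative is provided because the
  operational definition is not fixed by the source analysis.
* TMM on FPKM uses unweighted trimmed means (no count weights).
* Branch lengths are a required user input (unit lengths by default); the
  published analysis cites an external tree whose lengths are not
  reproduced here.
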