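# Methods

`symbiocor` analyses population-level meta-transcriptomes of an arthropod
host co-infected by two intracellular bacterial symbionts (A,
*Cardinium*-like; B, *Wolbachia*-like). One RNA-seq library per replicate
culture mixes host and symbiont reads; all inference is population-level
and correlative. This note records the models, the numerical choices, and
what the synthetic data generator does and does not emulate.

## Study design

Eight cultures — two infected only with symbiont A (5L, 5S), two only with
symbiont B (5N, 5P), and four mixed cultures founded from their crosses
(5LN, 5LP, 5SN, 5SP) — each with seven replicate flasks. Reads are
partitioned per organism into gene-by-sample count matrices. A symbiont's
counts are exactly zero in cultures that do not carry it.

## Standardization and read proportions

Counts are standardized by rarefaction: each sample is subsampled without
replacement (multivariate hypergeometric) to the smallest sample total of
its matrix, preserving integer counts and the zero pattern, with expected
downsampled count `count · min_total / sample_total`. A single seeded draw
is the default; repeated draws can be averaged by the caller. Symbiont
loads are summarized as the ratio of symbiont to host read totals per
sample, computed on unstandardized counts and compared between culture
types with the Mann–Whitney test (exact by full enumeration of group
assignments, ties included, when both groups have n ≤ 8; tie-corrected
normal approximation otherwise; the reported U follows the min(U₁,U₂)
convention and the z statistic is reported alongside).

## Expression diversity

Per-sample Shannon index H = −Σ pᵢ ln pᵢ over the organism's gene-count
distribution (natural log by default; base configurable), computed on
standardized counts. Two-group comparisons use Mann–Whitney, k ≥ 3 groups
tie-corrected Kruskal–Wallis (H = 0, p = 1 returned for fully tied input).
The diversity–diversity relation between organisms is ordinary least
squares with the slope F-test and 95% confidence and prediction bands at
the observed abscissae.

## Correlation networks

All row×column gene pairs between two organisms are scored with Spearman's
rho (Pearson on average ranks). Significance is by permutation of sample
labels: exact enumeration of all n! permutations when n ≤ 7 (p = k/n!,
identity included, so p > 0), otherwise Monte Carlo with the +1-corrected
estimator p = (1 + #{|rho_b| ≥ |rho_obs|})/(B+1), B = 9,999 by default
(999 in the pipeline for desk-scale runtime). One shared permutation index
stream drives the whole network, so a network is reproducible from one
seed and all pairs face identical null draws. Raw p < α (default 0.05)
defines an edge, split by the sign of rho; no multiplicity correction is
applied across the edge set by design (a Benjamini–Hochberg option
exists), mirroring the downstream use of edge *counts* rather than
individual edges. Genes constant across samples are excluded and logged.

Per-gene profiles (counts of significant positive/negative edges per
condition) feed three summaries: Tukey-fence outlier flags (count > Q3 +
1.5·IQR in any column; the factor and the rule are configurable, since
"outlier" is not otherwise pinned down), agglomerative clustering (Ward or
UPGMA linkage on Euclidean or Bray–Curtis distances), and an edge list
retaining significant edges with |rho| at or above a quantile (default
0.75) of the significant |rho| distribution.

## Ordination

*Distances.* Bray–Curtis for standardized counts. Robust Aitchison for
unstandardized counts: per sample, log counts of positive genes centred by
the sample's mean log over positive genes (zeros treated as missing), then
pairwise Euclidean over genes positive in both samples, scaled by
√(n_genes/n_shared); on zero-free data this is exactly classical CLR +
Euclidean.

*PCoA.* Gower double-centring and eigendecomposition; axes with
eigenvalues ≤ 1e-10 are dropped, negative eigenvalues are reported but not
corrected (no Lingoes/Cailliez by default). Total inertia is the positive
eigenvalue sum.

*dbRDA.* The PCoA coordinate matrix is regressed on the predictor columns
via an orthonormal (rank-revealing QR) basis; conditioning variables are
projected out of both sides first. Explained variability R² =
constrained/total inertia (unadjusted; adjusted R² also reported);
pseudo-F = (constrained/q)/(residual/(n−q−c−1)). Significance by permuting
response rows freely, or residual rows under the conditioning model for
partial dbRDA; B = 199 by default in models, deterministic per seed. With
Euclidean distances this reduces algebraically to classical RDA, which the
tests verify to 1e-8.

*Forward selection.* Candidates enter by lowest marginal permutation p
(ties: larger R², then column order), stopping when the best p ≥ α, when
an optional adjusted-R² guard (the selected model would exceed the
full-candidate model's adjusted R²) fires, or when an optional term cap is
reached. The guard can veto even the strongest first variable when noise
candidates depress the full model's adjusted R², which is why the
per-pathway models below disable it and rely on a stricter entry p.

*ANOSIM.* R = (mean between-group rank − mean within-group rank) /
(N(N−1)/4) on rank-transformed distances; one-sided permutation p, exact
by enumeration for N ≤ 8; pairwise two-group tests Bonferroni-adjusted
when there are more than two groups. *SIMPER* decomposes the average
between-group Bray–Curtis dissimilarity into per-gene contributions
(mean over between-group pairs of |y_ij − y_ik|/Σ_m(y_mj+y_mk)), which sum
exactly to the average dissimilarity.

## Differential expression

Per-gene two-sided Mann–Whitney on standardized counts between
single-infected and mixed cultures (Welch t on log₂(count+c) available),
Benjamini–Hochberg adjustment within each organism, classes up/down/ns by
q < α and the sign of the pseudocount-stabilized log₂ fold change
log₂((mean_mixed+c)/(mean_single+c)), c = 0.5. The nonparametric default
matches the rank-based character of the rest of the pipeline.

## Pathway effect models

For each host pathway (genes linked via KEGG ortholog annotation) and each
model condition — symbiont A or B in its single-infected cultures, A or B
in mixed cultures, and both symbionts in mixed cultures — a dbRDA is built
with the pathway's Bray–Curtis distances as response and forward-selected
symbiont genes as predictors (at most 4 terms; candidates prescreened to
the 12 genes most rank-correlated with the first distance axis when the
set is larger). Because every model screens a whole symbiont gene set, the
entry threshold defaults to p < 0.01 with B = 199; at 0.05 spurious
single-gene fits inflate unrelated pathways. A cell holds the final
model's R², 0 when nothing enters; pathways with fewer than two mapped
genes are skipped with a warning. Pathway profiles are clustered by
K-means (10 restarts, fixed seed; k chosen by maximal average silhouette
over 2..8 when not given), reporting within-group sum of squares,
pseudo-F, percent variance explained, and average silhouette.

## Synthetic data generator

The generator emulates the study design above at desk scale (defaults: 60
host / 30 + 30 symbiont genes, 7 replicates, 8 cultures, mean host library
5×10⁶ reads) with negative-binomial counts (gamma–Poisson, var = μ +
φμ², φ = 0.3 — the upper range of biological dispersion across replicate
cultures, chosen so that weak compositional artefacts stay below rank-test
detectability at n = 28). Planted structure, recorded in `GroundTruth`:

- **Read proportions.** Symbiont targets are fixed fractions of the host
  target (5% each; symbiont B multiplied by 0.1 in mixed cultures to
  emulate its 10-fold drop); per-sample depth is log-normal and cancels
  from proportions.
- **Inter-organism correlations.** A shared per-sample latent variate
  (bounded uniform, variance 1) acts on a "responder" subset of each
  organism's genes (65% of symbiont genes; the linked half of host genes)
  with strong positive loadings. Responder baselines are rescaled to 3% of
  the organism's read mass: under the compositional closure imposed by
  fixed library sizes and rarefaction, the non-responders' compensating
  response is proportional to the responders' mass swing, and a small mass
  keeps that compensation below the Spearman significance threshold while
  the responders themselves remain strongly correlated. Gaussian latent
  tails are avoided for the same reason. In mixed samples the latent
  contribution of exactly 90% of symbiont-B responders (the
  `latent_sign_mix` fraction, counted, not Bernoulli-sampled) is negated,
  planting the negative-dominated A↔B edge-sign structure.
- **Differential expression.** Six genes per organism (half up, half down,
  |log₂FC| = 2) shifted in mixed cultures, drawn among non-responders;
  down-gene baselines are rescaled so the up/down mass change cancels,
  leaving non-DE genes' expected shares untouched — otherwise closure
  would make every gene differentially expressed and "observed FDR"
  meaningless.
- **Culture-type shifts.** Per-gene log-normal composition shifts in mixed
  samples with sd 1.0 for symbiont A and 0.0 for symbiont B, reproducing
  the asymmetry in which symbiont A's expression responds strongly to the
  other symbiont's presence while B's bulk expression does not.
- **Pathway structure.** Host responders populate a "linked" half of the
  pathways, the rest receive noise genes, planting a two-cluster pathway
  effect profile.

What the generator does **not** emulate: real annotation sparsity and
pathway overlap (each synthetic gene maps to one pathway); correlation
between the organisms' Shannon diversities (the diversity regression is
implemented and tested on its own oracles, but the generator plants no
such relation); mapping ambiguity between host and symbiont reads;
phylogenetic or genomic structure of any kind; and the absolute scale of
the study (hundreds to thousands of genes per organism). Passing the
planted-recovery tests therefore demonstrates that the statistics recover
the stated signal classes under negative-binomial noise and compositional
closure, not that they would recover them under every real-data pathology.

## Problem sizes and determinism

Tests and the acceptance script run at the desk-scale defaults; null
calibrations use a reduced configuration (30/16/16 genes, 4 replicates)
with ≥ 500 replicates per test. The A↔B edge-sign ratio is reported pooled
over three generated datasets, since the per-dataset ratio of two modest
counts is noisy. Every stochastic component takes an explicit seed; the
pipeline expands one global seed into independent per-stage substreams and
records them, plus input hashes, in its run manifest.

## Known limitations

- Permutation p-values are one-sided (ANOSIM) or two-sided on |rho|
  (correlations); directional one-sided correlation tests are not exposed.
- Robust Aitchison pairs with no shared positive feature are an error
  rather than an imputation; extremely sparse matrices need prefiltering.
- The forward-selection adjusted-R² guard is conservative (see above); for
  pathway models it is replaced by a strict entry threshold and term cap.
- `detect_outliers` implements one defensible rule (Tukey fences); other
  reasonable outlier definitions will flag different gene sets.
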