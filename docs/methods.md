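# Methods

`pathnet` prioritizes biological pathways for a binary case/control
phenotype by combining four kinds of evidence: differential expression,
protein–protein interaction (PPI) support, pathway-level phenotype
association, and GO-based pathway–pathway similarity. This note describes
the model, its parameters and defaults, the numerical choices, what the
synthetic generator does and does not emulate, and the known limitations.

## The procedure

**1. Candidate genes.** Each gene is tested for differential expression
between case and control samples with a Welch two-sample t-test,
p-values adjusted by Benjamini–Hochberg. A gene is differential (DEG) when
q ≤ `q_threshold` (default 0.05) **and** its absolute mean case−control
difference is at least `min_abs_diff` (default 1.0; on log2 intensities this
is a two-fold change). DEGs are then screened through the PPI network: a
DEG is kept as a *candidate* only if at least one PPI edge joins it to
another DEG. This demands that an expression change be corroborated by an
interacting partner that also changed. Candidates are projected onto each
pathway's member list; pathways with no measured candidate are dropped
(the activity score below averages over candidates and is undefined for an
empty set).

**2. Pathway activity and mutual information.** The activity of pathway *t*
in sample *j* is the arithmetic mean expression of its *p* candidate genes,

  a_tj = (Σ_i e_ij) / p.

Each pathway's activity vector over the m samples is discretized into
B = ⌊log2(m) + 1⌋ equal-width bins spanning its own min–max range
(Sturges-style; the maximum falls in the top bin, a constant vector
collapses to one bin), and scored against the binary phenotype by plug-in
mutual information

  S(t) = Σ_x Σ_y p(x,y) log2 [ p(x,y) / (p(x) p(y)) ],

with empirical frequencies and no pseudo-counts. The log base is 2 (bits);
any base rescales all scores by the same factor and leaves the ranking
unchanged. Binning is per-pathway rather than global so that every
pathway's own dynamic range is resolved at the same number of levels;
a side effect is that MI is invariant under positive affine transforms of a
pathway's activity.

**3. Pathway similarity network.** Gene–gene similarity uses Wang's
graph-based GO measure. A term's semantic profile is the set of S-values
over its ancestor closure: S = 1 at the term itself, and each ancestor
receives the maximum over paths of the product of edge contribution
factors (`is_a` 0.8, `part_of` 0.6, configurable in (0,1)). Two terms are
compared by the summed S-values of their shared ancestors divided by their
total semantic values. Term similarities combine to gene level per
namespace by best-match averaging — the mean of (average row maxima,
average column maxima) of the term-similarity matrix — and gene-level
similarity is the arithmetic mean over the namespaces (BP/MF/CC) in which
both genes are annotated; genes with no shared annotated namespace score 0.

Pathway similarity is the sum of similarities over all M·N cross pairs of
the two pathways' candidate genes divided by M + N. This statistic is
deliberately *not* normalized to [0,1]: two identical singleton pathways
score 0.5, and the upper bound is M·N/(M+N), so large coherent pathways can
exceed 1. Because its scale is data-dependent, the edge threshold θ
defaults to the 75th percentile of the off-diagonal similarity distribution
(an absolute θ can be supplied instead). Edges satisfy sim ≥ θ (ties
included); the diagonal is excluded. The network is binary by default; a
weighted mode (w_ij = sim_ij on retained edges) is available behind a flag.

**4. GeneRank.** The per-pathway MI vector, L1-normalized, seeds a damped
random walk on the pathway network:

  r_j ← (1 − d)·ex_j + d·Σ_i w_ij r_i / deg_i,  r⁰ = ex,

iterated until the L1 change between iterations is ≤ ε (default 1e−10) or
`max_iter` (default 1000) is reached. The damping d (default 0.85) trades
the phenotype prior against network diffusion: d = 0 returns the MI
ordering, d → 1 is dominated by similarity structure. Isolated pathways
contribute nothing outward but keep receiving their (1 − d)·ex term, so
they are retained rather than dropped. The fixed point equals the solution
of (I − d·WᵀD⁻¹) r = (1 − d)·ex; with deg ≥ 1 on edges the iteration is a
contraction for d < 1 and the returned r satisfies the fixed-point residual
within 2ε. The final ordering sorts by descending r, ties broken by
descending MI then pathway name; the seed is normalized before iterating so
that rescaling the raw MI vector cannot change the result.

**5. Enrichment significance.** Each retained pathway gets the
hypergeometric upper-tail probability of observing at least x differential
genes in a pathway of M genes, given Nd differential genes in a universe of
U genes. U defaults to the number of genes in the expression matrix (a
fixed genome size can be supplied). M counts *all* pathway members while
the activity score uses only measured candidates — the two statistics
intentionally use different gene universes, since enrichment is a statement
about the annotated pathway, not about what the array measured. p-values
are reported raw (the ranking is by r, the p-value is annotation);
BH adjustment across pathways is available behind a flag.

**6. Evaluation.** The top-ranked pathways are converted into a feature
set: walking pathways in rank order and, within each, candidates by
descending |t|, de-duplicating, until k genes (default 80) are collected.
A linear-kernel SVM (features standardized on each training fold) is scored
by stratified 10-fold cross-validation repeated `repeats` times with
derived seeds, reporting the mean held-out AUC, against a baseline of the
top-k genes by t-test p-value. Stratification prevents degenerate folds
under class imbalance. Since the feature sets are picked on the full data,
these AUCs measure *separability of the selected panel*, not unbiased
generalization — which is why the chance-level check below uses features
chosen independently of the labels.

## Synthetic studies

The generator emulates the statistical structure the method assumes:
marginally Gaussian log-scale expression (already normalized), a planted
mean shift of `effect_size` SDs (default 1.5) added to the member genes of
`n_planted` (default 3) pathways in tumor samples, Bernoulli PPI edges
enriched within pathways (0.3 within vs 0.002 background), and a
three-namespace ontology in which every pathway owns a small clique of
"theme" leaf terms annotated to ~90% of its members plus uniform background
annotations. The themes are the generator's key device: they make genes of
one pathway semantically close under the Wang measure, giving the
similarity network the structure the method exploits. Planted pathways are
drawn disjoint from one another, and background pathways from the remaining
gene pool, so the planted truth is unambiguous; background pathways may
overlap each other. Defaults: 2000 genes, 50 normal + 50 tumor samples,
50 pathways of 10–40 genes.

Deliberately **not** modelled: probe-level noise, batch/platform effects,
heavy-tailed intensity distributions, correlated co-expression outside the
planted shift, realistic GO depth (tens of thousands of terms), and
incomplete/biased annotation. Passing tests on these studies therefore
demonstrate the pipeline's mechanics and its sensitivity to a pathway-level
mean shift under idealized noise — not performance on real microarray
compendia, where normalization and identifier mapping dominate the error
budget. At the default effect size nearly every planted member gene is a
DEG, so retained pathways are mostly the planted ones and the network is
small; the ranking task is correspondingly easier than on real data.

## Numerical choices and degenerate inputs

- Zero-variance genes: t = 0 (and p = 1) when group means agree; a large
  finite sentinel (±1e12, flagged) when they differ, so downstream sorts
  stay finite.
- 0·log 0 terms in MI contribute 0; MI is clipped at 0 against −0.0.
- Hypergeometric tails are computed via the survival function in log space
  (accurate to ~1e−15 deep in the tail, verified against exact rational
  combinatorics up to U = 60).
- Constant activity vectors discretize to a single bin and score MI = 0.
- The percentile θ on very few pathways is a coarse statistic; an absolute
  θ is preferable when fewer than ~10 pathways survive filtering.
- Ties: rank ordering breaks by MI then name; feature harvest breaks |t|
  ties by gene id; the t-test baseline breaks p ties by gene id. All ties
  are broken deterministically so runs are byte-reproducible.

## Problem sizes used in the shipped checks

The test-suite and the acceptance script run the full pipeline on 20
replicate synthetic studies at the default conditions above, carry 5 of
them into the SVM evaluation (10 folds × 3 repeats; the protocol's
historical 100 repeats adds precision to the fold mean but no information
at these effect sizes), and use 2 zero-effect studies for the chance-level
check with 80 label-independent feature genes.

## Known limitations

- Gene identifiers are matched as exact strings; no alias/probe resolution.
- Only binary phenotypes; no paired designs or covariates.
- The plug-in MI estimator is biased upward at small m; with
  B = ⌊log2 m + 1⌋ bins this bias is shared across pathways and mostly
  cancels in the ranking, but absolute MI values should not be compared
  across different m.
- Eq-style pathway similarity grows with pathway size; the percentile θ
  compensates globally but large pathways still connect more easily.
- The evaluation's feature selection precedes cross-validation (as in the
  protocol it follows), so reported AUCs are panel-separability scores,
  not unbiased estimates of out-of-sample accuracy.
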