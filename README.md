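# pathnet

Pathway-network prioritization for case/control gene-expression studies.

Given an expression matrix, binary phenotype labels, a protein–protein
interaction (PPI) network, pathway gene sets (GMT) and Gene Ontology
structure + annotations (OBO/GAF), `pathnet` ranks pathways by how strongly
they associate with the phenotype *and* how central they sit in a network
of functionally similar pathways — then checks the payoff by classifying
samples with genes harvested from the top pathways.

## Who it is for

Computational biologists analyzing tumor-vs-normal (or any two-group)
transcriptomics who want pathway-level candidates that respect three
pieces of context a plain enrichment test ignores: whether differential
genes interact (PPI support), how much a pathway's aggregate activity
carries about the phenotype (mutual information), and which pathways are
functionally related to other implicated pathways (GO similarity +
random-walk diffusion).

## The method

1. **Candidate genes** — Welch t-test with Benjamini–Hochberg control
   (q ≤ 0.05, |Δmean| ≥ 1 by default) gives the DEGs; only DEGs joined by a
   PPI edge to another DEG survive as candidates.
2. **Activity and association** — pathway activity per sample is the mean
   expression of its candidate genes, a_tj = Σ e_ij / p; each activity
   vector is discretized into ⌊log2 m + 1⌋ equal-width bins and scored by
   mutual information S(t) = Σ p(x,y) log2 p(x,y)/(p(x)p(y)) against the
   phenotype.
3. **Pathway network** — gene–gene similarity by Wang's GO measure
   (S-value decay 0.8 is_a / 0.6 part_of, best-match averaging per
   namespace); pathway similarity sim(p_i,p_j) = Σ sim(g_x,g_y)/(M+N) over
   all cross pairs of candidate genes; thresholding at θ (default: 75th
   percentile of off-diagonal similarities) gives a binary network.
4. **GeneRank** — the L1-normalized MI vector ex seeds the damped walk
   r_j ← (1−d) ex_j + d Σ_i w_ij r_i/deg_i (d = 0.85) to a fixed point;
   pathways are ranked by r.
5. **Significance and evaluation** — each pathway gets the hypergeometric
   upper-tail p-value for its differential-gene content; the top pathways
   supply 80 feature genes for a linear SVM scored by repeated stratified
   10-fold cross-validated AUC against a same-size t-test baseline.

A full derivation, parameter table and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

No downloads needed — the package ships a synthetic-study generator whose
defaults plant 3 disease pathways (1.5 SD tumor shift) among 50:

```python
from pathnet.pipeline import analyze
from pathnet.synthetic import SyntheticSpec, generate

bundle = generate(SyntheticSpec(seed=1))
res = analyze(bundle.expression, bundle.phenotype, bundle.pathways,
              bundle.ppi, bundle.ontology, bundle.annotations)
for rank, name in enumerate(res.result.ordering[:3], 1):
    i = res.result.index[name]
    print(rank, name, round(res.result.r[i], 4), f"{res.result.pvalues[i]:.3g}")
```

prints

```
1 PLANTED_02 0.3333 4.06e-37
2 PLANTED_03 0.3333 1.19e-49
3 PLANTED_01 0.05 1.38e-35
```

— the three planted pathways occupy the top three ranks: the first column
is the GeneRank score r (the two network-connected planted pathways share
diffused score; the isolated one keeps only its prior term), and the last
column is the hypergeometric enrichment p-value, astronomically small
because essentially every planted member gene is differential. The
scripts in `examples/` walk through each stage the same way
(`python examples/01_simulate_and_rank.py`, …).

The same pipeline runs from the shell on exported files:

```sh
pathnet simulate --out data --seed 1
pathnet run --expression data/expression.tsv --phenotype data/phenotype.tsv \
    --gene-sets data/pathways.gmt --ppi data/ppi.tsv \
    --ontology data/ontology.obo --annotations data/annotations.gaf \
    --out results --seed 1
```

writing `rank_table.tsv`, `deg_table.tsv`, `activity.tsv`, `similarity.tsv`,
`network_edges.tsv`, `evaluation.json` and a `metadata.json` with every
parameter and stage count. Subcommands `deg`, `activity`, `similarity`,
`rank` stop after the named stage.

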