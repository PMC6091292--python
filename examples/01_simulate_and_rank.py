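"""Simulate a case/control study with planted disease pathways and rank them.

Generates a synthetic expression study (2000 genes, 50 normal + 50 tumor
samples, 50 pathways of which 3 carry a 1.5 SD tumor shift), runs the full
prioritization pipeline in memory, and prints the top of the ranking.
"""

from pathnet.pipeline import analyze
from pathnet.synthetic import SyntheticSpec, generate

bundle = generate(SyntheticSpec(seed=1))
print(f"planted pathways: {bundle.truth_pathways}")

res = analyze(
    bundle.expression,
    bundle.phenotype,
    bundle.pathways,
    bundle.ppi,
    bundle.ontology,
    bundle.annotations,
)

print(f"{len(res.degs.genes)} differential genes, {len(res.cgs)} candidates "
      f"after PPI filtering, {len(res.pcm)} pathways retained")
print(f"pathway network: {res.net.n_edges} edge(s) at theta = {res.theta:.3f}")
print()
print(f"{'rank':>4}  {'pathway':<14} {'MI':>6} {'r':>8} {'p-value':>10}")
for rank, name in enumerate(res.result.ordering[:5], 1):
    i = res.result.index[name]
    print(f"{rank:>4}  {name:<14} {res.result.ex_raw[i]:>6.3f} "
          f"{res.result.r[i]:>8.4f} {res.result.pvalues[i]:>10.3g}")
print()
print("MI is the pathway-phenotype mutual information seeding the walk; r is")
print("the GeneRank score the ranking sorts by; the p-value is the")
print("hypergeometric enrichment of differential genes in the pathway.")
print("All planted pathways should appear at the top with tiny p-values.")
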