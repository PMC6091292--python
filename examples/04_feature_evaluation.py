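"""Classification payoff of the prioritized pathways.

Harvests 80 feature genes from the top-ranked pathways, scores them with a
linear SVM under repeated stratified 10-fold cross-validation, and compares
against the same number of genes picked by a plain t-test ranking.
"""

from pathnet.evaluation import cv_auc, select_feature_genes, ttest_baseline
from pathnet.pipeline import analyze
from pathnet.synthetic import SyntheticSpec, generate

bundle = generate(SyntheticSpec(seed=3))
res = analyze(bundle.expression, bundle.phenotype, bundle.pathways,
              bundle.ppi, bundle.ontology, bundle.annotations)

features = select_feature_genes(res.result, res.pcm, res.degs, k=80)
cv = cv_auc(bundle.expression, bundle.phenotype, features,
            folds=10, repeats=3, seed=3)

baseline = ttest_baseline(bundle.expression, bundle.phenotype, k=80)
cvb = cv_auc(bundle.expression, bundle.phenotype, baseline,
             folds=10, repeats=3, seed=3)

print(f"{len(features)} pathway-derived feature genes "
      f"(from {len(set(p for p, _ in features.provenance))} pathways)")
print(f"method   mean CV AUC: {cv.mean_auc:.3f}")
print(f"baseline mean CV AUC: {cvb.mean_auc:.3f}  (top-80 t-test genes)")
print()
print("AUC is the area under the held-out ROC curve, averaged over")
print("10 folds x 3 repeats; 1.0 = perfect case/control separation, 0.5 =")
print("chance.  With a planted 1.5 SD pathway signal both selectors find")
print("strongly separating genes; the pathway route additionally tells you")
print("WHICH biological processes the classifier is reading.")
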