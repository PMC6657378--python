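"""Rank candidate diseases for a new miRNA from its target genes.

Fits a model on synthetic training data, then scores a new miRNA whose
target genes are taken from one planted factor.  The top-ranked diseases
should be that factor's disease set: the query loads on the matching
component, and the component's disease weights (scaled by its canonical
correlation) propagate to the scores.
"""

import mirscca as m

spec = m.SyntheticSpec(
    n_mirnas=60, n_genes=50, n_diseases=30, n_factors=3,
    mirnas_per_factor=20, genes_per_factor=10, diseases_per_factor=6,
    pi_in=0.9, pi_bg=0.02, seed=5,
)
data = m.generate(spec)
model = m.fit_scca(data.gene, data.disease, m.SCCAConfig(c1=0.4, c2=0.4, K=3))

factor = data.factors[0]
query_genes = sorted(factor["genes"])[:6]
result = m.predict_disease_scores(model, query_genes, "new-mir")

print(f"query targets {len(query_genes)} genes from planted factor 1")
print("top 5 predicted diseases (disease, score, rank):")
for disease, score, rank in result.ranking[:5]:
    marker = "*" if disease in factor["diseases"] else " "
    print(f"  {rank}. {disease}  {score:+.3f} {marker}")
print("(* = disease truly belongs to the same planted factor)")
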