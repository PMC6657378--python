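"""Summarise a dataset: counts, mean degrees, degree histograms.

Generates a synthetic dataset at the scale of curated human miRNA data
(404 miRNAs; the generator defaults are calibrated so the expected number
of target genes and of associated diseases per miRNA lands near 19.8 and
12.7) and prints its statistics.
"""

import mirscca as m
from mirscca.profiles import dataset_statistics

data = m.generate(m.SyntheticSpec(seed=2))
stats = dataset_statistics(data.gene, data.disease)

print(f"miRNAs:                {stats.n_mirnas}")
print(f"genes:                 {stats.n_genes}")
print(f"diseases:              {stats.n_diseases}")
print(f"miRNA-gene edges:      {stats.n_gene_edges}")
print(f"miRNA-disease edges:   {stats.n_disease_edges}")
print(f"mean genes per miRNA:    {stats.mean_genes_per_mirna:.2f}")
print(f"mean diseases per miRNA: {stats.mean_diseases_per_mirna:.2f}")
top = sorted(stats.gene_degree_histogram.items())[-3:]
print(f"highest gene degrees observed: {top}")
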