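import numpy as np
import pytest

import mirscca as m


@pytest.fixture(scope="session")
def small_planted():
    """A small planted-factor dataset with strong, recoverable signal."""
    spec = m.SyntheticSpec(
        n_mirnas=60,
        n_genes=50,
        n_diseases=30,
        n_factors=3,
        mirnas_per_factor=20,
        genes_per_factor=10,
        diseases_per_factor=6,
        pi_in=0.9,
        pi_bg=0.02,
        seed=5,
    )
    return m.generate(spec)


@pytest.fixture(scope="session")
def small_model(small_planted):
    config = m.SCCAConfig(c1=0.45, c2=0.45, K=3)
    return m.fit_scca(small_planted.gene, small_planted.disease, config)


@pytest.fixture()
def toy_edges(tmp_path):
    """Tiny edge-list TSVs on disk: 3 miRNAs, one gene-only miRNA."""
    gene = tmp_path / "gene_edges.tsv"
    gene.write_text(
        "# mirna_id\tgene_id\n"
        "m1\tg1\nm2\tg1\nm2\tg2\nm3\tg9\n",
        encoding="utf-8",
    )
    disease = tmp_path / "disease_edges.tsv"
    disease.write_text("m1\td1\nm2\td1\n", encoding="utf-8")
    return gene, disease


def random_binary_profiles(rng, n, p, q):
    """Random binary X (n x p) and Y (n x q) with a nonzero cross-product."""
    while True:
        X = (rng.random((n, p)) < 0.4).astype(float)
        Y = (rng.random((n, q)) < 0.4).astype(float)
        if np.any(X.T @ Y):
            return X, Y
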