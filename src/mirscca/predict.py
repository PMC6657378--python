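"""Disease scoring for new miRNAs from their target-gene profiles.

A new miRNA arrives with a set of known target genes but no disease
annotation.  Encoding the genes as a binary vector ``x_new`` over the
training gene vocabulary, its disease score vector is the correlation-
weighted back-projection through the fitted canonical components,

    y_new = sum_k  rho_k * (alpha_k^T x_new) * beta_k,

so a query loading strongly on a component's gene set inherits that
component's disease set, scaled by how reliable (rho_k) the component's
gene-disease coupling was on the training data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .scca import SCCAModel

__all__ = ["PredictionResult", "predict_disease_scores", "batch_predict",
           "read_queries", "write_predictions"]

logger = logging.getLogger(__name__)


@dataclass
class PredictionResult:
    """Ranked disease scores for one query miRNA.

    ``scores`` is aligned to the model's disease vocabulary; ``ranking``
    sorts diseases by score descending (ties broken lexicographically by
    disease id) with ranks 1..q.  ``n_unknown_genes`` counts query genes
    absent from the training vocabulary, which are dropped from scoring.
    """

    mirna_id: str
    scores: np.ndarray
    ranking: list[tuple[str, float, int]]
    n_unknown_genes: int


def predict_disease_scores(
    model: SCCAModel, gene_ids_of_query: Iterable[str], mirna_id: str
) -> PredictionResult:
    """Score and rank all candidate diseases for one query miRNA."""
    if not model.components:
        raise ValueError("model has no components")
    query = set(gene_ids_of_query)
    vocab = {g: i for i, g in enumerate(model.gene_ids)}
    known = [g for g in query if g in vocab]
    n_unknown = len(query) - len(known)
    if n_unknown:
        logger.warning(
            "query %s: %d of %d genes absent from training vocabulary",
            mirna_id,
            n_unknown,
            len(query),
        )
    x_new = np.zeros(len(model.gene_ids))
    for g in known:
        x_new[vocab[g]] = 1.0
    if not known:
        logger.warning("query %s shares no genes with the model; scores are zero",
                       mirna_id)
    if model.config.center and model.gene_column_means is not None:
        x_new = x_new - model.gene_column_means
    scores = np.zeros(len(model.disease_ids))
    for comp in model.components:
        scores += comp.rho * float(comp.alpha @ x_new) * comp.beta
    order = sorted(
        range(len(scores)), key=lambda j: (-scores[j], model.disease_ids[j])
    )
    ranking = [
        (model.disease_ids[j], float(scores[j]), rank)
        for rank, j in enumerate(order, start=1)
    ]
    return PredictionResult(
        mirna_id=mirna_id,
        scores=scores,
        ranking=ranking,
        n_unknown_genes=n_unknown,
    )


def batch_predict(
    model: SCCAModel, queries: Sequence[tuple[str, Iterable[str]]]
) -> list[PredictionResult]:
    """Apply :func:`predict_disease_scores` to each (mirna_id, genes) query."""
    ids = [mirna_id for mirna_id, _ in queries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate miRNA ids in query batch")
    return [
        predict_disease_scores(model, genes, mirna_id)
        for mirna_id, genes in queries
    ]


def read_queries(path: str | Path) -> list[tuple[str, list[str]]]:
    """Read a ``mirna_id<TAB>gene_id`` edge list into grouped queries.

    Query order follows first appearance in the file.
    """
    grouped: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(
                    f"{path}: line {lineno}: expected mirna_id<TAB>gene_id"
                )
            grouped.setdefault(parts[0].strip().lower(), []).append(
                parts[1].strip().lower()
            )
    return [(mirna, genes) for mirna, genes in grouped.items()]


def write_predictions(
    results: Sequence[PredictionResult], path: str | Path
) -> None:
    """Write ``mirna_id, disease_id, score, rank`` rows for all queries."""
    lines = ["mirna_id\tdisease_id\tscore\trank"]
    for res in results:
        for disease_id, score, rank in res.ranking:
            lines.append(f"{res.mirna_id}\t{disease_id}\t{score:.10g}\t{rank}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
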