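"""Repeated k-fold cross-validation with ROC/AUC scoring.

miRNAs are split into folds; each fold in turn is held out, the model is
refit on the remaining miRNAs' gene and disease profiles, and every held-out
miRNA's diseases are scored from its gene profile alone.  All
(test miRNA, disease) pairs of a repeat are pooled: held-out known
associations are the positives, every other pair for those miRNAs the
negatives.  Sweeping a threshold delta over the pooled scores yields
TPR = TP/(TP+FN) and FPR = FP/(TN+FP) points; the area under that ROC curve
(trapezoidal, equivalent to the Mann-Whitney rank statistic with mid-rank
tie handling) summarises ranking accuracy.  Repeats re-randomize the fold
assignment; the mean AUC over repeats is the headline number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import ProfileMatrix
from .scca import SCCAConfig, fit_scca
from .predict import predict_disease_scores

__all__ = [
    "FoldPlan",
    "EvaluationReport",
    "make_folds",
    "roc_auc",
    "cross_validate",
    "tune_parameters",
]

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    """Per-repeat assignment of each miRNA to one of n_folds folds."""

    n_folds: int
    repeats: int
    seed: int
    assignments: list[dict[str, int]]

    def test_ids(self, repeat: int, fold: int) -> list[str]:
        return sorted(
            m for m, f in self.assignments[repeat].items() if f == fold
        )

    def train_ids(self, repeat: int, fold: int) -> list[str]:
        return sorted(
            m for m, f in self.assignments[repeat].items() if f != fold
        )


def make_folds(
    mirna_ids: Sequence[str],
    n_folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> FoldPlan:
    """Randomly partition miRNAs into folds of size differing by at most 1.

    Deterministic given ``seed``; repeat r uses the derived seed
    ``seed + r`` so repeats are independent but individually reproducible.
    """
    ids = sorted(set(mirna_ids))
    if len(ids) != len(mirna_ids):
        raise ValueError("duplicate miRNA ids")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if len(ids) < n_folds:
        raise ValueError(f"cannot split {len(ids)} miRNAs into {n_folds} folds")
    assignments: list[dict[str, int]] = []
    for r in range(repeats):
        rng = np.random.default_rng(seed + r)
        perm = rng.permutation(len(ids))
        mapping: dict[str, int] = {}
        for pos, idx in enumerate(perm):
            mapping[ids[idx]] = pos % n_folds
        assignments.append(mapping)
    return FoldPlan(n_folds=n_folds, repeats=repeats, seed=seed,
                    assignments=assignments)


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[list[tuple[float, float, float]], float]:
    """ROC points and trapezoidal AUC from a threshold sweep.

    Thresholds run over the unique scores (descending); tied scores enter a
    point together, which makes the trapezoidal area identical to the
    Mann-Whitney statistic with mid-rank ties.  Returns
    ``([(FPR, TPR, threshold), ...], auc)`` beginning at (0, 0) and ending
    at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain both classes")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # cumulative counts at each distinct-threshold block boundary
    distinct = np.nonzero(np.diff(s))[0]
    block_ends = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[block_ends]
    fp = block_ends + 1 - tp
    tpr = tp / n_pos
    fpr = fp / n_neg
    points = [(0.0, 0.0, float("inf"))]
    points += [
        (float(fpr[i]), float(tpr[i]), float(s[block_ends[i]]))
        for i in range(len(block_ends))
    ]
    xs = np.concatenate([[0.0], fpr])
    ys = np.concatenate([[0.0], tpr])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


@dataclass
class EvaluationReport:
    """Cross-validation outcome: per-repeat AUCs, pooled ROC, confusions."""

    per_repeat_auc: list[float]
    mean_auc: float
    pooled_auc: float
    roc_points: list[tuple[float, float, float]]
    confusion: list[dict[str, float]] = field(default_factory=list)
    n_positives_per_repeat: list[int] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "per_repeat_auc": self.per_repeat_auc,
            "mean_auc": self.mean_auc,
            "pooled_auc": self.pooled_auc,
            "n_positives_per_repeat": self.n_positives_per_repeat,
            "config": self.config,
            "n_roc_points": len(self.roc_points),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    def roc_tsv(self, path: str | Path) -> None:
        lines = ["fpr\ttpr\tthreshold"]
        for fpr, tpr, thr in self.roc_points:
            lines.append(f"{fpr:.10g}\t{tpr:.10g}\t{thr:.10g}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    def plot_roc(self, path: str | Path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        xs = [p[0] for p in self.roc_points]
        ys = [p[1] for p in self.roc_points]
        ax.plot(xs, ys, lw=1.5, label=f"mean AUC = {self.mean_auc:.4f}")
        ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _drop_zero_columns(matrix: ProfileMatrix) -> ProfileMatrix:
    """Remove all-zero columns (features unseen in this training subset)."""
    keep = np.nonzero(matrix.values.sum(axis=0) > 0)[0]
    if len(keep) == len(matrix.col_ids):
        return matrix
    logger.warning(
        "dropping %d all-zero training columns", len(matrix.col_ids) - len(keep)
    )
    return ProfileMatrix(
        values=matrix.values[:, keep],
        row_ids=matrix.row_ids,
        col_ids=tuple(matrix.col_ids[j] for j in keep),
    )


def _subset_rows(matrix: ProfileMatrix, ids: Sequence[str]) -> ProfileMatrix:
    index = {m: i for i, m in enumerate(matrix.row_ids)}
    rows = [index[m] for m in ids]
    return ProfileMatrix(
        values=matrix.values[rows],
        row_ids=tuple(ids),
        col_ids=matrix.col_ids,
    )


def cross_validate(
    gene: ProfileMatrix,
    disease: ProfileMatrix,
    config: SCCAConfig,
    plan: FoldPlan,
) -> EvaluationReport:
    """Run the repeated hold-out protocol and pool ROC/AUC per repeat.

    Each fold's model is trained on the remaining miRNAs' rows of both
    matrices (all-zero columns dropped for that fold); each test miRNA is
    then scored from its gene profile only, so its disease annotations never
    reach training.  Positives are the held-out known associations over the
    full disease vocabulary; negatives are all other (test miRNA, disease)
    pairs.
    """
    if gene.row_ids != disease.row_ids:
        raise ValueError("gene and disease matrices must share rows")
    disease_index = {d: j for j, d in enumerate(disease.col_ids)}
    per_repeat_auc: list[float] = []
    n_pos_per_repeat: list[int] = []
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for r in range(plan.repeats):
        rep_scores: list[np.ndarray] = []
        rep_labels: list[np.ndarray] = []
        for fold in range(plan.n_folds):
            train_ids = plan.train_ids(r, fold)
            test_ids = plan.test_ids(r, fold)
            train_gene = _drop_zero_columns(_subset_rows(gene, train_ids))
            train_disease = _drop_zero_columns(_subset_rows(disease, train_ids))
            model = fit_scca(train_gene, train_disease, config)
            gene_cols = np.array(gene.col_ids)
            for mirna in test_ids:
                profile_row = gene.values[gene.row_ids.index(mirna)]
                query_genes = gene_cols[profile_row > 0].tolist()
                result = predict_disease_scores(model, query_genes, mirna)
                # scatter the fold-local scores back onto the full vocabulary
                full = np.zeros(len(disease.col_ids))
                for j, dis in enumerate(model.disease_ids):
                    full[disease_index[dis]] = result.scores[j]
                rep_scores.append(full)
                rep_labels.append(disease.values[disease.row_ids.index(mirna)])
        scores = np.concatenate(rep_scores)
        labels = np.concatenate(rep_labels)
        _, auc = roc_auc(scores, labels)
        per_repeat_auc.append(auc)
        n_pos_per_repeat.append(int(labels.sum()))
        all_scores.append(scores)
        all_labels.append(labels)
    pooled_scores = np.concatenate(all_scores)
    pooled_labels = np.concatenate(all_labels)
    roc_points, pooled_auc = roc_auc(pooled_scores, pooled_labels)
    confusion = [
        {
            "threshold": thr,
            "TP": tpr * int(pooled_labels.sum()),
            "FP": fpr * int(len(pooled_labels) - pooled_labels.sum()),
        }
        for fpr, tpr, thr in roc_points
    ]
    return EvaluationReport(
        per_repeat_auc=per_repeat_auc,
        mean_auc=float(np.mean(per_repeat_auc)),
        pooled_auc=pooled_auc,
        roc_points=roc_points,
        confusion=confusion,
        n_positives_per_repeat=n_pos_per_repeat,
        config={
            "c1": config.c1,
            "c2": config.c2,
            "K": config.K,
            "center": config.center,
            "n_folds": plan.n_folds,
            "repeats": plan.repeats,
            "seed": plan.seed,
        },
    )


def tune_parameters(
    gene: ProfileMatrix,
    disease: ProfileMatrix,
    grid: Sequence[tuple[float, float, int]],
    plan: FoldPlan,
    center: bool = False,
) -> pd.DataFrame:
    """Exhaustively cross-validate every (c1, c2, K) grid point.

    Returns a table with one row per grid point, its mean AUC, and a
    ``best`` flag on the highest mean AUC (first row on ties).
    """
    if not grid:
        raise ValueError("empty parameter grid")
    rows = []
    for c1, c2, K in grid:
        config = SCCAConfig(c1=c1, c2=c2, K=K, center=center)
        report = cross_validate(gene, disease, config, plan)
        rows.append({"c1": c1, "c2": c2, "K": K, "mean_auc": report.mean_auc})
        logger.info("grid point c1=%g c2=%g K=%d -> mean AUC %.4f",
                    c1, c2, K, report.mean_auc)
    table = pd.DataFrame(rows)
    table["best"] = False
    table.loc[table["mean_auc"].idxmax(), "best"] = True
    return table
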