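"""Binary interaction profiles for miRNAs.

A miRNA is described by two binary vectors: a target-gene profile
``t = (t_1, ..., t_p)`` marking which genes it is experimentally known to
target, and a disease profile ``d = (d_1, ..., d_q)`` marking which diseases
it has been associated with.  Stacking the profiles of ``n`` miRNAs gives two
incidence matrices ``X`` (n x p) and ``Y`` (n x q) whose rows are aligned on
a shared miRNA universe.  This module reads tab-separated edge lists, merges
identifier synonyms, and encodes the matrices.

Only miRNAs that appear in *both* edge lists are retained: a miRNA with no
disease annotation (or no target-gene annotation) carries no cross-view
signal and cannot participate in canonical correlation.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "EdgeList",
    "ProfileMatrix",
    "DatasetStats",
    "read_edge_list",
    "read_synonym_map",
    "make_normalizer",
    "build_profiles",
    "dataset_statistics",
]


class EdgeListError(ValueError):
    """Malformed or empty edge-list input."""


def default_normalizer(identifier: str) -> str:
    """Lowercase and strip surrounding whitespace."""
    return identifier.strip().lower()


def strip_copy_suffix(mirna_id: str) -> str:
    """Collapse precursor copies (``mir-21-1``, ``mir-21-2``) to one mature id.

    Many miRNA genes exist in several genomic copies producing the same mature
    miRNA; databases list them with a trailing ``-1``/``-2``/... suffix.  This
    helper strips a single trailing ``-<digits>`` group when the remaining stem
    still contains a digit (so ``mir-21-1`` -> ``mir-21`` but ``mir-1`` is left
    alone).
    """
    mirna_id = default_normalizer(mirna_id)
    stem, sep, tail = mirna_id.rpartition("-")
    if sep and tail.isdigit() and any(ch.isdigit() for ch in stem):
        return stem
    return mirna_id


def read_synonym_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``alias<TAB>canonical`` mapping file."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise EdgeListError(
                    f"{path}: line {lineno}: expected alias<TAB>canonical"
                )
            mapping[default_normalizer(parts[0])] = default_normalizer(parts[1])
    return mapping


def make_normalizer(
    synonyms: dict[str, str] | None = None,
    collapse_copies: bool = False,
) -> Callable[[str], str]:
    """Compose an identifier normalizer.

    Lowercase/trim always applies; ``synonyms`` maps aliases to canonical
    names afterwards; ``collapse_copies`` additionally strips precursor-copy
    suffixes (intended for miRNA ids only).
    """

    def normalize(identifier: str) -> str:
        out = default_normalizer(identifier)
        if collapse_copies:
            out = strip_copy_suffix(out)
        if synonyms:
            out = synonyms.get(out, out)
        return out

    return normalize


@dataclass(frozen=True)
class EdgeList:
    """De-duplicated (miRNA, feature) pairs of one kind (gene or disease)."""

    pairs: tuple[tuple[str, str], ...]
    kind: Literal["gene", "disease"]

    def __post_init__(self) -> None:
        seen = set(self.pairs)
        if len(seen) != len(self.pairs):
            raise EdgeListError("duplicate pairs in EdgeList")
        for src, dst in self.pairs:
            if not src or not dst:
                raise EdgeListError("empty identifier in EdgeList")

    @property
    def mirnas(self) -> set[str]:
        return {src for src, _ in self.pairs}

    @property
    def features(self) -> set[str]:
        return {dst for _, dst in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


def read_edge_list(
    path: str | Path,
    kind: Literal["gene", "disease"],
    id_normalizer: Callable[[str], str] | None = None,
    feature_normalizer: Callable[[str], str] | None = None,
) -> EdgeList:
    """Read a ``mirna_id<TAB>feature_id`` file into a de-duplicated EdgeList.

    Lines starting with ``#`` and blank lines are skipped.  ``id_normalizer``
    is applied to the miRNA column and ``feature_normalizer`` to the feature
    column; both default to lowercase+trim.  Records that become identical
    after normalization are kept only once.
    """
    if id_normalizer is None:
        id_normalizer = default_normalizer
    if feature_normalizer is None:
        feature_normalizer = default_normalizer
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_lines = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            n_lines += 1
            parts = [p for p in line.split("\t")]
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise EdgeListError(
                    f"{path}: line {lineno}: expected mirna_id<TAB>feature_id"
                )
            pair = (id_normalizer(parts[0]), feature_normalizer(parts[1]))
            if not pair[0] or not pair[1]:
                raise EdgeListError(
                    f"{path}: line {lineno}: identifier empty after normalization"
                )
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    if n_lines == 0:
        raise EdgeListError(f"{path}: no data lines")
    return EdgeList(pairs=tuple(pairs), kind=kind)


def edge_list_from_pairs(
    pairs: Iterable[tuple[str, str]], kind: Literal["gene", "disease"]
) -> EdgeList:
    """Build an EdgeList in memory, de-duplicating while preserving order."""
    out: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for pair in pairs:
        if pair not in seen:
            seen.add(pair)
            out.append(pair)
    return EdgeList(pairs=tuple(out), kind=kind)


@dataclass
class ProfileMatrix:
    """Binary incidence matrix with labelled rows (miRNAs) and columns."""

    values: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = tuple(self.row_ids)
        self.col_ids = tuple(self.col_ids)
        if self.values.ndim != 2:
            raise ValueError("profile matrix must be 2-D")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("matrix shape does not match id lists")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row ids")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError("duplicate column ids")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("profile entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, mirna_id: str) -> np.ndarray:
        return self.values[self.row_ids.index(mirna_id)]

    def to_edge_pairs(self) -> list[tuple[str, str]]:
        """Emit the (miRNA, feature) pairs encoded by the 1-entries."""
        rows, cols = np.nonzero(self.values)
        return [(self.row_ids[i], self.col_ids[j]) for i, j in zip(rows, cols)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_ids), columns=list(self.col_ids)
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="mirna_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            values=frame.to_numpy(dtype=float),
            row_ids=tuple(str(i) for i in frame.index),
            col_ids=tuple(str(c) for c in frame.columns),
        )


def build_profiles(
    gene_edges: EdgeList, disease_edges: EdgeList
) -> tuple[ProfileMatrix, ProfileMatrix]:
    """Encode aligned gene and disease profile matrices.

    The miRNA universe is the intersection of miRNAs present in both edge
    lists; feature universes are the genes/diseases incident to that universe.
    Rows and columns are sorted lexicographically so the encoding is
    deterministic.
    """
    if not gene_edges.pairs or not disease_edges.pairs:
        raise EdgeListError("edge lists must be non-empty")
    shared = gene_edges.mirnas & disease_edges.mirnas
    if not shared:
        raise EdgeListError("no miRNA has both a gene profile and a disease profile")
    row_ids = tuple(sorted(shared))
    row_index = {m: i for i, m in enumerate(row_ids)}

    def encode(edges: EdgeList) -> ProfileMatrix:
        kept = [(m, f) for m, f in edges.pairs if m in row_index]
        col_ids = tuple(sorted({f for _, f in kept}))
        col_index = {f: j for j, f in enumerate(col_ids)}
        values = np.zeros((len(row_ids), len(col_ids)))
        for m, f in kept:
            values[row_index[m], col_index[f]] = 1.0
        return ProfileMatrix(values=values, row_ids=row_ids, col_ids=col_ids)

    return encode(gene_edges), encode(disease_edges)


@dataclass
class DatasetStats:
    """Headline counts and per-miRNA degree summaries for one dataset."""

    n_mirnas: int
    n_genes: int
    n_diseases: int
    n_gene_edges: int
    n_disease_edges: int
    mean_genes_per_mirna: float
    mean_diseases_per_mirna: float
    gene_degree_histogram: dict[int, int] = field(default_factory=dict)
    disease_degree_histogram: dict[int, int] = field(default_factory=dict)

    def rounded(self) -> dict[str, float]:
        """One-decimal rendering of the two means, as usually reported."""
        return {
            "mean_genes_per_mirna": round(self.mean_genes_per_mirna, 1),
            "mean_diseases_per_mirna": round(self.mean_diseases_per_mirna, 1),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_mirnas": self.n_mirnas,
            "n_genes": self.n_genes,
            "n_diseases": self.n_diseases,
            "n_gene_edges": self.n_gene_edges,
            "n_disease_edges": self.n_disease_edges,
            "mean_genes_per_mirna": self.mean_genes_per_mirna,
            "mean_diseases_per_mirna": self.mean_diseases_per_mirna,
            "mean_genes_per_mirna_1dp": round(self.mean_genes_per_mirna, 1),
            "mean_diseases_per_mirna_1dp": round(self.mean_diseases_per_mirna, 1),
            "gene_degree_histogram": {
                str(k): v for k, v in sorted(self.gene_degree_histogram.items())
            },
            "disease_degree_histogram": {
                str(k): v for k, v in sorted(self.disease_degree_histogram.items())
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def dataset_statistics(gene: ProfileMatrix, disease: ProfileMatrix) -> DatasetStats:
    """Count miRNAs, features and edges, and summarise degree distributions."""
    if gene.row_ids != disease.row_ids:
        raise ValueError("gene and disease matrices must share row ids")
    n = len(gene.row_ids)
    gene_deg = gene.values.sum(axis=1).astype(int)
    dis_deg = disease.values.sum(axis=1).astype(int)
    n_gene_edges = int(gene_deg.sum())
    n_dis_edges = int(dis_deg.sum())
    return DatasetStats(
        n_mirnas=n,
        n_genes=len(gene.col_ids),
        n_diseases=len(disease.col_ids),
        n_gene_edges=n_gene_edges,
        n_disease_edges=n_dis_edges,
        mean_genes_per_mirna=n_gene_edges / n,
        mean_diseases_per_mirna=n_dis_edges / n,
        gene_degree_histogram=dict(Counter(gene_deg.tolist())),
        disease_degree_histogram=dict(Counter(dis_deg.tolist())),
    )
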