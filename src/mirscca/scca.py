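"""Sparse canonical correlation analysis by penalized matrix decomposition.

Given aligned binary profile matrices ``X`` (n miRNAs x p genes) and ``Y``
(n miRNAs x q diseases), we seek sparse weight vectors maximizing

    alpha^T X^T Y beta   subject to   ||alpha||_2 <= 1, ||beta||_2 <= 1,
                                      ||alpha||_1 <= c1 sqrt(p),
                                      ||beta||_1  <= c2 sqrt(q).

The problem is solved on the cross-product matrix ``Z = X^T Y`` by an
alternating rank-1 penalized matrix decomposition: with one side fixed, the
other side's optimum is a soft-thresholded, L2-normalized image of ``Z``
(or ``Z^T``) with the threshold chosen by bisection so the L1 constraint
holds.  Successive component pairs are obtained by deflation,

    Z^(k+1) = Z^k - d_k alpha_k beta_k^T,   d_k = alpha_k^T Z^k beta_k.

With non-binding L1 bounds (c1 = c2 = 1) the procedure reduces to the
singular value decomposition of ``Z``.  Each component additionally records
the canonical correlation rho_k = corr(X alpha_k, Y beta_k) of the training
canonical variates, used later for prediction.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .profiles import ProfileMatrix

__all__ = [
    "SCCAConfig",
    "CanonicalComponent",
    "SCCAModel",
    "soft_threshold",
    "effective_l1_bound",
    "l1_unit_vector",
    "pmd_rank1",
    "pmd_decompose",
    "fit_scca",
    "canonical_correlation",
    "extract_correlated_sets",
]

logger = logging.getLogger(__name__)

#: tolerance below which a weight or inner product counts as zero
_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class SCCAConfig:
    """Hyper-parameters of the sparse CCA fit.

    ``c1``/``c2`` are sparsity fractions: the gene-side L1 budget is
    ``c1 * sqrt(p)`` (clamped to the feasible interval, see
    :func:`effective_l1_bound`) and likewise for diseases.  ``K`` is the
    number of component pairs extracted by deflation.  ``center`` column-
    centers X and Y before forming Z (off by default: on raw binary profiles
    Z is an interpretable co-occurrence count matrix).
    """

    c1: float = 0.01
    c2: float = 0.01
    K: int = 60
    center: bool = False
    max_iter: int = 1000
    tol: float = 1e-6
    seed: int = 0
    n_starts: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.c1 <= 1 and 0 < self.c2 <= 1):
            raise ValueError("c1 and c2 must lie in (0, 1]")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class CanonicalComponent:
    """One extracted pair of sparse weight vectors.

    ``alpha`` weights genes, ``beta`` weights diseases, ``d`` is the
    singular value of the deflation step and ``rho`` the canonical
    correlation of the training variates.  ``gene_set``/``disease_set`` list
    the nonzero-weight features sorted by |weight| descending (ties broken
    lexicographically by id); ``contributing_mirnas`` are the training
    miRNAs whose gene profile overlaps alpha AND disease profile overlaps
    beta.
    """

    alpha: np.ndarray
    beta: np.ndarray
    d: float
    rho: float
    gene_set: list[tuple[str, float]] = field(default_factory=list)
    disease_set: list[tuple[str, float]] = field(default_factory=list)
    contributing_mirnas: list[str] = field(default_factory=list)


@dataclass
class SCCAModel:
    """Ordered canonical components plus the vocabularies needed to predict."""

    components: list[CanonicalComponent]
    gene_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    config: SCCAConfig
    gene_column_means: np.ndarray | None = None
    disease_column_means: np.ndarray | None = None

    @property
    def K(self) -> int:
        return len(self.components)

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize to JSON with sparse weight lists; bit-exact round-trip."""

        def sparse(vec: np.ndarray) -> list[list]:
            idx = np.nonzero(vec)[0]
            return [[int(i), float(vec[i]).hex()] for i in idx]

        payload = {
            "gene_ids": list(self.gene_ids),
            "disease_ids": list(self.disease_ids),
            "config": asdict(self.config),
            "gene_column_means": (
                None
                if self.gene_column_means is None
                else [float(v).hex() for v in self.gene_column_means]
            ),
            "disease_column_means": (
                None
                if self.disease_column_means is None
                else [float(v).hex() for v in self.disease_column_means]
            ),
            "components": [
                {
                    "alpha": sparse(c.alpha),
                    "beta": sparse(c.beta),
                    "d": float(c.d).hex(),
                    "rho": float(c.rho).hex(),
                    "contributing_mirnas": c.contributing_mirnas,
                }
                for c in self.components
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SCCAModel":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = source
        payload = json.loads(text)
        gene_ids = tuple(payload["gene_ids"])
        disease_ids = tuple(payload["disease_ids"])
        config = SCCAConfig(**payload["config"])

        def dense(entries: list[list], size: int) -> np.ndarray:
            vec = np.zeros(size)
            for i, hexval in entries:
                vec[i] = float.fromhex(hexval)
            return vec

        components = []
        for comp in payload["components"]:
            alpha = dense(comp["alpha"], len(gene_ids))
            beta = dense(comp["beta"], len(disease_ids))
            component = CanonicalComponent(
                alpha=alpha,
                beta=beta,
                d=float.fromhex(comp["d"]),
                rho=float.fromhex(comp["rho"]),
                contributing_mirnas=list(comp["contributing_mirnas"]),
            )
            component.gene_set = _weight_set(alpha, gene_ids)
            component.disease_set = _weight_set(beta, disease_ids)
            components.append(component)
        gmeans = payload["gene_column_means"]
        dmeans = payload["disease_column_means"]
        return cls(
            components=components,
            gene_ids=gene_ids,
            disease_ids=disease_ids,
            config=config,
            gene_column_means=(
                None if gmeans is None else np.array([float.fromhex(v) for v in gmeans])
            ),
            disease_column_means=(
                None if dmeans is None else np.array([float.fromhex(v) for v in dmeans])
            ),
        )

    def component_report(self, path: str | Path) -> None:
        """Write a TSV listing each component's member genes, diseases and miRNAs."""
        lines = ["component\tside\tfeature_id\tweight"]
        for k, comp in enumerate(self.components, start=1):
            for gene, w in comp.gene_set:
                lines.append(f"{k}\tgene\t{gene}\t{w:.10g}")
            for dis, w in comp.disease_set:
                lines.append(f"{k}\tdisease\t{dis}\t{w:.10g}")
            for mirna in comp.contributing_mirnas:
                lines.append(f"{k}\tmirna\t{mirna}\t")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def soft_threshold(z: np.ndarray, delta: float) -> np.ndarray:
    """Componentwise ``sign(z) * max(|z| - delta, 0)``."""
    if delta < 0:
        raise ValueError("soft-threshold level must be nonnegative")
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.maximum(np.abs(z) - delta, 0.0)


def effective_l1_bound(c: float, m: int) -> float:
    """Feasible L1 budget for an m-dimensional unit vector.

    Any L2-unit vector satisfies ``1 <= ||u||_1 <= sqrt(m)``, so the nominal
    budget ``c * sqrt(m)`` is clamped to ``[1, sqrt(m)]``.  A nominal budget
    below 1 (e.g. very small ``c`` at large ``m``) is infeasible as written
    and is clamped up to 1, which selects maximally sparse components; the
    clamp is logged.
    """
    nominal = c * math.sqrt(m)
    bound = min(max(nominal, 1.0), math.sqrt(m))
    if nominal < 1.0:
        logger.warning(
            "L1 budget %.4g = c*sqrt(%d) below the feasible minimum 1; "
            "clamped to 1 (maximally sparse)",
            nominal,
            m,
        )
    return bound


def l1_unit_vector(a: np.ndarray, bound: float) -> np.ndarray:
    """L2-normalized soft-thresholding of ``a`` meeting an L1 budget.

    Returns ``u = S(a, delta*) / ||S(a, delta*)||_2`` where ``delta*`` is the
    smallest threshold (found by bisection) such that ``||u||_1 <= bound``.
    If the untresholded normalization already meets the budget it is
    returned unchanged.  When equal-magnitude leading entries make the budget
    unattainable (the achievable minimum L1 is sqrt(#ties)), the tie-limit
    vector is returned with a warning.
    """
    a = np.asarray(a, dtype=float)
    if bound < 1:
        raise ValueError("L1 bound below 1 is infeasible for a unit vector")
    norm = np.linalg.norm(a)
    if norm <= _ZERO_TOL:
        raise ValueError("cannot normalize an all-zero vector")
    u = a / norm
    if np.abs(u).sum() <= bound + 1e-10:
        return u
    lo, hi = 0.0, float(np.abs(a).max())
    for _ in range(150):
        mid = 0.5 * (lo + hi)
        s = soft_threshold(a, mid)
        snorm = np.linalg.norm(s)
        if snorm <= _ZERO_TOL or np.abs(s).sum() / snorm > bound:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    s = soft_threshold(a, hi)
    snorm = np.linalg.norm(s)
    if snorm <= _ZERO_TOL:
        # hi shrank everything: fall back to the tie-limit vector over argmax
        amax = np.abs(a).max()
        mask = np.abs(a) >= amax - 1e-12
        s = np.where(mask, np.sign(a), 0.0)
        snorm = np.linalg.norm(s)
    u = s / snorm
    l1 = np.abs(u).sum()
    if l1 > bound + 1e-6:
        warnings.warn(
            f"L1 bound {bound:.4g} unattainable (tied leading magnitudes); "
            f"returning limit vector with L1 = {l1:.4g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return u


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Resolve the sign ambiguity of a direction vector for reproducibility."""
    j = int(np.argmax(np.abs(v)))
    return -v if v[j] < 0 else v


def _initial_betas(Z: np.ndarray, bound2: float, n_starts: int) -> list[np.ndarray]:
    """Deterministic multi-start candidates for the beta iterate.

    The leading right singular vectors of ``Z`` are the natural starts (with
    non-binding budgets the first one is already the optimum).  When the L1
    budget binds, sparse optima may not lie near the leading singular
    subspace, so the coordinate axes of the largest-norm columns are added.
    """
    q = Z.shape[1]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    starts = [_fix_sign(vt[i]) for i in range(min(n_starts, vt.shape[0]))]
    if bound2 < math.sqrt(q) - 1e-9:
        col_norms = np.linalg.norm(Z, axis=0)
        for j in np.argsort(-col_norms)[:n_starts]:
            axis = np.zeros(q)
            axis[j] = 1.0
            starts.append(axis)
    return starts


def _alternate(
    Z: np.ndarray,
    beta0: np.ndarray,
    bound1: float,
    bound2: float,
    config: SCCAConfig,
) -> tuple[np.ndarray, np.ndarray, bool]:
    beta = beta0
    alpha = l1_unit_vector(Z @ beta, bound1)
    for _ in range(config.max_iter):
        alpha_old, beta_old = alpha, beta
        beta = l1_unit_vector(Z.T @ alpha, bound2)
        alpha = l1_unit_vector(Z @ beta, bound1)
        change = max(
            float(np.abs(alpha - alpha_old).max(initial=0.0)),
            float(np.abs(beta - beta_old).max(initial=0.0)),
        )
        if change < config.tol:
            return alpha, beta, True
    return alpha, beta, False


def pmd_rank1(
    Z: np.ndarray,
    bound1: float,
    bound2: float,
    config: SCCAConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Penalized rank-1 decomposition of ``Z`` by alternating updates.

    Maximizes ``alpha^T Z beta`` over unit vectors with L1 budgets ``bound1``
    (rows of Z, gene side) and ``bound2`` (columns, disease side).  With one
    side fixed, the other side's optimum is the soft-thresholded, normalized
    image of ``Z``; the two closed-form updates alternate until the largest
    componentwise change falls below ``config.tol``.  Because the objective
    is non-convex under binding budgets, a small set of deterministic starts
    (leading right singular vectors, plus dominant coordinate axes when the
    budget binds) is tried and the best objective kept.  Returns
    ``(alpha, beta, d)`` with ``d = alpha^T Z beta >= 0``.
    """
    if config is None:
        config = SCCAConfig()
    Z = np.asarray(Z, dtype=float)
    if not np.any(Z):
        raise ValueError("cannot decompose an all-zero matrix")
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    any_converged = False
    for beta0 in _initial_betas(Z, bound2, config.n_starts):
        if np.linalg.norm(Z @ beta0) <= _ZERO_TOL:
            continue  # start lies in the null space (rank-deficient Z)
        alpha, beta, converged = _alternate(Z, beta0, bound1, bound2, config)
        any_converged = any_converged or converged
        d = float(alpha @ Z @ beta)
        if d < 0:  # flip jointly so the singular value is nonnegative
            beta, d = -beta, -d
        if best is None or d > best[2] + 1e-12:
            best = (alpha, beta, d)
    if not any_converged:
        warnings.warn(
            "penalized rank-1 decomposition did not converge within "
            f"{config.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return best


def _apply_sign_convention(alpha: np.ndarray, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip (alpha, beta) jointly so alpha's largest-|weight| entry is positive."""
    j = int(np.argmax(np.abs(alpha)))
    if alpha[j] < 0:
        return -alpha, -beta
    return alpha, beta


def pmd_decompose(
    Z: np.ndarray,
    bound1: float,
    bound2: float,
    K: int,
    config: SCCAConfig | None = None,
) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Extract up to ``K`` penalized rank-1 triples from ``Z`` by deflation.

    Stops early when the deflated residual is numerically zero; the sign
    convention of :func:`_apply_sign_convention` is applied to every triple.
    """
    if config is None:
        config = SCCAConfig()
    Zk = np.asarray(Z, dtype=float).copy()
    triples: list[tuple[np.ndarray, np.ndarray, float]] = []
    for k in range(K):
        if np.linalg.norm(Zk) < config.tol:
            warnings.warn(
                f"residual numerically zero after {k} components; "
                f"truncating K from {K} to {k}",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        alpha, beta, d = pmd_rank1(Zk, bound1, bound2, config)
        alpha, beta = _apply_sign_convention(alpha, beta)
        triples.append((alpha, beta, d))
        Zk = Zk - d * np.outer(alpha, beta)
    return triples


def canonical_correlation(
    X: np.ndarray | ProfileMatrix,
    Y: np.ndarray | ProfileMatrix,
    alpha: np.ndarray,
    beta: np.ndarray,
) -> float:
    """Pearson correlation of the canonical variates u = X alpha, v = Y beta.

    Both variates are centered before correlating.  Returns 0 when either
    variate has zero variance (degenerate rule).
    """
    Xv = X.values if isinstance(X, ProfileMatrix) else np.asarray(X, dtype=float)
    Yv = Y.values if isinstance(Y, ProfileMatrix) else np.asarray(Y, dtype=float)
    u = Xv @ np.asarray(alpha, dtype=float)
    v = Yv @ np.asarray(beta, dtype=float)
    u = u - u.mean()
    v = v - v.mean()
    su = np.linalg.norm(u)
    sv = np.linalg.norm(v)
    if su <= _ZERO_TOL or sv <= _ZERO_TOL:
        return 0.0
    return float(u @ v / (su * sv))


def _weight_set(
    vec: np.ndarray, ids: Sequence[str]
) -> list[tuple[str, float]]:
    """Nonzero-weight features sorted by |weight| desc, ties lexicographic."""
    entries = [
        (ids[i], float(vec[i])) for i in np.nonzero(np.abs(vec) > _ZERO_TOL)[0]
    ]
    entries.sort(key=lambda item: (-abs(item[1]), item[0]))
    return entries


def fit_scca(X: ProfileMatrix, Y: ProfileMatrix, config: SCCAConfig) -> SCCAModel:
    """Fit K sparse canonical component pairs on aligned profile matrices.

    Forms ``Z = X^T Y`` (column-centering X and Y first iff
    ``config.center``), extracts up to K penalized rank-1 triples by
    deflation, and records for each component its training canonical
    correlation, its named nonzero-weight gene/disease sets, and the
    contributing miRNAs (training rows overlapping both weight vectors).
    """
    if X.row_ids != Y.row_ids:
        raise ValueError("X and Y must share the same miRNA rows in the same order")
    Xv, Yv = X.values, Y.values
    gene_means = disease_means = None
    if config.center:
        gene_means = Xv.mean(axis=0)
        disease_means = Yv.mean(axis=0)
        Xv = Xv - gene_means
        Yv = Yv - disease_means
    Z1 = Xv.T @ Yv
    bound1 = effective_l1_bound(config.c1, len(X.col_ids))
    bound2 = effective_l1_bound(config.c2, len(Y.col_ids))
    triples = pmd_decompose(Z1, bound1, bound2, config.K, config)
    components: list[CanonicalComponent] = []
    for alpha, beta, d in triples:
        rho = canonical_correlation(X, Y, alpha, beta)
        contributing = [
            X.row_ids[i]
            for i in range(len(X.row_ids))
            if abs(X.values[i] @ alpha) > _ZERO_TOL
            and abs(Y.values[i] @ beta) > _ZERO_TOL
        ]
        components.append(
            CanonicalComponent(
                alpha=alpha,
                beta=beta,
                d=d,
                rho=rho,
                gene_set=_weight_set(alpha, X.col_ids),
                disease_set=_weight_set(beta, Y.col_ids),
                contributing_mirnas=contributing,
            )
        )
    return SCCAModel(
        components=components,
        gene_ids=X.col_ids,
        disease_ids=Y.col_ids,
        config=config,
        gene_column_means=gene_means,
        disease_column_means=disease_means,
    )


def extract_correlated_sets(
    model: SCCAModel, k: int
) -> tuple[list[tuple[str, float]], list[tuple[str, float]], list[str]]:
    """Return the k-th (1-based) component's correlated sets.

    The gene set and disease set are the nonzero-weight features ordered by
    |weight| descending; contributing miRNAs are the training rows whose
    gene profile overlaps alpha AND disease profile overlaps beta.
    """
    if not 1 <= k <= len(model.components):
        raise IndexError(
            f"component index {k} out of range 1..{len(model.components)}"
        )
    comp = model.components[k - 1]
    return comp.gene_set, comp.disease_set, comp.contributing_mirnas
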