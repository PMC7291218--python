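"""Signed weighted co-expression network construction.

The network is built WGCNA-style: pairwise gene-gene correlation, the signed
adjacency transform a_ij = ((1 + r_ij)/2)^beta (so r = -1 maps to 0 and
r = +1 maps to 1), soft-threshold power selection by the scale-free topology
fit, and the topological overlap matrix (TOM)

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,

whose dissimilarity 1 - omega is the clustering input downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from braincoex.expression_io import ExpressionMatrix, ValidationError


@dataclass
class CorrelationMatrix:
    gene_ids: np.ndarray
    values: np.ndarray  # symmetric, unit diagonal, entries in [-1, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValidationError("correlation matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("correlation matrix is not symmetric")


@dataclass
class AdjacencyMatrix:
    gene_ids: np.ndarray
    values: np.ndarray  # symmetric, entries in [0, 1], unit diagonal
    beta: int


@dataclass
class TOMMatrix:
    gene_ids: np.ndarray
    values: np.ndarray  # symmetric, entries in [0, 1], unit diagonal

    def dissimilarity(self) -> np.ndarray:
        """1 - TOM, with an exactly-zero diagonal."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class ScaleFreeFit:
    """Goodness of the scale-free topology fit at one candidate power.

    ``r_squared`` is the R² of the regression of log10 p(k) on log10 k over
    non-empty connectivity bins; a scale-free network has a high R² with a
    negative slope.
    """

    beta: int
    r_squared: float
    slope: float


def pairwise_correlation(
    expr: ExpressionMatrix, method: str = "pearson"
) -> CorrelationMatrix:
    """All-pairs gene-gene correlation across samples.

    Genes with zero variance are rejected (the caller should pre-filter).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if expr.n_samples < 3:
        raise ValidationError("need at least 3 samples for correlation")
    X = expr.values
    sd = X.std(axis=1)
    if np.any(sd == 0):
        offenders = [g for g, s in zip(expr.gene_ids, sd) if s == 0]
        raise ValidationError(f"zero-variance genes: {offenders[:10]}")
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
    r = np.corrcoef(X)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(gene_ids=expr.gene_ids.copy(), values=r)


def signed_adjacency(cor: CorrelationMatrix, beta: int) -> AdjacencyMatrix:
    """Signed adjacency a_ij = ((1 + r_ij)/2)^beta."""
    if not float(beta).is_integer() or beta < 1:
        raise ValueError(f"soft-threshold power must be a positive integer, got {beta}")
    beta = int(beta)
    a = ((1.0 + cor.values) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(gene_ids=cor.gene_ids.copy(), values=a, beta=beta)


def connectivity(adj: AdjacencyMatrix) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    return adj.values.sum(axis=1) - np.diag(adj.values)


def scale_free_fit(adj: AdjacencyMatrix, n_bins: int = 10) -> ScaleFreeFit:
    """Scale-free topology fit of the connectivity distribution.

    Connectivities are binned into ``n_bins`` equal-width bins; the empirical
    frequency of each non-empty bin is regressed (log10-log10) on the bin's
    mean connectivity.
    """
    if n_bins < 5:
        raise ValueError("need at least 5 bins")
    k = connectivity(adj)
    if np.allclose(k, k[0]):
        raise ValidationError("degenerate connectivity distribution: all k equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.array([k[which == b].mean() if (which == b).any() else np.nan
                       for b in range(n_bins)])
    freq = np.array([(which == b).sum() for b in range(n_bins)], dtype=float) / len(k)
    ok = (freq > 0) & np.isfinite(mean_k) & (mean_k > 0)
    if ok.sum() < 2:
        raise ValidationError("fewer than 2 usable connectivity bins")
    res = stats.linregress(np.log10(mean_k[ok]), np.log10(freq[ok]))
    # constant frequencies fit a horizontal line exactly (r undefined)
    r_squared = 1.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return ScaleFreeFit(beta=adj.beta, r_squared=r_squared, slope=float(res.slope))


def pick_soft_threshold(
    expr: ExpressionMatrix,
    candidates: Sequence[int] = tuple(range(1, 31)),
    r2_cut: float = 0.8,
    method: str = "pearson",
    n_bins: int = 10,
) -> tuple[int, list[ScaleFreeFit]]:
    """Choose the smallest power whose scale-free fit reaches ``r2_cut``.

    If no candidate qualifies, the candidate with the highest R² is returned
    and a warning issued.  The full fit table is returned for reporting.
    """
    if not candidates:
        raise ValueError("candidate power list is empty")
    candidates = sorted(int(b) for b in candidates)
    cor = pairwise_correlation(expr, method=method)
    fits = [scale_free_fit(signed_adjacency(cor, b), n_bins=n_bins) for b in candidates]
    for fit in fits:
        if fit.r_squared >= r2_cut:
            return fit.beta, fits
    best = max(fits, key=lambda f: f.r_squared)
    warnings.warn(
        f"no candidate power reached scale-free R^2 >= {r2_cut}; "
        f"using power {best.beta} with R^2 = {best.r_squared:.3f}",
        stacklevel=2,
    )
    return best.beta, fits


def topological_overlap(adj: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap matrix of a weighted network.

    Uses the standard (unsigned) TOM on the given adjacency; with the signed
    adjacency transform upstream this is the conventional signed-network
    pipeline.
    """
    n = len(adj.gene_ids)
    if n < 3:
        raise ValidationError("TOM requires at least 3 genes")
    a = adj.values.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a  # l_ij = sum_u a_iu a_uj; diagonal of a is 0 so u != i, j
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    omega = (l + a) / denom
    omega = np.clip((omega + omega.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(omega, 1.0)
    return TOMMatrix(gene_ids=adj.gene_ids.copy(), values=omega)
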