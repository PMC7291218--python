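"""Module detection: hierarchical clustering of the TOM dissimilarity,
static tree cut, eigengene summaries, eigengene-based merging, and module
coherence filters.

A module eigengene (ME) is the first principal component of the module's
standardized expression (each gene scaled to mean 0, sd 1 across samples);
kME is the correlation of a gene's standardized profile with an eigengene.
Modules whose eigengenes are closer than the merge height (default 0.15
eigengene dissimilarity, i.e. correlation above 0.85) are merged, and
modules are kept only if they have at least ``min_genes`` members with mean
kME at or above ``min_cor`` (defaults 10 and 0.75).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from braincoex.expression_io import ExpressionMatrix, ValidationError
from braincoex.network import TOMMatrix

logger = logging.getLogger(__name__)

#: Label reserved for unassigned / background genes.
BACKGROUND = 0


@dataclass
class Dendrogram:
    """Average-linkage tree over TOM dissimilarity (scipy linkage encoding)."""

    gene_ids: np.ndarray
    linkage_matrix: np.ndarray

    @property
    def max_height(self) -> float:
        return float(self.linkage_matrix[:, 2].max())


@dataclass
class ModuleAssignment:
    """Gene → module-label map; label 0 is background (unassigned)."""

    gene_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.gene_ids):
            raise ValidationError("one label required per gene")

    @property
    def module_labels(self) -> list[int]:
        """Non-background labels, ascending."""
        return sorted(int(l) for l in np.unique(self.labels) if l != BACKGROUND)

    @property
    def module_sizes(self) -> dict[int, int]:
        return {l: int((self.labels == l).sum()) for l in self.module_labels}

    def genes_in(self, label: int) -> np.ndarray:
        return self.gene_ids[self.labels == label]


@dataclass
class EigengeneProfile:
    """First principal component of a module's standardized expression."""

    module_label: int
    sample_ids: np.ndarray
    values: np.ndarray  # unit-norm vector over samples
    variance_explained: float

    def __post_init__(self) -> None:
        norm = np.linalg.norm(self.values)
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise ValidationError(f"eigengene is not unit norm ({norm})")
        if not 0.0 <= self.variance_explained <= 1.0 + 1e-12:
            raise ValidationError("variance_explained outside [0, 1]")


def hierarchical_cluster(tom: TOMMatrix) -> Dendrogram:
    """Average-linkage hierarchical clustering of 1 - TOM."""
    if len(tom.gene_ids) < 3:
        raise ValidationError("need at least 3 genes to cluster")
    d = tom.dissimilarity()
    if not np.all(np.isfinite(d)):
        raise ValidationError("non-finite dissimilarities")
    z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(gene_ids=tom.gene_ids.copy(), linkage_matrix=z)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber non-background labels 1..K by decreasing size (ties: by the
    first gene index in the module, for determinism)."""
    out = np.zeros_like(labels)
    keyed = []
    for lab in np.unique(labels):
        if lab == BACKGROUND:
            continue
        idx = np.nonzero(labels == lab)[0]
        keyed.append((-len(idx), idx[0], lab))
    for new, (_, _, old) in enumerate(sorted(keyed), start=1):
        out[labels == old] = new
    return out


def cut_modules(
    dendrogram: Dendrogram,
    min_module_size: int = 20,
    cut_height: float | None = None,
) -> ModuleAssignment:
    """Static height cut of the dendrogram into contiguous-branch modules.

    ``cut_height`` defaults to 99% of the maximum merge height.  Clusters
    smaller than ``min_module_size`` become background; surviving modules
    are numbered 1..K by decreasing size.
    """
    if cut_height is None:
        cut_height = 0.99 * dendrogram.max_height
    raw = fcluster(dendrogram.linkage_matrix, t=cut_height, criterion="distance")
    labels = np.asarray(raw, dtype=int)
    for lab, size in zip(*np.unique(labels, return_counts=True)):
        if size < min_module_size:
            labels[labels == lab] = BACKGROUND
    labels = _relabel_by_size(labels)
    if not (labels != BACKGROUND).any():
        warnings.warn("no module reached the minimum size; all genes background",
                      stacklevel=2)
    return ModuleAssignment(gene_ids=dendrogram.gene_ids.copy(), labels=labels)


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValidationError("zero-variance gene in module")
    return (X - X.mean(axis=1, keepdims=True)) / sd


def module_eigengene(
    expr: ExpressionMatrix,
    genes: np.ndarray | list[str],
    module_label: int = -1,
) -> EigengeneProfile:
    """Eigengene of a gene set: first right-singular vector of the
    standardized module expression, oriented to correlate positively with
    the module's mean standardized profile."""
    genes = list(genes)
    if len(genes) < 2:
        raise ValidationError("a module needs at least 2 genes")
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for g in genes if g not in index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing[:10]}")
    X = _standardize(expr.values[[index[g] for g in genes]])
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    v = vt[0]
    variance_explained = float(s[0] ** 2 / (s**2).sum())
    # orient: positive correlation with the mean standardized profile
    mean_profile = X.mean(axis=0)
    orientation = float(v @ (mean_profile - mean_profile.mean()))
    if orientation == 0.0:
        orientation = float(v[np.argmax(np.abs(v))])
    if orientation < 0:
        v = -v
    return EigengeneProfile(
        module_label=module_label,
        sample_ids=expr.sample_ids.copy(),
        values=v,
        variance_explained=variance_explained,
    )


def module_eigengenes(
    expr: ExpressionMatrix, assignment: ModuleAssignment
) -> dict[int, EigengeneProfile]:
    """Eigengenes for every non-background module."""
    return {
        lab: module_eigengene(expr, assignment.genes_in(lab), module_label=lab)
        for lab in assignment.module_labels
    }


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0:
        return 0.0
    return float(np.clip(xc @ yc / denom, -1.0, 1.0))


def merge_close_modules(
    expr: ExpressionMatrix,
    assignment: ModuleAssignment,
    merge_height: float = 0.15,
) -> ModuleAssignment:
    """Merge modules whose eigengene dissimilarity (1 - correlation) falls
    below ``merge_height``, closest pair first, recomputing eigengenes after
    each merge, until all pairwise dissimilarities are at least the height.
    """
    labels = assignment.labels.copy()
    while True:
        current = sorted(l for l in np.unique(labels) if l != BACKGROUND)
        if len(current) < 2:
            break
        expr_mes = {
            lab: module_eigengene(
                expr, assignment.gene_ids[labels == lab], module_label=lab
            ).values
            for lab in current
        }
        best: tuple[float, int, int] | None = None
        for i, la in enumerate(current):
            for lb in current[i + 1:]:
                diss = 1.0 - _pearson(expr_mes[la], expr_mes[lb])
                if best is None or diss < best[0]:
                    best = (diss, la, lb)
        assert best is not None
        diss, la, lb = best
        if diss >= merge_height:
            break
        labels[labels == lb] = la
        logger.info("merged module %d into %d (eigengene dissimilarity %.3f)",
                    lb, la, diss)
    return ModuleAssignment(
        gene_ids=assignment.gene_ids.copy(), labels=_relabel_by_size(labels)
    )


def module_membership(
    expr: ExpressionMatrix, eigengenes: dict[int, EigengeneProfile]
) -> tuple[np.ndarray, list[int]]:
    """kME table: correlation of each gene's standardized profile with each
    module eigengene.  Returns (genes × modules matrix, module label order).
    """
    labels = sorted(eigengenes)
    X = _standardize(expr.values)
    n = expr.n_samples
    kme = np.empty((expr.n_genes, len(labels)))
    for j, lab in enumerate(labels):
        me = eigengenes[lab]
        if list(me.sample_ids) != list(expr.sample_ids):
            raise ValidationError("eigengene samples do not match expression samples")
        v = me.values - me.values.mean()
        v_norm = np.linalg.norm(v)
        kme[:, j] = np.clip(X @ v / (np.sqrt(n) * v_norm), -1.0, 1.0)
    return kme, labels


def module_coherence(
    expr: ExpressionMatrix,
    genes: np.ndarray | list[str],
    mode: str = "kme",
) -> float:
    """Coherence of a module: mean kME of members to the module eigengene
    (default), or mean off-diagonal pairwise correlation (``mode='pairwise'``).
    """
    genes = list(genes)
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    X = _standardize(expr.values[[index[g] for g in genes]])
    if mode == "pairwise":
        r = np.corrcoef(X)
        n = len(genes)
        return float((r.sum() - n) / (n * (n - 1)))
    if mode != "kme":
        raise ValueError(f"unknown coherence mode {mode!r}")
    me = module_eigengene(expr, genes)
    v = me.values - me.values.mean()
    kme = X @ v / (np.sqrt(X.shape[1]) * np.linalg.norm(v))
    return float(kme.mean())


def filter_modules(
    expr: ExpressionMatrix,
    assignment: ModuleAssignment,
    min_genes: int = 10,
    min_cor: float = 0.75,
    mode: str = "kme",
) -> ModuleAssignment:
    """Relabel as background every module with fewer than ``min_genes``
    members or coherence below ``min_cor``.  Idempotent."""
    labels = assignment.labels.copy()
    for lab in assignment.module_labels:
        genes = assignment.genes_in(lab)
        if len(genes) < min_genes:
            labels[assignment.labels == lab] = BACKGROUND
            continue
        if module_coherence(expr, genes, mode=mode) < min_cor:
            labels[assignment.labels == lab] = BACKGROUND
    return ModuleAssignment(
        gene_ids=assignment.gene_ids.copy(), labels=_relabel_by_size(labels)
    )


def detect_modules(
    expr: ExpressionMatrix,
    tom: TOMMatrix,
    min_module_size: int = 20,
    cut_height: float | None = None,
    merge_height: float = 0.15,
    min_genes: int = 10,
    min_cor: float = 0.75,
) -> ModuleAssignment:
    """Full detection chain: cluster → static cut → merge → coherence filter."""
    dendro = hierarchical_cluster(tom)
    assignment = cut_modules(dendro, min_module_size=min_module_size,
                             cut_height=cut_height)
    if assignment.module_labels:
        assignment = merge_close_modules(expr, assignment, merge_height=merge_height)
        assignment = filter_modules(expr, assignment, min_genes=min_genes,
                                    min_cor=min_cor)
    return assignment
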