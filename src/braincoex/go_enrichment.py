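"""Functional characterization of modules by GO over-representation.

Each module is tested against a user-supplied annotation (GMT of biological
process terms) with the upper-tail hypergeometric test, and per-module term
p-values are adjusted with Holm's step-down Bonferroni procedure (with
Benjamini-Hochberg as an optional FDR mode).  The term universe is the
intersection of the annotation background and the expression gene universe,
so unexpressed genes cannot inflate significance.  No ontology-graph
traversal or term-redundancy reduction is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from braincoex.enrichment import bh_adjust, holm_adjust, overlap_count
from braincoex.expression_io import GeneSet, ValidationError
from braincoex.modules import ModuleAssignment

logger = logging.getLogger(__name__)


@dataclass
class AnnotationCollection:
    """GO-style annotation: term id → (term name, gene set), plus a gene
    universe.  Terms are harmonized to the background and size-filtered on
    construction."""

    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    @classmethod
    def from_gene_sets(
        cls,
        sets: Sequence[GeneSet],
        background: Iterable[str],
        min_term_size: int = 5,
        max_term_size: int = 2000,
    ) -> "AnnotationCollection":
        background = frozenset(background)
        if not background:
            raise ValidationError("annotation background is empty")
        terms: dict[str, tuple[str, frozenset[str]]] = {}
        for s in sets:
            genes = frozenset(s.genes) & background
            if min_term_size <= len(genes) <= max_term_size:
                terms[s.name] = (s.description or s.name, genes)
        return cls(terms=terms, background=background)

    def __len__(self) -> int:
        return len(self.terms)


def hypergeometric_term_test(
    module: Iterable[str],
    term_genes: Iterable[str],
    background: Iterable[str],
) -> float:
    """Upper-tail hypergeometric over-representation p-value.

    p = P(X >= k) with population |background|, |term| successes, |module|
    draws, and observed overlap k.
    """
    module = set(module)
    term_genes = set(term_genes)
    background = set(background)
    if not module:
        raise ValidationError("module is empty")
    if not module <= background or not term_genes <= background:
        raise ValidationError("module and term must be subsets of the background")
    k = overlap_count(module, term_genes)
    return float(
        stats.hypergeom.sf(k - 1, len(background), len(term_genes), len(module))
    )


def annotate_modules(
    assignment: ModuleAssignment,
    annotation: AnnotationCollection,
    alpha: float = 0.05,
    correction: str = "holm",
) -> pd.DataFrame:
    """Test every (module, term) pair; adjust p-values within each module.

    Returns a tidy table (module, term_id, term_name, overlap, p, p_adj,
    significant, label_term) where ``label_term`` marks each module's most
    significant term.
    """
    universe = annotation.background & frozenset(assignment.gene_ids)
    if not universe:
        raise ValidationError("no gene overlap between annotation and assignment")
    adjust = holm_adjust if correction == "holm" else bh_adjust
    frames = []
    for lab in assignment.module_labels:
        module = set(assignment.genes_in(lab)) & universe
        if not module:
            continue
        rows = []
        for term_id, (term_name, genes) in sorted(annotation.terms.items()):
            genes_u = genes & universe
            if not genes_u:
                continue
            p = hypergeometric_term_test(module, genes_u, universe)
            rows.append((lab, term_id, term_name, overlap_count(module, genes_u), p))
        if not rows:
            continue
        table = pd.DataFrame(
            rows, columns=["module", "term_id", "term_name", "overlap", "p"]
        )
        table["p_adj"] = adjust(table["p"].to_numpy())
        table["significant"] = table["p_adj"] < alpha
        table = table.sort_values(["p_adj", "p", "term_id"], kind="stable")
        table["label_term"] = False
        table.iloc[0, table.columns.get_loc("label_term")] = True
        frames.append(table)
    if not frames:
        return pd.DataFrame(
            columns=["module", "term_id", "term_name", "overlap", "p", "p_adj",
                     "significant", "label_term"]
        )
    return pd.concat(frames, ignore_index=True)
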