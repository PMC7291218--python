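"""Synthetic expression data with planted co-expression modules.

The generator follows a single-factor-per-module model: each planted module
m has a latent sample profile f_m ~ N(0, I); a member gene is
lambda * f_m + sqrt(1 - lambda^2) * noise, so ``lambda`` is the target
module membership (kME) of member genes.  Background genes are pure noise.
Variant gene sets are drawn so that each gene lands in the target module
with probability ``fold × base_rate`` (fold = 1 gives a uniform control
set), giving planted enrichment with a binomially distributed module hit
count.

Metadata emulates the structure of developmental brain atlases: ages
spanning 8 post-conception weeks to 60 years over the five stages, the 16
brain region codes, and RIN quality scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from braincoex.expression_io import (
    ALL_REGION_CODES,
    ExpressionMatrix,
    GeneSet,
)

#: (low, high, unit) age ranges for the five developmental stages used when
#: drawing synthetic sample ages.
_STAGE_AGE_RANGES = {
    1: (8.0, 13.9, "pcw"),
    2: (14.0, 38.0, "pcw"),
    3: (0.0, 35.9, "month"),
    4: (3.0, 39.9, "year"),
    5: (40.0, 60.0, "year"),
}


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset."""

    module_of_gene: dict[str, int]  # 0 = background noise gene
    factor_profiles: np.ndarray     # n_modules × n_samples latent profiles
    kme_target: float
    enriched_pairs: list[tuple[str, int, float]] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.module_of_gene)

    def labels_for(self, gene_ids) -> np.ndarray:
        return np.array([self.module_of_gene[g] for g in gene_ids], dtype=int)

    def module_genes(self, label: int) -> list[str]:
        return [g for g, m in self.module_of_gene.items() if m == label]


def generate_expression(
    n_modules: int = 5,
    module_size: int = 50,
    n_background_genes: int = 0,
    n_samples: int = 100,
    kme_target: float = 0.8,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Factor-model expression matrix with planted modules.

    Genes in module m are ``kme_target * f_m + sqrt(1 - kme_target^2) * eps``
    with independent standard-normal factors and noise, so the expected
    module membership of member genes equals ``kme_target``.
    """
    if not 0.0 < kme_target <= 1.0:
        raise ValueError(f"kme_target must be in (0, 1], got {kme_target}")
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n_modules, n_samples))

    n_genes = n_modules * module_size + n_background_genes
    width = len(str(n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    sample_ids = [f"S{j + 1:03d}" for j in range(n_samples)]

    lam = kme_target
    noise_scale = np.sqrt(1.0 - lam**2)
    values = np.empty((n_genes, n_samples))
    module_of_gene: dict[str, int] = {}
    row = 0
    for m in range(1, n_modules + 1):
        eps = rng.standard_normal((module_size, n_samples))
        values[row:row + module_size] = lam * factors[m - 1] + noise_scale * eps
        for g in gene_ids[row:row + module_size]:
            module_of_gene[g] = m
        row += module_size
    if n_background_genes:
        values[row:] = rng.standard_normal((n_background_genes, n_samples))
        for g in gene_ids[row:]:
            module_of_gene[g] = 0

    expr = ExpressionMatrix(
        gene_ids=np.array(gene_ids, dtype=object),
        sample_ids=np.array(sample_ids, dtype=object),
        values=values,
    )
    truth = SimulationTruth(
        module_of_gene=module_of_gene,
        factor_profiles=factors,
        kme_target=kme_target,
    )
    return expr, truth


def generate_metadata(n_samples: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic sample metadata spanning all stages and the 16 regions.

    Region codes are assigned round-robin (so 16 samples cover every region
    and all 4 regional clusters); stages are drawn uniformly and an age is
    drawn uniformly within the stage's range; RIN ~ Uniform(5, 10).
    """
    if n_samples < 1:
        raise ValueError("need at least 1 sample")
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_samples):
        stage = int(rng.integers(1, 6))
        lo, hi, unit = _STAGE_AGE_RANGES[stage]
        age = float(np.round(rng.uniform(lo, hi), 2))
        rows.append(
            {
                "sample_id": f"S{j + 1:03d}",
                "age": age,
                "age_unit": unit,
                "region": ALL_REGION_CODES[j % len(ALL_REGION_CODES)],
                "rin": float(np.round(rng.uniform(5.0, 10.0), 2)),
            }
        )
    return pd.DataFrame(rows)


def generate_variant_sets(
    truth: SimulationTruth,
    set_size: int,
    target_module: int,
    fold: float = 1.0,
    seed: int = 0,
    name: str | None = None,
    category: str = "other",
) -> GeneSet:
    """Variant gene set with planted enrichment in ``target_module``.

    Each of ``set_size`` genes belongs to the target module with probability
    ``fold × base_rate`` (base_rate = module size / total genes); the module
    hit count is therefore Binomial(set_size, fold × base_rate), realized as
    that many distinct module genes plus uniformly drawn non-module genes.
    ``fold = 1`` yields a uniform control set.  If the drawn hit count
    exceeds the module (or the remainder exceeds the non-module pool), the
    draw saturates at the available genes with a warning.
    """
    module_genes = np.array(truth.module_genes(target_module), dtype=object)
    if module_genes.size == 0:
        raise ValueError(f"module {target_module} has no genes")
    all_genes = np.array(truth.gene_ids, dtype=object)
    other_genes = np.array(
        [g for g in all_genes if truth.module_of_gene[g] != target_module],
        dtype=object,
    )
    base_rate = len(module_genes) / len(all_genes)
    p_hit = fold * base_rate
    if fold < 1.0 or p_hit > 1.0:
        raise ValueError(
            f"infeasible fold {fold}: hit probability {p_hit:.3f} outside [base_rate, 1]"
        )
    if set_size > len(all_genes):
        raise ValueError("set_size exceeds the gene universe")

    rng = np.random.default_rng(seed)
    n_hit = int(rng.binomial(set_size, p_hit))
    if n_hit > len(module_genes):
        warnings.warn(
            f"requested enrichment saturates module {target_module}: "
            f"{n_hit} hits capped at {len(module_genes)} genes",
            stacklevel=2,
        )
        n_hit = len(module_genes)
    n_other = set_size - n_hit
    if n_other > len(other_genes):
        raise ValueError("set_size exceeds the non-module gene pool")
    picked = np.concatenate([
        rng.choice(module_genes, size=n_hit, replace=False),
        rng.choice(other_genes, size=n_other, replace=False),
    ])
    set_name = name or f"set_m{target_module}_fold{fold:g}"
    truth.enriched_pairs.append((set_name, target_module, fold))
    return GeneSet(name=set_name, genes=frozenset(picked.tolist()), category=category)
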