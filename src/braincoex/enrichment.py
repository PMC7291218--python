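"""Rare-variant gene-set enrichment in co-expression modules.

Two statistics are provided:

* A resampling z-score: repeatedly draw ``sample_size`` genes (default 800)
  without replacement from the case gene set, count the overlap x_t with a
  module, standardize each count against the binomial reference
  e = n·p, sd = sqrt(n·p·(1−p)) with p = |module| / |background|, and
  summarize over ``n_iter`` iterations (default 10,000) by the mean z.
  The subsampling equalizes case and control set sizes.
* A one-tailed binomial overlap test against reference sets (e.g. FMRP
  targets, cortical-layer laminae): P(X >= observed) with
  X ~ Binomial(|module|, |reference| / |background|).

Multiple testing over a (module × gene-set) table uses Holm's step-down
Bonferroni procedure by default, Benjamini-Hochberg optionally.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from braincoex.expression_io import GeneSet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Result of one (module, gene set) resampling enrichment test."""

    module_label: int | str
    set_name: str
    observed_overlap: int
    expected_overlap: float
    null_mean: float
    null_sd: float
    z_score: float
    p_value: float
    n_iterations: int
    sample_size: int
    seed: int
    background_size: int
    adjusted_p: float = np.nan
    iteration_overlaps: np.ndarray | None = field(default=None, repr=False)

    @property
    def iteration_z(self) -> np.ndarray:
        """Per-iteration standardized overlaps (x_t - e) / sd_binom."""
        if self.iteration_overlaps is None:
            raise ValueError("iteration overlaps were not retained")
        p = self.expected_overlap / self.sample_size
        sd = np.sqrt(self.sample_size * p * (1.0 - p))
        return (self.iteration_overlaps - self.expected_overlap) / sd


@dataclass
class ContrastResult:
    """Case-vs-control contrast of two enrichment results on one module."""

    module_label: int | str
    delta_z: float
    case_enriched: bool


def overlap_count(module_genes: Iterable[str], query: Iterable[str]) -> int:
    """Size of the intersection of two gene collections."""
    return len(set(module_genes) & set(query))


def _derive_seed(seed: int, module_label, set_name: str) -> int:
    """Deterministic, order-independent substream per (module, set)."""
    tag = zlib.crc32(f"{module_label}\x00{set_name}".encode())
    ss = np.random.SeedSequence([int(seed), tag])
    return int(ss.generate_state(1)[0] % (2**31))


def resampling_enrichment(
    module: Iterable[str],
    case_set: GeneSet,
    background: Iterable[str],
    sample_size: int = 800,
    n_iter: int = 10_000,
    seed: int = 0,
    mode: str = "case",
    keep_iterations: bool = True,
) -> EnrichmentResult:
    """Resampling enrichment of a case gene set in one module.

    In the default ``mode='case'``, each iteration draws ``sample_size``
    genes uniformly without replacement from the case set; its module
    overlap x_t is standardized against the binomial reference
    Binomial(sample_size, |module|/|background|), and the reported z-score
    is the mean of the per-iteration z values, with a one-tailed normal
    p-value.  In ``mode='background'`` the draws come from the background
    universe and the observed full-set overlap is standardized against the
    empirical null (empirical-z reading).
    """
    module = set(module)
    background = set(background)
    if not background:
        raise ValidationError("background universe is empty")
    if not module <= background:
        raise ValidationError("module is not a subset of the background")
    case_genes = set(case_set.genes)
    outside = case_genes - background
    if outside:
        warnings.warn(
            f"{len(outside)} case genes outside the background were dropped",
            stacklevel=2,
        )
        case_genes -= outside
    if sample_size > len(case_genes):
        raise ValueError(
            f"sample_size {sample_size} exceeds case set size {len(case_genes)}"
        )
    if mode not in ("case", "background"):
        raise ValueError(f"unknown resampling mode {mode!r}")

    p = len(module) / len(background)
    expected = sample_size * p
    sd_binom = np.sqrt(sample_size * p * (1.0 - p))
    observed = overlap_count(case_genes, module)

    rng = np.random.default_rng(seed)
    if mode == "case":
        ngood = observed                      # case genes inside the module
        nbad = len(case_genes) - observed
    else:
        ngood = len(module)                   # background genes inside the module
        nbad = len(background) - len(module)
    # drawing sample_size genes without replacement and intersecting with the
    # module is distributionally identical to one hypergeometric draw
    x = rng.hypergeometric(ngood, nbad, sample_size, size=n_iter).astype(float)

    null_mean = float(x.mean())
    null_sd = float(x.std(ddof=1)) if n_iter > 1 else 0.0
    if mode == "case":
        if sd_binom == 0:
            raise ValidationError("degenerate binomial reference (p is 0 or 1)")
        z = float(((x - expected) / sd_binom).mean())
    else:
        z = float((observed - null_mean) / null_sd) if null_sd > 0 else np.inf
    p_value = float(stats.norm.sf(z))

    return EnrichmentResult(
        module_label=-1,
        set_name=case_set.name,
        observed_overlap=observed,
        expected_overlap=float(expected),
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=z,
        p_value=p_value,
        n_iterations=n_iter,
        sample_size=sample_size,
        seed=seed,
        background_size=len(background),
        iteration_overlaps=x if keep_iterations else None,
    )


def case_control_contrast(
    case_result: EnrichmentResult, control_result: EnrichmentResult
) -> ContrastResult:
    """Δz = z_case − z_control; flagged case-enriched when z_case > 0 and
    Δz > 0."""
    if case_result.background_size != control_result.background_size:
        raise ValidationError("case and control results use different backgrounds")
    if case_result.module_label != control_result.module_label:
        raise ValidationError("case and control results are for different modules")
    delta = case_result.z_score - control_result.z_score
    return ContrastResult(
        module_label=case_result.module_label,
        delta_z=float(delta),
        case_enriched=bool(case_result.z_score > 0 and delta > 0),
    )


def binomial_overlap_test(
    module: Iterable[str],
    reference: GeneSet,
    background: Iterable[str],
) -> tuple[float, float]:
    """One-tailed binomial overlap test of a module against a reference set.

    Returns (p_value, z) with p = P(X >= observed), X ~ Binomial(|module|,
    |reference ∩ background| / |background|), and the standardized
    z = (observed − np) / sqrt(np(1−p)).
    """
    module = set(module)
    background = set(background)
    if not module or not background:
        raise ValidationError("module and background must be non-empty")
    ref_genes = set(reference.genes) & background
    observed = overlap_count(module, ref_genes)
    p = len(ref_genes) / len(background)
    n = len(module)
    if p == 0:
        if observed > 0:
            raise ValidationError("reference set empty in background")
        return 1.0, 0.0
    if p == 1:
        return 1.0, 0.0
    p_value = float(stats.binom.sf(observed - 1, n, p))
    z = float((observed - n * p) / np.sqrt(n * p * (1.0 - p)))
    return p_value, z


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down ("Bonferroni step-down") adjusted p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional FDR mode)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_table(
    module_genes: dict[int | str, Iterable[str]],
    gene_sets: Sequence[GeneSet],
    background: Iterable[str],
    sample_size: int = 800,
    n_iter: int = 10_000,
    seed: int = 0,
    mode: str = "case",
    correction: str = "holm",
) -> pd.DataFrame:
    """Tidy (module × gene-set) resampling enrichment table.

    Each (module, set) pair gets its own deterministic random substream
    derived from ``seed``, so results do not depend on evaluation order.
    A ``sample_size`` larger than any tested gene set is a parameter error.
    """
    background = set(background)
    rows = []
    for set_ in gene_sets:
        for label, genes in module_genes.items():
            sub_seed = _derive_seed(seed, label, set_.name)
            res = resampling_enrichment(
                genes, set_, background,
                sample_size=sample_size, n_iter=n_iter, seed=sub_seed, mode=mode,
                keep_iterations=False,
            )
            res.module_label = label
            rows.append(res)
    adjust = holm_adjust if correction == "holm" else bh_adjust
    p_adj = adjust([r.p_value for r in rows])
    for r, q in zip(rows, p_adj):
        r.adjusted_p = float(q)
    return pd.DataFrame(
        {
            "module": [r.module_label for r in rows],
            "set": [r.set_name for r in rows],
            "observed": [r.observed_overlap for r in rows],
            "expected": [r.expected_overlap for r in rows],
            "null_mean": [r.null_mean for r in rows],
            "null_sd": [r.null_sd for r in rows],
            "z": [r.z_score for r in rows],
            "p": [r.p_value for r in rows],
            "p_adj": [r.adjusted_p for r in rows],
        }
    )
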