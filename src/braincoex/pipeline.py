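"""End-to-end orchestration: stratify → network → modules → eigengenes →
enrichment → GO, with a machine-readable run manifest.

Every run writes, per stratum, the soft-threshold fit table, the module
assignment, eigengenes, the kME table, resampling-enrichment and GO tables,
plus a summary table (samples, modules, functional modules, mean genes per
module per stratum), a cross-stratum module-overlap (Jaccard) table for
stratified runs, and ``manifest.json`` recording parameters, seed, input
hashes, per-stage filter counts, and a content hash of every output file.
Outputs contain no timestamps, so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from braincoex import expression_io as eio
from braincoex import go_enrichment as goe
from braincoex import modules as mod
from braincoex import network as net
from braincoex.enrichment import enrichment_table
from braincoex.expression_io import ExpressionMatrix, GeneSet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run (round-trips through YAML)."""

    expression: str = ""
    metadata: str = ""
    gene_sets: str = ""            # GMT of case/control variant sets
    background: str = ""           # gene universe, one id per line ('' = matrix genes)
    go_annotation: str = ""        # optional GMT of GO terms
    stratify: str = "pooled"       # pooled | by_stage | by_region_cluster
    min_rin: float = 7.0
    min_samples: int = 20
    power: int | str = "auto"      # soft-threshold power or "auto"
    r2_cut: float = 0.8
    correlation: str = "pearson"
    min_module_size: int = 20
    cut_height: float | None = None
    merge_height: float = 0.15
    filter_min_genes: int = 10
    filter_min_cor: float = 0.75
    sample_size: int = 800
    n_iter: int = 10_000
    seed: int = 0
    correction: str = "holm"
    alpha: float = 0.05

    def validate(self) -> None:
        if self.stratify not in ("pooled", "by_stage", "by_region_cluster"):
            raise ValidationError(f"unknown stratification mode {self.stratify!r}")
        if not (0 <= self.r2_cut <= 1 and 0 <= self.merge_height <= 1
                and 0 <= self.alpha <= 1 and 0 <= self.filter_min_cor <= 1):
            raise ValidationError("a unit-interval parameter is out of range")
        if self.power != "auto" and (int(self.power) < 1):
            raise ValidationError("power must be 'auto' or a positive integer")
        if min(self.min_module_size, self.filter_min_genes, self.sample_size,
               self.n_iter, self.min_samples) < 1:
            raise ValidationError("count parameters must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def analyze_stratum(
    expr: ExpressionMatrix,
    config: RunConfig,
    gene_sets: Sequence[GeneSet],
    background: set[str],
    go_sets: Sequence[GeneSet],
    out_dir: Path,
    stratum: str,
) -> dict:
    """Network → modules → eigengenes → enrichment → GO for one stratum.

    Returns the summary record for the stratum; writes all tables under
    ``out_dir``.
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {"genes": expr.n_genes, "samples": expr.n_samples}

    # network
    try:
        if config.power == "auto":
            beta, fits = net.pick_soft_threshold(
                expr, r2_cut=config.r2_cut, method=config.correlation
            )
        else:
            beta = int(config.power)
            cor = net.pairwise_correlation(expr, method=config.correlation)
            fits = [net.scale_free_fit(net.signed_adjacency(cor, beta))]
        cor = net.pairwise_correlation(expr, method=config.correlation)
        adj = net.signed_adjacency(cor, beta)
        tom = net.topological_overlap(adj)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("network", exc) from exc
    _write_tsv(
        pd.DataFrame(
            {"power": [f.beta for f in fits],
             "r_squared": [f.r_squared for f in fits],
             "slope": [f.slope for f in fits]}
        ),
        out_dir / "soft_threshold.tsv",
    )

    # modules
    try:
        assignment = mod.detect_modules(
            expr, tom,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            merge_height=config.merge_height,
            min_genes=config.filter_min_genes,
            min_cor=config.filter_min_cor,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("modules", exc) from exc
    _write_tsv(
        pd.DataFrame({"gene_id": assignment.gene_ids, "module": assignment.labels}),
        out_dir / "modules.tsv",
    )
    counts["modules"] = len(assignment.module_labels)

    eigengene_cols: dict[str, np.ndarray] = {}
    kme_frame = pd.DataFrame(index=list(expr.gene_ids))
    if assignment.module_labels:
        try:
            mes = mod.module_eigengenes(expr, assignment)
            kme, labels = mod.module_membership(expr, mes)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("eigengenes", exc) from exc
        for lab in labels:
            eigengene_cols[f"M{lab}"] = mes[lab].values
            kme_frame[f"M{lab}"] = kme[:, labels.index(lab)]
    me_frame = pd.DataFrame(eigengene_cols, index=list(expr.sample_ids))
    me_frame.index.name = "sample_id"
    _write_tsv(me_frame, out_dir / "eigengenes.tsv", index=True)
    kme_frame.index.name = "gene_id"
    _write_tsv(kme_frame, out_dir / "kme.tsv", index=True)

    # variant-set enrichment
    if gene_sets and assignment.module_labels:
        try:
            module_genes = {
                lab: set(assignment.genes_in(lab)) for lab in assignment.module_labels
            }
            table = enrichment_table(
                module_genes, gene_sets, background,
                sample_size=config.sample_size, n_iter=config.n_iter,
                seed=config.seed, correction=config.correction,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("enrichment", exc) from exc
        _write_tsv(table, out_dir / "enrichment.tsv")
        _write_tsv(
            table.pivot(index="module", columns="set", values="z").reset_index(),
            out_dir / "enrichment_z_matrix.tsv",
        )

    # GO over-representation
    functional = len(assignment.module_labels)
    if go_sets and assignment.module_labels:
        try:
            annotation = goe.AnnotationCollection.from_gene_sets(
                go_sets, background=set(expr.gene_ids)
            )
            go_table = goe.annotate_modules(
                assignment, annotation, alpha=config.alpha,
                correction=config.correction,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("go", exc) from exc
        _write_tsv(go_table, out_dir / "go.tsv")
        functional = int(
            go_table[go_table["significant"]]["module"].nunique()
        ) if len(go_table) else 0

    sizes = list(assignment.module_sizes.values())
    return {
        "stratum": stratum,
        "n_samples": expr.n_samples,
        "n_genes": expr.n_genes,
        "power": beta,
        "n_modules": len(sizes),
        "n_functional_modules": functional,
        "mean_genes_per_module": float(np.mean(sizes)) if sizes else 0.0,
        "counts": counts,
        "assignment": assignment,
    }


def stratify_samples(meta: pd.DataFrame, mode: str) -> dict[str, list[str]]:
    """Group sample ids by developmental stage, regional cluster, or pooled."""
    if mode == "pooled":
        return {"pooled": list(meta["sample_id"])}
    meta = eio.annotate_metadata(meta)
    key = "stage" if mode == "by_stage" else "region_cluster"
    prefix = "stage" if mode == "by_stage" else "cluster"
    return {
        f"{prefix}{value}": list(group["sample_id"])
        for value, group in meta.groupby(key)
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full pipeline per ``config``; returns the run directory."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ingest
    try:
        expr = eio.read_expression_table(config.expression)
        meta = eio.read_metadata(config.metadata)
        meta, expr = eio.filter_samples_by_rin(meta, expr, min_rin=config.min_rin)
        gene_sets = eio.read_gmt(config.gene_sets) if config.gene_sets else []
        go_sets = eio.read_gmt(config.go_annotation) if config.go_annotation else []
        background = (
            set(eio.read_gene_list(config.background))
            if config.background
            else set(expr.gene_ids)
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("ingest", exc) from exc

    input_hashes = {
        name: _sha256(Path(path))
        for name, path in (
            ("expression", config.expression),
            ("metadata", config.metadata),
            ("gene_sets", config.gene_sets),
            ("background", config.background),
            ("go_annotation", config.go_annotation),
        )
        if path
    }

    strata = stratify_samples(meta, config.stratify)
    usable = {
        name: ids for name, ids in strata.items() if len(ids) >= config.min_samples
    }
    for name in set(strata) - set(usable):
        warnings.warn(
            f"stratum {name!r} has {len(strata[name])} samples "
            f"(< {config.min_samples}); skipped",
            stacklevel=2,
        )
    if not usable:
        raise PipelineError("stratify", ValidationError("no usable strata"))

    summaries = []
    assignments: dict[str, mod.ModuleAssignment] = {}
    for name in sorted(usable):
        sub = expr.select_samples(usable[name])
        record = analyze_stratum(
            sub, config, gene_sets, background, go_sets, out_dir / name, name
        )
        assignments[name] = record.pop("assignment")
        record.pop("counts")
        summaries.append(record)
    summary = pd.DataFrame(summaries)
    _write_tsv(summary, out_dir / "summary.tsv")

    # cross-stratum module overlap (Jaccard of module gene sets)
    names = sorted(assignments)
    if len(names) > 1:
        rows = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                for la in assignments[a].module_labels:
                    ga = set(assignments[a].genes_in(la))
                    for lb in assignments[b].module_labels:
                        gb = set(assignments[b].genes_in(lb))
                        union = len(ga | gb)
                        rows.append(
                            (a, la, b, lb, len(ga & gb),
                             len(ga & gb) / union if union else 0.0)
                        )
        _write_tsv(
            pd.DataFrame(
                rows,
                columns=["stratum_a", "module_a", "stratum_b", "module_b",
                         "overlap", "jaccard"],
            ),
            out_dir / "module_overlap.tsv",
        )

    config.to_yaml(out_dir / "config.yaml")
    outputs = {
        str(p.relative_to(out_dir)): _sha256(p)
        for p in sorted(out_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "parameters": asdict(config),
        "seed": config.seed,
        "inputs": input_hashes,
        "strata": {name: len(ids) for name, ids in sorted(usable.items())},
        "skipped_strata": sorted(set(strata) - set(usable)),
        "outputs": outputs,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out_dir
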