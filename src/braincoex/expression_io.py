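"""Reading, validation, filtering, and stratification of expression data.

Expression matrices are plain TSV/CSV text: a header row of sample ids and a
first column of gene ids, values on a log2-like scale.  Sample metadata
carries per-sample age (in post-conception weeks, months, or years), a brain
region code, and an RNA integrity number (RIN) used for quality filtering.

Samples are binned into five developmental stages spanning 8 post-conception
weeks (PCW) to 60 years, and the 16 brain region codes are grouped into four
transcriptionally similar clusters (neocortical frontal/motor-somatosensory;
temporal/visual cortex; striatum-hippocampus-amygdala; thalamus-cerebellum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Post-conception week at which birth is placed when mapping prenatal and
#: postnatal ages onto one axis (standard obstetric convention).
BIRTH_PCW = 40.0

#: Weeks per year used to convert postnatal ages expressed in PCW.
WEEKS_PER_YEAR = 52.0

VALID_AGE_UNITS = ("pcw", "month", "year")

#: The four regional clusters partitioning the 16 region codes.
REGION_CLUSTERS: dict[int, frozenset[str]] = {
    1: frozenset({"DFC", "M1C", "MFC", "OFC", "S1C", "VFC"}),
    2: frozenset({"A1C", "ITC", "IPC", "STC", "V1C"}),
    3: frozenset({"AMY", "HIP", "STR"}),
    4: frozenset({"CBC", "MD"}),
}

#: All 16 valid region codes, in a fixed order.
ALL_REGION_CODES: tuple[str, ...] = tuple(
    sorted(code for members in REGION_CLUSTERS.values() for code in members)
)

_REGION_TO_CLUSTER: dict[str, int] = {
    code: cluster for cluster, members in REGION_CLUSTERS.items() for code in members
}


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix with identifier bookkeeping.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique gene identifiers, one per row of ``values``.
    sample_ids : sequence of str
        Unique sample identifiers, one per column of ``values``.
    values : ndarray of shape (n_genes, n_samples)
        Expression values, assumed to be on a log2-like scale.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique("gene", self.gene_ids)
        _check_unique("sample", self.sample_ids)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=frame.index.to_numpy(dtype=object),
            sample_ids=frame.columns.to_numpy(dtype=object),
            values=frame.to_numpy(dtype=float),
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given samples, preserving their given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(
            gene_ids=self.gene_ids.copy(),
            sample_ids=np.asarray(list(sample_ids), dtype=object),
            values=self.values[:, cols],
        )


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers.

    ``category`` tags the provenance of the set (rare coding variants,
    regulatory variants, de novo variants, copy-number variants, a reference
    set such as FMRP targets, or a control set).
    """

    name: str
    genes: frozenset[str]
    category: str = "other"
    description: str = ""

    _CATEGORIES = ("coding", "regulatory", "dnv", "cnv", "reference", "control", "other")

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if self.category not in self._CATEGORIES:
            raise ValidationError(
                f"unknown gene-set category {self.category!r}; "
                f"expected one of {self._CATEGORIES}"
            )

    def __len__(self) -> int:
        return len(self.genes)


def _check_unique(kind: str, ids: np.ndarray) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dupes = sorted(set(ids[ids.duplicated()]))
        raise ValidationError(f"duplicate {kind} identifiers: {dupes}")


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path: str | Path,
    delimiter: str | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a genes × samples expression table from TSV/CSV text.

    The first row holds sample ids and the first column gene ids.  Rows with
    any empty or non-numeric cell are dropped and the count logged.  Set
    ``transpose=True`` for samples-in-rows dialects.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_delimiter(path, delimiter), index_col=0)
    if transpose:
        frame = frame.T
    frame = frame.apply(pd.to_numeric, errors="coerce")
    _check_unique("gene", frame.index.to_numpy(dtype=object))
    _check_unique("sample", frame.columns.to_numpy(dtype=object))
    bad = frame.isna().any(axis=1)
    if bad.any():
        logger.warning(
            "dropped %d of %d gene rows with missing or non-numeric values",
            int(bad.sum()),
            len(frame),
        )
        frame = frame.loc[~bad]
    return ExpressionMatrix.from_frame(frame)


def write_expression_table(
    expr: ExpressionMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    """Write the matrix as TSV/CSV text (round-trips through the reader)."""
    path = Path(path)
    expr.to_frame().to_csv(path, sep=_sniff_delimiter(path, delimiter))


METADATA_COLUMNS = ("sample_id", "age", "age_unit", "region", "rin")


def read_metadata(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a sample metadata table with columns sample_id, age, age_unit,
    region, rin."""
    path = Path(path)
    meta = pd.read_csv(path, sep=_sniff_delimiter(path, delimiter))
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata is missing columns: {missing}")
    _check_unique("sample", meta["sample_id"].to_numpy(dtype=object))
    bad_units = set(meta["age_unit"]) - set(VALID_AGE_UNITS)
    if bad_units:
        raise ValidationError(
            f"unknown age units {sorted(bad_units)}; expected {VALID_AGE_UNITS}"
        )
    if (meta["rin"].astype(float) < 0).any():
        raise ValidationError("RIN values must be non-negative")
    return meta.reset_index(drop=True)


def filter_samples_by_rin(
    meta: pd.DataFrame, expr: ExpressionMatrix, min_rin: float = 7.0
) -> tuple[pd.DataFrame, ExpressionMatrix]:
    """Drop low-RIN samples from metadata and matrix, preserving order.

    Every expression sample must have a metadata row.  Raises if no sample
    survives the threshold.
    """
    known = set(meta["sample_id"])
    orphans = [s for s in expr.sample_ids if s not in known]
    if orphans:
        raise ValidationError(f"samples missing from metadata: {orphans}")
    keep_meta = meta[meta["rin"].astype(float) >= min_rin]
    keep_ids = [s for s in expr.sample_ids if s in set(keep_meta["sample_id"])]
    if not keep_ids:
        raise ValidationError("no samples survive filtering")
    logger.info(
        "RIN >= %.2f retained %d of %d samples", min_rin, len(keep_ids), expr.n_samples
    )
    kept_meta = keep_meta[keep_meta["sample_id"].isin(keep_ids)].reset_index(drop=True)
    return kept_meta, expr.select_samples(keep_ids)


def age_to_postnatal_years(age_value: float, age_unit: str) -> float:
    """Convert an age to years since birth (negative while prenatal).

    Birth is placed at 40 PCW; 1 year = 12 months = 52 weeks.
    """
    if age_unit == "pcw":
        return (float(age_value) - BIRTH_PCW) / WEEKS_PER_YEAR
    if age_unit == "month":
        return float(age_value) / 12.0
    if age_unit == "year":
        return float(age_value)
    raise ValidationError(f"unknown age unit {age_unit!r}; expected {VALID_AGE_UNITS}")


def assign_developmental_stage(age_value: float, age_unit: str) -> int:
    """Assign one of the five developmental stages.

    Stage 1: early-mid fetal, 8 <= PCW < 14; Stage 2: mid-late fetal,
    14 <= PCW < birth; Stage 3: birth to < 3 years; Stage 4: 3 to < 40
    years; Stage 5: 40 to 60 years.  Stage boundaries at 3 and 40 years use
    half-open intervals (the exact boundary belongs to the later stage).
    Ages outside [8 PCW, 60 years] raise.
    """
    if age_unit == "pcw":
        pcw = float(age_value)
        if pcw < 8:
            raise ValidationError(f"age {pcw} PCW is below the 8 PCW minimum")
        if pcw < 14:
            return 1
        if pcw < BIRTH_PCW:
            return 2
    years = age_to_postnatal_years(age_value, age_unit)
    if years < 0:
        # prenatal age expressed in months/years is not meaningful here
        raise ValidationError(
            f"negative postnatal age {age_value} {age_unit}; "
            "prenatal ages must be given in PCW"
        )
    if years < 3:
        return 3
    if years < 40:
        return 4
    if years <= 60:
        return 5
    raise ValidationError(f"age {age_value} {age_unit} is above the 60-year maximum")


def assign_region_cluster(region_code: str) -> int:
    """Map one of the 16 brain region codes to its regional cluster (1-4)."""
    try:
        return _REGION_TO_CLUSTER[region_code]
    except KeyError:
        raise ValidationError(
            f"unknown region code {region_code!r}; valid codes: "
            f"{', '.join(ALL_REGION_CODES)}"
        ) from None


def annotate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Add derived ``stage`` and ``region_cluster`` columns to metadata."""
    meta = meta.copy()
    meta["stage"] = [
        assign_developmental_stage(a, u)
        for a, u in zip(meta["age"], meta["age_unit"])
    ]
    meta["region_cluster"] = [assign_region_cluster(r) for r in meta["region"]]
    return meta


def subset_genes(expr: ExpressionMatrix, keep: GeneSet | Iterable[str]) -> ExpressionMatrix:
    """Restrict the matrix to genes in ``keep``, preserving row order."""
    keep_genes = keep.genes if isinstance(keep, GeneSet) else set(keep)
    if not keep_genes:
        raise ValidationError("gene subset is empty")
    mask = np.array([g in keep_genes for g in expr.gene_ids], dtype=bool)
    if not mask.any():
        raise ValidationError("gene universe mismatch: no genes in common")
    logger.info("retained %d of %d genes", int(mask.sum()), expr.n_genes)
    return ExpressionMatrix(
        gene_ids=expr.gene_ids[mask],
        sample_ids=expr.sample_ids.copy(),
        values=expr.values[mask],
    )


def read_gmt(path: str | Path, category: str = "other") -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: list[GeneSet] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"{path}:{line_no}: GMT line needs name, description, >=1 gene"
            )
        name, description, *genes = parts
        genes = [g for g in genes if g]
        sets.append(
            GeneSet(
                name=name,
                genes=frozenset(genes),
                category=category,
                description=description,
            )
        )
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, s.description or s.category, *sorted(s.genes)])
        for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-identifier-per-line gene list."""
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
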