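"""Reading, curation and quality gating of qPCR Cq expression tables.

The raw material of reference-gene selection is a genes x samples matrix of
quantification-cycle (Cq/Ct) values from a high-throughput RT-qPCR panel.
Before stability scoring the table must be curated: chip-specific control
probes and duplicate probe identifiers are removed, reactions that never
reached the detection threshold (non-detects) are treated as missing, and any
gene carrying a missing value is dropped so that every scorer sees a complete
matrix.  Whole datasets are additionally screened against inclusion criteria
(minimum panel size, minimum sample count, maximum missingness) before they
are allowed to contribute to a cross-dataset consensus.
"""

from __future__ import annotations

import fnmatch
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawDataset",
    "CuratedDataset",
    "InclusionReport",
    "DEFAULT_MISSING_TOKENS",
    "load_expression_table",
    "load_group_labels",
    "load_geo_series_matrix",
    "curate_dataset",
    "check_inclusion",
    "write_curated_dataset",
]

#: Cell contents commonly used by qPCR instruments/exports for non-detects.
DEFAULT_MISSING_TOKENS: tuple[str, ...] = (
    "", "NA", "N/A", "NaN", "nan", "null", "None", "Undetermined", "undetermined",
)


class DatasetFormatError(ValueError):
    """Raised when an input table cannot be interpreted as a Cq matrix."""


@dataclass
class RawDataset:
    """A parsed, uncurated Cq matrix (genes in rows, samples in columns).

    ``values`` holds Cq cycles as floats with ``nan`` marking non-detects /
    missing reactions.  ``group_labels``, when present, assigns one categorical
    label per sample (e.g. disease vs control) and enables the grouped
    NormFinder variant downstream.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group_labels: list[str] | None = None
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.isinf(self.values).any():
            raise ValueError("Cq values must be finite where present")
        if self.group_labels is not None and len(self.group_labels) != len(self.sample_ids):
            raise ValueError("one group label per sample required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DatasetFormatError("duplicate sample identifiers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean()) if self.values.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class CuratedDataset(RawDataset):
    """A curated Cq matrix: complete, control-free, with unique gene ids.

    ``curation_log`` records every removed gene as ``(gene_id, reason)``.
    """

    curation_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.isnan(self.values).any():
            raise ValueError("curated dataset must contain no missing values")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("curated dataset must have unique gene ids")

    def to_expression_table(self):
        """Convert to the complete table consumed by the stability scorers."""
        from .stability import ExpressionTable

        return ExpressionTable(
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            cq=self.values.copy(),
            groups=list(self.group_labels) if self.group_labels is not None else None,
        )


@dataclass
class InclusionReport:
    """Outcome of the dataset-level inclusion screen."""

    n_genes: int
    n_samples: int
    missing_fraction: float
    passed: bool
    failed_rules: list[str]


def _coerce_cell(cell: object, missing_tokens: set[str], detection_ceiling: float | None) -> float:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return np.nan
    text = str(cell).strip()
    if text in missing_tokens:
        return np.nan
    try:
        value = float(text)
    except ValueError as exc:
        raise DatasetFormatError(f"cell {cell!r} is neither numeric nor a missing token") from exc
    if detection_ceiling is not None and value >= detection_ceiling:
        return np.nan
    return value


def load_group_labels(path) -> dict[str, str]:
    """Read a two-column sample -> group annotation file (CSV/TSV)."""
    table = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str, comment="#")
    if table.shape[1] < 2:
        raise DatasetFormatError(f"group file {path} needs two columns (sample, group)")
    # tolerate a header row
    first = table.iloc[0]
    if str(first[0]).lower() in {"sample", "sample_id", "id"}:
        table = table.iloc[1:]
    return dict(zip(table.iloc[:, 0].str.strip(), table.iloc[:, 1].str.strip()))


def load_expression_table(
    path,
    orientation: str = "genes-in-rows",
    missing_tokens=DEFAULT_MISSING_TOKENS,
    groups_path=None,
    detection_ceiling: float | None = None,
    sep: str | None = None,
) -> RawDataset:
    """Load a delimited Cq table into the canonical genes x samples layout.

    Parameters
    ----------
    path
        Delimited text file with one identifier column (first) and one
        identifier row (header).
    orientation
        ``"genes-in-rows"`` (canonical) or ``"samples-in-rows"`` (the table is
        transposed on load).
    missing_tokens
        Cell contents mapped to missing (non-detect) values.
    groups_path
        Optional two-column sample -> group annotation file.
    detection_ceiling
        Optional Cq cutoff: measured values at or above it are treated as
        non-detects.  Off by default; many exports already encode non-detects
        as a token.
    sep
        Field separator; auto-detected when None.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        # header=None keeps duplicate identifiers intact (no pandas mangling)
        cells = pd.read_csv(path, sep=sep, engine="python", header=None, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DatasetFormatError(f"could not parse {path}: {exc}") from exc
    if cells.shape[0] < 2 or cells.shape[1] < 2:
        raise DatasetFormatError(f"{path} parsed to fewer than 2 rows/columns")
    header = [str(c).strip() for c in cells.iloc[0, 1:]]
    row_ids = [str(r).strip() for r in cells.iloc[1:, 0]]
    frame = pd.DataFrame(
        cells.iloc[1:, 1:].to_numpy(), index=row_ids, columns=header
    )
    if orientation == "samples-in-rows":
        frame = frame.T

    tokens = {str(t) for t in missing_tokens}
    values = np.empty(frame.shape, dtype=float)
    for i, (gene, row) in enumerate(frame.iterrows()):
        for j, cell in enumerate(row):
            try:
                values[i, j] = _coerce_cell(cell, tokens, detection_ceiling)
            except DatasetFormatError as exc:
                raise DatasetFormatError(f"{path}, gene {gene!r}, column {frame.columns[j]!r}: {exc}") from exc

    sample_ids = [str(c).strip() for c in frame.columns]
    gene_ids = [str(g).strip() for g in frame.index]

    group_labels = None
    if groups_path is not None:
        mapping = load_group_labels(groups_path)
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise DatasetFormatError(f"group file lacks labels for samples: {missing}")
        group_labels = [mapping[s] for s in sample_ids]

    return RawDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        group_labels=group_labels,
        source_tag=str(path),
    )


def load_geo_series_matrix(
    path,
    missing_tokens=DEFAULT_MISSING_TOKENS,
    detection_ceiling: float | None = None,
) -> RawDataset:
    """Parse a local GEO series-matrix text file into a RawDataset.

    Reads the ``series_matrix_table`` block (probes in rows, GSM samples in
    columns).  Metadata lines (``!``-prefixed) are ignored.  This is an
    offline convenience; it performs no network access.
    """
    rows: list[list[str]] = []
    header: list[str] | None = None
    in_table = False
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if not in_table or not line:
                continue
            fields = [f.strip().strip('"') for f in line.split("\t")]
            if header is None:
                header = fields
            else:
                rows.append(fields)
    if header is None or not rows:
        raise DatasetFormatError(f"{path} contains no series_matrix_table block")

    tokens = {str(t) for t in missing_tokens}
    gene_ids = [r[0] for r in rows]
    sample_ids = header[1:]
    values = np.empty((len(rows), len(sample_ids)), dtype=float)
    for i, r in enumerate(rows):
        cells = r[1:]
        if len(cells) != len(sample_ids):
            raise DatasetFormatError(f"{path}: row {r[0]!r} has {len(cells)} cells, expected {len(sample_ids)}")
        for j, cell in enumerate(cells):
            values[i, j] = _coerce_cell(cell, tokens, detection_ceiling)
    return RawDataset(gene_ids=gene_ids, sample_ids=sample_ids, values=values, source_tag=str(path))


def _matches_any(gene_id: str, patterns) -> bool:
    for pat in patterns:
        if fnmatch.fnmatch(gene_id, pat) or re.search(pat, gene_id, flags=re.IGNORECASE):
            return True
    return False


def curate_dataset(raw: RawDataset, control_patterns=()) -> CuratedDataset:
    """Curate a raw Cq table for stability scoring.

    Removal order: control probes (identifier matches a glob or regex in
    ``control_patterns``), duplicate gene ids (first occurrence kept), then
    every gene with at least one missing value.  Each removal is logged.
    """
    keep: list[int] = []
    log: list[tuple[str, str]] = []
    seen: set[str] = set()
    for i, gene in enumerate(raw.gene_ids):
        if control_patterns and _matches_any(gene, control_patterns):
            log.append((gene, "control_probe"))
            continue
        if gene in seen:
            log.append((gene, "duplicate_id"))
            continue
        seen.add(gene)
        if np.isnan(raw.values[i]).any():
            log.append((gene, "missing_values"))
            continue
        keep.append(i)

    if len(keep) < 2:
        raise ValueError(
            f"curation left {len(keep)} gene(s); stability scoring needs at least 2"
        )
    return CuratedDataset(
        gene_ids=[raw.gene_ids[i] for i in keep],
        sample_ids=list(raw.sample_ids),
        values=raw.values[keep].copy(),
        group_labels=list(raw.group_labels) if raw.group_labels is not None else None,
        source_tag=raw.source_tag,
        curation_log=log,
    )


def check_inclusion(
    raw: RawDataset,
    min_genes: int = 170,
    min_samples: int = 5,
    max_missing: float = 0.20,
) -> InclusionReport:
    """Screen a dataset against the panel-size / sample-count / missingness gate.

    A dataset passes when it measures at least ``min_genes`` genes on at least
    ``min_samples`` samples with a missing-value fraction strictly below
    ``max_missing``.
    """
    failed: list[str] = []
    if raw.n_genes < min_genes:
        failed.append("min_genes")
    if raw.n_samples < min_samples:
        failed.append("min_samples")
    missing = raw.missing_fraction
    if not missing < max_missing:
        failed.append("max_missing")
    return InclusionReport(
        n_genes=raw.n_genes,
        n_samples=raw.n_samples,
        missing_fraction=missing,
        passed=not failed,
        failed_rules=failed,
    )


def write_curated_dataset(curated: CuratedDataset, matrix_path, log_path=None) -> None:
    """Write the curated matrix as CSV and, optionally, the curation log."""
    curated.to_frame().to_csv(matrix_path, index_label="gene_id")
    if log_path is not None:
        pd.DataFrame(curated.curation_log, columns=["gene_id", "reason"]).to_csv(log_path, index=False)
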