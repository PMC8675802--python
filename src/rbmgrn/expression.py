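"""Expression-matrix I/O, normalization, ranking and gene selection.

The central container is :class:`ExpressionMatrix`, a genes x samples real
matrix with named rows and columns and an optional per-sample phenotype
label (e.g. ``normal`` / ``diseased``).  Matrices are read from delimited
text or from minimal GEO GDS SOFT files, rescaled per gene to [0, 1] with
MAXMIN normalization, and ranked between phenotype groups with the
Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "RankedGene",
    "ExpressionFormatError",
    "read_expression_table",
    "write_expression_table",
    "read_geo_soft_gds",
    "maxmin_normalize",
    "wilcoxon_rank_genes",
    "select_genes",
]


class ExpressionFormatError(ValueError):
    """Raised when an input file violates the expression-table contract."""


@dataclass
class ExpressionMatrix:
    """Named genes x samples matrix of real expression intensities.

    Parameters
    ----------
    data
        DataFrame with unique gene ids as the index and unique sample ids
        as columns; all values finite floats.
    phenotype
        Optional mapping sample id -> group label (e.g. ``"normal"``).
    """

    data: pd.DataFrame
    phenotype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ExpressionFormatError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ExpressionFormatError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ExpressionFormatError(
                f"non-finite value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        self.data = self.data.astype(float)
        unknown = set(self.phenotype) - set(map(str, cols))
        if unknown:
            raise ValueError(f"phenotype labels for unknown samples: {sorted(unknown)}")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene across all samples."""
        if gene_id not in self.data.index:
            raise KeyError(f"unknown gene id {gene_id!r}")
        return self.data.loc[gene_id].to_numpy()

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.phenotype.get(s) == label]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        pheno = {s: self.phenotype[s] for s in sample_ids if s in self.phenotype}
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy(), pheno)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class RankedGene:
    """One gene's rank-sum test outcome between two phenotype groups."""

    gene_id: str
    statistic: float  # rank-sum z; positive when group_a ranks higher
    p_value: float
    rank: int


def read_expression_table(
    path: str | Path,
    delimiter: str = "\t",
    has_phenotype_row: bool | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression table.

    Layout: row 1 holds sample ids (first cell is a corner label or empty);
    an optional row 2 starting with ``#group`` holds per-sample phenotype
    labels; every following row is one gene: id first, then one numeric
    value per sample.

    ``has_phenotype_row=None`` auto-detects the ``#group`` row.
    """
    path = Path(path)
    raw = path.read_text()
    lines = [ln for ln in raw.splitlines() if ln.strip() != ""]
    if not lines:
        raise ExpressionFormatError(f"{path}: empty expression table")
    header = lines[0].split(delimiter)
    sample_ids = [c.strip() for c in header[1:]]
    if not sample_ids:
        raise ExpressionFormatError(f"{path}: header row has no sample ids")
    body_start = 1
    phenotype: dict[str, str] = {}
    second = lines[1].split(delimiter) if len(lines) > 1 else []
    pheno_present = bool(second) and second[0].strip().lower() == "#group"
    if has_phenotype_row is True and not pheno_present:
        raise ExpressionFormatError(f"{path}: expected a '#group' phenotype row")
    if pheno_present and has_phenotype_row is not False:
        labels = [c.strip() for c in second[1:]]
        if len(labels) != len(sample_ids):
            raise ExpressionFormatError(
                f"{path}: phenotype row has {len(labels)} labels for "
                f"{len(sample_ids)} samples"
            )
        phenotype = {s: g for s, g in zip(sample_ids, labels) if g != ""}
        body_start = 2

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for ln in lines[body_start:]:
        cells = ln.split(delimiter)
        gene = cells[0].strip()
        if gene in seen:
            raise ExpressionFormatError(f"{path}: duplicate gene id {gene!r}")
        seen.add(gene)
        if len(cells) - 1 != len(sample_ids):
            raise ExpressionFormatError(
                f"{path}: gene {gene!r} has {len(cells) - 1} values, "
                f"expected {len(sample_ids)}"
            )
        parsed = []
        for sample, cell in zip(sample_ids, cells[1:]):
            try:
                value = float(cell)
            except ValueError:
                raise ExpressionFormatError(
                    f"{path}: non-numeric cell at gene {gene!r}, sample {sample!r}: "
                    f"{cell!r}"
                ) from None
            if not math.isfinite(value):
                raise ExpressionFormatError(
                    f"{path}: non-finite cell at gene {gene!r}, sample {sample!r}"
                )
            parsed.append(value)
        gene_ids.append(gene)
        rows.append(parsed)
    if not gene_ids:
        raise ExpressionFormatError(f"{path}: no gene rows")
    df = pd.DataFrame(rows, index=gene_ids, columns=sample_ids, dtype=float)
    matrix = ExpressionMatrix(df, phenotype)
    logger.info("read %d genes x %d samples from %s", matrix.n_genes, matrix.n_samples, path)
    return matrix


def write_expression_table(
    x: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> Path:
    """Write the TSV dialect read by :func:`read_expression_table`.

    Values are written with ``repr`` so a write/read round trip is exact.
    """
    path = Path(path)
    lines = [delimiter.join(["gene_id", *x.sample_ids])]
    if x.phenotype:
        lines.append(
            delimiter.join(["#group", *(x.phenotype.get(s, "") for s in x.sample_ids)])
        )
    for gene in x.gene_ids:
        row = x.data.loc[gene]
        lines.append(delimiter.join([gene, *(repr(float(v)) for v in row)]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_geo_soft_gds(path: str | Path, drop_bad_rows: bool = True) -> ExpressionMatrix:
    """Read a minimal GEO GDS SOFT dataset file.

    Only the GDS dialect is handled: metadata lines starting with ``^``,
    ``!`` or ``#``; ``!subset_sample_id`` / ``!subset_description`` blocks
    defining phenotype groups; a table between ``!dataset_table_begin`` and
    ``!dataset_table_end`` whose columns are ``ID_REF``, ``IDENTIFIER`` and
    one column per GSM sample.  Gene ids come from IDENTIFIER, falling back
    to ID_REF on blanks.  Rows with any non-numeric entry are dropped with a
    logged count (``drop_bad_rows=False`` raises instead).
    """
    path = Path(path)
    subset_desc: str | None = None
    subsets: list[tuple[str, list[str]]] = []
    table_lines: list[str] = []
    in_table = False
    for ln in path.read_text().splitlines():
        stripped = ln.strip()
        if stripped.lower() == "!dataset_table_begin":
            in_table = True
            continue
        if stripped.lower() == "!dataset_table_end":
            in_table = False
            continue
        if in_table:
            if stripped:
                table_lines.append(ln)
            continue
        if stripped.startswith("!subset_description"):
            subset_desc = stripped.split("=", 1)[1].strip()
        elif stripped.startswith("!subset_sample_id"):
            ids = [s.strip() for s in stripped.split("=", 1)[1].split(",") if s.strip()]
            subsets.append((subset_desc or f"subset{len(subsets) + 1}", ids))
    if not table_lines:
        raise ExpressionFormatError(f"{path}: no dataset table block found")

    header = table_lines[0].split("\t")
    try:
        idref_col = header.index("ID_REF")
    except ValueError:
        raise ExpressionFormatError(f"{path}: table has no ID_REF column") from None
    ident_col = header.index("IDENTIFIER") if "IDENTIFIER" in header else None
    sample_cols = [
        i for i, name in enumerate(header) if i not in (idref_col, ident_col)
    ]
    sample_ids = [header[i] for i in sample_cols]

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    dropped = 0
    for ln in table_lines[1:]:
        cells = ln.split("\t")
        ident = cells[ident_col].strip() if ident_col is not None else ""
        gene = ident or cells[idref_col].strip()
        try:
            parsed = [float(cells[i]) for i in sample_cols]
            if not all(math.isfinite(v) for v in parsed):
                raise ValueError
        except (ValueError, IndexError):
            if drop_bad_rows:
                dropped += 1
                continue
            raise ExpressionFormatError(
                f"{path}: non-numeric entry in row {gene!r}"
            ) from None
        gene_ids.append(gene)
        rows.append(parsed)
    if dropped:
        logger.warning("%s: dropped %d rows with non-numeric entries", path, dropped)

    phenotype: dict[str, str] = {}
    for label, ids in subsets:
        for sid in ids:
            if sid not in sample_ids:
                logger.warning("%s: subset sample %s absent from table; ignored", path, sid)
                continue
            phenotype[sid] = label

    df = pd.DataFrame(rows, index=gene_ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(df, phenotype)


def maxmin_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each gene row to [0, 1] via (g - min(g)) / (max(g) - min(g)).

    Rows with zero range (constant genes) have no defined rescaling and are
    mapped to all zeros, with a warning.  The operation is idempotent and
    preserves within-row order statistics.
    """
    values = x.values.astype(float)
    mins = values.min(axis=1, keepdims=True)
    maxs = values.max(axis=1, keepdims=True)
    span = maxs - mins
    flat = (span == 0).ravel()
    if flat.any():
        logger.warning(
            "constant expression rows normalized to zeros: %s",
            [g for g, f in zip(x.gene_ids, flat) if f],
        )
    safe = np.where(span == 0, 1.0, span)
    normed = (values - mins) / safe
    normed[flat, :] = 0.0
    df = pd.DataFrame(normed, index=x.data.index, columns=x.data.columns)
    return ExpressionMatrix(df, dict(x.phenotype))


def _ranksum_z(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected normal-approximation z for the two-sample rank sum.

    Mid-ranks for ties; continuity correction deliberately off.  Positive z
    means the first group tends to rank higher.
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks
    w = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0
    return (w - mu) / math.sqrt(var)


def wilcoxon_rank_genes(
    x: ExpressionMatrix, group_a: str, group_b: str
) -> list[RankedGene]:
    """Rank genes by differential expression between two phenotype groups.

    Per gene, a two-sided Wilcoxon rank-sum test of ``group_a`` vs
    ``group_b`` samples (mid-ranks, tie-corrected normal approximation, no
    continuity correction).  Genes are sorted ascending by p-value; ties by
    ``|z|`` descending, then gene id.  No multiple-testing correction is
    applied: the p-values serve only to order the genes.
    """
    samples_a = x.samples_in_group(group_a)
    samples_b = x.samples_in_group(group_b)
    if not samples_a:
        raise ValueError(f"no samples labelled {group_a!r}")
    if not samples_b:
        raise ValueError(f"no samples labelled {group_b!r}")
    cols_a = [x.sample_ids.index(s) for s in samples_a]
    cols_b = [x.sample_ids.index(s) for s in samples_b]
    values = x.values
    scored = []
    for gene, row in zip(x.gene_ids, values):
        z = _ranksum_z(row[cols_a], row[cols_b])
        p = float(2.0 * stats.norm.sf(abs(z))) if z != 0 else 1.0
        scored.append((gene, z, min(p, 1.0)))
    scored.sort(key=lambda t: (t[2], -abs(t[1]), t[0]))
    return [
        RankedGene(gene_id=g, statistic=float(z), p_value=p, rank=i + 1)
        for i, (g, z, p) in enumerate(scored)
    ]


def select_genes(x: ExpressionMatrix, keep: Sequence[str]) -> ExpressionMatrix:
    """Return the submatrix of ``keep`` genes, rows in the order of ``keep``."""
    missing = [g for g in keep if g not in x.data.index]
    if missing:
        raise ValueError(f"gene ids not present in matrix: {missing}")
    df = x.data.loc[list(keep)].copy()
    return ExpressionMatrix(df, dict(x.phenotype))
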