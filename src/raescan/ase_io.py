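"""Input/output for phased allele-count matrices, interval annotations and
gene sets.

The count-matrix dialect is the phASER gene-level format: a tab-separated
table with gene IDs in the first column, tissue labels in the header, and
cells of the form ``HAP_A_COUNT|HAP_B_COUNT``.  Internally a table carries an
``X`` matrix (haplotype-A counts), an ``N`` matrix (total phased counts) and
an explicit missingness mask, so unexpressed ``0|0`` cells and absent cells
stay distinguishable.

All interval coordinates are 0-based half-open; GTF input (1-based closed)
is converted at the boundary.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlleleCountTable",
    "FilterLog",
    "GeneSets",
    "GenomicInterval",
    "MatrixFormatError",
    "apply_filters",
    "read_gene_set",
    "read_intervals",
    "read_phased_matrix",
    "write_phased_matrix",
]

VALID_SEX = ("female", "male", "unknown")

_NA_TOKENS = {"", "na", "nan", "none", "null", "."}

_CELL_RE = re.compile(r"^(\d+)\|(\d+)$")


class MatrixFormatError(ValueError):
    """Raised when a phased count matrix violates the format contract."""


@dataclass
class AlleleCountTable:
    """One individual's gene x tissue phased allele counts.

    ``X[g, t]`` is the haplotype-A read count and ``N[g, t]`` the total phased
    read count for gene ``g`` in tissue ``t``; ``missing[g, t]`` marks cells
    with no observation (distinct from an observed ``0|0``).
    """

    individual_id: str
    genes: list[str]
    tissues: list[str]
    X: np.ndarray
    N: np.ndarray
    missing: np.ndarray
    sex: str = "unknown"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int64)
        self.N = np.asarray(self.N, dtype=np.int64)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.genes = list(self.genes)
        self.tissues = list(self.tissues)
        shape = (len(self.genes), len(self.tissues))
        for name, arr in (("X", self.X), ("N", self.N), ("missing", self.missing)):
            if arr.shape != shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
        if self.sex not in VALID_SEX:
            raise ValueError(f"sex must be one of {VALID_SEX}, got {self.sex!r}")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene IDs must be unique within a table")
        obs = ~self.missing
        if np.any(self.X[obs] < 0) or np.any(self.N[obs] < 0):
            raise ValueError("allele counts must be non-negative")
        if np.any(self.X[obs] > self.N[obs]):
            raise ValueError("X must not exceed N in any observed cell")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    def gene_counts(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """Return the (X, N) vectors over non-missing tissues for one gene."""
        i = self.genes.index(gene)
        obs = ~self.missing[i]
        return self.X[i, obs], self.N[i, obs]

    def subset_genes(self, keep: Sequence[str]) -> "AlleleCountTable":
        keep_set = set(keep)
        idx = [i for i, g in enumerate(self.genes) if g in keep_set]
        return replace(
            self,
            genes=[self.genes[i] for i in idx],
            X=self.X[idx],
            N=self.N[idx],
            missing=self.missing[idx],
        )

    def subset_tissues(self, keep: Sequence[str]) -> "AlleleCountTable":
        keep_set = set(keep)
        idx = [j for j, t in enumerate(self.tissues) if t in keep_set]
        return replace(
            self,
            tissues=[self.tissues[j] for j in idx],
            X=self.X[:, idx],
            N=self.N[:, idx],
            missing=self.missing[:, idx],
        )


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-", "."):
            object.__setattr__(self, "strand", ".")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class GeneSets:
    """Named gene-ID sets used for exclusion and calibration.

    ``excluded_loci`` holds mappability-flagged genes removed at filtering;
    X-linked, imprinted and HLA genes are excluded from enrichment analyses.
    """

    xci_controls: set[str] = field(default_factory=set)
    imprinted: set[str] = field(default_factory=set)
    hla: set[str] = field(default_factory=set)
    excluded_loci: set[str] = field(default_factory=set)

    def enrichment_exclusions(self) -> set[str]:
        return self.xci_controls | self.imprinted | self.hla


@dataclass
class FilterLog:
    """Attrition record for :func:`apply_filters`."""

    genes_in: int = 0
    cells_observed_in: int = 0
    cells_below_depth: int = 0
    genes_below_tissue_min: int = 0
    genes_excluded_loci: int = 0
    genes_out: int = 0

    def to_text(self) -> str:
        lines = [
            f"genes_in\t{self.genes_in}",
            f"cells_observed_in\t{self.cells_observed_in}",
            f"cells_below_depth\t{self.cells_below_depth}",
            f"genes_below_tissue_min\t{self.genes_below_tissue_min}",
            f"genes_excluded_loci\t{self.genes_excluded_loci}",
            f"genes_out\t{self.genes_out}",
        ]
        return "\n".join(lines) + "\n"


def read_phased_matrix(
    path: str | Path, individual_id: str | None = None, sex: str = "unknown"
) -> AlleleCountTable:
    """Read a phASER-style gene-level phased count matrix.

    The file is tab-separated with a header of tissue labels (first header
    field names the gene-ID column and is ignored) and one row per gene with
    ``a|b`` cells.  Empty cells and NA tokens are marked missing; ``0|0`` is
    an observed cell.  Malformed cells, ragged rows and duplicate gene IDs
    reject the file with row/column context.
    """
    path = Path(path)
    if individual_id is None:
        individual_id = path.stem.split(".")[0]
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise MatrixFormatError(f"{path}: empty file")
        tissues = header.split("\t")[1:]
        if not tissues:
            raise MatrixFormatError(f"{path}: header has no tissue columns")
        n_t = len(tissues)
        genes: list[str] = []
        x_rows: list[list[int]] = []
        n_rows: list[list[int]] = []
        m_rows: list[list[bool]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_t + 1:
                raise MatrixFormatError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                    f"expected {n_t + 1})"
                )
            gene = fields[0]
            if gene in seen:
                raise MatrixFormatError(f"{path}:{lineno}: duplicate gene ID {gene!r}")
            seen.add(gene)
            xs, ns, ms = [], [], []
            for col, cell in enumerate(fields[1:]):
                token = cell.strip()
                if token.lower() in _NA_TOKENS:
                    xs.append(0)
                    ns.append(0)
                    ms.append(True)
                    continue
                m = _CELL_RE.match(token)
                if not m:
                    raise MatrixFormatError(
                        f"{path}:{lineno}: malformed cell {cell!r} for gene "
                        f"{gene!r}, tissue {tissues[col]!r} "
                        "(expected 'a|b' non-negative integers)"
                    )
                a, b = int(m.group(1)), int(m.group(2))
                xs.append(a)
                ns.append(a + b)
                ms.append(False)
            genes.append(gene)
            x_rows.append(xs)
            n_rows.append(ns)
            m_rows.append(ms)
    if not genes:
        raise MatrixFormatError(f"{path}: no gene rows")
    return AlleleCountTable(
        individual_id=individual_id,
        sex=sex,
        genes=genes,
        tissues=tissues,
        X=np.array(x_rows, dtype=np.int64),
        N=np.array(n_rows, dtype=np.int64),
        missing=np.array(m_rows, dtype=bool),
    )


def write_phased_matrix(table: AlleleCountTable, path: str | Path) -> None:
    """Write a table back to the phASER-style dialect (missing cells empty)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("name\t" + "\t".join(table.tissues) + "\n")
        for i, gene in enumerate(table.genes):
            cells = []
            for j in range(table.n_tissues):
                if table.missing[i, j]:
                    cells.append("")
                else:
                    x = table.X[i, j]
                    cells.append(f"{x}|{table.N[i, j] - x}")
            fh.write(gene + "\t" + "\t".join(cells) + "\n")


def apply_filters(
    table: AlleleCountTable,
    min_depth: int = 10,
    min_tissues: int = 3,
    excluded: GeneSets | None = None,
) -> tuple[AlleleCountTable, FilterLog]:
    """Depth/tissue/locus filtering of a validated table.

    Cells with ``N < min_depth`` become missing; genes with fewer than
    ``min_tissues`` surviving cells are dropped; genes in
    ``excluded.excluded_loci`` are dropped.  Returns the filtered table and a
    :class:`FilterLog` of per-step attrition.  Idempotent.
    """
    if min_depth < 1:
        raise ValueError(f"min_depth must be >= 1, got {min_depth}")
    if min_tissues < 1:
        raise ValueError(f"min_tissues must be >= 1, got {min_tissues}")
    log = FilterLog(
        genes_in=table.n_genes,
        cells_observed_in=int((~table.missing).sum()),
    )
    missing = table.missing | (table.N < min_depth)
    log.cells_below_depth = int(missing.sum() - table.missing.sum())

    tissues_per_gene = (~missing).sum(axis=1)
    keep = tissues_per_gene >= min_tissues
    log.genes_below_tissue_min = int((~keep).sum())

    if excluded is not None and excluded.excluded_loci:
        flagged = np.array([g in excluded.excluded_loci for g in table.genes])
        log.genes_excluded_loci = int((keep & flagged).sum())
        keep &= ~flagged

    idx = np.flatnonzero(keep)
    X = table.X.copy()
    N = table.N.copy()
    X[missing] = 0
    N[missing] = 0
    out = AlleleCountTable(
        individual_id=table.individual_id,
        sex=table.sex,
        genes=[table.genes[i] for i in idx],
        tissues=table.tissues,
        X=X[idx],
        N=N[idx],
        missing=missing[idx],
    )
    log.genes_out = out.n_genes
    return out, log


_GTF_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def read_intervals(path: str | Path, format: str = "bed") -> list[GenomicInterval]:
    """Read gene/domain intervals from BED or GTF.

    BED is consumed natively (0-based half-open).  GTF records (1-based
    closed) are converted to 0-based half-open; only ``gene`` features are
    kept when a feature column is present, so isoform-collapsed annotation is
    expected.  Records that are empty after conversion are skipped with a
    warning; unknown strand symbols map to ``.``.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt not in ("bed", "gtf"):
        raise ValueError(f"format must be 'bed' or 'gtf', got {format!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            f = line.split("\t")
            if fmt == "bed":
                if len(f) < 3:
                    raise ValueError(f"{path}:{lineno}: BED line has <3 fields")
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
                strand = f[5] if len(f) > 5 else "."
            else:
                if len(f) < 8:
                    raise ValueError(f"{path}:{lineno}: GTF line has <8 fields")
                if f[2] != "gene":
                    continue
                chrom = f[0]
                start = int(f[3]) - 1  # 1-based closed -> 0-based half-open
                end = int(f[4])
                strand = f[6]
                attrs = f[8] if len(f) > 8 else ""
                m = _GTF_GENE_ID_RE.search(attrs)
                name = m.group(1) if m else f"{chrom}:{start}-{end}"
            if strand not in ("+", "-"):
                strand = "."
            if end <= start:
                warnings.warn(
                    f"{path}:{lineno}: skipping record {name!r} with "
                    f"non-positive span after conversion"
                )
                continue
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def read_gene_set(path: str | Path) -> set[str]:
    """Read a plain-text gene-ID list (one ID per line, '#' comments)."""
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                ids.add(token.split("\t")[0])
    return ids


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom<TAB>size table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_results_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with a stable column order."""
    frame.to_csv(path, sep="\t", index=False)


def read_sex_map(path: str | Path) -> dict[str, str]:
    """Read individual<TAB>sex pairs; sex must be female/male/unknown."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            ind, sex = line.rstrip("\n").split("\t")[:2]
            sex = sex.strip().lower()
            if sex not in VALID_SEX:
                raise ValueError(f"invalid sex {sex!r} for individual {ind!r}")
            out[ind] = sex
    return out
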