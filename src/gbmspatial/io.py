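"""Readers and writers for the formats the pipeline touches.

Everything downstream consumes only the in-memory containers defined here:
raw integer count matrices (genes x cells or genes x spots), spot geometry
tables, gene genomic metadata, cell-state signature gene lists, and spot
region annotations.  Genomic positions are 0-based half-open throughout.
Gene symbols are the join key across reference, spatial, and signature
inputs; symbol collisions are resolved by first occurrence with a logged
warning.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "CountMatrix",
    "SpotGeometry",
    "GeneMeta",
    "RegionAnnotation",
    "DEFAULT_CHROMOSOMES",
    "read_counts",
    "read_counts_csv",
    "read_counts_mtx",
    "write_counts_csv",
    "write_counts_mtx",
    "read_spot_positions",
    "write_spot_positions",
    "read_signatures",
    "write_signatures",
    "read_gene_meta",
    "write_gene_meta",
    "read_region_annotation",
    "write_region_annotation",
]


class FormatError(ValueError):
    """A file does not have the structure the reader expects."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


#: Human chromosome order used to sort genes genomically.
DEFAULT_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dupes}")


@dataclass
class CountMatrix:
    """Raw integer counts, genes x units (cells or spots).

    ``values`` is a dense int64 array; synthetic and desk-scale inputs are
    small enough that sparsity buys nothing downstream.
    """

    values: np.ndarray
    gene_ids: list[str]
    unit_ids: list[str]
    unit_kind: str  # "cell" | "spot"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be 2-dimensional")
        if self.values.dtype.kind == "f":
            if not np.all(np.isfinite(self.values)) or np.any(self.values != np.floor(self.values)):
                raise ValidationError("counts must be integral")
            self.values = self.values.astype(np.int64)
        elif self.values.dtype.kind not in "iu":
            raise ValidationError(f"counts must be numeric, got dtype {self.values.dtype}")
        else:
            self.values = self.values.astype(np.int64)
        if np.any(self.values < 0):
            raise ValidationError("counts must be non-negative")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.unit_ids = [str(u) for u in self.unit_ids]
        if self.values.shape != (len(self.gene_ids), len(self.unit_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.unit_ids)} units"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.unit_ids, f"{self.unit_kind} barcodes")
        if self.unit_kind not in ("cell", "spot"):
            raise ValidationError(f"unit_kind must be 'cell' or 'spot', got {self.unit_kind!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.unit_ids)

    def select_units(self, unit_ids: Sequence[str]) -> "CountMatrix":
        pos = pd.Index(self.unit_ids).get_indexer(list(unit_ids))
        if np.any(pos < 0):
            missing = [u for u, p in zip(unit_ids, pos) if p < 0][:5]
            raise KeyError(f"unknown {self.unit_kind} barcodes: {missing}")
        return CountMatrix(self.values[:, pos], list(self.gene_ids), list(unit_ids), self.unit_kind)

    def select_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        pos = pd.Index(self.gene_ids).get_indexer(list(gene_ids))
        if np.any(pos < 0):
            missing = [g for g, p in zip(gene_ids, pos) if p < 0][:5]
            raise KeyError(f"unknown genes: {missing}")
        return CountMatrix(self.values[pos, :], list(gene_ids), list(self.unit_ids), self.unit_kind)


@dataclass
class SpotGeometry:
    """Per-spot slide geometry: integer array grid plus continuous positions."""

    unit_ids: list[str]
    array_row: np.ndarray
    array_col: np.ndarray
    x: np.ndarray
    y: np.ndarray
    in_tissue: np.ndarray

    def __post_init__(self) -> None:
        self.unit_ids = [str(u) for u in self.unit_ids]
        _check_unique(self.unit_ids, "spot barcodes")
        n = len(self.unit_ids)
        self.array_row = np.asarray(self.array_row, dtype=np.int64)
        self.array_col = np.asarray(self.array_col, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
        for name in ("array_row", "array_col", "x", "y", "in_tissue"):
            if len(getattr(self, name)) != n:
                raise FormatError(f"{name} length does not match number of barcodes")
        if not self.in_tissue.any():
            raise ValidationError("no spots flagged in_tissue")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.unit_ids,
                "in_tissue": self.in_tissue.astype(int),
                "array_row": self.array_row,
                "array_col": self.array_col,
                "y": self.y,
                "x": self.x,
            }
        )


@dataclass
class GeneMeta:
    """Gene genomic metadata: symbol, chromosome, 0-based start."""

    table: pd.DataFrame  # columns: gene_id, chromosome, start
    chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES

    def __post_init__(self) -> None:
        required = {"gene_id", "chromosome", "start"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"gene metadata needs columns {sorted(required)}")
        self.table = self.table.reset_index(drop=True).copy()
        self.table["gene_id"] = self.table["gene_id"].astype(str)
        self.table["chromosome"] = self.table["chromosome"].astype(str)
        self.table["start"] = self.table["start"].astype(np.int64)
        _check_unique(self.table["gene_id"].tolist(), "gene ids in gene metadata")
        if (self.table["start"] < 0).any():
            raise ValidationError("gene start positions must be non-negative")
        unknown = set(self.table["chromosome"]) - set(self.chromosomes)
        if unknown:
            raise ValidationError(f"chromosomes not in the declared list: {sorted(unknown)}")

    def genomic_order(self, gene_ids: Sequence[str]) -> list[str]:
        """Sort the given genes by (chromosome order, start); drops genes without metadata."""
        tab = self.table.set_index("gene_id")
        present = [g for g in gene_ids if g in tab.index]
        dropped = len(gene_ids) - len(present)
        if dropped:
            logger.warning("%d genes lack genomic metadata and were dropped", dropped)
        chrom_rank = {c: i for i, c in enumerate(self.chromosomes)}
        return sorted(present, key=lambda g: (chrom_rank[tab.at[g, "chromosome"]], tab.at[g, "start"], g))


@dataclass
class RegionAnnotation:
    """Spot barcode -> niche/region label (at most one label per spot)."""

    labels: pd.Series  # index: barcode, values: label

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        self.labels.index = self.labels.index.astype(str)
        if self.labels.index.has_duplicates:
            raise ValidationError("a spot may carry at most one region label")

    @property
    def unit_ids(self) -> list[str]:
        return self.labels.index.tolist()

    def validate_against(self, counts: CountMatrix) -> None:
        missing = set(self.labels.index) - set(counts.unit_ids)
        if missing:
            raise ValidationError(f"annotated barcodes absent from the count matrix: {sorted(missing)[:5]}")

    def spots(self, label: str) -> list[str]:
        return self.labels.index[self.labels == label].tolist()


# ---------------------------------------------------------------------------
# count matrices

def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_id_column(path: Path, column: int | None = None) -> list[str]:
    rows = []
    with _open_text(Path(path)) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise FormatError(f"empty id file: {path}")
    ncol = len(rows[0])
    if column is None:
        # 10x features files are (gene_id, gene_symbol, type); barcodes one column
        column = 1 if ncol >= 2 else 0
    return [r[column] for r in rows]


def _resolve_gene_collisions(values: np.ndarray, gene_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    idx = pd.Index(gene_ids)
    if not idx.has_duplicates:
        return values, gene_ids
    keep = ~idx.duplicated(keep="first")
    n_drop = int((~keep).sum())
    logger.warning("%d duplicate gene symbols resolved by first occurrence", n_drop)
    return values[keep.nonzero()[0], :], idx[keep].tolist()


def read_counts_mtx(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    unit_kind: str = "cell",
    feature_column: int | None = None,
) -> CountMatrix:
    """Read a 10x-style MatrixMarket triplet.

    Both genes-in-rows and genes-in-columns matrices are accepted; the
    orientation is detected from the features/barcodes lengths.
    """
    genes = _read_id_column(features_path, feature_column)
    barcodes = _read_id_column(barcodes_path, 0)
    mat = spio.mmread(str(matrix_path))
    mat = sparse.coo_matrix(mat)
    if mat.shape == (len(genes), len(barcodes)):
        pass
    elif mat.shape == (len(barcodes), len(genes)):
        mat = mat.T
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither {len(genes)} genes x "
            f"{len(barcodes)} barcodes nor its transpose"
        )
    dense = np.asarray(mat.todense())
    if np.any(dense < 0) or (dense.dtype.kind == "f" and np.any(dense != np.floor(dense))):
        raise ValidationError("MTX entries must be non-negative integers")
    _check_unique(barcodes, "barcodes")
    dense, genes = _resolve_gene_collisions(dense.astype(np.int64), genes)
    return CountMatrix(dense, genes, barcodes, unit_kind)


def read_counts_csv(path: str | Path, unit_kind: str = "cell") -> CountMatrix:
    """Read a dense CSV with gene rows (first column = gene symbol) and unit columns."""
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise FormatError(f"empty count CSV: {path}")
    values = df.to_numpy()
    if values.dtype.kind not in "iuf":
        raise ValidationError("count CSV contains non-numeric entries")
    _check_unique([str(c) for c in df.columns], "barcodes")
    dense, genes = _resolve_gene_collisions(values, [str(g) for g in df.index])
    return CountMatrix(dense, genes, [str(c) for c in df.columns], unit_kind)


def read_counts(path_set, unit_kind: str = "cell") -> CountMatrix:
    """Dispatch: a single CSV path, an MTX-triplet directory, or a 3-tuple of paths."""
    if isinstance(path_set, (tuple, list)):
        if len(path_set) != 3:
            raise FormatError("expected (matrix, features, barcodes) paths")
        return read_counts_mtx(*path_set, unit_kind=unit_kind)
    p = Path(path_set)
    if p.is_dir():
        def find(*names):
            for name in names:
                for cand in (p / name, p / (name + ".gz")):
                    if cand.exists():
                        return cand
            raise FormatError(f"none of {names} found in {p}")
        return read_counts_mtx(
            find("matrix.mtx"), find("features.tsv", "genes.tsv"), find("barcodes.tsv"),
            unit_kind=unit_kind,
        )
    return read_counts_csv(p, unit_kind=unit_kind)


def write_counts_csv(counts: CountMatrix, path: str | Path) -> None:
    counts.to_frame().to_csv(path, index_label="gene")


def write_counts_mtx(counts: CountMatrix, outdir: str | Path) -> None:
    """Write a plain-text 10x-style triplet (matrix.mtx, features.tsv, barcodes.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(counts.values))
    with open(outdir / "features.tsv", "w") as fh:
        for g in counts.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(outdir / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(counts.unit_ids) + "\n")


# ---------------------------------------------------------------------------
# spot positions

POSITION_COLUMNS = ("barcode", "in_tissue", "array_row", "array_col", "y", "x")


def read_spot_positions(
    path: str | Path,
    columns: Sequence[str] = POSITION_COLUMNS,
) -> SpotGeometry:
    """Read a spot-positions CSV (10x tissue_positions convention by default).

    The header is optional and auto-detected; ``columns`` declares the column
    order when the file has no (or non-standard) header.
    """
    missing = set(POSITION_COLUMNS) - set(columns)
    if missing:
        raise FormatError(f"column specification is missing {sorted(missing)}")
    first = pd.read_csv(path, header=None, nrows=1)
    has_header = not str(first.iloc[0, 1]).strip().lstrip("-").isdigit()
    if has_header:
        df = pd.read_csv(path)
        missing = set(columns) - set(df.columns)
        if missing:
            raise FormatError(f"positions file is missing columns {sorted(missing)}")
    else:
        df = pd.read_csv(path, header=None, names=list(columns))
    _check_unique(df["barcode"].astype(str).tolist(), "spot barcodes")
    return SpotGeometry(
        unit_ids=df["barcode"].astype(str).tolist(),
        array_row=df["array_row"].to_numpy(),
        array_col=df["array_col"].to_numpy(),
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        in_tissue=df["in_tissue"].to_numpy().astype(bool),
    )


def write_spot_positions(geom: SpotGeometry, path: str | Path) -> None:
    geom.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# signatures

def read_signatures(
    path: str | Path | Mapping[str, str | Path],
    counts: CountMatrix | None = None,
) -> dict[str, list[str]]:
    """Read cell-state signature gene lists.

    Accepts either a two-column CSV (state, gene) or a mapping
    state -> one-gene-per-line list file.  Duplicate genes within a state are
    dropped with a warning; a state with zero genes is an error.  If a count
    matrix is supplied, genes absent from it are warned about (not removed).
    """
    out: dict[str, list[str]] = {}
    if isinstance(path, Mapping):
        for state, p in path.items():
            with _open_text(Path(p)) as fh:
                genes = [ln.strip() for ln in fh if ln.strip()]
            out[str(state)] = genes
    else:
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise FormatError("signature CSV needs (state, gene) columns")
        state_col, gene_col = df.columns[:2]
        for state, grp in df.groupby(state_col, sort=False):
            out[str(state)] = [str(g) for g in grp[gene_col]]
    result: dict[str, list[str]] = {}
    for state, genes in out.items():
        unique = list(dict.fromkeys(genes))
        if len(unique) < len(genes):
            logger.warning("state %s: %d duplicate genes dropped", state, len(genes) - len(unique))
        if not unique:
            raise ValidationError(f"state {state!r} has an empty gene list")
        if counts is not None:
            absent = sorted(set(unique) - set(counts.gene_ids))
            if absent:
                logger.warning("state %s: %d signature genes absent from the matrix (%s...)",
                               state, len(absent), absent[:3])
        result[state] = unique
    return result


def write_signatures(signatures: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [(state, g) for state, genes in signatures.items() for g in genes]
    pd.DataFrame(rows, columns=["state", "gene"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# gene metadata and region annotations

def read_gene_meta(path: str | Path, chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES) -> GeneMeta:
    df = pd.read_csv(path)
    return GeneMeta(df, chromosomes)


def write_gene_meta(meta: GeneMeta, path: str | Path) -> None:
    meta.table.to_csv(path, index=False)


def read_region_annotation(path: str | Path) -> RegionAnnotation:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("region annotation needs (barcode, label) columns")
    ser = pd.Series(df.iloc[:, 1].astype(str).to_numpy(), index=df.iloc[:, 0].astype(str), name="label")
    return RegionAnnotation(ser)


def write_region_annotation(ann: RegionAnnotation, path: str | Path) -> None:
    ann.labels.rename_axis("barcode").to_csv(path)
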