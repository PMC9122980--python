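"""Domain containers and on-disk readers/writers.

The package works with two primary inputs: a spatial reference map (3D cell
coordinates plus binary expression calls for a small panel of reference
genes) and a normalized single-nucleus expression matrix.  Both are plain
rectangular tables; :class:`SpatialMap` and :class:`ExpressionMatrix` wrap
them with the invariants every downstream step relies on (binary reference
calls, non-negative expression, unique identifiers, cells/nuclei as rows).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class FormatError(ValueError):
    """A file does not follow the expected on-disk schema."""


class ValidationError(ValueError):
    """Parsed data violate a container invariant."""


# ---------------------------------------------------------------------------
# containers


@dataclasses.dataclass
class SpatialMap:
    """3D cell positions plus binary reference-gene calls.

    Parameters
    ----------
    cell_ids : sequence of str
        Unique cell identifiers, one per row of ``coords``/``ref_expr``.
    coords : (n_cells, 3) float array
        Cell center positions; treated as unitless Euclidean.
    ref_genes : sequence of str
        Ordered reference-gene identifiers (columns of ``ref_expr``).
    ref_expr : (n_cells, n_ref_genes) array of {0, 1}
        Binary expression calls.
    attrs : DataFrame, optional
        Per-cell scalar annotations (volume, lineage, growth, ...).
    """

    cell_ids: np.ndarray
    coords: np.ndarray
    ref_genes: np.ndarray
    ref_expr: np.ndarray
    attrs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.ref_genes = np.asarray(self.ref_genes, dtype=object)
        self.ref_expr = np.asarray(self.ref_expr)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must be an (n_cells, 3) array")
        if not np.isfinite(self.coords).all():
            raise ValidationError("coords contain non-finite values")
        n = len(self.cell_ids)
        if self.coords.shape[0] != n or self.ref_expr.shape[0] != n:
            raise ValidationError("row counts of cell_ids/coords/ref_expr differ")
        if self.ref_expr.shape[1] != len(self.ref_genes):
            raise ValidationError("ref_expr columns must match ref_genes")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("duplicate cell ids")
        vals = np.unique(self.ref_expr)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError(
                "reference-gene calls must be binary (0/1); "
                "pass binarize_threshold to coerce graded calls"
            )
        self.ref_expr = self.ref_expr.astype(np.int8)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_ref_genes(self) -> int:
        return len(self.ref_genes)

    def subset_cells(self, mask: np.ndarray) -> "SpatialMap":
        """Row-subset preserving order; ``mask`` is boolean or index array."""
        attrs = self.attrs.iloc[np.flatnonzero(mask)] if (
            self.attrs is not None and np.asarray(mask).dtype == bool
        ) else (self.attrs.iloc[mask] if self.attrs is not None else None)
        return SpatialMap(
            self.cell_ids[mask], self.coords[mask], self.ref_genes,
            self.ref_expr[mask], attrs,
        )

    def subset_genes(self, genes: Sequence[str]) -> "SpatialMap":
        idx = [int(np.flatnonzero(self.ref_genes == g)[0]) for g in genes]
        return SpatialMap(
            self.cell_ids, self.coords, np.asarray(genes, dtype=object),
            self.ref_expr[:, idx], self.attrs,
        )

    def drop_gene(self, gene: str) -> "SpatialMap":
        keep = [g for g in self.ref_genes if g != gene]
        if len(keep) == len(self.ref_genes):
            raise KeyError(gene)
        return self.subset_genes(keep)


@dataclasses.dataclass
class ExpressionMatrix:
    """Nuclei × genes non-negative normalized expression."""

    barcodes: np.ndarray
    genes: np.ndarray
    values: np.ndarray
    binary_flag: bool = False

    def __post_init__(self) -> None:
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.genes = np.asarray(self.genes, dtype=object)
        if sparse.issparse(self.values):
            self.values = np.asarray(self.values.todense())
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D (nuclei × genes)")
        if self.values.shape != (len(self.barcodes), len(self.genes)):
            raise ValidationError("values shape must be (n_barcodes, n_genes)")
        if len(self.barcodes) == 0:
            raise ValidationError("no nuclei")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValidationError("duplicate barcodes")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes")
        if (self.values < 0).any():
            raise ValidationError("negative expression values")
        if self.binary_flag and not np.isin(np.unique(self.values), (0, 1)).all():
            raise ValidationError("binary_flag set but values are not 0/1")

    @property
    def n_nuclei(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
        return np.array([pos[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            self.barcodes, np.asarray(genes, dtype=object),
            self.values[:, idx], self.binary_flag,
        )

    def subset_nuclei(self, mask: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.barcodes[mask], self.genes, self.values[mask], self.binary_flag
        )


class GeneSet(tuple):
    """Ordered, unique gene identifiers."""

    def __new__(cls, genes: Iterable[str]):
        genes = list(genes)
        if len(set(genes)) != len(genes):
            raise ValidationError("GeneSet entries must be unique")
        return super().__new__(cls, genes)


@dataclasses.dataclass
class ClusterLabels:
    """barcode → cluster id mapping."""

    mapping: dict

    def __post_init__(self) -> None:
        self.mapping = dict(self.mapping)

    def labels_for(self, barcodes: Sequence[str], fill: str = "unassigned"):
        return np.asarray(
            [self.mapping.get(b, fill) for b in barcodes], dtype=object
        )


# ---------------------------------------------------------------------------
# readers


_COORD_COLS = ("x", "y", "z")


def read_spatial_map(
    path: str | Path,
    fmt: str | None = None,
    binarize_threshold: float | None = None,
) -> SpatialMap:
    """Read a spatial reference map from CSV/TSV.

    Expected header: ``cell_id,x,y,z,<gene>...``; extra non-gene columns named
    ``volume``/``lineage``/``growth`` are kept as per-cell attributes.  Gene
    columns must be 0/1 unless ``binarize_threshold`` is given, in which case
    values ``> threshold`` are called expressed.
    """
    path = Path(path)
    sep = _sep_for(path, fmt)
    df = pd.read_csv(path, sep=sep)
    if "cell_id" not in df.columns:
        raise FormatError("missing 'cell_id' column")
    for c in _COORD_COLS:
        if c not in df.columns:
            raise FormatError(f"missing coordinate column '{c}'")
    attr_cols = [c for c in ("volume", "lineage", "growth") if c in df.columns]
    gene_cols = [
        c for c in df.columns
        if c not in ("cell_id", *_COORD_COLS) and c not in attr_cols
    ]
    if not gene_cols:
        raise FormatError("no reference-gene columns found")
    expr = df[gene_cols].to_numpy(dtype=float)
    if binarize_threshold is not None:
        expr = (expr > binarize_threshold).astype(np.int8)
    ids = df["cell_id"].astype(str).to_numpy(dtype=object)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate cell ids")
    attrs = df[attr_cols].copy() if attr_cols else None
    return SpatialMap(
        ids, df[list(_COORD_COLS)].to_numpy(dtype=float),
        np.asarray(gene_cols, dtype=object), expr, attrs,
    )


def read_expression(
    path_matrix: str | Path,
    path_genes: str | Path | None = None,
    path_barcodes: str | Path | None = None,
    orientation: str = "nuclei_by_genes",
) -> ExpressionMatrix:
    """Read an expression matrix.

    Either a dense CSV/TSV with a header row of gene (or barcode) names and an
    index column, orientation declared via ``orientation`` in
    ``{"nuclei_by_genes", "genes_by_nuclei"}``, or a Matrix Market triplet file
    accompanied by one-column gene and barcode lists (genes as MTX rows,
    barcodes as columns, the 10x convention).
    """
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        if path_genes is None or path_barcodes is None:
            raise FormatError("MTX input requires gene and barcode lists")
        mat = spio.mmread(path_matrix)
        genes = _read_list(path_genes)
        barcodes = _read_list(path_barcodes)
        if mat.shape != (len(genes), len(barcodes)):
            raise FormatError(
                f"MTX shape {mat.shape} does not match gene list "
                f"({len(genes)}) × barcode list ({len(barcodes)})"
            )
        values = np.asarray(mat.todense()).T  # nuclei as rows
        return ExpressionMatrix(barcodes, genes, values)
    sep = _sep_for(path_matrix, None)
    df = pd.read_csv(path_matrix, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError("no nuclei")
    if orientation == "genes_by_nuclei":
        df = df.T
    elif orientation != "nuclei_by_genes":
        raise FormatError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(
        df.index.astype(str).to_numpy(dtype=object),
        df.columns.astype(str).to_numpy(dtype=object),
        df.to_numpy(dtype=float),
    )


def read_gene_set(path: str | Path) -> GeneSet:
    return GeneSet(_read_list(path))


def read_cluster_labels(path: str | Path) -> ClusterLabels:
    """Two-column CSV/TSV: barcode, cluster id."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, None), header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("cluster labels need two columns: barcode, cluster")
    if df.iloc[0, 0].lower() in ("barcode", "cell", "cell_id"):
        df = df.iloc[1:]
    dup = df.iloc[:, 0].duplicated()
    if dup.any():
        raise ValidationError("barcode labelled more than once")
    return ClusterLabels(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


# ---------------------------------------------------------------------------
# writers


def standardize(values: np.ndarray) -> np.ndarray:
    """Per-column z-score with population variance.

    Zero-variance columns map to all-zeros rather than dividing by zero.
    """
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=0)
    sd = values.std(axis=0)  # population sd
    out = values - mu
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


def write_atlas(atlas, spatial_map: SpatialMap, out_dir: str | Path,
                standardized: bool = False) -> dict:
    """Write a reconstructed atlas next to its map.

    Emits ``predicted_expression.csv`` (cells × genes), ``atlas_long.csv``
    (cell, x, y, z, gene, value — for 3D viewers) and, optionally,
    ``predicted_expression_standardized.csv`` (per-gene mean 0, variance 1,
    the convention used for visual comparison of patterns).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not np.array_equal(atlas.cell_ids, spatial_map.cell_ids):
        raise ValidationError("atlas cell order does not match the spatial map")
    wide = pd.DataFrame(atlas.values, index=atlas.cell_ids, columns=atlas.genes)
    wide.index.name = "cell_id"
    paths = {"predicted": out_dir / "predicted_expression.csv"}
    wide.to_csv(paths["predicted"])
    long = wide.reset_index().melt(id_vars="cell_id", var_name="gene",
                                   value_name="value")
    coords = pd.DataFrame(spatial_map.coords, columns=list(_COORD_COLS))
    coords.insert(0, "cell_id", spatial_map.cell_ids)
    long = coords.merge(long, on="cell_id")
    paths["long"] = out_dir / "atlas_long.csv"
    long.to_csv(paths["long"], index=False)
    if standardized:
        std = pd.DataFrame(standardize(atlas.values), index=atlas.cell_ids,
                           columns=atlas.genes)
        std.index.name = "cell_id"
        paths["standardized"] = out_dir / "predicted_expression_standardized.csv"
        std.to_csv(paths["standardized"])
    return paths


def write_spatial_map(spatial_map: SpatialMap, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(spatial_map.coords, columns=list(_COORD_COLS))
    df.insert(0, "cell_id", spatial_map.cell_ids)
    for j, g in enumerate(spatial_map.ref_genes):
        df[g] = spatial_map.ref_expr[:, j]
    df.to_csv(path, index=False)
    return path


def write_expression(expr: ExpressionMatrix, path_matrix: str | Path,
                     path_genes: str | Path | None = None,
                     path_barcodes: str | Path | None = None) -> None:
    """Write dense CSV (default) or MTX triplet when given the list paths."""
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        if path_genes is None or path_barcodes is None:
            raise FormatError("MTX output requires gene and barcode list paths")
        spio.mmwrite(path_matrix, sparse.csr_matrix(expr.values.T))
        Path(path_genes).write_text("\n".join(map(str, expr.genes)) + "\n")
        Path(path_barcodes).write_text("\n".join(map(str, expr.barcodes)) + "\n")
        return
    df = pd.DataFrame(expr.values, index=expr.barcodes, columns=expr.genes)
    df.index.name = "barcode"
    df.to_csv(path_matrix)


def convert_reference_map(source: str | Path, out_csv: str | Path,
                          coord_columns: Sequence[str] = _COORD_COLS,
                          id_column: str = "cell_id") -> Path:
    """Convert a downloaded reference-map table to the canonical CSV schema.

    Published 3D reconstructions ship in various tabular layouts; this
    helper renames the identifier/coordinate columns to the canonical
    ``cell_id,x,y,z,<gene>...`` header so :func:`read_spatial_map` can
    consume the result.  Columns other than the identifier and coordinates
    are passed through unchanged (gene calls must already be binary, or be
    coerced at read time via ``binarize_threshold``).
    """
    source = Path(source)
    df = pd.read_csv(source, sep=_sep_for(source, None))
    rename = dict(zip(coord_columns, _COORD_COLS))
    rename[id_column] = "cell_id"
    missing = [c for c in rename if c not in df.columns]
    if missing:
        raise FormatError(f"source table lacks columns: {missing}")
    df = df.rename(columns=rename)
    ordered = ["cell_id", *_COORD_COLS] + [
        c for c in df.columns if c not in ("cell_id", *_COORD_COLS)]
    out_csv = Path(out_csv)
    df[ordered].to_csv(out_csv, index=False)
    return out_csv


def write_run_manifest(path: str | Path, parameters: Mapping,
                       inputs: Mapping[str, str | Path] | None = None,
                       extras: Mapping | None = None) -> Path:
    """JSON run-manifest: parameters, input checksums, free-form extras."""
    manifest = {"parameters": _jsonable(parameters)}
    if inputs:
        manifest["input_checksums"] = {
            k: _sha256(Path(v)) for k, v in inputs.items()
        }
    if extras:
        manifest["extras"] = _jsonable(extras)
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# helpers


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt == "tsv" or (fmt is None and path.suffix in (".tsv", ".txt")):
        return "\t"
    return ","


def _read_list(path: str | Path) -> np.ndarray:
    lines = [ln.split("\t")[0].split(",")[0].strip()
             for ln in Path(path).read_text().splitlines() if ln.strip()]
    return np.asarray(lines, dtype=object)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
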