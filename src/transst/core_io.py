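"""Data containers, file I/O and preprocessing shared by all pipeline stages.

The central container is :class:`ExpressionMatrix`, a dense spots-by-genes
matrix with string identifiers on both axes.  Labeled source data pairs an
expression matrix with integer cluster labels; target spatial data pairs one
with 2-D coordinates.  On-disk formats are deliberately plain: MatrixMarket
plus sidecar name files for sparse counts, headed CSV/TSV for dense values,
and two/three-column TSV for labels and coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as the declared format."""


class DimensionError(ValueError):
    """Raised when matrix dimensions disagree with companion files."""


def _dedupe(names: Sequence[str]) -> list[str]:
    """Disambiguate duplicated identifiers by suffixing ``.1``, ``.2``, ...

    Matches the convention pandas uses for duplicated columns so that the
    same gene name appearing twice yields ``ACTB`` and ``ACTB.1``.
    """
    seen: dict[str, int] = {}
    out = []
    for name in names:
        name = str(name)
        if name in seen:
            seen[name] += 1
            new = f"{name}.{seen[name]}"
            while new in seen:
                seen[name] += 1
                new = f"{name}.{seen[name]}"
            seen[new] = 0
            out.append(new)
        else:
            seen[name] = 0
            out.append(name)
    return out


@dataclass
class ExpressionMatrix:
    """Dense spots/cells × genes expression matrix with identifiers.

    Internally spots are always rows; readers transpose genes-by-spots
    inputs on the way in.
    """

    values: np.ndarray
    row_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        self.row_ids = [str(r) for r in self.row_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, p = self.values.shape
        if len(self.row_ids) != n:
            raise DimensionError(
                f"{len(self.row_ids)} row ids for {n} rows"
            )
        if len(self.gene_ids) != p:
            raise DimensionError(
                f"{len(self.gene_ids)} gene ids for {p} columns"
            )
        if len(set(self.row_ids)) != n:
            raise ValueError("row_ids must be unique")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str], fill_missing: bool = False):
        """Return a copy restricted to ``genes`` in the given order.

        Missing genes raise unless ``fill_missing``, in which case they
        become all-zero columns; the second return value lists them.
        """
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing and not fill_missing:
            raise KeyError(f"genes not present: {missing[:10]}")
        out = np.zeros((self.n_spots, len(genes)))
        for j, g in enumerate(genes):
            if g in index:
                out[:, j] = self.values[:, index[g]]
        return ExpressionMatrix(out, list(self.row_ids), list(genes)), missing

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.gene_ids)


@dataclass
class LabeledSource:
    """Source expression with known per-row cluster labels in ``1..K``."""

    expr: ExpressionMatrix
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != self.expr.n_spots:
            raise DimensionError("labels length must equal the row count")
        if self.labels.min() < 1:
            raise ValueError("labels must be positive integers 1..K")

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())


@dataclass
class SpatialCoords:
    """n0 × 2 spatial coordinates, same row order as the target matrix."""

    coords: np.ndarray
    row_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise DimensionError("coords must be an n×2 matrix")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    fmt: str = "csv",
    orientation: str = "spots_by_genes",
) -> ExpressionMatrix:
    """Read an expression matrix from disk in spots×genes orientation.

    Parameters
    ----------
    path
        For ``csv``/``tsv``: a headed delimited file with row identifiers in
        the first column.  For ``mtx``: a MatrixMarket file; companion
        ``<stem>.rownames.txt`` and ``<stem>.colnames.txt`` files must sit
        next to it, one identifier per line.
    fmt
        One of ``mtx``, ``csv``, ``tsv``.
    orientation
        How the file is stored on disk.  ``genes_by_spots`` inputs are
        transposed so the result is always spots×genes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in ("spots_by_genes", "genes_by_spots"):
        raise ValueError(f"unknown orientation {orientation!r}")

    if fmt == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise FormatError(f"malformed MatrixMarket file {path}: {exc}") from exc
        mat = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        rn_path = path.with_suffix("").with_suffix(".rownames.txt")
        cn_path = path.with_suffix("").with_suffix(".colnames.txt")
        for p in (rn_path, cn_path):
            if not p.exists():
                raise FileNotFoundError(f"companion name file missing: {p}")
        row_names = rn_path.read_text().split()
        col_names = cn_path.read_text().split()
        if len(row_names) != mat.shape[0]:
            raise DimensionError(
                f"{len(row_names)} row names for {mat.shape[0]} matrix rows"
            )
        if len(col_names) != mat.shape[1]:
            raise DimensionError(
                f"{len(col_names)} column names for {mat.shape[1]} matrix columns"
            )
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise FormatError(f"malformed {fmt} file {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise FormatError(f"no data columns parsed from {path} (header line 1)")
        try:
            mat = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise FormatError(f"non-numeric entries in {path}: {exc}") from exc
        row_names = [str(i) for i in df.index]
        col_names = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if orientation == "genes_by_spots":
        mat = mat.T
        row_names, col_names = col_names, row_names
    return ExpressionMatrix(mat, _dedupe(row_names), _dedupe(col_names))


def write_expression(expr: ExpressionMatrix, path: str | Path, fmt: str = "csv") -> None:
    """Write ``expr`` in spots×genes orientation (inverse of read_expression)."""
    path = Path(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        expr.to_frame().to_csv(path, sep=sep)
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(expr.values))
        path.with_suffix("").with_suffix(".rownames.txt").write_text(
            "\n".join(expr.row_ids) + "\n"
        )
        path.with_suffix("").with_suffix(".colnames.txt").write_text(
            "\n".join(expr.gene_ids) + "\n"
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_labels(path: str | Path, row_ids: Sequence[str] | None = None) -> np.ndarray:
    """Read a two-column (row_id, label) TSV; labels re-coded to 1..K.

    String labels are mapped to integer codes by sorted order.  If
    ``row_ids`` is given the labels are re-ordered to match it.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["row_id", "label"], dtype=str)
    if row_ids is not None:
        df = df.set_index("row_id").loc[list(row_ids)].reset_index()
    raw = df["label"].to_numpy()
    try:
        codes = raw.astype(int)
        if codes.min() >= 1:
            return codes
    except ValueError:
        pass
    vocab = {lab: i + 1 for i, lab in enumerate(sorted(set(raw)))}
    return np.array([vocab[lab] for lab in raw], dtype=int)


def write_labels(row_ids: Sequence[str], labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"row_id": list(row_ids), "label": np.asarray(labels)}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_coords(path: str | Path, row_ids: Sequence[str] | None = None) -> SpatialCoords:
    """Read a three-column (row_id, x, y) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["row_id", "x", "y"])
    df["row_id"] = df["row_id"].astype(str)
    if row_ids is not None:
        df = df.set_index("row_id").loc[list(row_ids)].reset_index()
    return SpatialCoords(df[["x", "y"]].to_numpy(float), list(df["row_id"]))


def write_coords(coords: SpatialCoords, path: str | Path) -> None:
    ids = coords.row_ids or [f"spot{i}" for i in range(len(coords.coords))]
    pd.DataFrame(
        {"row_id": ids, "x": coords.coords[:, 0], "y": coords.coords[:, 1]}
    ).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _normalize_log(values: np.ndarray, row_ids: Sequence[str]) -> np.ndarray:
    """Library-size normalize rows to the median total count, then log1p."""
    totals = values.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        names = [row_ids[i] for i in zero[:20]]
        raise ValueError(f"rows with zero total count: {names}")
    target = float(np.median(totals))
    return np.log1p(values * (target / totals)[:, None])


def _center_scale(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center each gene and scale to unit variance; returns (matrix, keep mask).

    Variance-zero genes cannot be scaled and are flagged for dropping.
    """
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    keep = sd > 0
    out = values - mu
    out[:, keep] /= sd[keep]
    return out, keep


def preprocess(
    expr: ExpressionMatrix, n_hvg: int = 2000, normalize: bool = True
) -> ExpressionMatrix:
    """Standard expression preprocessing ahead of dimension reduction.

    With ``normalize`` on (raw counts): rows are library-size normalized to
    the median total count and log1p-transformed.  The ``n_hvg``
    highest-variance genes on the (log) scale are retained, in ranking
    order, then each gene is centered and unit-scaled.  Variance-zero genes
    are dropped with a warning rather than divided by zero.  Deterministic.
    """
    if n_hvg < 1:
        raise ValueError("n_hvg must be positive")
    values = expr.values.copy()
    if normalize:
        values = _normalize_log(values, expr.row_ids)
    var = values.var(axis=0)
    n_keep = min(n_hvg, expr.n_genes)
    # stable HVG ranking: descending variance, ties by original column order;
    # variances quantized to 12 relative digits so float noise cannot
    # reshuffle exactly-tied genes (keeps preprocessing idempotent)
    scale_ref = var.max() if var.max() > 0 else 1.0
    var_key = np.round(var / scale_ref, 12)
    order = np.lexsort((np.arange(expr.n_genes), -var_key))[:n_keep]
    values = values[:, order]
    gene_ids = [expr.gene_ids[j] for j in order]
    values, keep = _center_scale(values)
    if not keep.all():
        dropped = [g for g, k in zip(gene_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} variance-zero genes: {dropped[:10]}",
            stacklevel=2,
        )
        values = values[:, keep]
        gene_ids = [g for g, k in zip(gene_ids, keep) if k]
    return ExpressionMatrix(values, list(expr.row_ids), gene_ids)


@dataclass
class CombineReport:
    """Per-source record of genes that had to be zero-filled."""

    missing_genes: dict[int, list[str]] = field(default_factory=dict)
    label_vocabulary: list[str] = field(default_factory=list)


def align_and_combine_sources(
    sources: Sequence[LabeledSource | tuple[ExpressionMatrix, Sequence]],
    target_genes: Sequence[str],
    min_overlap: int = 1,
    normalize: bool = False,
) -> tuple[LabeledSource, CombineReport]:
    """Subset sources to the target gene space and stack them into one.

    Each source is restricted to ``target_genes`` (absent genes become
    all-zero columns, recorded in the report), normalized independently
    (the preprocess recipe without HVG re-selection: optional library
    normalization + log1p, then per-gene center/scale with variance-zero
    columns left centered but unscaled so the gene space keeps full
    dimension), and the rows are concatenated.  Label codes are re-indexed
    to a shared 1..K space by label-string identity across sources.
    """
    target_genes = list(target_genes)
    report = CombineReport()
    blocks, label_strings, row_ids = [], [], []
    for s_idx, src in enumerate(sources):
        if isinstance(src, LabeledSource):
            expr, labels = src.expr, src.labels
        else:
            expr, labels = src
        shared = set(expr.gene_ids) & set(target_genes)
        if len(shared) < min_overlap:
            raise ValueError(
                f"source {s_idx} shares only {len(shared)} genes with the "
                f"target (minimum {min_overlap})"
            )
        sub, missing = expr.subset_genes(target_genes, fill_missing=True)
        if missing:
            report.missing_genes[s_idx] = missing
        values = sub.values
        if normalize:
            values = _normalize_log(values, sub.row_ids)
        mu = values.mean(axis=0)
        sd = values.std(axis=0)
        scale = np.where(sd > 0, sd, 1.0)
        blocks.append((values - mu) / scale)
        label_strings.extend(str(l) for l in labels)
        row_ids.extend(f"s{s_idx}_{r}" if len(sources) > 1 else r for r in sub.row_ids)
    vocab = sorted(set(label_strings))
    report.label_vocabulary = vocab
    code = {lab: i + 1 for i, lab in enumerate(vocab)}
    labels = np.array([code[lab] for lab in label_strings], dtype=int)
    combined = ExpressionMatrix(np.vstack(blocks), row_ids, target_genes)
    return LabeledSource(combined, labels), report


def harmonize_gene_spaces(
    source: LabeledSource, target: ExpressionMatrix
) -> tuple[LabeledSource, ExpressionMatrix]:
    """Drop genes with zero variance in either matrix, from both.

    Applied after align_and_combine so that scaling is well defined and the
    two matrices share an identical, informative gene space.
    """
    keep = (source.expr.values.std(axis=0) > 0) & (target.values.std(axis=0) > 0)
    if keep.all():
        return source, target
    dropped = [g for g, k in zip(target.gene_ids, keep) if not k]
    warnings.warn(
        f"dropping {len(dropped)} genes with zero variance in source or "
        f"target: {dropped[:10]}",
        stacklevel=2,
    )
    genes = [g for g, k in zip(target.gene_ids, keep) if k]
    src_expr, _ = source.expr.subset_genes(genes)
    tgt_expr, _ = target.subset_genes(genes)
    return LabeledSource(src_expr, source.labels), tgt_expr
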