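"""Expression-matrix input/output and preprocessing.

The central container is :class:`ExpressionDataset`: a dense cells-by-genes
matrix with a required per-cell phenotype label and an optional per-cell
biological label (typically a cell type). Readers are provided for
delimited text, MatrixMarket triplets with companion gene/barcode files,
and AnnData ``.h5ad`` containers; all of them delegate parsing to pandas,
scipy and anndata respectively and only handle label encoding and
validation here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """Raised for malformed or inconsistent expression inputs."""


def dedup_gene_names(names: Sequence[str]) -> List[str]:
    """Make gene names unique by suffixing the k-th recurrence with ``.k``.

    Keeps the column count unchanged and is deterministic in input order.
    """
    seen: Dict[str, int] = {}
    out = []
    n_dup = 0
    for name in names:
        k = seen.get(name, 0)
        seen[name] = k + 1
        if k == 0:
            out.append(name)
        else:
            out.append(f"{name}.{k}")
            n_dup += 1
    if n_dup:
        logger.warning("deduplicated %d recurring gene name(s) by suffixing", n_dup)
    return out


@dataclass
class ExpressionDataset:
    """Cells x genes expression with phenotype (and optional cell-type) labels.

    Attributes
    ----------
    X : ndarray, shape (n, N)
        Expression values, cells as rows.
    gene_names : list of str
        N unique gene names (duplicates are suffixed on construction).
    y : ndarray of int, shape (n,)
        Phenotype labels encoded 1..C.
    q : ndarray of int or None, shape (n,)
        Optional biological labels encoded 1..B_labels.
    y_categories, q_categories : list
        Original label values in encoding order (``y_categories[k-1]`` is
        the phenotype encoded as ``k``).
    """

    X: np.ndarray
    gene_names: List[str]
    y: np.ndarray
    q: Optional[np.ndarray] = None
    y_categories: List = field(default_factory=list)
    q_categories: List = field(default_factory=list)
    normalized: bool = False
    logged: bool = False

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise DataError("X must be 2-D (cells x genes)")
        self.gene_names = dedup_gene_names(list(self.gene_names))
        if len(self.gene_names) != self.X.shape[1]:
            raise DataError(
                f"{len(self.gene_names)} gene names for {self.X.shape[1]} columns")
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.y.shape != (self.X.shape[0],):
            raise DataError("y must assign one phenotype per cell")
        if not self.y_categories:
            self.y_categories = sorted(set(self.y.tolist()))
            remap = {v: i + 1 for i, v in enumerate(self.y_categories)}
            self.y = np.array([remap[v] for v in self.y], dtype=np.int64)
        if self.y.min() < 1:
            raise DataError("phenotype codes must be 1..C")
        for k in range(1, self.C + 1):
            if not np.any(self.y == k):
                raise DataError(f"phenotype class {k} has no cells")
        if self.q is not None:
            self.q = np.asarray(self.q, dtype=np.int64)
            if self.q.shape != (self.X.shape[0],):
                raise DataError("q must assign one label per cell")
            if not self.q_categories:
                self.q_categories = sorted(set(self.q.tolist()))
                remap = {v: i + 1 for i, v in enumerate(self.q_categories)}
                self.q = np.array([remap[v] for v in self.q], dtype=np.int64)

    # -- dimensions ---------------------------------------------------

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def N(self) -> int:
        return self.X.shape[1]

    @property
    def C(self) -> int:
        return len(self.y_categories) if self.y_categories else int(self.y.max())

    @property
    def n_labels(self) -> int:
        if self.q is None:
            return 0
        return len(self.q_categories) if self.q_categories else int(self.q.max())

    def subset(self, idx: np.ndarray) -> "ExpressionDataset":
        """Row subset keeping the global label encoding."""
        return ExpressionDataset(
            X=self.X[idx], gene_names=list(self.gene_names),
            y=self.y[idx], q=None if self.q is None else self.q[idx],
            y_categories=list(self.y_categories),
            q_categories=list(self.q_categories),
            normalized=self.normalized, logged=self.logged)

    # -- I/O ----------------------------------------------------------

    def to_anndata(self):
        import anndata as ad

        obs = pd.DataFrame({"phenotype": [self.y_categories[v - 1] for v in self.y]})
        if self.q is not None:
            obs["celltype"] = [self.q_categories[v - 1] for v in self.q]
        obs.index = [f"cell{i}" for i in range(self.n)]
        adata = ad.AnnData(X=self.X.copy(), obs=obs,
                           var=pd.DataFrame(index=self.gene_names))
        adata.uns["normalized"] = self.normalized
        adata.uns["logged"] = self.logged
        return adata

    def write(self, path: str | Path) -> None:
        """Write as an .h5ad container (phenotype/celltype in obs)."""
        self.to_anndata().write_h5ad(Path(path))

    def write_mtx(self, prefix: str | Path) -> None:
        """Write MatrixMarket triplets + genes/metadata text companions."""
        import scipy.io
        import scipy.sparse

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(prefix) + ".mtx", scipy.sparse.csr_matrix(self.X))
        Path(str(prefix) + ".genes.txt").write_text(
            "\n".join(self.gene_names) + "\n")
        meta = pd.DataFrame({
            "cell": [f"cell{i}" for i in range(self.n)],
            "phenotype": [self.y_categories[v - 1] for v in self.y]})
        if self.q is not None:
            meta["celltype"] = [self.q_categories[v - 1] for v in self.q]
        meta.to_csv(str(prefix) + ".metadata.tsv", sep="\t", index=False)


def _encode_labels(values: pd.Series):
    cats = sorted(pd.unique(values).tolist())
    remap = {v: i + 1 for i, v in enumerate(cats)}
    return np.array([remap[v] for v in values], dtype=np.int64), cats


def _dataset_from_frame(X: np.ndarray, gene_names: Sequence[str],
                        meta: pd.DataFrame, pheno_key: str,
                        celltype_key: Optional[str]) -> ExpressionDataset:
    if pheno_key not in meta.columns:
        raise DataError(f"phenotype key {pheno_key!r} not found in metadata "
                        f"(available: {list(meta.columns)})")
    keep = meta[pheno_key].notna().to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d cell(s) with missing phenotype", n_drop)
    if not keep.any():
        raise DataError("no cells remain after dropping missing phenotypes")
    X = X[keep]
    meta = meta.loc[keep]
    y, y_cats = _encode_labels(meta[pheno_key])
    q = q_cats = None
    if celltype_key is not None:
        if celltype_key not in meta.columns:
            raise DataError(f"cell-type key {celltype_key!r} not found in metadata")
        q, q_cats = _encode_labels(meta[celltype_key])
    return ExpressionDataset(X=X, gene_names=gene_names, y=y, q=q,
                             y_categories=y_cats, q_categories=q_cats or [])


def read_expression(path: str | Path, format: str = "delimited", *,
                    pheno_key: str = "phenotype",
                    celltype_key: Optional[str] = None,
                    metadata: Optional[str | Path] = None,
                    sep: str = "\t") -> ExpressionDataset:
    """Read an expression matrix plus cell metadata into a dataset.

    Parameters
    ----------
    path : path
        ``delimited``: table with a header row of gene names, cells as rows
        (a companion metadata table is required). ``mtx``: MatrixMarket file;
        ``<stem>.genes.txt`` and ``<stem>.metadata.tsv`` companions are used
        unless ``metadata`` is given. ``h5ad``: AnnData container with the
        labels in ``.obs``.
    pheno_key : str
        Metadata column holding the phenotype label (required).
    celltype_key : str, optional
        Metadata column holding a biological (cell-type) label.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    if format == "delimited":
        df = pd.read_csv(path, sep=sep, index_col=0)
        if metadata is None:
            raise DataError("delimited format requires a metadata table")
        meta = pd.read_csv(metadata, sep=sep, index_col=0)
        meta = meta.reindex(df.index)
        X = df.to_numpy(dtype=np.float64)
        return _dataset_from_frame(X, list(df.columns), meta, pheno_key,
                                   celltype_key)
    if format == "mtx":
        import scipy.io

        stem = str(path)[:-4] if str(path).endswith(".mtx") else str(path)
        M = scipy.io.mmread(path)
        X = np.asarray(M.todense() if hasattr(M, "todense") else M,
                       dtype=np.float64)
        gene_names = Path(stem + ".genes.txt").read_text().split()
        meta_path = Path(metadata) if metadata else Path(stem + ".metadata.tsv")
        meta = pd.read_csv(meta_path, sep="\t")
        if X.shape[0] != len(meta) and X.shape[1] == len(meta):
            X = X.T  # column-major input: transpose to cells-as-rows
        return _dataset_from_frame(X, gene_names, meta, pheno_key, celltype_key)
    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        return _dataset_from_frame(np.asarray(X, dtype=np.float64),
                                   list(adata.var_names), adata.obs,
                                   pheno_key, celltype_key)
    raise DataError(f"unknown expression format: {format!r}")


def preprocess(ds: ExpressionDataset, *, normalize: bool = True,
               log1p: bool = True, scale_factor: float = 1e4) -> ExpressionDataset:
    """Library-size normalize each cell to ``scale_factor`` and/or log1p.

    The default (normalize to 1e4 counts then log1p) is standard single-cell
    practice and is applied before gene-set masking, so a masked feature is
    the masked normalized profile.
    """
    X = ds.X
    if normalize:
        if np.any(X < 0):
            raise DataError("normalize requires nonnegative expression values")
        if scale_factor <= 0:
            raise DataError("scale_factor must be positive")
        totals = X.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0  # empty cells stay all-zero
        X = X / totals * scale_factor
    if log1p:
        X = np.log1p(X)
    return ExpressionDataset(
        X=X, gene_names=list(ds.gene_names), y=ds.y.copy(),
        q=None if ds.q is None else ds.q.copy(),
        y_categories=list(ds.y_categories), q_categories=list(ds.q_categories),
        normalized=ds.normalized or normalize, logged=ds.logged or log1p)
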