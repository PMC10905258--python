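"""Data model for multi-batch expression data, plus readers and dataset merging.

The central container is :class:`IntegratedDataset`: an observations x genes
count matrix with a batch label per observation, optional cell/domain-type
labels, optional 2-D spatial coordinates, and named low-dimensional embeddings
and transformed layers. Batches are the merged datasets (tissue sections,
platforms, time points); ``N`` observations total, ``k`` batches of sizes
``n_i`` with ``sum(n_i) == N``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd


class GenePolicy(str, Enum):
    """How to reconcile gene sets when merging datasets."""

    INTERSECTION = "intersection"
    UNION_ZERO_FILL = "union_zero_fill"


@dataclass
class MergeConfig:
    gene_policy: GenePolicy = GenePolicy.INTERSECTION
    batch_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.gene_policy = GenePolicy(self.gene_policy)


@dataclass
class IntegratedDataset:
    """Merged observations x genes expression matrix with batch metadata.

    Parameters
    ----------
    matrix
        Raw counts, shape ``(N, n_genes)``, non-negative and finite.
    obs_ids, gene_ids
        Observation and gene identifiers; lengths match the matrix shape.
    batch
        Categorical batch label per observation.
    cell_type
        Optional cell/domain-type label per observation.
    spatial
        Optional ``(N, 2)`` coordinates.
    embeddings
        Named low-dimensional matrices, e.g. ``"pca"``, ``"umap"``;
        each has exactly ``N`` rows.
    layers
        Named transformed matrices, e.g. ``"normalized"``.
    """

    matrix: np.ndarray
    obs_ids: list[str]
    gene_ids: list[str]
    batch: np.ndarray
    cell_type: np.ndarray | None = None
    spatial: np.ndarray | None = None
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.batch = np.asarray(self.batch, dtype=object)
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type, dtype=object)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n, g = self.matrix.shape
        if len(self.obs_ids) != n or len(self.batch) != n:
            raise ValueError(
                f"matrix has {n} rows but {len(self.obs_ids)} obs_ids and "
                f"{len(self.batch)} batch labels"
            )
        if len(self.gene_ids) != g:
            raise ValueError(f"matrix has {g} columns but {len(self.gene_ids)} gene_ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains non-finite entries")
        if self.matrix.size and self.matrix.min() < 0:
            raise ValueError("matrix contains negative entries")
        if self.cell_type is not None and len(self.cell_type) != n:
            raise ValueError("cell_type length does not match observation count")
        if self.spatial is not None and self.spatial.shape != (n, 2):
            raise ValueError("spatial must be (N, 2)")
        for name, emb in self.embeddings.items():
            if emb.shape[0] != n:
                raise ValueError(f"embedding {name!r} has {emb.shape[0]} rows, expected {n}")
        for name, lay in self.layers.items():
            if lay.shape[0] != n:
                raise ValueError(f"layer {name!r} has {lay.shape[0]} rows, expected {n}")

    # -- convenience --------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def batch_names(self) -> list[str]:
        return sorted(set(map(str, self.batch)))

    def batch_sizes(self) -> dict[str, int]:
        names, counts = np.unique(self.batch.astype(str), return_counts=True)
        return dict(zip(names.tolist(), counts.tolist()))

    def copy(self) -> "IntegratedDataset":
        return IntegratedDataset(
            matrix=self.matrix.copy(),
            obs_ids=list(self.obs_ids),
            gene_ids=list(self.gene_ids),
            batch=self.batch.copy(),
            cell_type=None if self.cell_type is None else self.cell_type.copy(),
            spatial=None if self.spatial is None else self.spatial.copy(),
            embeddings={k: v.copy() for k, v in self.embeddings.items()},
            layers={k: v.copy() for k, v in self.layers.items()},
        )

    def to_anndata(self):
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(self.obs_ids, name="obs_id"))
        obs["batch"] = pd.Categorical(self.batch.astype(str))
        if self.cell_type is not None:
            obs["cell_type"] = pd.Categorical(self.cell_type.astype(str))
        adata = ad.AnnData(X=self.matrix.copy(), obs=obs,
                           var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")))
        if self.spatial is not None:
            adata.obsm["spatial"] = self.spatial.copy()
        for name, emb in self.embeddings.items():
            adata.obsm[f"X_{name}"] = emb.copy()
        for name, lay in self.layers.items():
            adata.layers[name] = lay.copy()
        return adata


def _dense(x) -> np.ndarray:
    if hasattr(x, "toarray"):
        x = x.toarray()
    return np.asarray(x, dtype=float)


def from_anndata(adata, batch_key: str = "batch",
                 celltype_key: str | None = None) -> IntegratedDataset:
    """Build an :class:`IntegratedDataset` from an AnnData object."""
    if batch_key in adata.obs.columns:
        batch = adata.obs[batch_key].astype(str).to_numpy()
    else:
        raise KeyError(
            f"batch_key {batch_key!r} not found; available obs columns: "
            f"{sorted(adata.obs.columns)}"
        )
    cell_type = None
    if celltype_key is not None:
        if celltype_key not in adata.obs.columns:
            raise KeyError(
                f"celltype_key {celltype_key!r} not found; available obs columns: "
                f"{sorted(adata.obs.columns)}"
            )
        cell_type = adata.obs[celltype_key].astype(str).to_numpy()
    spatial = adata.obsm.get("spatial")
    embeddings = {
        key[2:]: np.asarray(val, dtype=float)
        for key, val in adata.obsm.items()
        if key.startswith("X_")
    }
    return IntegratedDataset(
        matrix=_dense(adata.X),
        obs_ids=[str(i) for i in adata.obs_names],
        gene_ids=[str(g) for g in adata.var_names],
        batch=batch,
        cell_type=cell_type,
        spatial=None if spatial is None else np.asarray(spatial, dtype=float)[:, :2],
        embeddings=embeddings,
        layers={k: _dense(v) for k, v in adata.layers.items()},
    )


def load_dataset(path: str | Path, format: str | None = None,
                 batch_key: str = "batch",
                 celltype_key: str | None = None,
                 default_batch: str | None = None) -> IntegratedDataset:
    """Read a dataset from h5ad, MTX triplet, or dense CSV/TSV.

    ``batch_key`` names a metadata column and must exist in formats that
    carry metadata (h5ad obs, CSV columns) — a missing column raises an
    error listing the available columns, so a typo cannot silently collapse
    a multi-batch file into one batch. To label a file that genuinely has no
    batch column, pass ``default_batch``: it is assigned as a constant label
    to every observation (always the case for MTX, which carries no
    per-observation metadata; default constant ``"batch0"``).

    For ``format="mtx"`` the path is the directory holding ``matrix.mtx``,
    ``barcodes.tsv`` and ``features.tsv`` (genes x cells orientation as
    written by CellRanger-style tools, transposed on load).
    """
    path = Path(path)
    if format is None:
        if path.suffix == ".h5ad":
            format = "h5ad"
        elif path.is_dir() or path.suffix == ".mtx":
            format = "mtx"
        else:
            format = "csv"
    if format == "h5ad":
        if not path.exists():
            raise FileNotFoundError(path)
        import anndata as ad

        return from_anndata(ad.read_h5ad(path), batch_key=batch_key,
                            celltype_key=celltype_key)
    if format == "mtx":
        return _load_mtx(path, default_batch=default_batch or "batch0")
    if format == "csv":
        return _load_csv(path, batch_key=batch_key, celltype_key=celltype_key,
                         default_batch=default_batch)
    raise ValueError(f"unknown format {format!r}")


def _load_mtx(path: Path, default_batch: str) -> IntegratedDataset:
    from scipy.io import mmread

    d = path if path.is_dir() else path.parent
    mtx = d / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(mtx)
    mat = _dense(mmread(mtx)).T  # stored genes x cells
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    feat = pd.read_csv(d / "features.tsv", sep="\t", header=None)
    genes = feat.iloc[:, 1] if feat.shape[1] > 1 else feat.iloc[:, 0]
    return IntegratedDataset(
        matrix=mat,
        obs_ids=barcodes,
        gene_ids=genes.astype(str).tolist(),
        batch=np.repeat(str(default_batch), mat.shape[0]),
    )


def _load_csv(path: Path, batch_key: str, celltype_key: str | None,
              default_batch: str | None) -> IntegratedDataset:
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    meta_cols = [c for c in (batch_key, celltype_key) if c is not None and c in df.columns]
    if batch_key in df.columns:
        batch = df[batch_key].astype(str).to_numpy()
    elif default_batch is not None:
        batch = np.repeat(str(default_batch), len(df))
    else:
        raise KeyError(
            f"batch_key {batch_key!r} not found; available columns: "
            f"{sorted(df.columns)} (pass default_batch to label the whole "
            f"file as one batch)"
        )
    cell_type = None
    if celltype_key is not None:
        if celltype_key not in df.columns:
            raise KeyError(
                f"celltype_key {celltype_key!r} not found; available columns: "
                f"{sorted(df.columns)}"
            )
        cell_type = df[celltype_key].astype(str).to_numpy()
    expr = df.drop(columns=meta_cols)
    try:
        matrix = expr.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(
            f"non-numeric expression columns in {path.name}; if {batch_key!r} was "
            f"meant as a metadata column it is absent — available columns: "
            f"{sorted(df.columns)}"
        ) from exc
    return IntegratedDataset(
        matrix=matrix,
        obs_ids=[str(i) for i in df.index],
        gene_ids=[str(g) for g in expr.columns],
        batch=batch,
        cell_type=cell_type,
    )


def merge_datasets(datasets: list[IntegratedDataset],
                   config: MergeConfig | None = None) -> IntegratedDataset:
    """Concatenate datasets into one multi-batch dataset.

    The gene set follows ``config.gene_policy``: intersection (default; the
    downstream distribution tests compare totals over a common gene universe)
    or union with zero fill. Each input contributes one batch; observation
    identifiers are suffixed with the batch name to avoid barcode collisions.
    """
    config = config or MergeConfig()
    if len(datasets) < 2:
        raise ValueError("merge requires at least two datasets")
    if config.batch_names is not None:
        if len(config.batch_names) != len(datasets):
            raise ValueError("batch_names length must match number of datasets")
        names = list(config.batch_names)
    else:
        names = [f"batch{i}" for i in range(len(datasets))]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate batch names: {names}")

    gene_sets = [set(d.gene_ids) for d in datasets]
    if config.gene_policy is GenePolicy.INTERSECTION:
        common = set.intersection(*gene_sets)
        if not common:
            raise ValueError("gene intersection is empty under the intersection policy")
        # keep the first dataset's gene order for the shared genes
        genes = [g for g in datasets[0].gene_ids if g in common]
    else:
        genes = list(datasets[0].gene_ids)
        seen = set(genes)
        for d in datasets[1:]:
            for g in d.gene_ids:
                if g not in seen:
                    genes.append(g)
                    seen.add(g)

    n_total = sum(d.n_obs for d in datasets)
    matrix = np.zeros((n_total, len(genes)))
    obs_ids: list[str] = []
    batch = np.empty(n_total, dtype=object)
    has_types = all(d.cell_type is not None for d in datasets)
    cell_type = np.empty(n_total, dtype=object) if has_types else None
    has_spatial = all(d.spatial is not None for d in datasets)
    spatial = np.zeros((n_total, 2)) if has_spatial else None

    col_of = {g: j for j, g in enumerate(genes)}
    row = 0
    for d, name in zip(datasets, names):
        idx = [(col_of[g], j) for j, g in enumerate(d.gene_ids) if g in col_of]
        dst = [i for i, _ in idx]
        src = [j for _, j in idx]
        matrix[row:row + d.n_obs][:, dst] = d.matrix[:, src]
        obs_ids.extend(f"{o}-{name}" for o in d.obs_ids)
        batch[row:row + d.n_obs] = name
        if cell_type is not None:
            cell_type[row:row + d.n_obs] = d.cell_type
        if spatial is not None:
            spatial[row:row + d.n_obs] = d.spatial
        row += d.n_obs

    return IntegratedDataset(matrix=matrix, obs_ids=obs_ids, gene_ids=genes,
                             batch=batch, cell_type=cell_type, spatial=spatial)


# -- metrics export ---------------------------------------------------------

def export_metrics(bundle, path: str | Path) -> Path:
    """Write every number of a benchmark summary to JSON at full precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = bundle.to_dict() if hasattr(bundle, "to_dict") else bundle
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_metrics(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
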