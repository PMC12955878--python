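"""Readers and writers for the on-disk formats the pipeline consumes.

Spot tables follow the Space Ranger tissue-positions dialects (headerless v1
``tissue_positions_list.csv`` and headered v2 ``tissue_positions.csv``);
counts come as MatrixMarket triplets with barcode/feature sidecar lists or as
dense delimited tables; grids are serialized as NPZ arrays with a JSON
sidecar recording the indexing convention and gene panel.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .grid import ExpressionGrid, LabelGrid, SpotLayout

__all__ = [
    "read_tissue_positions", "write_tissue_positions",
    "read_counts_mtx", "write_counts_mtx",
    "read_counts_dense", "write_counts_dense",
    "write_grid", "read_grid",
    "read_clinical",
]

_POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col",
                     "pxl_row_in_fullres", "pxl_col_in_fullres"]


def read_tissue_positions(path: str | Path) -> SpotLayout:
    """Read either tissue-positions dialect into a :class:`SpotLayout`.

    Note pixel *row* is the image y coordinate and pixel *col* is x.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    has_header = first.lower().startswith("barcode")
    df = pd.read_csv(path, header=0 if has_header else None)
    if not has_header:
        df.columns = _POSITION_COLUMNS[: df.shape[1]]
    missing = [c for c in _POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tissue positions file missing columns {missing}")
    return SpotLayout(
        barcodes=df["barcode"].astype(str).tolist(),
        array_row=df["array_row"].to_numpy(),
        array_col=df["array_col"].to_numpy(),
        pixel_x=df["pxl_col_in_fullres"].to_numpy(dtype=float),
        pixel_y=df["pxl_row_in_fullres"].to_numpy(dtype=float),
        in_tissue=df["in_tissue"].to_numpy().astype(bool),
    )


def write_tissue_positions(layout: SpotLayout, path: str | Path,
                           header: bool = True) -> None:
    df = pd.DataFrame({
        "barcode": layout.barcodes,
        "in_tissue": layout.in_tissue.astype(int),
        "array_row": layout.array_row,
        "array_col": layout.array_col,
        "pxl_row_in_fullres": layout.pixel_y,
        "pxl_col_in_fullres": layout.pixel_x,
    })
    df.to_csv(path, index=False, header=header)


def read_counts_mtx(matrix: str | Path, features: str | Path,
                    barcodes: str | Path) -> pd.DataFrame:
    """MatrixMarket triplet counts (genes x spots) to a dense DataFrame."""
    mat = spio.mmread(str(matrix))
    if sparse.issparse(mat):
        mat = mat.toarray()
    feat = pd.read_csv(features, sep="\t", header=None)
    # 10x feature files carry (id, name, type); use the name column if present
    gene_names = feat.iloc[:, 1 if feat.shape[1] > 1 else 0].astype(str).tolist()
    bcs = pd.read_csv(barcodes, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    if mat.shape != (len(gene_names), len(bcs)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(gene_names)} features "
            f"x {len(bcs)} barcodes")
    return pd.DataFrame(np.asarray(mat), index=gene_names, columns=bcs)


def write_counts_mtx(counts: pd.DataFrame, matrix: str | Path,
                     features: str | Path, barcodes: str | Path) -> None:
    spio.mmwrite(str(matrix), sparse.coo_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(features, sep="\t", index=False, header=False)
    pd.Series(counts.columns).to_csv(barcodes, sep="\t", index=False, header=False)


def read_counts_dense(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col=0)


def write_counts_dense(counts: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    counts.to_csv(path, sep=sep)


def write_grid(grid, path: str | Path) -> None:
    """Serialize a grid as ``<path>.npz`` plus a ``<path>.json`` sidecar."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".npz" else path
    arrays = {"values": grid.values, "validity": grid.validity}
    meta = {
        "kind": type(grid).__name__,
        "convention": "rows/cols 0-based; paper rows are 1-based (row+1)",
        "shape": list(grid.values.shape),
    }
    if isinstance(grid, ExpressionGrid):
        meta["gene_panel"] = list(grid.gene_names)
    np.savez_compressed(str(base) + ".npz", **arrays)
    with open(str(base) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_grid(path: str | Path):
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".npz", ".json") else path
    with np.load(str(base) + ".npz") as npz:
        values, validity = npz["values"], npz["validity"]
    with open(str(base) + ".json") as fh:
        meta = json.load(fh)
    if meta["kind"] == "ExpressionGrid":
        return ExpressionGrid(values, meta["gene_panel"], validity)
    if meta["kind"] == "LabelGrid":
        return LabelGrid(values, validity)
    from .images import FeatureMap
    if meta["kind"] == "FeatureMap":
        # blank vector recoverable from any invalid cell; fall back to zeros
        inv = np.argwhere(~validity)
        blank = values[:, inv[0][0], inv[0][1]] if len(inv) else np.zeros(values.shape[0])
        return FeatureMap(values, validity, blank)
    raise ValueError(f"unknown grid kind {meta['kind']!r}")


def read_clinical(path: str | Path, time_col: str, event_col: str,
                  covariate_cols: Sequence[str] = ()) -> pd.DataFrame:
    """Clinical table with survival time, event indicator and covariates."""
    df = pd.read_csv(path)
    cols = [time_col, event_col, *covariate_cols]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns {missing}")
    out = df[cols].rename(columns={time_col: "time", event_col: "event"})
    if (out["time"] < 0).any():
        raise ValueError("survival times must be non-negative")
    if not out["event"].isin((0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    return out
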