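"""Hexagonal spot lattice <-> dense grid transforms.

10x Visium spots are hexagonally packed: a spot at array row ``r`` has array
column ``c`` with the same parity as ``r``, columns advance in steps of two,
and odd rows are offset by half a spot pitch.  To feed a convolutional network
the spots are re-indexed into a dense matrix that preserves relative
proximity: a spot maps to grid row ``r + 1`` (1-based) and grid column
``phi(r, c) = c/2 + 1`` on even rows or ``(c+1)/2`` on odd rows.  Internally
everything is stored 0-based, where the transform collapses to
``(row, col) = (r, c // 2)``; serialized sidecars record the convention.

On the full Visium lattice (78 rows x 64 spots/row) this maps 4,992 spots
bijectively onto a 78x64 grid, and hex-adjacent spots land within Chebyshev
distance 1 of each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpotLayout", "GridAssignment", "ExpressionGrid", "LabelGrid",
    "GridError", "CollisionError", "LayoutError", "GeometryError",
    "map_spots_to_grid", "build_expression_grid", "build_tumor_mask",
    "pad_to_model_grid", "unmap_grid", "normalize_counts",
    "VISIUM_GRID_SHAPE", "MODEL_GRID_SHAPE",
]

#: dense grid of the full Visium lattice (rows x collapsed columns)
VISIUM_GRID_SHAPE = (78, 64)
#: geometry after appending two blank rows so four 2x downsamplings divide evenly
MODEL_GRID_SHAPE = (80, 64)


class GridError(ValueError):
    """Base class for spot-to-grid mapping failures."""


class CollisionError(GridError):
    """Two barcodes mapped to the same grid cell (corrupted input)."""


class LayoutError(GridError):
    """Spot table violates the hexagonal lattice constraints."""


class GeometryError(GridError):
    """Array shape incompatible with the requested operation."""


@dataclass
class SpotLayout:
    """Spot table: barcodes with hex array indices and pixel centers."""

    barcodes: list[str]
    array_row: np.ndarray
    array_col: np.ndarray
    pixel_x: np.ndarray
    pixel_y: np.ndarray
    in_tissue: np.ndarray

    def __post_init__(self):
        self.barcodes = list(self.barcodes)
        self.array_row = np.asarray(self.array_row, dtype=np.int64)
        self.array_col = np.asarray(self.array_col, dtype=np.int64)
        self.pixel_x = np.asarray(self.pixel_x, dtype=np.float64)
        self.pixel_y = np.asarray(self.pixel_y, dtype=np.float64)
        self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
        n = len(self.barcodes)
        for name in ("array_row", "array_col", "pixel_x", "pixel_y", "in_tissue"):
            if len(getattr(self, name)) != n:
                raise LayoutError(f"{name} has length {len(getattr(self, name))}, expected {n}")
        if len(set(self.barcodes)) != n:
            raise LayoutError("duplicate barcodes in layout")

    def __len__(self) -> int:
        return len(self.barcodes)

    def validate_hex(self) -> None:
        """Check the hex parity constraint (array_row and array_col same parity)."""
        bad = (self.array_row % 2) != (self.array_col % 2)
        if bad.any():
            names = [self.barcodes[i] for i in np.flatnonzero(bad)[:5]]
            raise LayoutError(f"row/column parity violation for spots {names}")

    def tissue_subset(self) -> "SpotLayout":
        keep = np.flatnonzero(self.in_tissue)
        return SpotLayout(
            [self.barcodes[i] for i in keep],
            self.array_row[keep], self.array_col[keep],
            self.pixel_x[keep], self.pixel_y[keep],
            self.in_tissue[keep],
        )


@dataclass
class GridAssignment:
    """Injective barcode -> grid-cell map (0-based cells) with its inverse."""

    shape: tuple[int, int]
    cell_of: dict[str, tuple[int, int]]
    barcode_at: dict[tuple[int, int], str] = field(default=None)  # type: ignore

    def __post_init__(self):
        if self.barcode_at is None:
            self.barcode_at = {cell: bc for bc, cell in self.cell_of.items()}
        if len(self.barcode_at) != len(self.cell_of):
            raise CollisionError("cell_of is not injective")

    @property
    def barcodes(self) -> list[str]:
        return list(self.cell_of)

    def __len__(self) -> int:
        return len(self.cell_of)

    def rows_cols(self, barcodes: Sequence[str] | None = None):
        bcs = list(self.cell_of) if barcodes is None else list(barcodes)
        cells = np.array([self.cell_of[b] for b in bcs], dtype=np.int64).reshape(-1, 2)
        return cells[:, 0], cells[:, 1]

    def validity_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        r, c = self.rows_cols()
        mask[r, c] = True
        return mask


@dataclass
class ExpressionGrid:
    """Gene x height x width expression map with a validity mask.

    Invalid cells (no spot) hold exactly zero.
    """

    values: np.ndarray          # (G, H, W)
    gene_names: list[str]
    validity: np.ndarray        # (H, W) bool

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.values.ndim != 3:
            raise GeometryError(f"values must be 3-D, got shape {self.values.shape}")
        if self.values.shape[0] != len(self.gene_names):
            raise GeometryError("gene_names length does not match channel count")
        if self.values.shape[1:] != self.validity.shape:
            raise GeometryError("validity shape does not match values")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene_names must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("expression grid contains non-finite values")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class LabelGrid:
    """Binary tumor mask on the dense grid; invalid cells are zero."""

    values: np.ndarray          # (H, W) in {0, 1}
    validity: np.ndarray        # (H, W) bool

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.validity = np.asarray(self.validity, dtype=bool)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("label grid values must be 0/1")
        self.values = self.values.astype(np.float32)
        if self.values.shape != self.validity.shape:
            raise GeometryError("validity shape does not match values")

    @property
    def shape(self):
        return self.values.shape


def hex_to_grid_cell(array_row: np.ndarray, array_col: np.ndarray):
    """0-based dense cell for hex indices; equals the 1-based (r+1, phi) rule."""
    return np.asarray(array_row, dtype=np.int64), np.asarray(array_col, dtype=np.int64) // 2


def map_spots_to_grid(layout: SpotLayout, shape: tuple[int, int] = VISIUM_GRID_SHAPE,
                      hex_transform: bool = True) -> GridAssignment:
    """Assign each in-tissue spot to a dense grid cell.

    With ``hex_transform`` (the Visium dialect) the parity rule above is
    applied; without it, (array_row, array_col) pass through unchanged
    (rectangular legacy-ST arrays).
    """
    lay = layout.tissue_subset()
    if hex_transform:
        lay.validate_hex()
        rows, cols = hex_to_grid_cell(lay.array_row, lay.array_col)
    else:
        rows, cols = lay.array_row, lay.array_col
    n_rows, n_cols = shape
    oob = (rows < 0) | (rows >= n_rows) | (cols < 0) | (cols >= n_cols)
    if oob.any():
        names = [lay.barcodes[i] for i in np.flatnonzero(oob)[:5]]
        raise LayoutError(f"spots map outside the {n_rows}x{n_cols} grid: {names}")
    cell_of: dict[str, tuple[int, int]] = {}
    barcode_at: dict[tuple[int, int], str] = {}
    for bc, r, c in zip(lay.barcodes, rows, cols):
        cell = (int(r), int(c))
        if cell in barcode_at:
            raise CollisionError(
                f"barcodes {barcode_at[cell]!r} and {bc!r} both map to cell {cell}")
        barcode_at[cell] = bc
        cell_of[bc] = cell
    return GridAssignment(shape=tuple(shape), cell_of=cell_of, barcode_at=barcode_at)


class MissingGeneError(KeyError):
    pass


def build_expression_grid(counts: pd.DataFrame, assignment: GridAssignment,
                          genes: Sequence[str] | None = None) -> ExpressionGrid:
    """Place per-spot expression onto the dense grid, one channel per gene.

    ``counts`` is a genes x barcodes table (already normalized).  Cells
    without a spot hold zero; validity mirrors the assignment.
    """
    genes = list(counts.index) if genes is None else list(genes)
    missing = [g for g in genes if g not in counts.index]
    if missing:
        raise MissingGeneError(f"panel genes absent from counts: {missing[:5]}")
    barcodes = assignment.barcodes
    absent = [b for b in barcodes if b not in counts.columns]
    if absent:
        raise KeyError(f"assigned barcodes absent from counts: {absent[:5]}")
    h, w = assignment.shape
    values = np.zeros((len(genes), h, w), dtype=np.float32)
    rows, cols = assignment.rows_cols(barcodes)
    sub = counts.loc[genes, barcodes].to_numpy(dtype=np.float32)
    values[:, rows, cols] = sub
    return ExpressionGrid(values=values, gene_names=genes,
                          validity=assignment.validity_mask())


def build_tumor_mask(labels: Mapping[str, str] | pd.DataFrame,
                     assignment: GridAssignment,
                     tumor_label: str = "tumor",
                     normal_label: str = "normal") -> LabelGrid:
    """Binary mask from a barcode -> {tumor, normal} table; blanks are zero."""
    if isinstance(labels, pd.DataFrame):
        if labels.shape[1] != 1:
            raise ValueError("label table must have exactly one label column")
        labels = dict(zip(labels.index, labels.iloc[:, 0]))
    h, w = assignment.shape
    mask = np.zeros((h, w), dtype=np.float32)
    for bc, lab in labels.items():
        if bc not in assignment.cell_of:
            raise KeyError(f"labeled barcode {bc!r} not present in the assignment")
        if lab == tumor_label:
            r, c = assignment.cell_of[bc]
            mask[r, c] = 1.0
        elif lab != normal_label:
            raise ValueError(f"unknown label {lab!r} for barcode {bc!r} "
                             f"(expected {tumor_label!r} or {normal_label!r})")
    return LabelGrid(values=mask, validity=assignment.validity_mask())


def pad_to_model_grid(grid, pad_rows: int = 2,
                      expect_height: int = VISIUM_GRID_SHAPE[0]):
    """Append blank rows at the bottom so the height divides by 16 (78 -> 80).

    Works on :class:`ExpressionGrid`, :class:`LabelGrid` and
    :class:`~hist_st.images.FeatureMap` (the latter supplies its own blank
    filler).  Padded rows are marked invalid.
    """
    from .images import FeatureMap  # local import to avoid a cycle

    h = grid.values.shape[-2]
    if h != expect_height:
        raise GeometryError(
            f"pad_to_model_grid expects height {expect_height}, got {h} "
            "(already padded?)")
    pad_validity = np.zeros((pad_rows, grid.values.shape[-1]), dtype=bool)
    validity = np.concatenate([grid.validity, pad_validity], axis=0)
    if isinstance(grid, ExpressionGrid):
        pad = np.zeros((grid.values.shape[0], pad_rows, grid.values.shape[2]),
                       dtype=grid.values.dtype)
        return ExpressionGrid(np.concatenate([grid.values, pad], axis=1),
                              list(grid.gene_names), validity)
    if isinstance(grid, LabelGrid):
        pad = np.zeros((pad_rows, grid.values.shape[1]), dtype=grid.values.dtype)
        return LabelGrid(np.concatenate([grid.values, pad], axis=0), validity)
    if isinstance(grid, FeatureMap):
        filler = np.broadcast_to(
            grid.blank_vector[:, None, None],
            (grid.values.shape[0], pad_rows, grid.values.shape[2]))
        return FeatureMap(np.concatenate([grid.values, filler], axis=1),
                          validity, grid.blank_vector)
    raise TypeError(f"cannot pad object of type {type(grid).__name__}")


def unmap_grid(grid: ExpressionGrid, assignment: GridAssignment) -> pd.DataFrame:
    """Inverse of :func:`build_expression_grid`: genes x barcodes table.

    Output columns follow the assignment's spot ordering.  Accepts grids that
    were padded below the assignment's height.
    """
    h, w = assignment.shape
    gh, gw = grid.values.shape[1:]
    if gw != w or gh < h:
        raise GeometryError(
            f"grid spatial shape {gh}x{gw} incompatible with assignment {h}x{w}")
    barcodes = assignment.barcodes
    if not barcodes:
        return pd.DataFrame(index=list(grid.gene_names), dtype=np.float32)
    rows, cols = assignment.rows_cols(barcodes)
    data = grid.values[:, rows, cols]
    return pd.DataFrame(data, index=list(grid.gene_names), columns=barcodes)


def normalize_counts(raw: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-size normalize each spot to ``scale`` counts, then log1p.

    This is the log-normalization convention of the Seurat ecosystem the
    upstream count processing belongs to.  All-zero spots are left as zeros
    (a warning reports how many).
    """
    mat = raw.to_numpy(dtype=np.float64)
    if (mat < 0).any():
        raise ValueError("raw counts must be non-negative")
    libsize = mat.sum(axis=0)
    zero = libsize == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} spot(s) have zero total counts; left as zeros")
    denom = np.where(zero, 1.0, libsize)
    normed = np.log1p(mat / denom * scale)
    normed[:, zero] = 0.0
    return pd.DataFrame(normed, index=raw.index, columns=raw.columns)
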