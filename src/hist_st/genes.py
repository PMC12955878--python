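"""Spatially variable gene selection via Moran's I.

Moran's I measures spatial autocorrelation of a per-spot signal x:

    I = (N / S) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with S = sum_ij w_ij.  Spatial weights are binary k-nearest-neighbour
weights (w_ij = 1 for the k = 15 nearest neighbours of i, else 0); the
matrix is generally asymmetric and is used as-is, without row
normalization.  Under a random arrangement E[I] = -1/(N-1); smooth fields
push I towards 1.

Prediction targets are the genes whose median I across samples exceeds 0.4
with median p below 0.01 (a strict per-sample mode is available), optionally
augmented with lineage marker genes of prevalent tumor cell types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .grid import SpotLayout

__all__ = [
    "SpatialWeights", "MoranResult", "GenePanel",
    "hex_spot_coords", "knn_weights", "morans_i", "morans_i_table",
    "morans_p", "select_target_genes", "augment_with_markers",
    "score_sample",
]

DEFAULT_K = 15
DEFAULT_P_CUT = 0.01
DEFAULT_I_CUT = 0.4


@dataclass
class SpatialWeights:
    """Binary k-NN weights: unit i has w_ij = 1 for each j in neighbors[i]."""

    neighbors: np.ndarray  # (n, k) int indices

    def __post_init__(self):
        self.neighbors = np.asarray(self.neighbors, dtype=np.int64)
        n, k = self.neighbors.shape
        if (self.neighbors == np.arange(n)[:, None]).any():
            raise ValueError("self-neighbors are not allowed")

    @property
    def n(self) -> int:
        return self.neighbors.shape[0]

    @property
    def k(self) -> int:
        return self.neighbors.shape[1]

    @property
    def total_weight(self) -> float:
        return float(self.neighbors.size)

    def to_sparse(self) -> sparse.csr_matrix:
        n, k = self.neighbors.shape
        rows = np.repeat(np.arange(n), k)
        return sparse.csr_matrix(
            (np.ones(n * k), (rows, self.neighbors.ravel())), shape=(n, n))


@dataclass
class MoranResult:
    gene: str
    i_statistic: float
    p_value: float
    sample: str


@dataclass
class GenePanel:
    """Ordered unique gene names with per-gene provenance tags."""

    genes: list[str] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel genes must be unique")

    def __len__(self):
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes,
                             "provenance": [self.provenance[g] for g in self.genes]})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenePanel":
        df = pd.read_csv(path, sep="\t")
        return cls(genes=df["gene"].tolist(),
                   provenance=dict(zip(df["gene"], df["provenance"])))


def hex_spot_coords(layout: SpotLayout) -> np.ndarray:
    """Array-space coordinates scaled so hex neighbours are at distance 1.

    Columns advance by half the neighbour pitch and rows by sqrt(3)/2, so
    both in-row neighbours (c +/- 2) and diagonal neighbours (r +/- 1,
    c +/- 1) sit at unit distance.
    """
    x = layout.array_col.astype(np.float64) * 0.5
    y = layout.array_row.astype(np.float64) * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x, y])


def knn_weights(coords: np.ndarray, k: int = DEFAULT_K,
                chunk: int = 1024) -> SpatialWeights:
    """Euclidean k-NN binary weights; ties broken by ascending index.

    Brute-force with an explicit lexicographic (distance, index) order so the
    tie-break is deterministic, computed in row chunks to bound memory.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least two spatial units")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of units n={n}")
    neighbors = np.empty((n, k), dtype=np.int64)
    idx = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = np.sqrt(((coords[start:stop, None, :] - coords[None, :, :]) ** 2).sum(-1))
        d[idx[start:stop] - start, idx[start:stop]] = np.inf  # exclude self
        # stable sort on distance keeps ascending-index order among ties
        order = np.argsort(d, axis=1, kind="stable")
        neighbors[start:stop] = order[:, :k]
    return SpatialWeights(neighbors=neighbors)


def morans_i(values: np.ndarray, weights: SpatialWeights) -> float:
    """Moran's I for one gene (vector of per-spot values)."""
    return float(morans_i_table(np.asarray(values, dtype=np.float64)[None, :],
                                weights)[0])


def morans_i_table(values: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    """Vectorized Moran's I for a genes x spots matrix."""
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != weights.n:
        raise ValueError(f"values shape {x.shape} incompatible with n={weights.n}")
    n = weights.n
    z = x - x.mean(axis=1, keepdims=True)
    denom = (z * z).sum(axis=1)
    if (denom == 0).any():
        bad = int((denom == 0).sum())
        raise ValueError(f"{bad} gene(s) have zero variance; Moran's I undefined")
    wz = z[:, weights.neighbors].sum(axis=2)      # (G, n): sum_j w_ij z_j
    num = (z * wz).sum(axis=1)
    return (n / weights.total_weight) * num / denom


def _moran_moments(weights: SpatialWeights) -> tuple[float, float]:
    """E[I] and Var[I] under the normality null (analytic z test)."""
    w = weights.to_sparse()
    n = weights.n
    s0 = weights.total_weight
    wt = w.T.tocsr()
    s1 = 0.5 * ((w + wt).power(2)).sum()
    row = np.asarray(w.sum(axis=1)).ravel()
    col = np.asarray(w.sum(axis=0)).ravel()
    s2 = ((row + col) ** 2).sum()
    e_i = -1.0 / (n - 1)
    var = ((n * n * s1 - n * s2 + 3.0 * s0 * s0)
           / (s0 * s0 * (n * n - 1.0))) - e_i ** 2
    return e_i, var


def morans_p(values: np.ndarray, weights: SpatialWeights,
             method: Literal["analytic_z", "permutation"] = "analytic_z",
             n_perm: int = 999, seed: int = 0,
             i_obs: float | None = None) -> float:
    """One-sided p-value for positive spatial autocorrelation."""
    if i_obs is None:
        i_obs = morans_i(values, weights)
    if method == "analytic_z":
        e_i, var = _moran_moments(weights)
        z = (i_obs - e_i) / np.sqrt(var)
        return float(stats.norm.sf(z))
    if method == "permutation":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        x = np.asarray(values, dtype=np.float64)
        perms = np.array([rng.permutation(x) for _ in range(n_perm)])
        i_perm = morans_i_table(perms, weights)
        return float((1 + (i_perm >= i_obs).sum()) / (1 + n_perm))
    raise ValueError(f"unknown method {method!r}")


def score_sample(counts: pd.DataFrame, layout: SpotLayout, sample: str,
                 k: int = DEFAULT_K,
                 method: Literal["analytic_z", "permutation"] = "analytic_z",
                 n_perm: int = 999, seed: int = 0) -> list[MoranResult]:
    """Moran's I + p for every gene of one slide (genes x barcodes counts).

    Zero-variance genes get I = nan, p = 1 (they can never be selected).
    """
    lay = layout.tissue_subset()
    coords = hex_spot_coords(lay)
    weights = knn_weights(coords, k=k)
    mat = counts[lay.barcodes].to_numpy(dtype=np.float64)
    z = mat - mat.mean(axis=1, keepdims=True)
    varying = (z * z).sum(axis=1) > 0
    i_vals = np.full(mat.shape[0], np.nan)
    if varying.any():
        i_vals[varying] = morans_i_table(mat[varying], weights)
    results = []
    e_i, var = _moran_moments(weights)
    for gi, gene in enumerate(counts.index):
        if not varying[gi]:
            results.append(MoranResult(gene, float("nan"), 1.0, sample))
            continue
        if method == "analytic_z":
            p = float(stats.norm.sf((i_vals[gi] - e_i) / np.sqrt(var)))
        else:
            p = morans_p(mat[gi], weights, method="permutation",
                         n_perm=n_perm, seed=seed, i_obs=i_vals[gi])
        results.append(MoranResult(gene, float(i_vals[gi]), p, sample))
    return results


def select_target_genes(results: Iterable[MoranResult],
                        p_cut: float = DEFAULT_P_CUT,
                        i_cut: float = DEFAULT_I_CUT,
                        p_mode: Literal["median", "all"] = "median") -> GenePanel:
    """Keep genes with median I > i_cut across samples and p below p_cut.

    ``p_mode='median'`` requires the median p across samples < p_cut;
    ``'all'`` requires every sample's p < p_cut.  Ordering is deterministic:
    descending median I, then gene name.
    """
    by_gene: dict[str, list[MoranResult]] = {}
    for r in results:
        by_gene.setdefault(r.gene, []).append(r)
    selected: list[tuple[float, str]] = []
    for gene, rs in by_gene.items():
        i_vals = np.array([r.i_statistic for r in rs], dtype=float)
        p_vals = np.array([r.p_value for r in rs], dtype=float)
        if np.isnan(i_vals).any():
            continue
        med_i = float(np.median(i_vals))
        if not med_i > i_cut:
            continue
        p_ok = (float(np.median(p_vals)) < p_cut if p_mode == "median"
                else bool((p_vals < p_cut).all()))
        if p_ok:
            selected.append((med_i, gene))
    if not selected:
        warnings.warn("no genes passed the spatial-autocorrelation thresholds")
    selected.sort(key=lambda t: (-t[0], t[1]))
    genes = [g for _, g in selected]
    return GenePanel(genes=genes, provenance={g: "autocorrelation" for g in genes})


def augment_with_markers(panel: GenePanel, markers: Sequence[str],
                         universe: Sequence[str]) -> GenePanel:
    """Union the panel with lineage marker genes detected in the data."""
    universe_set = set(universe)
    genes = list(panel.genes)
    provenance = dict(panel.provenance)
    for m in markers:
        if m in provenance:
            continue
        if m not in universe_set:
            warnings.warn(f"marker gene {m!r} not detected; dropped")
            continue
        genes.append(m)
        provenance[m] = "marker"
    return GenePanel(genes=genes, provenance=provenance)
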