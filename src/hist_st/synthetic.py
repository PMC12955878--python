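"""Synthetic fixtures with the statistical structure the method assumes.

Generators emulate every input of the pipeline: a hexagonal Visium-style
spot lattice (78 rows x 64 spots/row = 4,992 spots by default), counts in
which a chosen fraction of genes carry spatially autocorrelated signal
(Gaussian-kernel-smoothed white-noise fields, exponentiated to Poisson
counts) while the rest are i.i.d. noise, a blob-shaped tumor label field,
an image whose per-spot intensity is an affine function of a designated
gene's expression plus texture noise, and survival / immunotherapy cohorts
generated from a linear Cox model or a two-class mean shift.

Every generator is a pure function of its seed: same configuration, same
bytes.  All on-disk formats the real readers consume can be produced by
:func:`write_fixture_dir`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .application import SurvivalRecord
from .genes import hex_spot_coords
from .grid import ExpressionGrid, SpotLayout, normalize_counts

__all__ = [
    "SyntheticSlideConfig", "make_layout", "make_expression",
    "make_tumor_labels", "make_image", "make_slide",
    "make_survival_cohort", "make_icb_cohort", "write_fixture_dir",
    "smooth_field",
]


@dataclass
class SyntheticSlideConfig:
    """Knobs of one synthetic slide; defaults follow the full Visium dialect."""

    n_rows: int = 78
    cols_per_row: int = 64
    n_genes: int = 100
    smooth_fraction: float = 0.10
    bandwidth: float = 3.0          # Gaussian smoothing length (lattice units)
    signal_amplitude: float = 1.5   # log-scale amplitude of the smooth field
    noise_sd: float = 0.3           # extra log-scale white noise on smooth genes
    base_log_mean: float = 1.5      # log of the baseline Poisson mean
    tumor_center: tuple[float, float] = (0.5, 0.5)  # fractional (row, col)
    tumor_radius: float = 0.30      # fraction of the smaller lattice extent
    image_px_per_spot: int = 10     # neighbour pitch in pixels
    image_noise_sd: float = 5.0     # pixel-intensity texture noise
    tumor_shade: float = 40.0       # intensity drop of tumor-spot squares
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.smooth_fraction <= 1.0:
            raise ValueError("smooth_fraction must be in [0, 1]")
        if min(self.n_rows, self.cols_per_row, self.n_genes,
               self.image_px_per_spot) <= 0:
            raise ValueError("size parameters must be positive")

    def with_(self, **kwargs) -> "SyntheticSlideConfig":
        return replace(self, **kwargs)


def make_layout(cfg: SyntheticSlideConfig) -> SpotLayout:
    """Hex lattice: row r holds columns r % 2, r % 2 + 2, ... (parity match).

    Pixel centers lie on a triangular lattice with a constant
    nearest-neighbour pitch of ``image_px_per_spot`` pixels.
    """
    rows, cols = [], []
    for r in range(cfg.n_rows):
        for j in range(cfg.cols_per_row):
            rows.append(r)
            cols.append((r % 2) + 2 * j)
    rows = np.array(rows)
    cols = np.array(cols)
    s = float(cfg.image_px_per_spot)
    margin = 2.0 * s
    return SpotLayout(
        barcodes=[f"spot-{r:03d}-{c:03d}" for r, c in zip(rows, cols)],
        array_row=rows, array_col=cols,
        pixel_x=margin + 0.5 * cols * s,
        pixel_y=margin + (np.sqrt(3.0) / 2.0) * rows * s,
        in_tissue=np.ones(len(rows), dtype=bool),
    )


def smooth_field(coords: np.ndarray, bandwidth: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Standardized Gaussian-kernel-smoothed white noise over spot positions.

    The kernel is truncated at three bandwidths; bandwidth 0 degenerates to
    the raw i.i.d. noise.
    """
    n = coords.shape[0]
    noise = rng.normal(size=n)
    if bandwidth <= 0:
        return noise
    tree = cKDTree(coords)
    pairs = tree.sparse_distance_matrix(tree, 3.0 * bandwidth, output_type="coo_matrix")
    k = sparse.csr_matrix(
        (np.exp(-0.5 * (pairs.data / bandwidth) ** 2), (pairs.row, pairs.col)),
        shape=(n, n))
    k = k + sparse.eye(n)  # self-distance pairs may be dropped by the tree
    k.data = np.minimum(k.data, 1.0)
    f = k @ noise
    return (f - f.mean()) / f.std()


def make_expression(cfg: SyntheticSlideConfig, layout: SpotLayout,
                    seed: int | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Counts (genes x barcodes) plus the ground-truth smooth-gene names.

    Smooth genes: counts ~ Poisson(exp(base + amplitude * field + noise));
    noise genes: i.i.d. Poisson(exp(base)).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    coords = hex_spot_coords(layout)
    n_spots = len(layout)
    n_smooth = int(round(cfg.smooth_fraction * cfg.n_genes))
    genes = [f"gene_{i:04d}" for i in range(cfg.n_genes)]
    smooth_genes = genes[:n_smooth]
    counts = np.empty((cfg.n_genes, n_spots), dtype=np.int64)
    for gi in range(cfg.n_genes):
        if gi < n_smooth:
            z = smooth_field(coords, cfg.bandwidth, rng)
            log_mu = (cfg.base_log_mean + cfg.signal_amplitude * z
                      + rng.normal(0.0, cfg.noise_sd, size=n_spots))
        else:
            log_mu = np.full(n_spots, cfg.base_log_mean)
        counts[gi] = rng.poisson(np.exp(log_mu))
    return pd.DataFrame(counts, index=genes, columns=layout.barcodes), smooth_genes


def make_tumor_labels(cfg: SyntheticSlideConfig,
                      layout: SpotLayout) -> dict[str, str]:
    """Blob-shaped tumor region: spots within the stated radius of the center."""
    coords = hex_spot_coords(layout)
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    center = lo + np.array([cfg.tumor_center[1], cfg.tumor_center[0]]) * (hi - lo)
    radius = cfg.tumor_radius * min(hi - lo)
    dist = np.sqrt(((coords - center) ** 2).sum(axis=1))
    return {bc: ("tumor" if d <= radius else "normal")
            for bc, d in zip(layout.barcodes, dist)}


def make_image(cfg: SyntheticSlideConfig, layout: SpotLayout,
               expression: pd.DataFrame,
               genes: str | Sequence[str] | None = None,
               tumor_labels: dict[str, str] | None = None,
               seed: int | None = None) -> tuple[np.ndarray, list[str]]:
    """Image whose per-spot local color encodes driving genes' values.

    Each spot paints a square of side 0.7x the spot pitch (squares of hex
    neighbours never overlap); each of up to three color channels is a
    fixed affine map of one driving gene's log1p raw count, plus
    Gaussian texture noise (channels beyond the driving genes repeat the
    first).  When ``tumor_labels`` is given, tumor spots are additionally
    darkened by ``tumor_shade`` — emulating the denser morphology of tumor
    tissue, which is what makes segmentation learnable from the image.
    Returned as float64 in 0..255 so the affine link is exact at zero
    noise; cast to uint8 for PNG export.
    """
    rng = np.random.default_rng(cfg.seed + 17 if seed is None else seed)
    if genes is None:
        genes = [expression.index[0]]
    elif isinstance(genes, str):
        genes = [genes]
    genes = list(genes)[:3]
    # fixed (slide-independent) affine encoding of log1p counts, so the
    # image -> expression link transfers across slides
    norms = [np.log1p(expression.loc[g, layout.barcodes].to_numpy(dtype=float))
             for g in genes]
    while len(norms) < 3:
        norms.append(norms[0])
    norms = np.stack(norms, axis=1) / 7.0  # (n_spots, 3), ~[0, 1)
    s = cfg.image_px_per_spot
    h = int(np.ceil(layout.pixel_y.max() + 2 * s))
    w = int(np.ceil(layout.pixel_x.max() + 2 * s))
    img = np.full((h, w, 3), 255.0)
    fill = max(int(0.7 * s), 1)
    half = fill // 2
    for i in range(len(layout)):
        cy, cx = int(round(layout.pixel_y[i])), int(round(layout.pixel_x[i]))
        base = 50.0 + 150.0 * norms[i]
        if tumor_labels is not None and tumor_labels.get(layout.barcodes[i]) == "tumor":
            base = np.maximum(base - cfg.tumor_shade, 0.0)
        block = np.broadcast_to(base, (fill, fill, 3)).copy()
        if cfg.image_noise_sd > 0:
            block = block + rng.normal(0, cfg.image_noise_sd, size=block.shape)
        img[cy - half:cy - half + fill, cx - half:cx - half + fill] = block
    return np.clip(img, 0.0, 255.0), genes


@dataclass
class SyntheticSlide:
    """One fully assembled slide: everything the pipeline consumes."""

    layout: SpotLayout
    counts_raw: pd.DataFrame
    counts: pd.DataFrame          # log-normalized
    smooth_genes: list[str]
    tumor_labels: dict[str, str]
    image: np.ndarray
    driving_genes: list[str]
    config: SyntheticSlideConfig = field(repr=False, default=None)  # type: ignore


def make_slide(cfg: SyntheticSlideConfig) -> SyntheticSlide:
    layout = make_layout(cfg)
    counts_raw, smooth = make_expression(cfg, layout)
    labels = make_tumor_labels(cfg, layout)
    image, genes = make_image(cfg, layout, counts_raw,
                              genes=smooth[:3] or counts_raw.index[:1].tolist(),
                              tumor_labels=labels)
    return SyntheticSlide(
        layout=layout, counts_raw=counts_raw,
        counts=normalize_counts(counts_raw), smooth_genes=smooth,
        tumor_labels=labels, image=image, driving_genes=genes, config=cfg)


# ---------------------------------------------------------------------------
# cohorts


def _subject_grid(rng: np.random.Generator, shape: tuple[int, int],
                  n_genes: int, latents: np.ndarray,
                  bandwidth: float = 2.0) -> np.ndarray:
    """Per-subject grids: channel g carries field + latents[g] mean shift."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    coords = np.column_stack([xx.ravel() * 1.0, yy.ravel() * 1.0])
    grid = np.empty((n_genes, h, w), dtype=np.float32)
    for g in range(n_genes):
        z = smooth_field(coords, bandwidth, rng).reshape(h, w)
        grid[g] = z + latents[g]
    return grid


def _solve_censoring_rate(lam: np.ndarray, target: float) -> float:
    """Exponential censoring rate theta with mean P(C < T) = target.

    For T_i ~ Exp(lam_i), C ~ Exp(theta) independent:
    P(censored_i) = theta / (theta + lam_i); solved by bisection.
    """
    if target <= 0:
        return 0.0
    lo, hi = 1e-12, 1e12

    def frac(theta):
        return float(np.mean(theta / (theta + lam)))

    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def make_survival_cohort(n: int, beta: float | Sequence[float] = 1.0,
                         censoring_rate: float = 0.3, seed: int = 0,
                         grid_shape: tuple[int, int] = (16, 8),
                         n_genes: int = 4, n_signal: int = 2,
                         baseline_rate: float = 0.1,
                         covariate_effect: float = 0.0):
    """Cohort of expression grids with survival driven by their pseudo-bulk.

    The first ``n_signal`` gene channels carry subject-level latent shifts
    z_ig ~ N(0,1); the linear predictor is eta_i = sum_g beta_g z_ig (plus an
    optional ordinal covariate effect), times are exponential with rate
    baseline_rate * exp(eta), censoring is independent exponential tuned to
    the target rate.  Returns (grids, records, truth) where truth records
    eta and the latents.
    """
    rng = np.random.default_rng(seed)
    beta_vec = np.broadcast_to(np.atleast_1d(np.asarray(beta, dtype=float)),
                               (n_signal,))
    grades = ["low", "intermediate", "high"]
    grids, records, etas = [], [], []
    gene_names = [f"gene_{i:04d}" for i in range(n_genes)]
    latents_all = rng.normal(size=(n, n_genes))
    latents_all[:, n_signal:] = 0.0
    grade_idx = rng.integers(0, 3, size=n)
    eta = latents_all[:, :n_signal] @ beta_vec + covariate_effect * (grade_idx - 1)
    lam = baseline_rate * np.exp(eta)
    t_event = rng.exponential(1.0 / lam)
    theta = _solve_censoring_rate(lam, censoring_rate)
    c = rng.exponential(1.0 / theta, size=n) if theta > 0 else np.full(n, np.inf)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    h, w = grid_shape
    validity = np.ones((h, w), dtype=bool)
    for i in range(n):
        vals = _subject_grid(rng, grid_shape, n_genes, latents_all[i])
        grids.append(ExpressionGrid(values=vals, gene_names=gene_names,
                                    validity=validity))
        records.append(SurvivalRecord(time=float(time[i]), event=int(event[i]),
                                      covariates={"grade": grades[grade_idx[i]]}))
        etas.append(float(eta[i]))
    truth = {"eta": np.array(etas), "latents": latents_all,
             "signal_genes": gene_names[:n_signal], "theta": theta}
    return grids, records, truth


def make_icb_cohort(n: int | tuple[int, int] = (29, 102),
                    class_balance: float | None = None,
                    separation: float = 2.0, seed: int = 0,
                    grid_shape: tuple[int, int] = (16, 8),
                    n_genes: int = 4, n_pathway: int = 2):
    """Two-class cohort: responder grids shift designated pathway genes.

    ``n`` may be a total (labels drawn at ``class_balance``) or an explicit
    (responders, non-responders) pair — the default mirrors a 29:102
    imbalanced cohort.  Returns (grids, labels) with 1 = responder.
    """
    rng = np.random.default_rng(seed)
    if isinstance(n, tuple):
        n_r, n_nr = n
        labels = np.array([1] * n_r + [0] * n_nr)
    else:
        if class_balance is None or not 0 < class_balance < 1:
            raise ValueError("class_balance in (0,1) required for scalar n")
        labels = (rng.random(n) < class_balance).astype(int)
    gene_names = [f"gene_{i:04d}" for i in range(n_genes)]
    h, w = grid_shape
    validity = np.ones((h, w), dtype=bool)
    grids = []
    for lab in labels:
        latents = np.zeros(n_genes)
        latents[:n_pathway] = separation * lab + rng.normal(0, 1.0, n_pathway)
        vals = _subject_grid(rng, grid_shape, n_genes, latents)
        grids.append(ExpressionGrid(values=vals, gene_names=gene_names,
                                    validity=validity))
    return grids, labels


def write_fixture_dir(slide: SyntheticSlide, outdir) -> dict[str, str]:
    """Write a slide in the on-disk formats the real readers consume."""
    from pathlib import Path

    from PIL import Image

    from .io import write_counts_mtx, write_tissue_positions

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "positions": str(out / "tissue_positions.csv"),
        "matrix": str(out / "matrix.mtx"),
        "features": str(out / "features.tsv"),
        "barcodes": str(out / "barcodes.tsv"),
        "image": str(out / "image.png"),
        "labels": str(out / "tumor_labels.tsv"),
    }
    write_tissue_positions(slide.layout, paths["positions"])
    write_counts_mtx(slide.counts_raw, paths["matrix"], paths["features"],
                     paths["barcodes"])
    Image.fromarray(np.round(slide.image).astype(np.uint8)).save(paths["image"])
    pd.Series(slide.tumor_labels, name="label").rename_axis("barcode") \
        .to_frame().to_csv(paths["labels"], sep="\t")
    return paths
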