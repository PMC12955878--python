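"""H&E image preprocessing: patch cropping, feature extraction, feature maps,
and whole-slide-image tiling.

Each spot contributes one square patch centered on its pixel position.  A
pluggable extractor turns normalized patches into fixed-length feature
vectors (the production adapter would be a pathology-pretrained transformer
supplied by the user; a deterministic statistics-based stub ships for tests
and synthetic pipelines).  Feature vectors are then re-arranged onto the
dense spot grid — preserving relative spot positions — and padded to the
80 x 64 model geometry, with blank cells holding the feature vector of an
all-blank patch.

Variable-size WSIs are handled by padding to a 5:4 aspect ratio with white
(blank-tissue) pixels and tiling into 80 x 64 = 5,120 square patches; an
N-segment mode tiles sub-blocks independently for (80N) x (64N)
high-resolution output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .grid import (GeometryError, GridAssignment, SpotLayout,
                   pad_to_model_grid)

__all__ = [
    "IMAGENET_MEAN", "IMAGENET_STD",
    "PatchSpec", "FeatureMatrix", "FeatureMap", "FeatureExtractor",
    "StubExtractor", "load_image",
    "crop_patches", "prepare_patch", "extract_features",
    "assemble_feature_map", "tile_wsi", "tile_wsi_highres",
    "stitch_segment_grids", "reconstruct_from_tiles",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class PatchSpec:
    """Patch geometry and normalization constants.

    ``side_px`` is the crop edge in source pixels: 30 for the high-resolution
    slide mode, or ``round(scale_factor * fiducial_diameter)`` in WSI mode.
    """

    side_px: int = 30
    resize_to: int = 224
    mean: np.ndarray = field(default_factory=lambda: IMAGENET_MEAN.copy())
    std: np.ndarray = field(default_factory=lambda: IMAGENET_STD.copy())

    def __post_init__(self):
        if self.side_px < 1 or self.resize_to < 1:
            raise ValueError("side_px and resize_to must be >= 1")

    @classmethod
    def from_fiducial(cls, fiducial_diameter_px: float, scale_factor: float,
                      resize_to: int = 224) -> "PatchSpec":
        return cls(side_px=int(round(scale_factor * fiducial_diameter_px)),
                   resize_to=resize_to)


@dataclass
class FeatureMatrix:
    """Per-patch feature vectors, rows aligned with ``patch_order`` barcodes."""

    features: np.ndarray   # (n_patches, C)
    patch_order: list[str]

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float32)
        if self.features.shape[0] != len(self.patch_order):
            raise ValueError("feature row count does not match patch count")


@dataclass
class FeatureMap:
    """C x H x W grid of patch features; blank cells hold ``blank_vector``."""

    values: np.ndarray      # (C, H, W)
    validity: np.ndarray    # (H, W) bool
    blank_vector: np.ndarray  # (C,)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.validity = np.asarray(self.validity, dtype=bool)
        self.blank_vector = np.asarray(self.blank_vector, dtype=np.float32)
        if self.values.shape[1:] != self.validity.shape:
            raise GeometryError("validity shape does not match values")
        if self.blank_vector.shape != (self.values.shape[0],):
            raise GeometryError("blank vector length does not match channels")

    @property
    def shape(self):
        return self.values.shape


class FeatureExtractor(Protocol):
    """One normalized patch (3, resize, resize) -> feature vector (output_dim,).

    Must be deterministic: the same patch yields a bit-identical vector.
    """

    output_dim: int

    def __call__(self, patch: np.ndarray) -> np.ndarray: ...


class StubExtractor:
    """Deterministic feature extractor from pooled patch statistics.

    Summarizes each normalized patch by channel means/standard deviations, a
    coarse 6x6 block-mean thumbnail per channel, and mean gradient
    magnitudes, then applies a fixed seeded Gaussian projection to
    ``output_dim``.  Purely a function of (patch, seed): no external weights.
    """

    def __init__(self, output_dim: int = 768, seed: int = 0, pool: int = 6):
        self.output_dim = output_dim
        self.pool = pool
        n_stats = 3 + 3 + 3 * pool * pool + 3
        rng = np.random.default_rng(seed)
        self.projection = rng.normal(
            0.0, 1.0 / math.sqrt(n_stats), size=(n_stats, output_dim)
        ).astype(np.float32)

    def _stats(self, patch: np.ndarray) -> np.ndarray:
        c, h, w = patch.shape
        means = patch.mean(axis=(1, 2))
        stds = patch.std(axis=(1, 2))
        p = self.pool
        # block-mean thumbnail (crop to a multiple of the pool size)
        hh, ww = (h // p) * p, (w // p) * p
        thumb = patch[:, :hh, :ww].reshape(c, p, hh // p, p, ww // p).mean(axis=(2, 4))
        gy = np.abs(np.diff(patch, axis=1)).mean(axis=(1, 2))
        return np.concatenate([means, stds, thumb.reshape(-1), gy]).astype(np.float32)

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        patch = np.asarray(patch, dtype=np.float32)
        if patch.ndim != 3 or patch.shape[0] != 3:
            raise ValueError(f"expected a (3, H, W) patch, got {patch.shape}")
        return self._stats(patch) @ self.projection


def load_image(path) -> np.ndarray:
    """Load a PNG/TIFF/JPEG image as an (H, W, 3) uint8 array."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def crop_patches(image: np.ndarray, layout: SpotLayout,
                 spec: PatchSpec) -> tuple[np.ndarray, list[str]]:
    """Square crops of ``spec.side_px`` centered on each in-tissue spot.

    Crops extending past the image border are zero-padded to full size.
    Returns (n, side, side, 3) uint8-ish patches plus their barcodes.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got {image.shape}")
    lay = layout.tissue_subset()
    h, w = image.shape[:2]
    cx = np.round(lay.pixel_x).astype(int)
    cy = np.round(lay.pixel_y).astype(int)
    outside = (cx < 0) | (cx >= w) | (cy < 0) | (cy >= h)
    if outside.any():
        names = [lay.barcodes[i] for i in np.flatnonzero(outside)[:5]]
        raise ValueError(f"spot centers outside the image for barcodes {names}")
    side = spec.side_px
    half = side // 2
    patches = np.zeros((len(lay), side, side, image.shape[2]), dtype=image.dtype)
    for i in range(len(lay)):
        y0, x0 = cy[i] - half, cx[i] - half
        ys, xs = slice(max(y0, 0), min(y0 + side, h)), slice(max(x0, 0), min(x0 + side, w))
        patches[i, ys.start - y0:ys.stop - y0, xs.start - x0:xs.stop - x0] = image[ys, xs]
    return patches, lay.barcodes


def _bilinear_resize_hwc(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize with half-pixel centers (align_corners=False)."""
    h, w = img.shape[:2]
    ys = np.clip((np.arange(out_h) + 0.5) * h / out_h - 0.5, 0, h - 1)
    xs = np.clip((np.arange(out_w) + 0.5) * w / out_w - 0.5, 0, w - 1)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    out = np.empty((out_h, out_w, img.shape[2]), dtype=np.float32)
    for c in range(img.shape[2]):
        out[..., c] = ndimage.map_coordinates(
            img[..., c].astype(np.float32), [gy, gx], order=1, mode="nearest")
    return out


def prepare_patch(patch: np.ndarray, spec: PatchSpec) -> np.ndarray:
    """Resize to ``resize_to`` squared and normalize channel-wise.

    Input is (H, W, 3) with intensities in 0..255; output is a (3, R, R)
    float32 patch, ``(x/255 - mean) / std`` with the ImageNet constants.
    """
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError(f"expected a 3-channel (H, W, 3) patch, got {patch.shape}")
    resized = _bilinear_resize_hwc(patch.astype(np.float32), spec.resize_to, spec.resize_to)
    normed = (resized / 255.0 - spec.mean) / spec.std
    return np.ascontiguousarray(normed.transpose(2, 0, 1))


def blank_patch_vector(extractor: FeatureExtractor, spec: PatchSpec) -> np.ndarray:
    """Feature vector of an all-blank (zero-intensity) patch."""
    blank = np.zeros((spec.resize_to, spec.resize_to, 3), dtype=np.float32)
    return np.asarray(extractor(prepare_patch(blank, spec)), dtype=np.float32)


def extract_features(patches: np.ndarray, barcodes: Sequence[str],
                     extractor: FeatureExtractor,
                     spec: PatchSpec | None = None) -> FeatureMatrix:
    """Run the extractor over all patches, rows in patch order."""
    spec = spec or PatchSpec()
    rows = np.empty((len(patches), extractor.output_dim), dtype=np.float32)
    for i, patch in enumerate(patches):
        try:
            rows[i] = extractor(prepare_patch(patch, spec))
        except Exception as exc:  # re-raise with patch identity
            raise RuntimeError(
                f"feature extraction failed for patch {i} "
                f"(barcode {barcodes[i]!r})") from exc
    return FeatureMatrix(features=rows, patch_order=list(barcodes))


def assemble_feature_map(fm: FeatureMatrix, assignment: GridAssignment,
                         blank_vector: np.ndarray,
                         pad_rows: int = 2) -> FeatureMap:
    """Place feature rows at their grid cells and pad to model height.

    Cells without a spot — and the appended pad rows — hold the blank-patch
    vector, mirroring features extracted from blank tissue.
    """
    unknown = [b for b in fm.patch_order if b not in assignment.cell_of]
    if unknown:
        raise KeyError(f"barcodes not present in the assignment: {unknown[:5]}")
    h, w = assignment.shape
    c = fm.features.shape[1]
    blank_vector = np.asarray(blank_vector, dtype=np.float32)
    values = np.broadcast_to(blank_vector[:, None, None], (c, h, w)).copy()
    rows, cols = assignment.rows_cols(fm.patch_order)
    values[:, rows, cols] = fm.features.T
    validity = np.zeros((h, w), dtype=bool)
    validity[rows, cols] = True
    fmap = FeatureMap(values=values, validity=validity, blank_vector=blank_vector)
    if pad_rows:
        fmap = pad_to_model_grid(fmap, pad_rows=pad_rows, expect_height=h)
    return fmap


def tile_wsi(image: np.ndarray, grid: tuple[int, int] = (80, 64),
             blank_value: int = 255) -> tuple[np.ndarray, dict]:
    """Pad a WSI to a 5:4 aspect ratio and tile it into grid[0]*grid[1] patches.

    The patch side is ``s = ceil(max(H/gr, W/gc))``; the image is centered in
    a white ``gr*s x gc*s`` canvas and tiled row-major.  The manifest records
    everything needed to reconstruct the padded image exactly.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    gr, gc = grid
    h, w = image.shape[:2]
    s = math.ceil(max(h / gr, w / gc))
    canvas_h, canvas_w = gr * s, gc * s
    pad_top = (canvas_h - h) // 2
    pad_left = (canvas_w - w) // 2
    canvas = np.full((canvas_h, canvas_w, image.shape[2]), blank_value,
                     dtype=image.dtype)
    canvas[pad_top:pad_top + h, pad_left:pad_left + w] = image
    patches = canvas.reshape(gr, s, gc, s, -1).transpose(0, 2, 1, 3, 4)
    patches = patches.reshape(gr * gc, s, s, -1)
    manifest = {
        "grid": [gr, gc], "patch_side": s,
        "pad_top": pad_top, "pad_left": pad_left,
        "original_shape": [h, w], "order": "row-major",
        "blank_value": blank_value,
    }
    return patches, manifest


def reconstruct_from_tiles(patches: np.ndarray, manifest: dict) -> np.ndarray:
    """Exact inverse of :func:`tile_wsi` (returns the padded canvas)."""
    gr, gc = manifest["grid"]
    s = manifest["patch_side"]
    canvas = patches.reshape(gr, gc, s, s, -1).transpose(0, 2, 1, 3, 4)
    return canvas.reshape(gr * s, gc * s, -1)


def tile_wsi_highres(image: np.ndarray, n_segments: int,
                     grid: tuple[int, int] = (80, 64),
                     blank_value: int = 255) -> list[dict]:
    """Tile an image as N x N independent blocks for high-resolution output.

    Each block is tiled by :func:`tile_wsi`; predictions on the blocks stitch
    into a (grid[0]*N) x (grid[1]*N) geometry.  Returns one manifest per
    block with keys ``block`` (row, col), ``patches`` and the tile manifest.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    image = np.asarray(image)
    h, w = image.shape[:2]
    row_edges = np.linspace(0, h, n_segments + 1).round().astype(int)
    col_edges = np.linspace(0, w, n_segments + 1).round().astype(int)
    manifests = []
    for bi in range(n_segments):
        for bj in range(n_segments):
            block = image[row_edges[bi]:row_edges[bi + 1],
                          col_edges[bj]:col_edges[bj + 1]]
            patches, man = tile_wsi(block, grid=grid, blank_value=blank_value)
            manifests.append({"block": (bi, bj), "patches": patches,
                              "manifest": man})
    return manifests


def stitch_segment_grids(block_grids: dict[tuple[int, int], np.ndarray],
                         n_segments: int,
                         grid: tuple[int, int] = (80, 64)) -> np.ndarray:
    """Place per-block (G, gr, gc) prediction grids at their block offsets."""
    gr, gc = grid
    sample = next(iter(block_grids.values()))
    out = np.zeros((sample.shape[0], gr * n_segments, gc * n_segments),
                   dtype=sample.dtype)
    for (bi, bj), vals in block_grids.items():
        out[:, bi * gr:(bi + 1) * gr, bj * gc:(bj + 1) * gc] = vals
    return out
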