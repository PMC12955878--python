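"""Tile a variable-size whole-slide image into the fixed model geometry.

The prediction network expects an 80 x 64 spot grid, so arbitrary WSIs are
padded with blank (white) pixels to a 5:4 aspect ratio and cut into
80 x 64 = 5,120 square patches. An N-segment mode tiles sub-blocks
independently, giving high-resolution output of (80N) x (64N).
"""

import numpy as np

from hist_st.images import (reconstruct_from_tiles, stitch_segment_grids,
                            tile_wsi, tile_wsi_highres)

rng = np.random.default_rng(0)
image = rng.integers(0, 255, size=(1000, 700, 3)).astype(np.uint8)

patches, manifest = tile_wsi(image)
print(f"image {image.shape[:2]} -> patch side {manifest['patch_side']} px, "
      f"{patches.shape[0]} patches")
print(f"padded canvas: {80 * manifest['patch_side']} x "
      f"{64 * manifest['patch_side']} "
      f"(pad offsets {manifest['pad_top']}, {manifest['pad_left']})")

canvas = reconstruct_from_tiles(patches, manifest)
t, l = manifest["pad_top"], manifest["pad_left"]
exact = np.array_equal(canvas[t:t + 1000, l:l + 700], image)
print(f"tiles reconstruct the padded image exactly: {exact}")

blocks = tile_wsi_highres(image, n_segments=2)
stitched = stitch_segment_grids(
    {b["block"]: np.zeros((5, 80, 64)) for b in blocks}, n_segments=2)
print(f"N=2 high-resolution mode: {len(blocks)} blocks, "
      f"stitched prediction geometry {stitched.shape[1:]} per gene")
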