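import numpy as np
import pytest

from hist_st.grid import SpotLayout, map_spots_to_grid
from hist_st.synthetic import SyntheticSlideConfig, make_slide


@pytest.fixture(scope="session")
def mini_cfg() -> SyntheticSlideConfig:
    """Reduced lattice used across tests: 14 x 16 spots, grid 16 x 16 padded."""
    return SyntheticSlideConfig(n_rows=14, cols_per_row=16, n_genes=30,
                                smooth_fraction=0.2, seed=42)


@pytest.fixture(scope="session")
def mini_slide(mini_cfg):
    return make_slide(mini_cfg)


@pytest.fixture(scope="session")
def mini_assignment(mini_cfg, mini_slide):
    return map_spots_to_grid(mini_slide.layout,
                             shape=(mini_cfg.n_rows, mini_cfg.cols_per_row))


def hex_layout(n_rows: int, cols_per_row: int, pitch: float = 10.0) -> SpotLayout:
    """Plain hex layout without expression (used where a slide is overkill)."""
    rows, cols = [], []
    for r in range(n_rows):
        for j in range(cols_per_row):
            rows.append(r)
            cols.append((r % 2) + 2 * j)
    rows, cols = np.array(rows), np.array(cols)
    return SpotLayout(
        barcodes=[f"bc-{r}-{c}" for r, c in zip(rows, cols)],
        array_row=rows, array_col=cols,
        pixel_x=20.0 + 0.5 * cols * pitch,
        pixel_y=20.0 + (np.sqrt(3.0) / 2.0) * rows * pitch,
        in_tissue=np.ones(len(rows), dtype=bool),
    )


@pytest.fixture(scope="session")
def full_visium_layout():
    return hex_layout(78, 64)
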