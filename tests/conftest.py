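import numpy as np
import pandas as pd
import pytest

from cytoviz import CellTable, ImageStack, SegmentationMask, SimulationSpec, make_t1d_like_scenario


@pytest.fixture
def simple_mask():
    """4x6 mask with two rectangular objects (ids 1 and 3, non-consecutive)."""
    labels = np.zeros((4, 6), dtype=np.int64)
    labels[0:2, 0:2] = 1
    labels[2:4, 3:6] = 3
    return SegmentationMask(labels, pixel_size_um=1.0)


@pytest.fixture
def simple_stack(simple_mask):
    """Two-channel stack constant per object: obj1 -> (2, 10), obj3 -> (4, 0)."""
    pixels = np.zeros((4, 6, 2))
    pixels[simple_mask.labels == 1, 0] = 2.0
    pixels[simple_mask.labels == 1, 1] = 10.0
    pixels[simple_mask.labels == 3, 0] = 4.0
    return ImageStack(pixels, ["CD4", "CD8a"], pixel_size_um=1.0)


@pytest.fixture
def simple_cells():
    df = pd.DataFrame(
        {
            "image_name": ["A", "A", "B"],
            "object_id": [1, 3, 1],
            "CD4": [0.1, 0.7, 0.9],
            "CD8a": [0.5, 0.2, 0.8],
            "cell_type": pd.Categorical(["Th", "Tc", "Th"]),
        }
    )
    return CellTable(df, ["CD4", "CD8a"])


def brute_force_boundary(labels):
    """Double-loop oracle: object pixel with any 8-neighbour of different label."""
    rows, cols = labels.shape
    out = np.zeros_like(labels, dtype=bool)
    for r in range(rows):
        for c in range(cols):
            if labels[r, c] == 0:
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and labels[rr, cc] != labels[r, c]:
                        out[r, c] = True
    return out


@pytest.fixture(scope="session")
def small_scenario():
    """Zero-noise disease-course scenario, small enough for fast tests."""
    spec = SimulationSpec(shape=(128, 128), n_cells=60, radius_range=(2, 3), seed=0)
    return make_t1d_like_scenario(seed=7, images_per_group=2, base_spec=spec)
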