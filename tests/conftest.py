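"""Shared fixtures: small synthetic fields reused across test modules.

Fields are scaled down (416 px, ~40 cells) relative to the camera-sized
default so the suite stays fast; the per-cell geometry (nucleus size,
spacing, droplet load) is unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from lipidhca.pipeline import segment_field
from lipidhca.synthetic import FieldConfig, generate_field

SMALL = dict(field_size_px=(416, 416), cells_per_field_mean=40.0)


@pytest.fixture(scope="session")
def small_config() -> FieldConfig:
    return FieldConfig(**SMALL)


@pytest.fixture(scope="session")
def vehicle_field(small_config):
    return generate_field(small_config, 0.0, 72.0, 11, treatment="vehicle")


@pytest.fixture(scope="session")
def treated_field(small_config):
    return generate_field(small_config, 50.0, 72.0, 12, treatment="TBT")


@pytest.fixture(scope="session")
def vehicle_masks(vehicle_field):
    image, _ = vehicle_field
    return segment_field(image)


def match_cells(truth_cells: pd.DataFrame, nuclei_labels: np.ndarray, max_dist: float = 10.0):
    """Match measured nuclei to ground-truth cells by centroid distance.

    Returns (truth_index, measured_label) pairs for matches within
    ``max_dist`` pixels (one-to-one, greedy nearest).
    """
    from scipy import ndimage as ndi

    n = int(nuclei_labels.max())
    if n == 0 or truth_cells.empty:
        return np.zeros((0, 2), dtype=int)
    cent = np.array(
        ndi.center_of_mass(np.ones_like(nuclei_labels), nuclei_labels, np.arange(1, n + 1))
    )
    tree = cKDTree(cent)
    d, idx = tree.query(truth_cells[["y", "x"]].to_numpy())
    pairs = []
    used = set()
    for ti in np.argsort(d):
        if d[ti] <= max_dist and idx[ti] not in used:
            pairs.append((ti, idx[ti] + 1))
            used.add(idx[ti])
    return np.array(pairs, dtype=int)
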