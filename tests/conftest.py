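import numpy as np
import pandas as pd
import pytest

from merfish3d.codebook import generate_codebook
from merfish3d.synthetic import (
    CellMapConfig,
    VesselSpec,
    gaussian_psf,
    plant_random_molecules,
    simulate_cell_map,
    simulate_image_stack,
)


@pytest.fixture(scope="session")
def codebook16():
    """16-bit codebook with 100 genes and 10 blanks."""
    return generate_codebook(16, 100, 10, seed=42)


@pytest.fixture(scope="session")
def codebook16_heavy_blanks():
    """16-bit codebook with 100 genes and 40 blanks (the full 140-word code)."""
    return generate_codebook(16, 100, 40, seed=42)


@pytest.fixture(scope="session")
def psf():
    return gaussian_psf(sigma=1.2, radius=4)


@pytest.fixture(scope="session")
def clean_stack(codebook16):
    """Noiseless 200-molecule stack with ground truth."""
    planted = plant_random_molecules(codebook16, 200, (3, 256, 256), seed=7)
    stack, truth = simulate_image_stack(codebook16, planted)
    return stack, truth


@pytest.fixture(scope="session")
def y_vessel_cells():
    """Cell map with a Y-shaped vessel: trunk sections 0-10, arms 10-20."""
    trunk = np.array([[500.0, 500.0, 0.0], [500.0, 500.0, 300.0]])
    arm_a = np.array([[500.0, 500.0, 300.0], [200.0, 500.0, 600.0]])
    arm_b = np.array([[500.0, 500.0, 300.0], [800.0, 500.0, 600.0]])
    cfg = CellMapConfig(
        background_types={"vCM": 6000, "Fibro": 3000, "BEC": 1000},
        vessels=[
            VesselSpec(trunk, radius=15.0, cells_per_section=8),
            VesselSpec(arm_a, radius=15.0, cells_per_section=8),
            VesselSpec(arm_b, radius=15.0, cells_per_section=8),
        ],
        seed=3,
    )
    return simulate_cell_map(cfg)


def match_molecules(truth: pd.DataFrame, decoded: pd.DataFrame, radius: float = 3.0):
    """Fraction of planted molecules recovered with the right gene nearby."""
    from scipy.spatial import cKDTree

    if len(decoded) == 0:
        return 0.0
    tree = cKDTree(decoded[["z", "y", "x"]].to_numpy())
    hits = 0
    for _, row in truth.iterrows():
        d, i = tree.query([row["z"], row["y"], row["x"]])
        if d < radius and decoded.iloc[i]["gene"] == row["gene"]:
            hits += 1
    return hits / len(truth)
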