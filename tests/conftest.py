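import numpy as np
import pytest

import catrace

# Mixed-composition 30-mer spanning the residue-volume range, small G/A
# termini — the standard single-helix construct used across the suite.
HELIX_SEQ = "GAGSWLKFHDAYTRVWGAMQILNVCPESAG"


@pytest.fixture(scope="session")
def helix30():
    return catrace.make_helix(30, sequence=HELIX_SEQ)


@pytest.fixture(scope="session")
def helix_map(helix30):
    """4 Å-class simulated map of the 30-residue helix (σ_sim = 2 Å)."""
    return catrace.simulate_map(helix30, voxel=1.0, sigma_sim=2.0, pad=8.0)


@pytest.fixture(scope="session")
def helix_ldps(helix_map):
    return catrace.detect_ldps(
        helix_map, catrace.MeanShiftParams(threshold_fraction=0.5)
    )


def blob_map(center=(5.0, 5.0, 5.0), sigma=2.0, extent=21, voxel=0.5):
    """Map of one isotropic Gaussian blob rendered on the grid."""
    center = np.asarray(center, dtype=float)
    ax = voxel * np.arange(extent)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
    values = np.exp(-1.5 * d2 / sigma**2)
    values[values < 1e-6] = 0.0  # same kernel floor as the map simulator
    grid = catrace.DensityGrid(values, np.zeros(3), np.full(3, voxel))
    grid.contour_level = float(np.percentile(values[values > 0], 60.0))
    return grid


def random_ca(rng, n, box=20.0, start_index=1):
    coords = rng.uniform(0, box, size=(n, 3))
    return catrace.CaStructure.from_arrays(coords, start_index=start_index)
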