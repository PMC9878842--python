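import numpy as np
import pytest

from pcpquant import synthetic as sim


@pytest.fixture(scope="session")
def noiseless_follicle_fixture():
    """Small noiseless backskin: 8 follicles, 70% polarized, seed fixed."""
    params = sim.FollicleSimParams(
        image_size=(512, 512), n_follicles=8, polarized_fraction=0.7,
        angle_mean=0.0, angle_concentration=4.0, noise_sd=0.0,
        background_level=0.0, seed=3)
    img, truth = sim.make_follicle_image(params)
    return params, img, truth


@pytest.fixture(scope="session")
def modulated_mesh_fixture():
    """Noiseless Voronoi mesh with polarity axis 30 degrees."""
    params = sim.MeshSimParams(
        n_cells=36, domain_size=(300, 300), polarity_axis=30.0,
        base_intensity=100.0, modulation_amplitude=50.0, noise_sd=0.0, seed=2)
    labels, intensity, truth = sim.make_cell_mesh(params)
    return params, labels, intensity, truth


@pytest.fixture(scope="session")
def pair_fixture():
    """Noiseless cell pair with 4x junction enrichment over background 20."""
    params = sim.PairSimParams(enrichment_factor=4.0, background_level=20.0,
                               noise_sd=0.0, seed=0)
    img, rois, truth = sim.make_cellpair_image(params)
    return params, img, rois, truth


def brute_force_nematic(rows, cols, intensities, centroid):
    """Independent oracle: per-pixel complex sum of I * exp(2i*phi).

    Angles computed from scratch here (y-up convention) so the oracle shares
    no code with the implementation under test.
    """
    dy = -(np.asarray(rows, float) - centroid[0])
    dx = np.asarray(cols, float) - centroid[1]
    phi = np.arctan2(dy, dx)
    vals = np.asarray(intensities, float)
    q = np.sum(vals * np.exp(2j * phi)) / np.sum(vals)
    mag = abs(q)
    axis = (np.degrees(np.angle(q)) / 2.0) % 180.0
    return mag, axis
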