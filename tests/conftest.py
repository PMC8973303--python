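import numpy as np
import pytest

from mitomotility import DetectionParams, SimParams, WellSummary
from mitomotility.simulate import simulate_well_distances


@pytest.fixture
def det_params():
    return DetectionParams()


@pytest.fixture
def fast_axon_params():
    """Small, quick single-axon movie for unit tests."""
    return SimParams(field_size=(48, 256), n_frames=80, seed=0)


def render_gaussian_frame(shape, spots, sigma=1.5, background=10.0,
                          photons=2000.0, noise_rng=None):
    """Render Gaussian spots at (x, y) positions; optional Poisson noise."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    frame = np.full(shape, float(background))
    amp = photons / (2 * np.pi * sigma**2)
    for (x, y) in spots:
        frame += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    if noise_rng is not None:
        frame = noise_rng.poisson(frame).astype(float)
    return frame


def make_well(name, compound, replicate, fraction_motile, is_vehicle, rng,
              n_particles=1000):
    """A WellSummary from the trajectory-level well simulator."""
    df = simulate_well_distances(n_particles, fraction_motile, rng)
    motile = df["net_displacement_um"] >= 2.0
    return WellSummary(
        well=name, compound=compound, replicate=replicate,
        distances_um=df["distance_um"].to_numpy(), is_vehicle=is_vehicle,
        percent_motile=100.0 * float(motile.mean()))
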