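import numpy as np
import pytest

from msidiscrim import synthetic_data as syn
from msidiscrim.io_core import FeatureTable, RoiMask, SpectraDataset


@pytest.fixture
def tiny_dataset():
    """3-pixel, 5-bin dataset on a common grid."""
    mz = np.array([800.0, 800.1, 800.2, 800.3, 800.4])
    inten = np.array(
        [
            [0.0, 1.0, 2.0, 1.0, 0.0],
            [1.0, 2.0, 3.0, 2.0, 1.0],
            [0.5, 0.5, 0.5, 0.5, 0.5],
        ]
    )
    coords = np.array([[0, 0], [1, 0], [0, 1]])
    return SpectraDataset(mz, inten, coords, mass_range=(800.0, 800.4))


@pytest.fixture
def small_phantom():
    """12x12 phantom with 20 components, mild corruption, fixed seed."""
    region = syn.make_phantom((12, 12), 0.4, seed=11)
    comps = syn.make_component_library(
        20, (800.0, 1200.0), frac_discriminatory=0.5,
        effect_size_range=(1.5, 1.5), skew_fraction=0.2, seed=12,
    )
    ds, mask, truth = syn.synthesize_dataset(
        region, comps, noise_sd=0.01, baseline_amp=0.05, mz_jitter_sd=0.03,
        tic_spread=0.15, outlier_rate=0.0, seed=13,
        grid_step=0.1, mass_range=(800.0, 1200.0),
    )
    return ds, mask, truth


@pytest.fixture
def abundance_phantom():
    """40x40 abundance-table phantom: 30 components, 5 discriminatory d=2."""
    region = syn.make_phantom((40, 40), 0.4, seed=21)
    comps = syn.make_component_library(
        30, (800.0, 4000.0), frac_discriminatory=5 / 30,
        effect_size_range=(2.0, 2.0), skew_fraction=0.0, seed=22,
    )
    table, mask, coords = syn.make_abundance_table(region, comps, seed=23)
    return table, mask, comps, coords
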