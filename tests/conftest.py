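import numpy as np
import pytest
from hypothesis import settings

from amylofilter.msi_core import IMSDataset, PixelSpectrum
from amylofilter.synthetic_data import GeneratorConfig, calibration_panel

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_dataset(pixel_peaks, width=None, height=None, n_drift_bins=200, metadata=None):
    """Build an IMSDataset from {(x, y): [(mz, drift, intensity), ...]}."""
    spectra = []
    for (x, y), peaks in pixel_peaks.items():
        if peaks:
            mz, drift, inten = map(np.asarray, zip(*peaks))
        else:
            mz = np.empty(0)
            drift = np.empty(0, dtype=np.int32)
            inten = np.empty(0, dtype=np.float32)
        spectra.append(PixelSpectrum(x=x, y=y, mz=mz, drift=drift, intensity=inten))
    if width is None:
        width = max((s.x for s in spectra), default=0) + 1
    if height is None:
        height = max((s.y for s in spectra), default=0) + 1
    return IMSDataset(width=width, height=height, spectra=spectra,
                      n_drift_bins=n_drift_bins, metadata=metadata or {})


def random_dataset(rng, width=4, height=4, max_peaks=12, n_drift_bins=200):
    pixel_peaks = {}
    for y in range(height):
        for x in range(width):
            n = int(rng.integers(0, max_peaks + 1))
            peaks = [
                (float(rng.uniform(700, 2000)), int(rng.integers(0, n_drift_bins)),
                 float(rng.uniform(1, 1000)))
                for _ in range(n)
            ]
            pixel_peaks[(x, y)] = peaks
    return make_dataset(pixel_peaks, width=width, height=height,
                        n_drift_bins=n_drift_bins)


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down generator conditions for fast unit tests."""
    return GeneratorConfig(width=16, height=16, n_blobs=3, blob_radius=(2.0, 4.0),
                           decoys_per_pixel=8)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    """Default panel with the small generator's true drift means filled in."""
    return calibration_panel(small_cfg)


@pytest.fixture(scope="session")
def default_cfg():
    return GeneratorConfig()
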