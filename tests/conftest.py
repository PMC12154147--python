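"""Shared fixtures: small synthetic inputs reused across test modules."""

import numpy as np
import pytest

from fusquant.cavitation import PulseSpectrum, SpectralSettings
from fusquant.microscopy import max_intensity_projection, segment_vessels
from fusquant.synthetic import MriPhantomSpec, default_scene, gen_mri_volume, gen_vessel_image


@pytest.fixture(scope="session")
def settings() -> SpectralSettings:
    return SpectralSettings()


def random_spectrum(rng: np.random.Generator, n_samples: int = 50_000, fs: float = 50e6,
                    settings: SpectralSettings | None = None) -> PulseSpectrum:
    """Random non-negative amplitude spectrum on a realistic pulse grid."""
    settings = settings or SpectralSettings()
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amplitudes = rng.exponential(scale=1.0, size=freqs.size)
    band = (freqs >= settings.band_low) & (freqs <= settings.band_high)
    return PulseSpectrum(
        frequencies=freqs, amplitudes=amplitudes, band_mask=band,
        n_samples=n_samples, sampling_rate=fs,
    )


@pytest.fixture(scope="session")
def fixture_scene():
    return default_scene()


@pytest.fixture(scope="session")
def fixture_render(fixture_scene):
    return gen_vessel_image(fixture_scene)


@pytest.fixture(scope="session")
def fixture_mip(fixture_render):
    return max_intensity_projection(fixture_render.stack)


@pytest.fixture(scope="session")
def fixture_vessels(fixture_scene, fixture_mip):
    segs = segment_vessels(
        fixture_mip.channel("vessel"),
        fixture_mip.pixel_size_um,
        threshold=fixture_scene.vessel_amplitude / 2.0,
    )
    # order by image row so segments align with the generator truth table
    segs.sort(key=lambda s: s.centroid[0])
    return segs


@pytest.fixture(scope="session")
def mri_phantom():
    return gen_mri_volume(MriPhantomSpec(seed=7))
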