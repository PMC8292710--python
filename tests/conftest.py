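import numpy as np
import pytest

from ventavoid import phantom4d as p4


@pytest.fixture(scope="session")
def small_anatomy() -> p4.PhantomAnatomy:
    """48^3 at 5 mm: fast anatomy for unit tests."""
    cfg = p4.PhantomConfig(shape=(48, 48, 48), spacing=(5.0, 5.0, 5.0))
    return p4.build_reference_anatomy(cfg, seed=11)


@pytest.fixture(scope="session")
def small_dvf(small_anatomy) -> p4.PhantomDVF:
    return p4.synthesize_dvf(small_anatomy, amplitude_mm=6.0, defect_factor=0.05,
                             seed=11)


@pytest.fixture(scope="session")
def small_4dct(small_anatomy, small_dvf) -> p4.FourDCT:
    return p4.make_4dct(small_anatomy, small_dvf,
                        p4.BreathingConfig(tumor_amplitude_mm=6.0))


@pytest.fixture(scope="session")
def medium_anatomy() -> p4.PhantomAnatomy:
    """64^3 at 3.75 mm: used where 48^3 is too coarse."""
    cfg = p4.PhantomConfig(shape=(64, 64, 64), spacing=(3.75, 3.75, 3.75))
    return p4.build_reference_anatomy(cfg, seed=7)


@pytest.fixture(scope="session")
def medium_pair(medium_anatomy):
    dvf = p4.synthesize_dvf(medium_anatomy, amplitude_mm=6.0, defect_factor=0.05,
                            seed=7)
    exhale = p4.render_phase(medium_anatomy, dvf, 0.0)
    inhale = p4.render_phase(medium_anatomy, dvf, 1.0)
    return medium_anatomy, dvf, exhale, inhale


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
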