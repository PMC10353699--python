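import numpy as np
import pytest

from ptep import FluidSpec, ParticleSpec, SceneSpec


@pytest.fixture(scope="session")
def fluid() -> FluidSpec:
    """Distilled water with the study's Na+/Cl- Soret coefficients."""
    return FluidSpec()


@pytest.fixture(scope="session")
def ps_sizes(fluid) -> dict[float, ParticleSpec]:
    """Polystyrene microspheres at the three studied diameters (µm)."""
    return {dp: ParticleSpec(diameter_um=dp, density=1050.0)
            for dp in (1.1, 5.0, 15.0)}


@pytest.fixture(scope="session")
def tracking_run():
    """One shared noise-free tracking scenario (simulation + rendering)."""
    from ptep.scenarios import tracking_scenario

    return tracking_scenario(seed=101)


@pytest.fixture(scope="session")
def accumulation_run():
    """One shared accumulation scenario at the default attraction."""
    from ptep.scenarios import accumulation_scenario

    return accumulation_scenario(seed=202)


def disk_frame(shape=(64, 64), centers=((32.0, 32.0),), radius=8.0,
               bg=220.0, fg=60.0) -> np.ndarray:
    """Analytic anti-aliased dark-disk frame for detector tests."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full(shape, bg)
    for cx, cy in centers:
        cov = np.clip(radius + 0.5 - np.hypot(xx - cx, yy - cy), 0.0, 1.0)
        img = np.minimum(img, bg + (fg - bg) * cov)
    return img
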