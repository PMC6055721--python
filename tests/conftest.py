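import numpy as np
import pytest

from uegsim import (
    APParams,
    GeneratorConfig,
    MarkerMap,
    gen_geometry,
    gen_timing_fields,
    simulate_from_markers,
)


@pytest.fixture(scope="session")
def params() -> APParams:
    return APParams()


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """A reduced sock (fast) with the default physiology."""
    return GeneratorConfig(n_sites=60, n_beats=10, n_corrupt_channels=4)


@pytest.fixture(scope="session")
def timing_240() -> MarkerMap:
    """Default-physiology ground-truth timing for a full 240-site sock at CL 600."""
    cfg = GeneratorConfig()
    geom = gen_geometry(cfg, seed=7)
    return gen_timing_fields(geom, cfg, seed=7)


@pytest.fixture(scope="session")
def ueg_240(timing_240):
    """Model electrograms simulated from the 240-site ground truth."""
    at = np.asarray(timing_240.at, float)
    rt = np.asarray(timing_240.rt, float)
    return simulate_from_markers(at, rt, cycle_length=600.0)
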