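import numpy as np
import pytest
from dataclasses import replace

from nmjkit.ephys_sim import build_scenario, spontaneous_protocol, simulate_recording
from nmjkit.image_sim import build_image_scenario, generate_nmj


@pytest.fixture(scope="session")
def wt2_scenario():
    return build_scenario(2, "WT")


@pytest.fixture(scope="session")
def sod1_sym_scenario():
    return build_scenario(20, "SOD1")


@pytest.fixture(scope="session")
def spontaneous_trace(sod1_sym_scenario):
    """One 30 s spontaneous recording plus its ground truth (fixed seed)."""
    return simulate_recording(sod1_sym_scenario, spontaneous_protocol(), seed=42)


@pytest.fixture(scope="session")
def clean_image():
    """A healthy synthetic pretzel: no dim area, no speckle, no satellites."""
    sc = replace(build_image_scenario(12, "WT"), dim_fraction=0.0,
                 floccular_fraction=0.0, n_extrajunctional=0)
    return generate_nmj(sc, seed=7)


@pytest.fixture(scope="session")
def diseased_image():
    """Early-symptomatic synthetic NMJ with fixed disruption levels."""
    sc = replace(build_image_scenario(20, "SOD1"),
                 floccular_fraction=0.7, n_extrajunctional=2)
    return generate_nmj(sc, seed=7)
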