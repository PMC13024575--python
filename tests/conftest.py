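import numpy as np
import pytest

from needleforce.params import LIVER, InsertionProtocol
from needleforce.synthetic import (TrialSpec, generate_insertion_curve,
                                   generate_layered_curve, renal_three_layer)


@pytest.fixture(scope="session")
def liver_noiseless():
    """Noiseless liver insertion at 0.5 mm/s to 40 mm, 10 Hz sampling."""
    spec = TrialSpec(protocol=InsertionProtocol(speed=0.5, max_depth=40.0),
                     tissue=LIVER, noise_sd=0.0, sample_rate=10.0)
    return generate_insertion_curve(spec)


@pytest.fixture(scope="session")
def renal_layered_noiseless():
    """Noiseless three-layer renal curve with known boundaries 10/25 mm."""
    spec = TrialSpec(protocol=InsertionProtocol(speed=0.5, max_depth=40.0),
                     tissue=renal_three_layer(), noise_sd=0.0,
                     sample_rate=10.0)
    return generate_layered_curve(spec)


@pytest.fixture(scope="session")
def fast_sampled_base():
    """Short base curve sampled at 20 kHz, resolving a 1 kHz disturbance."""
    spec = TrialSpec(protocol=InsertionProtocol(speed=2.5, max_depth=0.25),
                     tissue=LIVER, noise_sd=0.0, sample_rate=20000.0)
    return generate_insertion_curve(spec)
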