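import pytest

from peekflow.rig import CircuitConfig, SensorSpec


@pytest.fixture
def ideal_sensor():
    return SensorSpec.ideal()


@pytest.fixture
def blue_circuit():
    """Matched-resistance blue-tubing circuit at 25 cm head, no backpressure."""
    return CircuitConfig(height_cm=25.0, r_tubing=10.0, r_sample=10.0)
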