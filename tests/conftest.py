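import pytest
from hypothesis import HealthCheck, settings

from mitochar.data import load_reference_annotations
from mitochar.simulate import generate_genome, load_templates
from mitochar.data import simulation_template_path

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    """Transcribed annotation tables for the two study circles."""
    return load_reference_annotations()


@pytest.fixture(scope="session")
def templates():
    return load_templates(simulation_template_path())


@pytest.fixture(scope="session")
def sim_circle1(templates):
    """Small simulated circle (14 genes, one planted overlap)."""
    return generate_genome(templates[0], seed=42)


@pytest.fixture(scope="session")
def sim_circle2(templates):
    """Larger simulated circle (69 genes, two planted overlaps)."""
    return generate_genome(templates[1], seed=43)
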