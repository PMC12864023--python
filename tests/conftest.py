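import pytest
from hypothesis import HealthCheck, settings

from stigma_screen import default_lexicon
from stigma_screen.synthetic_data import NoteLengthSpec, SyntheticCorpusSpec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture()
def short_spec():
    """Generator spec with short notes for structure-only tests (grouping,
    splitting, counting), where the measured quantity is length-invariant."""
    def _make(**overrides):
        overrides.setdefault("note_length", NoteLengthSpec(mean=60, sd=20))
        return SyntheticCorpusSpec(**overrides)
    return _make
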