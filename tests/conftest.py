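import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# Oligo and target sequences printed in the binding experiments; the unit
# counts they carry pin down the counting convention.
PRINTED = {
    "hairpin_purine_24": "TGGGGGAAGAAGAGGGGGCAGAGA",
    "purine_core_22": "GGGGGAAGAAGAGGGGGCAGAG",
    "mir483": "AAGACGGGAGGAAAGAAGGGAG",
    "opti": "GAGACGGGGGAGAAGAAGGGGG",
    "scramble": "GGAAGGGCAGGGAGGGGGAAGA",
    "l11": "GAAGAAGGGGG",
    "r11": "GAGACGGGGGA",
}


@pytest.fixture
def printed():
    return dict(PRINTED)
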