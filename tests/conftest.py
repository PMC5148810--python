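import pytest

from ehrvec import (SynthConfig, generate_cohort, chain_admissions,
                    build_sequences)


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient cohort with perfectly planted signatures (no noise-free
    guarantee: background_rate=5)."""
    cfg = SynthConfig(n_patients=300, n_dx_codes=10, signature_strength=1.0,
                      background_rate=5.0, seed=11)
    records, truth = generate_cohort(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def small_sequences(small_cohort):
    _, records, truth = small_cohort
    return build_sequences(chain_admissions(records)), truth
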