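import numpy as np
import pytest

from dynamilc import CohortSpec, MilcModel, TimecourseRecord, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_model():
    """Miniature architecture in float64 for closed-form and gradient checks."""
    return MilcModel(
        n_components=4, window_length=5, d_enc=6, d_top=5,
        enc_attn_hidden=3, top_attn_hidden=3, d_head=4,
        seed=7, dtype=np.float64,
    )


@pytest.fixture
def small_model():
    """Small but non-trivial architecture for fast end-to-end training tests."""
    return MilcModel(
        n_components=8, window_length=10, d_enc=24, d_top=16,
        enc_attn_hidden=8, top_attn_hidden=8, d_head=16,
        seed=7,
    )


def small_cohort_spec(**kw):
    """Cohort matched to `small_model` (C=8, short series, strong effect)."""
    defaults = dict(
        n_per_class=12, n_components=8, n_timepoints=60,
        affected_components=(1, 3, 5), event_window=(25, 45),
        effect_size=2.5, seed=42,
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


@pytest.fixture
def small_cohort():
    return generate_cohort(small_cohort_spec())


@pytest.fixture
def record(rng):
    return TimecourseRecord("sub-demo", rng.standard_normal((6, 50)), label=1)
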