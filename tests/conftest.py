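import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture(scope="session")
def small_cohort():
    """A 9-sample cohort (3 per grade group) shared by read-only tests."""
    from meniscus_qmri.phantom import PhantomSpec, generate_cohort

    spec = PhantomSpec(
        n_samples=9, grade_fractions=(1 / 3, 1 / 3, 1 / 3), seed=7
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_summary(small_cohort):
    """ROI summary + delta tables of the small cohort, computed once."""
    from meniscus_qmri.pipeline import analyze_sample
    from meniscus_qmri.response import delta_table, summarize_maps

    frames = []
    for s in small_cohort.samples:
        states = analyze_sample(s, small_cohort.spec.apex_side)
        frames.append(summarize_maps(states, s.sample_id, s.truth.grade_group))
    summary = pd.concat(frames, ignore_index=True)
    return summary, delta_table(summary)
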