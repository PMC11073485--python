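import numpy as np
import pytest

from ifscreen import if_core, synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-subject cohort shared by read-only tests."""
    cfg = syn.CohortConfig(n=20, prevalence=0.3, seed=101)
    recordings, truths = syn.gen_cohort(cfg)
    return cfg, recordings, truths


@pytest.fixture()
def truth_subject():
    """One deterministic synthetic subject (normal LVEF)."""
    cfg = syn.CohortConfig(n=4, prevalence=0.0, seed=7)
    return cfg, syn.make_subject_truth(cfg, 1, positive=False)


@pytest.fixture(scope="session")
def narrow_fit_config():
    """Physiological search range used by bulk fitting tests.

    Covers every frequency the cohort generator can emit, with margin.
    """
    return if_core.FitConfig(omega1_range=(60.0, 200.0), omega2_range=(20.0, 160.0))


def make_cycle(truth, noise_sd=0.0, seed=1, fs=250.0):
    return syn.gen_cycle(truth, noise_sd, seed, fs)
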