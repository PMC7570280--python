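import numpy as np
import pytest

import trimodal as tm


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic study (6 animals, identity latent corr)."""
    return tm.generate_study(tm.StudyConfig(rng_seed=7))


@pytest.fixture(scope="session")
def default_tables(default_bundle):
    """The default study assembled into analysis tables.

    Uses the generator's analytic histology values (the image pipeline is
    exercised by its own tests).
    """
    b = default_bundle
    channel_metrics, outcomes, _ = tm.recording_metrics(b.channel_units)
    weekly = tm.behavior_weekly(b.behavior_trials)
    return tm.assemble(b.config, channel_metrics, outcomes, weekly,
                       b.histology_table)


def make_tables(config: tm.StudyConfig):
    """Full metric-level pipeline for an arbitrary study config."""
    b = tm.generate_study(config)
    channel_metrics, outcomes, _ = tm.recording_metrics(
        b.channel_units, n_channels=config.n_channels, n_keep=config.n_keep)
    weekly = tm.behavior_weekly(b.behavior_trials)
    return tm.assemble(config, channel_metrics, outcomes, weekly,
                       b.histology_table)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
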