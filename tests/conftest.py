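import pytest

import liftrisk as lr


@pytest.fixture(scope="session")
def default_profiles():
    return lr.sample_participants(10, seed=1)


@pytest.fixture(scope="session")
def default_tasks():
    return lr.build_task_grid()


@pytest.fixture(scope="session")
def small_trials():
    """3 participants x 12 tasks: enough structure for estimator tests, fast."""
    profiles = lr.sample_participants(3, seed=7)
    tasks = lr.build_task_grid(n_masses=3, n_heights=4)
    trials, manifest = lr.generate_dataset(profiles, tasks, seed=7)
    return profiles, tasks, trials, manifest


@pytest.fixture()
def smoke_config(tmp_path):
    """Tiny end-to-end configuration (3 participants, 6 tasks, 50 days)."""
    cfg = lr.RunConfig(
        seed=3,
        n_participants=3,
        tasks=lr.TaskGridConfig(n_masses=2, n_heights=3),
    )
    cfg.workday.n_days = 50
    return cfg


@pytest.fixture(scope="session")
def full_run():
    """The default study conditions: 10 participants, 50 tasks, 1000 days each."""
    return lr.run_pipeline(lr.RunConfig(seed=1))
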