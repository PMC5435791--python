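import numpy as np
import pytest

from graspkin import GeneratorConfig, GraspStudy
from graspkin.synth import draw_participants, iter_cohort_trials


def make_config(**overrides) -> GeneratorConfig:
    """A small, fast cohort config for unit tests."""
    defaults = dict(n_inexperienced=2, n_magicians=1, trials_per_cell=2, seed=0)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def make_noise_free_config(**overrides) -> GeneratorConfig:
    """All random variation switched off: the analytic-invertibility regime."""
    cfg = make_config(trial_noise_sd_ma=0.0, marker_jitter_sd=0.0,
                      rest_aperture_sd=0.0, **overrides)
    for group in cfg.params:
        for task in cfg.params[group]:
            p = cfg.params[group][task]
            p.ma_intercept_sd = 0.0
            p.ma_slope_sd = 0.0
            p.pv_sd = 0.0
            p.bias_corrected_sd = 0.0
            for size in p.mt_sd:
                p.mt_sd[size] = 0.0
    return cfg


def trials_from(config: GeneratorConfig, limit: int | None = None):
    rng = np.random.default_rng(config.seed)
    participants = draw_participants(config, rng)
    out = []
    for trial in iter_cohort_trials(config, participants, rng):
        out.append(trial)
        if limit is not None and len(out) >= limit:
            break
    return out


@pytest.fixture(scope="session")
def small_cohort_trials():
    return trials_from(make_config())


@pytest.fixture(scope="session")
def noise_free_trials():
    return trials_from(make_noise_free_config())


@pytest.fixture(scope="session")
def default_cohort_results():
    """One full-size cohort fitted end to end (shared across tests)."""
    return GraspStudy.simulate(GeneratorConfig(seed=123)).fit()
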