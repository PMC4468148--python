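import dataclasses
import math

import numpy as np
import pytest
import yaml
from hypothesis import HealthCheck, settings

from nivoi.markov import interval_probs_from_cumulative
from nivoi.params import ParamSpec, default_config_path, load_config

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def case():
    """(ModelConfig, specs) of the packaged case study."""
    return load_config()


@pytest.fixture(scope="session")
def config(case):
    return case[0]


@pytest.fixture(scope="session")
def specs(case):
    return case[1]


@pytest.fixture(scope="session")
def theta_means(specs):
    """Single parameter vector at the prior means (RR at its censoring point)."""
    by_name = {s.name: s for s in specs}
    q1, q2, q3 = interval_probs_from_cumulative(0.211, 0.222, 0.245)
    return {
        "q1": q1, "q2": q2, "q3": q3, "rr_tailored": 1.0,
        "disutility_mild_pts": by_name["disutility_mild_pts"].mean,
        "disutility_severe_pts": by_name["disutility_severe_pts"].mean,
        "disutility_ecs": by_name["disutility_ecs"].mean,
        "cost_mild_pts": by_name["cost_mild_pts"].mean,
        "cost_severe_pts": by_name["cost_severe_pts"].mean,
        "homecare_fraction": by_name["homecare_fraction"].mean,
    }


@pytest.fixture(scope="session")
def fixed_specs(specs, theta_means):
    """Zero-variance version of the case priors (every parameter fixed)."""
    out = []
    for s in specs:
        if s.name == "rr_tailored":
            mean = 1.0
        elif s.name.startswith("cum_inc"):
            mean = s.mean
        else:
            mean = theta_means[s.name]
        out.append(ParamSpec(name=s.name, family="fixed", mean=mean, units=s.units))
    return out


@pytest.fixture(scope="session")
def no_mortality_config(config):
    """Case config with background mortality switched off."""
    return dataclasses.replace(config, life_expectancy=math.inf)


@pytest.fixture()
def raw_config_dict():
    """Mutable dict form of the packaged YAML config, for invalid-config tests."""
    with open(default_config_path()) as fh:
        return yaml.safe_load(fh)


@pytest.fixture()
def write_config(tmp_path):
    def _write(raw: dict):
        p = tmp_path / "config.yaml"
        p.write_text(yaml.safe_dump(raw))
        return p

    return _write


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
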