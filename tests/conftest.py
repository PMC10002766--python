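import pytest
from hypothesis import HealthCheck, settings

import oxypair as ox

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bupivacaine():
    return ox.parse_formula("C18H28N2O")


@pytest.fixture(scope="session")
def candidates(bupivacaine):
    """Default depth-3 enumeration, keyed by class label."""
    return {
        c.class_label: c for c in ox.enumerate_candidates(bupivacaine)
    }


def compact_sim_config(seed: int = 0, **overrides) -> ox.SimConfig:
    """A shortened gradient used by most pipeline tests: same scan rate,
    noise and patterns as the full 15-min run, ~5x fewer scans."""
    kwargs = dict(
        gradient_span=(0.0, 6.0),
        parent_rt=5.5,
        seed=seed,
    )
    kwargs.update(overrides)
    return ox.SimConfig(**kwargs)


def compact_scenario(candidates, q: float = 0.3):
    """Six planted metabolites spanning Z in {0, 1, 2} on the short gradient."""
    plan = [
        ("H", 3.51, 8e5), ("DH", 1.10, 6e5), ("O", 4.83, 6e5),
        ("HO", 1.45, 6e5), ("DAH", 2.43, 6e5), ("DA", 3.06, 6e5),
    ]
    return [
        ox.PlantedMetabolite(candidate=candidates[label], rt_apex=rt, area=area, q=q)
        for label, rt, area in plan
    ]


@pytest.fixture(scope="module")
def paired_runs(bupivacaine, candidates):
    """(air, 18O2, controls, planted) for seed 0 on the short gradient."""
    planted = compact_scenario(candidates)
    air, o18, controls = ox.make_paired_runs(
        bupivacaine, planted, compact_sim_config(seed=0)
    )
    return air, o18, controls, planted
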