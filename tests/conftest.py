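import math

import pytest
from hypothesis import HealthCheck, settings

import fibrotime as ft

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """300-gene synthetic dataset with defaults; shared across tests."""
    cfg = ft.SimulationConfig(n_genes=300, seed=1)
    cm, truth = ft.generate_dataset(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def study_like_dataset():
    """2000-gene dataset with defaults; large enough for the sample-level
    diagnostics to show the study's qualitative structure."""
    cfg = ft.SimulationConfig(n_genes=2000, seed=1)
    cm, truth = ft.generate_dataset(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def small_rpkm(small_dataset):
    _, cm, _ = small_dataset
    expressed = ft.filter_expressed(cm)
    return cm, expressed, ft.compute_rpkm(expressed)


@pytest.fixture(scope="session")
def clean_monotone_dataset():
    """High-expression, low-dispersion dataset whose monotone genes have
    essentially noise-free orderings across PDs."""
    cfg = ft.SimulationConfig(
        n_genes=2000,
        seed=11,
        archetype_fractions={
            "flat": 0.9,
            "monotone_up": 0.05,
            "monotone_down": 0.05,
            "early_step": 0.0,
            "late_step": 0.0,
            "parabolic": 0.0,
        },
        shared_fraction=1.0,
        effect_size=1.0,
        dispersion_params=(0.02, 0.5),
        baseline_meanlog=math.log(200.0),
        baseline_sdlog=0.8,
    )
    cm, truth = ft.generate_dataset(cfg)
    return cfg, cm, truth
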