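import pytest
from hypothesis import settings

from sugarsem.psem import default_graph
from sugarsem.synthetic import GeneratorConfig, simulate_experiment

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def small_config(seed: int = 42, **overrides) -> GeneratorConfig:
    """Reduced design (12 subjects x 6 pairs) for fast mixed-model tests."""
    cfg = GeneratorConfig(seed=seed).replace(
        n_subjects=12, n_male=5, n_female=7, n_pairs=6
    )
    return cfg.replace(**overrides) if overrides else cfg


def zero_noise(cfg: GeneratorConfig) -> GeneratorConfig:
    zeros = {eq: 0.0 for eq in cfg.residual_sd}
    return cfg.replace(
        residual_sd=dict(zeros), subject_re_sd=dict(zeros), pair_re_sd=dict(zeros)
    )


def interpolation_config(node: str, seed: int = 13) -> GeneratorConfig:
    """Zero noise in ``node``'s equation only (exact-interpolation limit).

    Upstream equations keep their noise so mediator predictors vary freely;
    zeroing every equation would make the mediators deterministic functions
    of (label, gender, age) and the downstream designs rank-deficient.
    """
    cfg = small_config(seed=seed)
    cfg.residual_sd[node] = 0.0
    cfg.subject_re_sd[node] = 0.0
    cfg.pair_re_sd[node] = 0.0
    return cfg


@pytest.fixture(scope="session")
def graph():
    return default_graph()


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_experiment(small_config())


@pytest.fixture(scope="session")
def noiseless_dataset():
    return simulate_experiment(zero_noise(small_config(seed=5)))


@pytest.fixture(scope="session")
def default_dataset():
    """Full study design: 50 subjects x 30 pairs, latent mode."""
    return simulate_experiment(GeneratorConfig(seed=7))
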