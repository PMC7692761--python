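import numpy as np
import pytest

from ramanauth import GeneratorConfig, generate_dataset, make_component_profiles


@pytest.fixture(scope="session")
def profiles():
    return {p.name: p for p in make_component_profiles(0)}


@pytest.fixture(scope="session")
def clean_config():
    """Noiseless, baseline-free, shift-free generator setup."""
    return GeneratorConfig(
        n_target=8,
        n_compliant=4,
        n_unknown=2,
        n_nontarget=2,
        noise_sd=0.0,
        baseline_amplitude=0.0,
        session_shifts=(0.0, 0.0),
        session_gains=(1.0, 1.0),
        rind_gain_by_session=(1.0, 1.0),
        point_gain_sd=0.0,
        points_per_package=2,
        replicate_plan={},
        seed=3,
    )


@pytest.fixture(scope="session")
def small_config():
    """Reduced but structurally complete campaign for pipeline tests."""
    return GeneratorConfig(
        n_target=20,
        n_compliant=8,
        n_unknown=3,
        n_nontarget=3,
        points_per_package=3,
        replicate_plan={"PR1st": 1, "PR2nd": 1},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


def gaussian_class_data(a, p, n, seed, top_var=5.0, resid_var=0.1):
    """Gaussian target-class data with a leading components + isotropic
    residual variance (shared helper for SIMCA calibration tests)."""
    rng = np.random.default_rng(seed)
    sd = np.concatenate(
        [np.sqrt(np.linspace(top_var, 1.0, a)), np.full(p - a, np.sqrt(resid_var))]
    )
    return rng.standard_normal((n, p)) * sd


@pytest.fixture(scope="session")
def mixture_system(profiles):
    """Noiseless pulp/rind mixture builder on the default axis."""
    cfg = GeneratorConfig()
    axis = cfg.axis
    pulp = profiles["pulp"].evaluate(axis)
    rind = profiles["rind"].evaluate(axis)

    def build(fractions, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        f = np.asarray(fractions, dtype=float)
        x = np.outer(f, rind) + np.outer(1.0 - f, pulp)
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, size=x.shape)
        return axis, x, 100.0 * f

    return build
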