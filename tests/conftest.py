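import numpy as np
import pytest

from socpools.synth import LandscapeConfig, generate_horizon_table


@pytest.fixture(scope="session")
def landscape():
    """One default-sized synthetic landscape shared across tests."""
    table, truth = generate_horizon_table(LandscapeConfig(seed=42))
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_stable_spec(rng, n_pools):
    """A random valid 2- or 3-pool model within the study's kinetic envelope."""
    from socpools.compartments import PoolModelSpec

    k = np.sort(rng.uniform([1e-3, 5e-4, 1e-4][:n_pools],
                            [0.5, 0.05, 5e-3][:n_pools]))[::-1]
    alpha = np.zeros((n_pools, n_pools))
    alpha[1, 0] = rng.uniform(0.1, 0.9)
    alpha[0, 1] = rng.uniform(0.05, 1 - alpha[1, 0] if n_pools == 2 else 0.4)
    if n_pools == 3:
        alpha[2, 1] = rng.uniform(0.05, min(0.5, 1 - alpha[0, 1]))
        alpha[1, 2] = rng.uniform(0.05, 0.5)
    gamma = rng.dirichlet(np.ones(n_pools) * 2)
    return PoolModelSpec(k=k, alpha=alpha, gamma=gamma,
                         c_init=rng.uniform(5e3, 3e4))


def euler_trajectory(spec, times, dt=1e-3):
    """Independent fixed-step explicit Euler integration oracle."""
    from socpools.compartments import build_system_matrix

    A = build_system_matrix(spec)
    c = spec.c_init * spec.gamma.astype(float).copy()
    out = [c.copy()]
    t = 0.0
    for target in times[1:]:
        while t < target - dt / 2:
            c = c + dt * (spec.inputs + A @ c)
            t += dt
        out.append(c.copy())
    return np.array(out)
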