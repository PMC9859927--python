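import numpy as np
import pytest

from vaxalloc import EpidemicParameters, SupplySchedule


def random_admissible_parameters(rng: np.random.Generator, n: int | None = None,
                                 target_R0: float | None = None
                                 ) -> EpidemicParameters:
    """Random parameter set respecting all model constraints.

    The vaccine tiers are generated as beta2 = r_tr * beta1,
    beta3 = r_inf * beta1, beta4 = r_inf * r_tr * beta1 with multipliers in
    (0, 1], guaranteeing beta1 >= beta2 and beta3 >= beta4; mu2 >= mu1 and
    kappa <= 1 likewise hold by construction.  beta1 is rescaled so the
    next-generation spectral radius lands in a clearly supercritical range,
    keeping epidemics well-defined and fast to burn out.
    """
    if n is None:
        n = int(rng.integers(1, 4))
    if target_R0 is None:
        target_R0 = float(rng.uniform(1.5, 3.0))
    beta1 = rng.uniform(0.2, 1.0, (n, n))
    beta1[np.diag_indices(n)] += rng.uniform(0.2, 0.8, n)   # assortative-ish
    r_inf = rng.uniform(0.3, 1.0)
    r_tr = rng.uniform(0.3, 1.0)
    mu1 = rng.uniform(0.7, 1.3, n)
    mu2 = mu1 * rng.uniform(1.0, 1.3, n)
    N = rng.dirichlet(np.full(n, 5.0))
    ngm = N[:, None] * beta1 / mu1[None, :]
    rho = np.max(np.abs(np.linalg.eigvals(ngm)))
    beta1 = beta1 * (target_R0 / rho)
    I0 = 1e-3 * N
    return EpidemicParameters(
        n=n,
        beta1=beta1, beta2=r_tr * beta1, beta3=r_inf * beta1,
        beta4=r_inf * r_tr * beta1,
        mu1=mu1, mu2=mu2, N=N,
        p=rng.uniform(0.2, 2.0, n),
        kappa=rng.uniform(0.1, 1.0, n),
        S0=N - I0, I0=I0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230120)


@pytest.fixture
def homogeneous_beta2():
    """One-group model with beta = 2 and a half-effective vaccine."""
    from vaxalloc import homogeneous_example
    params, schedule = homogeneous_example(2.0, 0.01)
    return params, schedule


@pytest.fixture
def two_group_default():
    """Two-group example at eps = 0.3, I* = 0.01, p* = 1, chi = rho = 0.5."""
    from vaxalloc import two_group_example
    return two_group_example(0.3, 0.01, 1.0, 0.5, 0.5)


@pytest.fixture
def capped_unit_schedule():
    """A(t) = 1 with supply arriving at unit rate up to a total of 1."""
    return SupplySchedule.rate_limited(rate=1.0, total_supply=1.0)
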