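"""Worked examples: two-group crossover, homogeneous population, age structure.

Three model families exercise the theory end to end:

* **Two-group**: a tiny vulnerable group (size ``eps``, weight ``1/eps``)
  alongside a large infectious group.  Comparing the infectious-first
  policy ``U`` with its vulnerable-first swap ``tilde U`` over a grid of
  ``eps`` locates the crossover ``eps*`` below which vaccinating the
  vulnerable group first wins.
* **Homogeneous**: one group, supply ``eps`` available immediately; the
  final-size gradient ``y`` is sharpest for basic reproduction numbers
  near 1.
* **Age-structured**: a transmission matrix built from an (synthetic,
  assortative) contact matrix calibrated to a target R0, with
  case-fatality-ratio weights; the knapsack gradient ranks age groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import EpidemicParameters, Trajectory, objective_h, simulate
from .policies import SupplySchedule, VaccinationPolicy, prioritized_policy
from .small_supply import SmallSupplyLinearization, calibrate_beta, gradient_y

__all__ = [
    "TwoGroupExample",
    "CrossoverResult",
    "two_group_example",
    "epsilon_star",
    "homogeneous_example",
    "age_structured_example",
    "synthetic_contact_fixture",
    "write_fixture_csv",
    "load_contact_csv",
    "infected_groups",
]

#: base transmission matrix of the two-group example: the vulnerable group 1
#: is weakly infectious, group 2 strongly so.
TWO_GROUP_BETA1 = np.array([[1.0, 2.0], [2.0, 4.0]])


@dataclass
class TwoGroupExample:
    """Small-vulnerable-group example: parameters, schedule and both policies."""

    epsilon: float
    I_star: float
    p_star: float
    chi_eff: float    # infection-blocking multiplier (0 = perfect vaccine)
    rho_eff: float    # transmission-blocking multiplier
    params: EpidemicParameters
    schedule: SupplySchedule
    policy_infectious_first: VaccinationPolicy   # 'U': group 2 then group 1
    policy_vulnerable_first: VaccinationPolicy   # 'tilde U': group 1 then group 2

    def objectives(self, **sim_kwargs) -> tuple[float, float]:
        """(H(U), H(tilde U)) by simulation."""
        h_u = objective_h(simulate(self.params, self.policy_infectious_first,
                                   **sim_kwargs))
        h_t = objective_h(simulate(self.params, self.policy_vulnerable_first,
                                   **sim_kwargs))
        return h_u, h_t


def two_group_example(epsilon: float, I_star: float = 0.01, p_star: float = 1.0,
                      chi_eff: float = 0.5, rho_eff: float = 0.5) -> TwoGroupExample:
    """Build the two-group model and its two bang-bang policies.

    Group 1 has size ``epsilon``, weight ``1/epsilon``, starts fully
    susceptible; group 2 has size 1, weight ``p_star`` and carries the
    initial infections ``I_star``.  The vaccine blocks infection with
    multiplier ``chi_eff`` and transmission with ``rho_eff``
    (``beta2 = chi beta1``, ``beta3 = rho beta1``, ``beta4 = chi rho beta1``).
    Doses arrive at unit rate up to a total of 1 (enough for group 2 only).
    """
    if not 0 < epsilon <= 1:
        raise ValueError("epsilon must lie in (0, 1]")
    if not 0 <= I_star <= 1:
        raise ValueError("I_star must lie in [0, 1]")
    if not (0 <= chi_eff <= 1 and 0 <= rho_eff <= 1):
        raise ValueError("effectiveness multipliers must lie in [0, 1]")
    if p_star < 0:
        raise ValueError("p_star must be non-negative")
    b1 = TWO_GROUP_BETA1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")    # total population is 1 + eps by design
        params = EpidemicParameters(
            n=2,
            beta1=b1, beta2=chi_eff * b1, beta3=rho_eff * b1,
            beta4=chi_eff * rho_eff * b1,
            mu1=[1.0, 1.0], mu2=[1.0, 1.0],
            N=[epsilon, 1.0],
            p=[1.0 / epsilon, p_star],
            kappa=[1.0, 1.0],
            S0=[epsilon, 1.0 - I_star],
            I0=[0.0, I_star],
        )
    # supply at unit rate, capped at a total of 1 (group 2's size)
    schedule = SupplySchedule.rate_limited(rate=1.0, total_supply=1.0)
    pol_u = prioritized_policy([1, 0], schedule, params,
                               per_group_caps=[epsilon, 1.0])
    pol_t = prioritized_policy([0, 1], schedule, params,
                               per_group_caps=[epsilon, 1.0])
    return TwoGroupExample(epsilon, I_star, p_star, chi_eff, rho_eff,
                           params, schedule, pol_u, pol_t)


@dataclass
class CrossoverResult:
    """Crossover diagnostic eps*: the infimum of the set of group-1 sizes at
    which the infectious-first policy beats the vulnerable-first one, capped
    at 1 when the set is empty on (0, 1]."""

    epsilon_star: float
    grid: np.ndarray = field(repr=False)
    H_infectious_first: np.ndarray = field(repr=False)
    H_vulnerable_first: np.ndarray = field(repr=False)
    capped: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epsilon": self.grid,
            "H_infectious_first": self.H_infectious_first,
            "H_vulnerable_first": self.H_vulnerable_first,
        })


def epsilon_star(I_star: float = 0.01, p_star: float = 1.0,
                 chi_eff: float = 0.5, rho_eff: float = 0.5,
                 grid: np.ndarray | None = None,
                 n_grid: int = 25, bisect_steps: int = 20,
                 **sim_kwargs) -> CrossoverResult:
    """Locate the crossover size eps* of the two-group example.

    Simulates both policies over a log-spaced grid of ``epsilon`` on
    [1e-3, 1], then bisects the smallest bracketing interval where
    ``H(tilde U) - H(U)`` changes sign.  If the vulnerable-first policy wins
    at every grid point the diagnostic is capped at 1.
    """
    if grid is None:
        grid = np.logspace(-3, 0, n_grid)
    grid = np.asarray(grid, dtype=float)

    def diff(eps: float) -> tuple[float, float, float]:
        ex = two_group_example(eps, I_star, p_star, chi_eff, rho_eff)
        h_u, h_t = ex.objectives(**sim_kwargs)
        return h_t - h_u, h_u, h_t

    d = np.empty_like(grid)
    h_us = np.empty_like(grid)
    h_ts = np.empty_like(grid)
    for k, eps in enumerate(grid):
        d[k], h_us[k], h_ts[k] = diff(eps)

    positive = np.nonzero(d > 0)[0]
    if positive.size == 0:
        return CrossoverResult(1.0, grid, h_us, h_ts, capped=True)
    k = int(positive[0])
    if k == 0:
        return CrossoverResult(float(grid[0]), grid, h_us, h_ts, capped=False)
    lo, hi = float(grid[k - 1]), float(grid[k])
    for _ in range(bisect_steps):
        mid = np.sqrt(lo * hi)       # bisect in log space, matching the grid
        if diff(mid)[0] > 0:
            hi = mid
        else:
            lo = mid
    return CrossoverResult(hi, grid, h_us, h_ts, capped=False)


def homogeneous_example(beta: float, epsilon: float
                        ) -> tuple[EpidemicParameters, SupplySchedule]:
    """One-group model with unit size/recovery/weight and supply ``epsilon``.

    The vaccine halves both infection and transmission:
    ``beta2 = beta3 = beta / 2``, ``beta4 = beta / 4``.  Since ``mu = 1``,
    ``beta`` equals the initial reproduction number (up to ``S(0) ~ 1``).
    All ``epsilon`` doses are available immediately at unit rate cap.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not 0 <= epsilon <= 1:
        raise ValueError("epsilon must lie in [0, 1]")
    params = EpidemicParameters(
        n=1,
        beta1=[[beta]], beta2=[[0.5 * beta]], beta3=[[0.5 * beta]],
        beta4=[[0.25 * beta]],
        mu1=[1.0], mu2=[1.0], N=[1.0], p=[1.0], kappa=[1.0],
        S0=[1.0 - 1e-4], I0=[1e-4],
    )
    schedule = SupplySchedule.constant(rate=1.0, supply=epsilon)
    return params, schedule


# ---------------------------------------------------------------------------
# synthetic age-structured fixture


def synthetic_contact_fixture(n_groups: int = 8, assortativity: float = 0.6,
                              elderly_contact_decay: float = 0.5,
                              seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic synthetic contact matrix and population vector.

    Emulates survey-derived age-contact data: strongly assortative mixing
    (within-group contacts dominate, controlled by ``assortativity``) and a
    per-capita contact budget that falls off linearly across groups by a
    factor ``elderly_contact_decay`` from youngest to oldest.  Reciprocity
    ``N_i Lambda_ij = N_j Lambda_ji`` (total contacts balance) is enforced
    by symmetric Sinkhorn scaling of a jittered kernel.  Returns
    ``(Lambda, N)`` with ``Lambda_ij`` the per-capita contacts of a group-i
    member with group ``j`` and ``N`` summing to 1.
    """
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if not (0 <= assortativity <= 1 and 0 <= elderly_contact_decay <= 1):
        raise ValueError("assortativity and decay must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_groups)
    # population: mildly declining with age plus seeded jitter
    N = (1.0 - 0.3 * idx / (n_groups - 1)) * (1.0 + 0.05 * rng.uniform(-1, 1, n_groups))
    N = N / N.sum()
    # per-capita contact budget, strictly decreasing when decay > 0
    budget = 12.0 * (1.0 - elderly_contact_decay * idx / (n_groups - 1))
    if assortativity >= 1.0:
        Lam = np.diag(budget)
        return Lam, N
    # kernel: off-diagonal mass decays with age distance, jittered, symmetric
    dist = np.abs(idx[:, None] - idx[None, :])
    K = (1.0 - assortativity) * np.exp(-dist / max(n_groups / 3.0, 1.0))
    jitter = rng.uniform(0.9, 1.1, (n_groups, n_groups))
    K = K * (jitter + jitter.T) / 2.0
    np.fill_diagonal(K, np.diagonal(K) + assortativity * n_groups / 2.0)
    # symmetric Sinkhorn: T = diag(d) K diag(d) with row sums N_j * budget_j
    r = N * budget
    dvec = np.sqrt(r / K.sum(axis=1))
    for _ in range(200):
        dvec = np.sqrt(r / (K @ dvec) / dvec) * dvec
        if np.max(np.abs(dvec[:, None] * (K @ dvec) - r)) < 1e-13:
            break
    T = dvec[:, None] * K * dvec[None, :]
    Lam = T / N[:, None]
    return Lam, N


def write_fixture_csv(contact_path, population_path, Lam: np.ndarray,
                      N: np.ndarray, labels=None) -> None:
    """Write a contact matrix and population vector as labelled CSVs."""
    n = len(N)
    if labels is None:
        labels = [f"group_{i + 1}" for i in range(n)]
    pd.DataFrame(Lam, index=labels, columns=labels).to_csv(contact_path)
    pd.Series(N, index=labels, name="population").to_csv(population_path)


def load_contact_csv(contact_path, population_path) -> tuple[np.ndarray, np.ndarray, list]:
    """Read the CSV layout of :func:`write_fixture_csv` (first row/column
    are labels).  Real survey data in the same layout loads identically."""
    cm = pd.read_csv(contact_path, index_col=0)
    pop = pd.read_csv(population_path, index_col=0).iloc[:, 0]
    if cm.shape[0] != cm.shape[1] or cm.shape[0] != len(pop):
        raise ValueError("contact matrix must be square and match the "
                         "population vector length")
    return cm.to_numpy(dtype=float), pop.to_numpy(dtype=float), list(cm.index)


def age_structured_example(
    contact_matrix,
    population,
    cfr,
    target_R0: float = 4.0,
    kappa_scalar: float = 0.1,
    initial_infected: float = 1e-4,
) -> tuple[EpidemicParameters, SmallSupplyLinearization, pd.DataFrame]:
    """Calibrated age-structured model plus its knapsack gradient report.

    The contact matrix is scaled so the next-generation matrix has spectral
    radius ``target_R0``; the vaccinated tiers halve infection and
    transmission; ``cfr`` supplies the infection-cost weights, reduced by
    ``kappa_scalar`` for vaccinated cases.  Every group starts with an
    infected fraction ``initial_infected`` of its size.  Returns the
    parameters, the linearization and a per-group report with ``y`` and the
    effectiveness proportions ``y_i / min_j y_j``.
    """
    Lam = np.atleast_2d(np.asarray(contact_matrix, dtype=float))
    N = np.atleast_1d(np.asarray(population, dtype=float))
    cfr = np.atleast_1d(np.asarray(cfr, dtype=float))
    n = len(N)
    if Lam.shape != (n, n) or len(cfr) != n:
        raise ValueError("contact matrix, population and cfr dimensions "
                         "must agree")
    if np.any(cfr < 0):
        raise ValueError("case fatality ratios must be non-negative")
    mu1 = np.ones(n)
    _, patch = calibrate_beta(Lam, N, mu1, target_R0, tiered=True)
    params = EpidemicParameters(
        n=n, mu1=mu1, mu2=np.ones(n), N=N, p=cfr,
        kappa=np.full(n, float(kappa_scalar)),
        S0=(1.0 - initial_infected) * N, I0=initial_infected * N,
        **patch,
    )
    lin = gradient_y(params)
    report = pd.DataFrame({
        "group": np.arange(1, n + 1),
        "y": lin.y,
        "effectiveness": lin.effectiveness_ratio,
    })
    return params, lin, report


def infected_groups(params: EpidemicParameters, policy=None,
                    threshold: float = 1e-9, **sim_kwargs) -> set[int]:
    """Groups whose unvaccinated infected compartment ever exceeds
    ``threshold`` along the simulated trajectory (0-based indices).

    This is the seeding set of the asymptotic analysis: groups outside it
    never experience an epidemic and can be dropped from the analysis.
    """
    traj: Trajectory = simulate(params, policy, **sim_kwargs)
    peaks = traj.I.max(axis=0)
    return {int(i) for i in np.nonzero(peaks > threshold)[0]}
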