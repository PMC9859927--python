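"""Small-supply linearization of the final-size objective (knapsack policy).

For a vanishing vaccine supply ``eps`` the weighted final-size objective is
linear in the administered doses,

    H(U) = H(0) + y . W + o(eps),

where the per-dose marginal cost ``y`` follows from implicit
differentiation of the stacked final-size relation.  With
``E_i = sum_k (beta'_ik / mu'_k) (R_k(inf;0) - R_k(0))`` the baseline
exponents and ``S_i(inf) = S_i(0) e^{-E_i}`` the baseline terminal
susceptibles, define

    Q_ij = [ delta_ij - S_i(inf) beta'_ij / mu'_j ] / (1 - e^{-E_i}),

solve ``Q^T x = p'`` and set ``y_i = (S_i(0)/N_i) (x_{i+n} - x_i)``.
All supply then goes to the group minimising ``y`` (a knapsack with one
item chosen), administered at the maximal rate ``A(t)`` until exhausted.

The next-generation matrix ``R_ij = N_i beta1_ij / mu1_j`` and its spectral
radius (the population R0) are provided for calibrating a transmission
matrix built from contact-survey data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .final_size import (FinalSizeSolution, StackedSystem, solve_final_size,
                         stack_parameters)
from .model import EpidemicParameters
from .policies import SupplySchedule, VaccinationPolicy

__all__ = [
    "SmallSupplyLinearization",
    "NextGenerationSummary",
    "BaselineSingularityError",
    "build_Q",
    "gradient_y",
    "leading_order_objective",
    "optimal_small_supply_policy",
    "next_generation_matrix",
    "calibrate_beta",
]


class BaselineSingularityError(RuntimeError):
    """A stacked group receives no infectious force at baseline, so the
    linearization matrix Q is singular."""


@dataclass
class SmallSupplyLinearization:
    Q: np.ndarray            # (2n, 2n)
    x: np.ndarray            # (2n,)
    y: np.ndarray            # (n,) per-dose marginal cost
    H0: float                # baseline objective H(0)
    best_group: int          # argmin of y (0-based, lowest index on ties)
    unique_min: bool
    system: StackedSystem
    baseline: FinalSizeSolution

    @property
    def effectiveness_ratio(self) -> np.ndarray:
        """y_i / min_j y_j -- 'proportion of effectiveness' of each group
        (meaningful when every y_i <= 0)."""
        return self.y / self.y.min()


def build_Q(system: StackedSystem, baseline: FinalSizeSolution,
            singular_tol: float = 1e-12) -> np.ndarray:
    """Linearization matrix Q of the stacked final-size relation.

    Requires every stacked group to receive positive infectious force at
    baseline (E_i > 0); otherwise 1 - e^{-E_i} vanishes and Q is singular,
    which is reported with the offending group named.
    """
    C = system.contact_ratio
    E = C @ (baseline.R_inf - system.R0)
    bad = np.nonzero(E < singular_tol)[0]
    if bad.size:
        i = int(bad[0])
        n = system.n
        label = (f"group {i + 1} (unvaccinated slot)" if i < n
                 else f"group {i - n + 1} (vaccinated slot)")
        raise BaselineSingularityError(
            f"{label} receives no infectious force at baseline "
            f"(E = {E[i]:.3g}); Q is singular")
    S_inf = system.S0 * np.exp(-E)
    m = 2 * system.n
    M = np.eye(m) - S_inf[:, None] * C
    return M / (1.0 - np.exp(-E))[:, None]


def gradient_y(params: EpidemicParameters) -> SmallSupplyLinearization:
    """Per-dose marginal cost of vaccinating each group, at zero supply.

    Solves the baseline (unvaccinated) final size, builds Q, solves the
    transposed linear system ``Q^T x = p'`` and assembles
    ``y_i = (S_i(0)/N_i)(x_{i+n} - x_i)``.  A weakly protective vaccine
    should give ``y <= 0``; a positive component triggers a warning (it
    would indicate a harmful allocation, not an error of the method).
    """
    system = stack_parameters(params)
    baseline = solve_final_size(system)
    Q = build_Q(system, baseline)
    try:
        x = np.linalg.solve(Q.T, system.p_prime)
    except np.linalg.LinAlgError as exc:
        raise BaselineSingularityError(
            "linearization matrix Q is numerically singular") from exc
    n = params.n
    y = system.S0[:n] / params.N * (x[n:] - x[:n])
    H0 = float(np.sum(system.p_prime * (baseline.R_inf - system.R0)))
    y_min = y.min()
    best = int(np.argmin(y))
    unique = int(np.sum(np.isclose(y, y_min, rtol=1e-9, atol=1e-12))) == 1
    if not unique:
        warnings.warn("minimum of y is not unique; ties broken by lowest "
                      "group index", stacklevel=2)
    if np.any(y > 1e-10):
        warnings.warn("some y_i > 0: vaccinating that group would increase "
                      "the objective", stacklevel=2)
    return SmallSupplyLinearization(
        Q=Q, x=x, y=y, H0=H0, best_group=best, unique_min=unique,
        system=system, baseline=baseline)


def leading_order_objective(lin: SmallSupplyLinearization, W_final) -> float:
    """Leading-order prediction H(0) + y . W for final dose counts W."""
    W = np.atleast_1d(np.asarray(W_final, dtype=float))
    return float(lin.H0 + lin.y @ W)


def optimal_small_supply_policy(
    lin: SmallSupplyLinearization,
    schedule: SupplySchedule,
    epsilon: float,
) -> tuple[VaccinationPolicy, int]:
    """All-supply-to-argmin(y) bang-bang policy for a supply of ``epsilon``.

    The chosen group is vaccinated at the full rate cap ``A(t)`` until
    ``int_0^t A = epsilon`` (the exhaustion time ``tau(epsilon)``).
    Requires ``A(0) > 0`` and ``epsilon`` at most the chosen group's size.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    n = lin.system.n
    if float(schedule.A(0.0)) <= 0:
        raise ValueError("schedule must have A(0) > 0")
    group = lin.best_group
    if epsilon > lin.system.N[group] + 1e-12:
        candidates = np.nonzero(lin.system.N >= epsilon - 1e-12)[0]
        if candidates.size == 0:
            raise ValueError(
                f"supply epsilon = {epsilon} exceeds every group size")
        order = candidates[np.argsort(lin.y[candidates], kind="stable")]
        group = int(order[0])
    if epsilon == 0:
        return VaccinationPolicy.zero(n), group
    # invert int_A to find tau(epsilon)
    from scipy.optimize import brentq
    hi = 1.0
    while schedule.int_A(hi) < epsilon:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("rate cap A never delivers the requested supply")
    tau = brentq(lambda t: float(schedule.int_A(t)) - epsilon, 0.0, hi,
                 xtol=1e-14, rtol=1e-15)
    segs = [t for t in schedule.a_times if 0.0 < t < tau]
    bp = np.asarray([0.0, *segs, tau])
    rates = np.zeros((len(bp) - 1, n))
    for k, (t0, t1) in enumerate(zip(bp[:-1], bp[1:])):
        rates[k, group] = float(schedule.A(0.5 * (t0 + t1)))
    return VaccinationPolicy(bp, rates).simplify(), group


@dataclass
class NextGenerationSummary:
    R_matrix: np.ndarray        # (n, n)
    spectral_radius: float
    total_force: np.ndarray     # (n,) column sums
    external_force: np.ndarray  # (n,) column sums minus the diagonal


def next_generation_matrix(params: EpidemicParameters) -> NextGenerationSummary:
    """Disease-free next-generation matrix R_ij = N_i beta1_ij / mu1_j.

    Its spectral radius is the population-level basic reproduction number.
    The total infectious force of group j is the j-th column sum; the
    external force excludes the within-group (diagonal) term.
    """
    R = params.N[:, None] * params.beta1 / params.mu1[None, :]
    eig = np.linalg.eigvals(R)
    rho = float(np.max(np.abs(eig)))
    total = R.sum(axis=0)
    return NextGenerationSummary(
        R_matrix=R, spectral_radius=rho,
        total_force=total, external_force=total - np.diag(R))


def calibrate_beta(
    contact_matrix,
    N,
    mu1,
    target_R0: float,
    tiered: bool = True,
    vaccinated_infection_factor: float = 0.5,
    vaccinated_transmission_factor: float = 0.5,
) -> tuple[float, dict]:
    """Scale a contact matrix to a target basic reproduction number.

    The transmission matrix is ``beta1_ij = beta * Lambda_ij / N_j`` with the
    scalar ``beta`` chosen so that the next-generation matrix
    ``N_i beta1_ij / mu1_j`` has spectral radius ``target_R0``.  With
    ``tiered=True`` the vaccinated tiers are filled in as
    ``beta2 = beta3 = f * beta1`` and ``beta4 = f_inf * f_tr * beta1``
    (default halving of infection and transmission, quartering both).

    Returns ``(beta, patch)`` where the patch maps parameter-field names to
    the calibrated matrices, ready for ``EpidemicParameters``.
    """
    Lam = np.atleast_2d(np.asarray(contact_matrix, dtype=float))
    N = np.atleast_1d(np.asarray(N, dtype=float))
    mu1 = np.atleast_1d(np.asarray(mu1, dtype=float))
    n = len(N)
    if Lam.shape != (n, n):
        raise ValueError("contact matrix must be square and match len(N)")
    if np.any(Lam < 0):
        raise ValueError("contact matrix must be non-negative")
    # crude irreducibility screen: a zero row or column disconnects a group
    if np.any(Lam.sum(axis=0) == 0) or np.any(Lam.sum(axis=1) == 0):
        warnings.warn("contact matrix has an all-zero row or column "
                      "(reducible mixing)", stacklevel=2)
    unit_beta1 = Lam / N[None, :]
    ngm_unit = N[:, None] * unit_beta1 / mu1[None, :]
    rho_unit = float(np.max(np.abs(np.linalg.eigvals(ngm_unit))))
    if rho_unit <= 0:
        raise ValueError("contact matrix has zero spectral radius; "
                         "cannot calibrate")
    beta = target_R0 / rho_unit
    beta1 = beta * unit_beta1
    patch = {"beta1": beta1}
    if tiered:
        fi, ft = vaccinated_infection_factor, vaccinated_transmission_factor
        patch.update(beta2=ft * beta1, beta3=fi * beta1, beta4=fi * ft * beta1)
    return beta, patch
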