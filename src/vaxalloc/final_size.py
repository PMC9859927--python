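"""Stacked 2n-group system and the SIR final-size fixed point.

Once dosing has ceased there is no further movement between unvaccinated
and vaccinated compartments, so the model is an ordinary ``2n``-group SIR:
unvaccinated groups occupy slots ``0..n-1`` and vaccinated ones slots
``n..2n-1`` of a stacked transmission matrix

    beta' = [[beta1, beta2],
             [beta3, beta4]],

with stacked recovery rates ``mu' = (mu1, mu2)`` and infection-cost weights
``p' = (p, kappa * p)``.  The total recovered in each stacked group then
obeys the classical final-size relation

    S_i(inf) = S_i(0) * exp(-sum_k (beta'_ik / mu'_k) (R_k(inf) - R_k(0))),
    R_i(inf) = S_i(0) + I_i(0) + R_i(0) - S_i(inf),

solved here by fixed-point iteration started from the attack-size-maximal
side (S = 0), which converges to the root realised by the ODE dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import EpidemicParameters

__all__ = ["StackedSystem", "FinalSizeSolution", "FinalSizeError",
           "stack_parameters", "solve_final_size"]


class FinalSizeError(RuntimeError):
    """Raised when the final-size iteration fails to converge."""

    def __init__(self, message: str, last_iterate: np.ndarray | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class StackedSystem:
    """2n-group SIR system: vaccinated compartments as standalone groups."""

    n: int
    beta_prime: np.ndarray   # (2n, 2n)
    mu_prime: np.ndarray     # (2n,)
    p_prime: np.ndarray      # (2n,)
    S0: np.ndarray           # (2n,)
    I0: np.ndarray           # (2n,)
    R0: np.ndarray           # (2n,)
    N: np.ndarray            # (n,) original group sizes

    @property
    def contact_ratio(self) -> np.ndarray:
        """Matrix beta'_ik / mu'_k appearing in the final-size exponent."""
        return self.beta_prime / self.mu_prime[None, :]


@dataclass
class FinalSizeSolution:
    R_inf: np.ndarray
    residual: float
    iterations: int

    def S_inf(self, system: StackedSystem) -> np.ndarray:
        return system.S0 + system.I0 + system.R0 - self.R_inf


def stack_parameters(params: EpidemicParameters,
                     W_final=None) -> StackedSystem:
    """Build the stacked system after ``W_final`` doses per group.

    Doses land on susceptibles with probability ``S0_i / N_i`` (random
    allocation among the initially unvaccinated), so
    ``W_final * S0 / N`` susceptibles move from the unvaccinated to the
    vaccinated slot.  ``W_final = None`` (or zeros) gives the baseline
    system used by the small-supply linearization.
    """
    n = params.n
    if W_final is None:
        doses = np.zeros(n)
    else:
        doses = np.atleast_1d(np.asarray(W_final, dtype=float))
        if np.any(doses < 0) or np.any(doses > params.N + 1e-12):
            raise ValueError("W_final must lie in [0, N] elementwise")
    moved = doses * params.S0 / params.N
    beta_prime = np.block([[params.beta1, params.beta2],
                           [params.beta3, params.beta4]])
    return StackedSystem(
        n=n,
        beta_prime=beta_prime,
        mu_prime=np.concatenate([params.mu1, params.mu2]),
        p_prime=np.concatenate([params.p, params.kappa * params.p]),
        S0=np.concatenate([params.S0 - moved, params.SV0 + moved]),
        I0=np.concatenate([params.I0, params.IV0]),
        R0=np.concatenate([params.R0, params.RV0]),
        N=params.N.copy(),
    )


def solve_final_size(system: StackedSystem, tol: float = 1e-13,
                     max_iter: int = 10_000) -> FinalSizeSolution:
    """Solve the final-size fixed point of a stacked system.

    Iterates ``R <- S0 + I0 + R0 - S0 exp(-C (R - R0))`` from the maximal
    attack size ``R = S0 + I0 + R0`` downwards; the map is monotone, so the
    sequence decreases to the epidemiologically relevant (largest) root.  A
    Newton polish via :func:`scipy.optimize.root` is applied if plain
    iteration stalls.
    """
    C = system.contact_ratio
    top = system.S0 + system.I0 + system.R0
    if np.all(system.I0 == 0):
        return FinalSizeSolution(R_inf=system.R0.copy(), residual=0.0, iterations=0)

    def fmap(R):
        return top - system.S0 * np.exp(-C @ (R - system.R0))

    R = top.copy()
    residual = np.inf
    for it in range(1, max_iter + 1):
        R_new = fmap(R)
        residual = float(np.max(np.abs(R_new - R)))
        R = R_new
        if residual < tol:
            return FinalSizeSolution(R_inf=R, residual=residual, iterations=it)

    from scipy.optimize import root

    sol = root(lambda r: fmap(r) - r, R, method="hybr", tol=1e-14)
    residual = float(np.max(np.abs(fmap(sol.x) - sol.x)))
    if residual > 1e-10:
        raise FinalSizeError(
            f"final-size iteration did not converge (residual {residual:.3g})",
            last_iterate=R)
    return FinalSizeSolution(R_inf=sol.x, residual=residual, iterations=max_iter)
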