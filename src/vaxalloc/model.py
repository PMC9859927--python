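"""Multi-group SIR dynamics with vaccination of the unvaccinated.

The population is split into ``n`` groups, each with six compartments:
susceptible / infected / recovered, for unvaccinated (S, I, R) and
vaccinated (SV, IV, RV) individuals.  Transmission is governed by four
``n x n`` rate matrices:

* ``beta1`` -- unvaccinated susceptibles infected by unvaccinated infecteds,
* ``beta2`` -- unvaccinated susceptibles infected by vaccinated infecteds,
* ``beta3`` -- vaccinated susceptibles infected by unvaccinated infecteds,
* ``beta4`` -- vaccinated susceptibles infected by vaccinated infecteds,

with entry ``(i, j)`` the rate of transmission *from* group ``j`` *to*
group ``i``.  Recovery rates are ``mu1`` (unvaccinated) and ``mu2``
(vaccinated).  Vaccines are administered at a per-group rate ``U_i(t)``
and are distributed at random among the not-yet-vaccinated members of the
group, so the flow of *susceptibles* into the vaccinated class is
``U_i S_i / (N_i - W_i)`` where ``W_i(t)`` is the cumulative number of
doses given to group ``i``.

The objective of a vaccination policy is the weighted count of infections

    H(U) = sum_i p_i * (R_i(inf) + kappa_i * RV_i(inf)),

reported net of initially recovered individuals so that H = 0 when no
epidemic occurs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpidemicParameters",
    "StateVector",
    "Trajectory",
    "derivative",
    "simulate",
    "objective_h",
    "FULLY_VACCINATED_RTOL",
]

#: Group i counts as fully vaccinated once N_i - W_i < FULLY_VACCINATED_RTOL * N_i;
#: its vaccination transfer rate is then clamped to zero (removable singularity).
FULLY_VACCINATED_RTOL = 1e-12


def _as_matrix(x, n: int, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}, got shape {a.shape}")
    if np.any(a < 0):
        raise ValueError(f"{name} must be non-negative")
    return a


def _as_vector(x, n: int, name: str, nonneg: bool = True) -> np.ndarray:
    a = np.atleast_1d(np.asarray(x, dtype=float))
    if a.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {a.shape}")
    if nonneg and np.any(a < 0):
        raise ValueError(f"{name} must be non-negative")
    return a


@dataclass
class EpidemicParameters:
    """All rates, sizes, weights and initial conditions for an ``n``-group model.

    Population sizes are fractions of a normalised total; a total differing
    from 1 triggers a warning only (some worked examples deliberately use a
    total of ``1 + eps``).
    """

    n: int
    beta1: np.ndarray
    beta2: np.ndarray
    beta3: np.ndarray
    beta4: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    N: np.ndarray
    p: np.ndarray
    kappa: np.ndarray
    S0: np.ndarray
    I0: np.ndarray
    R0: np.ndarray = None
    SV0: np.ndarray = None
    IV0: np.ndarray = None
    RV0: np.ndarray = None

    def __post_init__(self):
        n = int(self.n)
        if n < 1:
            raise ValueError("n must be >= 1")
        self.n = n
        for name in ("beta1", "beta2", "beta3", "beta4"):
            setattr(self, name, _as_matrix(getattr(self, name), n, name))
        for name in ("mu1", "mu2", "N", "p", "kappa", "S0", "I0"):
            setattr(self, name, _as_vector(getattr(self, name), n, name))
        for name in ("R0", "SV0", "IV0", "RV0"):
            v = getattr(self, name)
            setattr(self, name, np.zeros(n) if v is None else _as_vector(v, n, name))
        if np.any(self.mu1 <= 0) or np.any(self.mu2 <= 0):
            raise ValueError("recovery rates mu1, mu2 must be positive")
        if np.any(self.N <= 0):
            raise ValueError("group sizes N must be positive")
        # Vaccine must not be harmful: it weakly reduces infection and
        # transmission rates and weakly shortens the infectious period.
        if np.any(self.beta1 < self.beta2 - 1e-15) or np.any(self.beta3 < self.beta4 - 1e-15):
            raise ValueError("require beta1 >= beta2 and beta3 >= beta4 elementwise")
        if np.any(self.mu1 > self.mu2 + 1e-15):
            raise ValueError("require mu1 <= mu2 elementwise")
        if np.any(self.kappa > 1 + 1e-15):
            raise ValueError("vaccinated cost multipliers kappa must be <= 1")
        total = self.S0 + self.I0 + self.R0 + self.SV0 + self.IV0 + self.RV0
        if not np.allclose(total, self.N, rtol=1e-9, atol=1e-12):
            raise ValueError("initial compartments must sum to N in every group")
        if not np.isclose(self.N.sum(), 1.0, rtol=1e-9):
            warnings.warn(
                f"group sizes sum to {self.N.sum():.6g}, not 1; proceeding anyway",
                stacklevel=2,
            )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {"n": self.n}
        for name in ("beta1", "beta2", "beta3", "beta4"):
            d[name] = getattr(self, name).tolist()
        for name in ("mu1", "mu2", "N", "p", "kappa", "S0", "I0", "R0", "SV0", "IV0", "RV0"):
            d[name] = getattr(self, name).tolist()
        return d

    def to_json(self, path=None, **kwargs) -> str:
        s = json.dumps(self.to_dict(), **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "EpidemicParameters":
        return cls(**d)

    @classmethod
    def from_json(cls, source) -> "EpidemicParameters":
        try:
            d = json.loads(source)
        except (ValueError, TypeError):
            with open(source) as fh:
                d = json.load(fh)
        return cls.from_dict(d)

    def copy_with(self, **changes) -> "EpidemicParameters":
        return replace(self, **changes)


@dataclass
class StateVector:
    """Compartment values of all groups at a single time."""

    t: float
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    SV: np.ndarray
    IV: np.ndarray
    RV: np.ndarray

    @property
    def total_infected(self) -> float:
        return float(self.I.sum() + self.IV.sum())

    def group_totals(self) -> np.ndarray:
        return self.S + self.I + self.R + self.SV + self.IV + self.RV


def _pack(S, I, R, SV, IV, RV) -> np.ndarray:
    return np.concatenate([S, I, R, SV, IV, RV])


def _unpack(y: np.ndarray, n: int):
    return tuple(y[k * n:(k + 1) * n] for k in range(6))


@dataclass
class Trajectory:
    """Solver output: times and the six compartment blocks, each ``(m, n)``."""

    t: np.ndarray
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    SV: np.ndarray
    IV: np.ndarray
    RV: np.ndarray
    converged: bool
    params: EpidemicParameters = field(repr=False)

    @property
    def terminal_state(self) -> StateVector:
        return self.state_at(-1)

    def state_at(self, idx: int) -> StateVector:
        return StateVector(
            t=float(self.t[idx]),
            S=self.S[idx], I=self.I[idx], R=self.R[idx],
            SV=self.SV[idx], IV=self.IV[idx], RV=self.RV[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        n = self.params.n
        data = {"t": self.t}
        for name in ("S", "I", "R", "SV", "IV", "RV"):
            block = getattr(self, name)
            for i in range(n):
                data[f"{name}_{i + 1}"] = block[:, i]
        return pd.DataFrame(data)

    def to_csv(self, path, **kwargs) -> None:
        self.to_frame().to_csv(path, index=False, **kwargs)


def derivative(
    state: StateVector,
    params: EpidemicParameters,
    u: Sequence[float],
    w: Sequence[float],
) -> np.ndarray:
    """Time derivative of the packed state ``(S, I, R, SV, IV, RV)``.

    ``u`` is the instantaneous per-group vaccination rate and ``w`` the
    cumulative doses already administered.  The vaccination transfer is
    ``u_i S_i / (N_i - w_i)``, clamped to zero for fully vaccinated groups.
    """
    u = _as_vector(u, params.n, "u")
    w = np.atleast_1d(np.asarray(w, dtype=float))
    if np.any(w > params.N + 1e-9):
        raise ValueError("cumulative doses w may not exceed group sizes N")
    y = _pack(state.S, state.I, state.R, state.SV, state.IV, state.RV)
    return _rhs(y, params, u, w)


def _rhs(y: np.ndarray, params: EpidemicParameters, u: np.ndarray, w: np.ndarray) -> np.ndarray:
    n = params.n
    S, I, R, SV, IV, RV = _unpack(y, n)
    lam_u = params.beta1 @ I + params.beta2 @ IV   # force on unvaccinated
    lam_v = params.beta3 @ I + params.beta4 @ IV   # force on vaccinated
    headroom = params.N - w
    # Removable singularity: once a group is fully vaccinated the transfer is 0.
    with np.errstate(divide="ignore", invalid="ignore"):
        vacc = np.where(
            headroom > FULLY_VACCINATED_RTOL * params.N,
            u * S / headroom,
            0.0,
        )
    new_inf_u = lam_u * S
    new_inf_v = lam_v * SV
    rec_u = params.mu1 * I
    rec_v = params.mu2 * IV
    return _pack(
        -new_inf_u - vacc,
        new_inf_u - rec_u,
        rec_u,
        -new_inf_v + vacc,
        new_inf_v - rec_v,
        rec_v,
    )


def simulate(
    params: EpidemicParameters,
    policy=None,
    infection_threshold: float = 1e-10,
    t_max: float | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model under a (possibly zero) vaccination policy.

    Integration restarts at every policy breakpoint so the piecewise-constant
    rates are seen exactly.  After the policy's support ends, integration
    stops as soon as the total infected mass drops below
    ``infection_threshold`` (an event of the solver), or at ``t_max``;
    ``converged`` records which happened.  The default horizon is 200 mean
    infectious periods of the slowest-recovering compartment.
    """
    from scipy.integrate import solve_ivp

    from .policies import VaccinationPolicy

    n = params.n
    if policy is None:
        policy = VaccinationPolicy.zero(n)
    if t_max is None:
        t_max = 200.0 / min(params.mu1.min(), params.mu2.min())

    y0 = _pack(params.S0, params.I0, params.R0, params.SV0, params.IV0, params.RV0)
    seg_edges = [float(b) for b in policy.breakpoints if 0.0 < b < t_max]
    seg_edges = sorted(set(seg_edges)) + [t_max]

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    t0, y = 0.0, y0
    converged = False
    support_end = policy.support_end

    for t1 in seg_edges:
        u = policy.rate_at(0.5 * (t0 + t1))
        w0 = policy.cumulative(t0)

        def rhs(t, yv, u=u, w0=w0, t0=t0):
            return _rhs(yv, params, u, w0 + u * (t - t0))

        in_tail = t0 >= support_end - 1e-12
        events = None
        if in_tail:
            def extinction(t, yv, n=n):
                return yv[n:2 * n].sum() + yv[4 * n:5 * n].sum() - infection_threshold
            extinction.terminal = True
            extinction.direction = -1
            events = extinction
            if y[n:2 * n].sum() + y[4 * n:5 * n].sum() < infection_threshold:
                converged = True
                break
        sol = solve_ivp(
            rhs, (t0, t1), y, method=method, rtol=rtol, atol=atol,
            events=events, dense_output=False,
        )
        if not sol.success:  # pragma: no cover - solver failure is exceptional
            raise RuntimeError(f"ODE solver failed on [{t0}, {t1}]: {sol.message}")
        ts.append(sol.t)
        ys.append(sol.y.T)
        y = sol.y[:, -1]
        t0 = sol.t[-1]
        if in_tail and sol.t_events is not None and len(sol.t_events[0]) > 0:
            converged = True
            break

    if not ts:  # policy-free model already extinct at t=0
        ts.append(np.array([0.0]))
        ys.append(y0[None, :])
    if not converged:
        total_inf = y[n:2 * n].sum() + y[4 * n:5 * n].sum()
        converged = total_inf < infection_threshold

    t_all = np.concatenate(ts)
    y_all = np.vstack(ys)
    # drop duplicated segment-junction points
    keep = np.concatenate([[True], np.diff(t_all) > 0])
    t_all, y_all = t_all[keep], y_all[keep]
    blocks = [y_all[:, k * n:(k + 1) * n] for k in range(6)]
    return Trajectory(t_all, *blocks, converged=converged, params=params)


def objective_h(trajectory: Trajectory, params: EpidemicParameters | None = None) -> float:
    """Weighted infection cost H of a simulated epidemic.

    H = sum_i p_i [ (R_i(inf) - R_i(0)) + kappa_i (RV_i(inf) - RV_i(0)) ],
    using terminal trajectory values for the limits.  Subtracting the initial
    recovered mass makes H = 0 for a disease-free run; all worked examples
    start with R(0) = 0, where the two conventions coincide.
    """
    if params is None:
        params = trajectory.params
    if not trajectory.converged:
        warnings.warn(
            "trajectory did not reach the extinction threshold; "
            "H is evaluated at the final time", stacklevel=2,
        )
    dR = trajectory.R[-1] - params.R0
    dRV = trajectory.RV[-1] - params.RV0
    return float(np.sum(params.p * (dR + params.kappa * dRV)))
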