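"""Vaccination policies and supply schedules.

A policy assigns each group a piecewise-constant vaccination rate
``U_i(t)`` with finite support; its cumulative dose count
``W_i(t) = int_0^t U_i`` is piecewise linear and available in closed form.
A supply schedule constrains feasible policies through a maximal
instantaneous rate ``A(t)`` and a maximal cumulative supply ``B(t)``:

    sum_i U_i(t) <= A(t)   and   sum_i W_i(t) <= B(t).

The fastest admissible total rate is

    chi(t) = A(t)                 while int_0^t A < B(t),
           = min(A(t), B'(t+))    otherwise,

and any supply-exhausting prioritised (bang-bang) policy distributes chi(t)
to one group at a time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SupplySchedule",
    "VaccinationPolicy",
    "VulnerableScenario",
    "chi_rate",
    "cumulative",
    "is_feasible",
    "build_tilde_policy",
    "prioritized_policy",
]

_EPS = 1e-12


@dataclass
class SupplySchedule:
    """Rate cap A(t) (piecewise constant) and supply cap B(t) (piecewise linear).

    ``A`` is given by right-continuous steps at ``a_times`` (first entry 0)
    holding its last value forever.  ``B`` interpolates linearly through
    ``(b_times, b_values)`` and continues beyond the last knot with slope
    ``b_final_slope``.  ``B`` must be non-decreasing.
    """

    a_times: np.ndarray
    a_values: np.ndarray
    b_times: np.ndarray
    b_values: np.ndarray
    b_final_slope: float = 0.0

    def __post_init__(self):
        self.a_times = np.atleast_1d(np.asarray(self.a_times, dtype=float))
        self.a_values = np.atleast_1d(np.asarray(self.a_values, dtype=float))
        self.b_times = np.atleast_1d(np.asarray(self.b_times, dtype=float))
        self.b_values = np.atleast_1d(np.asarray(self.b_values, dtype=float))
        if self.a_times[0] != 0.0 or self.b_times[0] != 0.0:
            raise ValueError("schedules must start at t=0")
        if np.any(np.diff(self.a_times) <= 0) or np.any(np.diff(self.b_times) <= 0):
            raise ValueError("schedule times must be strictly increasing")
        if np.any(self.a_values < 0):
            raise ValueError("rate cap A must be non-negative")
        if np.any(np.diff(self.b_values) < -_EPS) or self.b_final_slope < 0:
            raise ValueError("supply cap B must be non-decreasing")

    # -- convenience constructors ----------------------------------------
    @classmethod
    def constant(cls, rate: float, supply: float) -> "SupplySchedule":
        """A(t) = rate, B(t) = supply (all doses available immediately)."""
        return cls([0.0], [rate], [0.0], [supply], 0.0)

    @classmethod
    def rate_limited(cls, rate: float, total_supply: float) -> "SupplySchedule":
        """A(t) = rate with supply arriving at the same rate up to a total:
        B(t) = min(rate * t, total_supply)."""
        t_full = total_supply / rate
        return cls([0.0], [rate], [0.0, t_full], [0.0, total_supply], 0.0)

    # -- evaluation --------------------------------------------------------
    def A(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.a_times, t, side="right") - 1, 0, None)
        return self.a_values[idx]

    def int_A(self, t):
        """Exact integral of the step function A over [0, t]."""
        t = np.asarray(t, dtype=float)
        edges = self.a_times
        widths = np.diff(np.append(edges, np.inf))
        cum = np.concatenate([[0.0], np.cumsum(self.a_values[:-1] * widths[:-1])]) \
            if len(edges) > 1 else np.array([0.0])
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, None)
        return cum[idx] + self.a_values[idx] * (t - edges[idx])

    def B(self, t):
        t = np.asarray(t, dtype=float)
        tail = self.b_values[-1] + self.b_final_slope * (t - self.b_times[-1])
        interp = np.interp(t, self.b_times, self.b_values)
        return np.where(t > self.b_times[-1], tail, interp)

    def B_prime_right(self, t) -> np.ndarray:
        """One-sided (right) derivative of B; the right slope is used at kinks."""
        t = np.asarray(t, dtype=float)
        if len(self.b_times) == 1:
            return np.full_like(t, self.b_final_slope, dtype=float)
        slopes = np.diff(self.b_values) / np.diff(self.b_times)
        slopes = np.append(slopes, self.b_final_slope)
        idx = np.clip(np.searchsorted(self.b_times, t, side="right") - 1, 0, None)
        return slopes[idx]

    def chi(self, t):
        """Maximal administrable total vaccination rate at time t."""
        t = np.asarray(t, dtype=float)
        unexhausted = self.int_A(t) < self.B(t) - _EPS
        return np.where(unexhausted, self.A(t), np.minimum(self.A(t), self.B_prime_right(t)))

    def chi_segments(self, horizon: float) -> list[tuple[float, float, float]]:
        """Piecewise-constant segments ``(t0, t1, chi)`` of chi on [0, horizon].

        Within each interval between schedule knots A is constant and
        ``int_A - B`` is linear, so chi changes at most once (at the crossing
        of supply exhaustion), which is solved in closed form.
        """
        knots = sorted({0.0, horizon, *self.a_times[self.a_times < horizon],
                        *self.b_times[self.b_times < horizon]})
        refined = []
        for t0, t1 in zip(knots[:-1], knots[1:]):
            g0 = float(self.int_A(t0) - self.B(t0))
            g1 = float(self.int_A(t1) - self.B(np.nextafter(t1, t0)))
            refined.append(t0)
            if (g0 < -_EPS) != (g1 < -_EPS) and abs(g1 - g0) > _EPS:
                tc = t0 + (0.0 - g0) / (g1 - g0) * (t1 - t0)
                if t0 + _EPS < tc < t1 - _EPS:
                    refined.append(tc)
        refined.append(horizon)
        segs = []
        for t0, t1 in zip(refined[:-1], refined[1:]):
            tm = 0.5 * (t0 + t1)
            segs.append((t0, t1, float(self.chi(tm))))
        return segs

    def int_chi(self, t: float) -> float:
        total = 0.0
        for t0, t1, c in self.chi_segments(max(float(t), _EPS)):
            total += c * (min(t1, float(t)) - t0)
            if t1 >= t:
                break
        return total

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "a_times": self.a_times.tolist(),
            "a_values": self.a_values.tolist(),
            "b_times": self.b_times.tolist(),
            "b_values": self.b_values.tolist(),
            "b_final_slope": self.b_final_slope,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SupplySchedule":
        return cls(**d)


@dataclass
class VaccinationPolicy:
    """Piecewise-constant per-group vaccination rates.

    ``breakpoints`` has length ``m + 1`` (starting at 0) and ``rates`` has
    shape ``(m, n)``: row ``k`` applies on ``[breakpoints[k], breakpoints[k+1])``.
    All rates are zero beyond the last breakpoint.
    """

    breakpoints: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        self.breakpoints = np.atleast_1d(np.asarray(self.breakpoints, dtype=float))
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if self.breakpoints[0] != 0.0:
            raise ValueError("breakpoints must start at 0")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if self.rates.shape[0] != len(self.breakpoints) - 1:
            raise ValueError("need one rate vector per breakpoint interval")
        if np.any(self.rates < 0):
            raise ValueError("vaccination rates must be non-negative")

    @classmethod
    def zero(cls, n: int) -> "VaccinationPolicy":
        return cls([0.0, 1.0], np.zeros((1, n)))

    @property
    def n(self) -> int:
        return self.rates.shape[1]

    @property
    def support_end(self) -> float:
        """Last time any group has a positive rate (0 for the zero policy)."""
        active = np.any(self.rates > 0, axis=1)
        if not active.any():
            return 0.0
        return float(self.breakpoints[1:][active][-1])

    def rate_at(self, t) -> np.ndarray:
        t = float(t)
        if t < 0 or t >= self.breakpoints[-1]:
            return np.zeros(self.n)
        k = int(np.searchsorted(self.breakpoints, t, side="right") - 1)
        return self.rates[k]

    def cumulative(self, t) -> np.ndarray:
        """W(t): exact piecewise-linear integral of the rates; shape (n,)
        for scalar t, (len(t), n) for array t."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        widths = np.diff(self.breakpoints)
        cum = np.vstack([np.zeros(self.n), np.cumsum(self.rates * widths[:, None], axis=0)])
        idx = np.clip(np.searchsorted(self.breakpoints, t_arr, side="right") - 1,
                      0, len(self.breakpoints) - 2)
        frac = np.clip(t_arr - self.breakpoints[idx], 0.0,
                       widths[idx])
        out = cum[idx] + self.rates[idx] * frac[:, None]
        out[t_arr <= 0] = 0.0
        return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out

    def total_rate(self) -> np.ndarray:
        return self.rates.sum(axis=1)

    def simplify(self) -> "VaccinationPolicy":
        """Merge adjacent intervals with identical rates, drop trailing zeros."""
        bp = [self.breakpoints[0]]
        rates = []
        for k in range(self.rates.shape[0]):
            if rates and np.array_equal(rates[-1], self.rates[k]):
                bp[-1] = self.breakpoints[k + 1]
            else:
                rates.append(self.rates[k].copy())
                bp.append(self.breakpoints[k + 1])
        while len(rates) > 1 and not np.any(rates[-1] > 0):
            rates.pop()
            bp.pop()
        return VaccinationPolicy(np.asarray(bp), np.asarray(rates))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {"breakpoints": self.breakpoints.tolist(), "rates": self.rates.tolist()}

    def to_json(self, path=None, **kwargs) -> str:
        s = json.dumps(self.to_dict(), **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "VaccinationPolicy":
        return cls(d["breakpoints"], d["rates"])

    @classmethod
    def from_json(cls, source) -> "VaccinationPolicy":
        try:
            d = json.loads(source)
        except (ValueError, TypeError):
            with open(source) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


@dataclass
class VulnerableScenario:
    """Constants of the small-vulnerable-group asymptotics.

    ``epsilon`` is the vulnerable group's size, ``sigma`` its initially
    susceptible fraction; ``alpha``, ``tau`` and ``w`` witness that a policy
    does *not* vaccinate the vulnerable group first: by the checkpoint time
    ``tau``, less than ``alpha * epsilon`` doses have reached group 1 while
    more than ``w`` doses have been given in total.
    """

    epsilon: float
    sigma: float = 1.0
    alpha: float = 0.5
    tau: float = 1.0
    w: float = 0.1

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if not 0 < self.sigma <= 1:
            raise ValueError("sigma must lie in (0, 1]")

    def condition_holds(self, policy: VaccinationPolicy) -> bool:
        """Check W_1(tau) < alpha * epsilon and sum_i W_i(tau) > w."""
        W = policy.cumulative(self.tau)
        return bool(W[0] < self.alpha * self.epsilon and W.sum() > self.w)


# ---------------------------------------------------------------------------
# module-level operations


def chi_rate(schedule: SupplySchedule, t) -> float | np.ndarray:
    """Maximal administrable total vaccination rate at time(s) t."""
    out = schedule.chi(t)
    return float(out) if np.ndim(t) == 0 else out


def cumulative(policy: VaccinationPolicy, t) -> np.ndarray:
    """Cumulative doses W(t) per group."""
    return policy.cumulative(t)


def is_feasible(
    policy: VaccinationPolicy,
    schedule: SupplySchedule,
    params,
    n_grid: int = 200,
    tol: float = 1e-9,
) -> tuple[bool, list[str]]:
    """Check the rate, supply, positivity and group-capacity constraints.

    Constraints are evaluated on a grid refined at every policy and schedule
    breakpoint (rates just inside each interval, cumulative quantities at the
    interval ends).  Returns ``(ok, report)`` where the report lists the
    first violated constraint and the time of violation.
    """
    report: list[str] = []
    horizon = max(policy.breakpoints[-1], schedule.a_times[-1], schedule.b_times[-1], 1.0)
    knots = np.unique(np.concatenate([
        policy.breakpoints, schedule.a_times, schedule.b_times, [horizon]]))
    grid = np.unique(np.concatenate([
        knots, np.linspace(0.0, horizon, n_grid)]))
    # rate constraint, checked just inside each interval
    for t0, t1 in zip(grid[:-1], grid[1:]):
        tm = t0 + 1e-9 * (t1 - t0)
        total_u = policy.rate_at(tm).sum()
        if total_u > schedule.A(tm) + tol:
            report.append(f"rate constraint violated at t={t0:.6g}: "
                          f"sum U = {total_u:.6g} > A = {float(schedule.A(tm)):.6g}")
            break
    # cumulative supply and per-group capacity
    if not report:
        W = policy.cumulative(grid)
        totals = W.sum(axis=1)
        Bv = schedule.B(grid)
        bad = np.nonzero(totals > Bv + tol)[0]
        if bad.size:
            k = bad[0]
            report.append(f"supply constraint violated at t={grid[k]:.6g}: "
                          f"sum W = {totals[k]:.6g} > B = {Bv[k]:.6g}")
    if not report and params is not None:
        W_end = policy.cumulative(policy.breakpoints[-1])
        over = np.nonzero(W_end > params.N + tol)[0]
        if over.size:
            i = over[0]
            report.append(f"group {i + 1} over-vaccinated: W = {W_end[i]:.6g} "
                          f"> N = {params.N[i]:.6g}")
    return (len(report) == 0), report


def build_tilde_policy(policy: VaccinationPolicy, epsilon: float,
                       group_size: float | None = None) -> VaccinationPolicy:
    """Redirect all doses to group 1 until ``epsilon`` doses have been given.

    This is the vulnerable-group-first swap: while the cumulative *total* of
    the original policy is below ``epsilon``, group 1 receives the whole rate
    ``sum_i U_i(t)``; afterwards group 1 receives nothing and the other
    groups resume their original rates.  The switch time is the exact root of
    ``sum_i W_i(t) = epsilon`` (closed form on a breakpoint interval).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if group_size is not None and epsilon > group_size + _EPS:
        raise ValueError(
            f"epsilon = {epsilon} exceeds group 1 size {group_size}: "
            "the swap would over-vaccinate group 1")
    n = policy.n
    totals_rate = policy.total_rate()
    widths = np.diff(policy.breakpoints)
    cum_total = np.concatenate([[0.0], np.cumsum(totals_rate * widths)])

    if epsilon <= 0:
        # switching set has measure zero: group 1 silenced, others unchanged
        rates = policy.rates.copy()
        rates[:, 0] = 0.0
        return VaccinationPolicy(policy.breakpoints.copy(), rates).simplify()

    if cum_total[-1] <= epsilon:
        t_switch = float(policy.breakpoints[-1])   # never switches back
    else:
        k = int(np.searchsorted(cum_total, epsilon, side="left") - 1)
        k = max(k, 0)
        t_switch = float(policy.breakpoints[k]
                         + (epsilon - cum_total[k]) / totals_rate[k])

    bp = np.unique(np.concatenate([policy.breakpoints, [t_switch]]))
    bp = bp[bp <= policy.breakpoints[-1] + _EPS]
    new_rates = np.zeros((len(bp) - 1, n))
    for k, (t0, t1) in enumerate(zip(bp[:-1], bp[1:])):
        tm = 0.5 * (t0 + t1)
        orig = policy.rate_at(tm)
        if tm < t_switch:
            new_rates[k, 0] = orig.sum()
        else:
            new_rates[k] = orig
            new_rates[k, 0] = 0.0
    return VaccinationPolicy(bp, new_rates).simplify()


def prioritized_policy(
    order: Sequence[int],
    schedule: SupplySchedule,
    params,
    per_group_caps: Sequence[float] | None = None,
    horizon: float | None = None,
) -> VaccinationPolicy:
    """Bang-bang policy: vaccinate at rate chi(t), one group at a time.

    Groups are filled in the given ``order`` (0-based indices) up to their
    caps (defaults: the group sizes).  The cumulative total administered by
    time t equals ``min(int_0^t chi, sum of caps)``.
    """
    n = params.n
    caps = params.N.copy() if per_group_caps is None else \
        np.asarray(per_group_caps, dtype=float)
    if np.any(caps > params.N + 1e-9):
        raise ValueError("per-group caps may not exceed group sizes")
    order = list(order)
    if sorted(order) != list(range(n)):
        raise ValueError("order must be a permutation of range(n)")
    if horizon is None:
        horizon = max(schedule.a_times[-1], schedule.b_times[-1], 0.0) + \
            caps.sum() / max(schedule.a_values.max(), _EPS) + 1.0

    segs = schedule.chi_segments(horizon)
    bp = [0.0]
    rates = []
    pos = 0                       # index into order
    filled = 0.0                  # doses already given to the active group
    for t0, t1, c in segs:
        t = t0
        while t < t1 - _EPS and pos < n:
            g = order[pos]
            need = caps[g] - filled
            if need <= _EPS:
                pos += 1
                filled = 0.0
                continue
            if c <= _EPS:
                break
            t_fill = t + need / c
            t_end = min(t_fill, t1)
            row = np.zeros(n)
            row[g] = c
            rates.append(row)
            bp.append(t_end)
            filled += c * (t_end - t)
            t = t_end
            if t_fill <= t1 + _EPS and abs(filled - caps[g]) <= 1e-9:
                pos += 1
                filled = 0.0
        if pos >= n:
            break
        if c <= _EPS and t < t1 - _EPS:
            row = np.zeros(n)
            rates.append(row)
            bp.append(t1)
    if not rates:
        return VaccinationPolicy.zero(n)
    return VaccinationPolicy(np.asarray(bp), np.asarray(rates)).simplify()
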