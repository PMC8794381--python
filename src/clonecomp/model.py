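"""Piecewise exponential / competitive Lotka-Volterra model of two tumor subclones.

The model describes co-culture dynamics of a "loser" line L (168FARN) and a
"winner" line W (4T07) in three experimental phases:

* phase 1 (0 to ``t1`` h): pure exponential growth of both types, rates
  ``r_L1`` and ``r_W1`` — a transition period before the cells remodel their
  environment;
* phase 2 (``t1`` to ``t2`` h): density-dependent competitive Lotka-Volterra
  dynamics, ``dL/dt = L (r_L2 + a L + b W)``, ``dW/dt = W (r_W2 + c L + d W)``;
* phase 3 (``t2`` to ``t_end`` h): same structure with the winner's intrinsic
  rate replaced by ``r_W3`` (a degraded-environment effect; the loser keeps
  ``r_L2``).

Population sizes are dimensionless, measured relative to the total seeded
population, so the seeded state satisfies ``L + W = 1`` at t = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp


__all__ = [
    "PhaseSchedule",
    "LVParams",
    "DerivedQuantities",
    "Trajectory",
    "REFERENCE_PARAMS",
    "simulate",
    "logistic_solution",
    "logistic_mean",
    "net_growth_rates",
    "mean_net_growth_rates",
    "crossover_proportion",
    "derived_quantities",
]


@dataclass(frozen=True)
class PhaseSchedule:
    """Phase boundary times of the experiment, in hours.

    ``[0, t1)`` is phase 1, ``[t1, t2)`` phase 2, ``[t2, t_end]`` phase 3.
    """

    t1: float = 45.0
    t2: float = 72.0
    t_end: float = 96.0

    def __post_init__(self) -> None:
        if not (0.0 < self.t1 < self.t2 <= self.t_end):
            raise ValueError(
                f"require 0 < t1 < t2 <= t_end, got {self.t1}, {self.t2}, {self.t_end}"
            )

    def phase_of(self, t: float) -> int:
        if t < self.t1:
            return 1
        if t < self.t2:
            return 2
        return 3


@dataclass(frozen=True)
class LVParams:
    """The nine dynamical parameters of the piecewise model.

    Rates are per hour; interaction coefficients are per normalized
    population unit per hour.  ``a`` and ``d`` are the within-type
    (self-limitation) terms, ``b`` the effect of W on L and ``c`` the effect
    of L on W.  ``r_W3`` may be NaN when phase 3 has not been fitted.
    """

    r_L1: float
    r_W1: float
    r_L2: float
    r_W2: float
    r_W3: float
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "r_W3":
                if math.isinf(v):
                    raise ValueError("r_W3 must be finite or NaN")
                continue
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v}")

    @property
    def has_phase3(self) -> bool:
        return math.isfinite(self.r_W3)

    def replace(self, **kwargs) -> "LVParams":
        from dataclasses import replace

        return replace(self, **kwargs)


#: Parameter set inferred for the 168FARN/4T07 subclone pair (the package's
#: worked example and the default for the synthetic-data generator).
REFERENCE_PARAMS = LVParams(
    r_L1=0.044,
    r_W1=0.031,
    r_L2=0.073,
    r_W2=0.102,
    r_W3=0.04,
    a=-0.004,
    b=-0.010,
    c=0.000,
    d=-0.008,
)


@dataclass(frozen=True)
class DerivedQuantities:
    """Carrying capacities and relative interaction strengths.

    ``K_L = -r_L2/a`` and ``K_W = -r_W2/d`` are the homotypic carrying
    capacities relative to the seeded population; ``beta_ratio = b/a`` and
    ``gamma_ratio = c/d`` compare between-type to within-type effects.
    """

    K_L: float
    K_W: float
    beta_ratio: float
    gamma_ratio: float


def derived_quantities(params: LVParams) -> DerivedQuantities:
    """Carrying capacities and interaction ratios from the phase-2 parameters."""
    if params.a >= 0 or params.d >= 0:
        raise ValueError(
            "carrying capacities require self-limitation (a < 0 and d < 0); "
            f"got a={params.a}, d={params.d}"
        )
    return DerivedQuantities(
        K_L=-params.r_L2 / params.a,
        K_W=-params.r_W2 / params.d,
        beta_ratio=params.b / params.a,
        gamma_ratio=params.c / params.d,
    )


@dataclass(frozen=True)
class Trajectory:
    """Model solution at requested times: arrays ``t``, ``L``, ``W``, ``phase``."""

    t: np.ndarray
    L: np.ndarray
    W: np.ndarray
    phase: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_h": self.t, "L": self.L, "W": self.W, "phase": self.phase}
        )

    @property
    def w(self) -> np.ndarray:
        """Winner proportion W/(L+W) at each time."""
        return self.W / (self.L + self.W)


def _rhs(params: LVParams, phase: int):
    if phase == 2:
        rW = params.r_W2
    elif phase == 3:
        rW = params.r_W3
    else:
        raise ValueError("numerical RHS only defined for phases 2 and 3")

    a, b, c, d, rL = params.a, params.b, params.c, params.d, params.r_L2

    def f(t, y):
        L, W = y
        return [L * (rL + a * L + b * W), W * (rW + c * L + d * W)]

    return f


def simulate(
    params: LVParams,
    schedule: PhaseSchedule,
    initial: tuple[float, float],
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Solve the piecewise model from ``(L0, W0)`` at t = 0.

    Phase 1 is solved in closed form (pure exponentials); phases 2 and 3 by
    adaptive numerical integration with a hard restart at each phase
    boundary, so the state is continuous at ``t1`` and ``t2``.  When phase 3
    is reached but ``r_W3`` is NaN, the phase-2 rate is carried through
    (homotypic loser curves never notice: the phase-3 change applies to W
    only).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("times must be a non-empty 1-d sequence")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t[0] < 0 or t[-1] > schedule.t_end + 1e-9:
        raise ValueError(f"times must lie within [0, {schedule.t_end}]")
    L0, W0 = float(initial[0]), float(initial[1])
    if L0 < 0 or W0 < 0 or L0 + W0 <= 0:
        raise ValueError("initial sizes must be non-negative with L0 + W0 > 0")

    out_L = np.empty_like(t)
    out_W = np.empty_like(t)

    # phase 1: closed form
    m1 = t < schedule.t1
    out_L[m1] = L0 * np.exp(params.r_L1 * t[m1])
    out_W[m1] = W0 * np.exp(params.r_W1 * t[m1])

    # state at t1
    y = np.array(
        [L0 * math.exp(params.r_L1 * schedule.t1), W0 * math.exp(params.r_W1 * schedule.t1)]
    )

    p = params
    if not p.has_phase3:
        p = p.replace(r_W3=p.r_W2)

    segments = [
        (2, schedule.t1, schedule.t2, (t >= schedule.t1) & (t < schedule.t2)),
        (3, schedule.t2, schedule.t_end, t >= schedule.t2),
    ]
    for i, (phase, lo, hi, mask) in enumerate(segments):
        t_eval = t[mask]
        # integrate only as far as needed: to the last requested point in
        # this segment, or to the boundary if a later segment has points
        later = any(seg_mask.any() for _, _, _, seg_mask in segments[i + 1 :])
        stop = hi if later else (t_eval[-1] if len(t_eval) else None)
        if stop is None:
            continue
        fill = t_eval == lo  # boundary points carry the incoming state
        interior = t_eval[~fill]
        out_L[mask & (t == lo)], out_W[mask & (t == lo)] = y[0], y[1]
        if stop > lo:
            needs_end = len(interior) == 0 or interior[-1] < stop
            sol = solve_ivp(
                _rhs(p, phase),
                (lo, stop),
                y,
                method="LSODA",
                t_eval=np.concatenate([interior, [stop]]) if needs_end else interior,
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise RuntimeError(
                    f"integration failed in phase {phase} near t={sol.t[-1]:.3f}: {sol.message}"
                )
            n = len(interior)
            out_L[mask & (t > lo)] = sol.y[0][:n]
            out_W[mask & (t > lo)] = sol.y[1][:n]
            y = sol.y[:, -1].copy()

    phase_arr = np.array([schedule.phase_of(tt) for tt in t])
    # multiplicative structure keeps sizes non-negative; clip tiny negatives
    out_L = np.maximum(out_L, 0.0)
    out_W = np.maximum(out_W, 0.0)
    return Trajectory(t=t, L=out_L, W=out_W, phase=phase_arr)


def logistic_solution(r: float, self_coeff: float, x_t1, tau):
    """Closed-form solution of ``dx/dt = x (r + self_coeff * x)``.

    ``x_t1`` is the size at the start of phase 2 and ``tau`` the time elapsed
    since then: ``x(tau) = x_t1 r e^{r tau} / (r - x_t1 self_coeff (e^{r tau} - 1))``.
    Requires ``self_coeff < 0`` (with a positive coefficient the solution
    blows up in finite time once the denominator reaches zero).
    """
    if self_coeff >= 0:
        raise ValueError("self_coeff must be negative (self-limitation)")
    x_t1 = np.asarray(x_t1, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(x_t1 <= 0):
        raise ValueError("x_t1 must be positive")
    e = np.exp(r * tau)
    den = r - x_t1 * self_coeff * (e - 1.0)
    if np.any(den <= 0):
        raise ValueError("logistic denominator <= 0 (finite-time blow-up)")
    out = x_t1 * r * e / den
    return float(out) if out.ndim == 0 else out


def logistic_mean(r: float, self_coeff: float, x_t1: float, tau: float) -> float:
    """Time-average of the logistic solution over ``[0, tau]``, closed form.

    Uses the antiderivative identity ``d(ln x)/dt = r + self_coeff x``, so
    ``mean(x) = (ln x(tau) - ln x(0) - r tau) / (self_coeff tau)``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    x_end = logistic_solution(r, self_coeff, x_t1, tau)
    return (math.log(x_end) - math.log(x_t1) - r * tau) / (self_coeff * tau)


def net_growth_rates(
    params: LVParams, L: float, W: float, phase: int
) -> tuple[float, float]:
    """Per-capita net growth rates (g_L, g_W) of both types at a given state.

    The net rate is the intrinsic rate plus the interaction terms; in phase 1
    the types grow exponentially so the net rate equals the intrinsic rate.
    """
    if phase == 1:
        return params.r_L1, params.r_W1
    if phase == 2:
        rW = params.r_W2
    elif phase == 3:
        rW = params.r_W3
    else:
        raise ValueError(f"phase must be 1, 2 or 3, got {phase}")
    g_L = params.r_L2 + params.a * L + params.b * W
    g_W = rW + params.c * L + params.d * W
    return g_L, g_W


def mean_net_growth_rates(
    params: LVParams,
    schedule: PhaseSchedule,
    w0: float,
    window: tuple[float, float],
) -> tuple[float, float, float]:
    """Mean per-capita rates of both types over a time window, plus the gain.

    Simulates from t = 0 at total size 1 and winner proportion ``w0``; the
    mean rate of a type is the log-endpoint slope
    ``(ln X(t_stop) - ln X(t_start)) / (t_stop - t_start)`` — identical to the
    time-average of the instantaneous per-capita rate.  The gain function is
    ``mean g_W - mean g_L``, which equals the mean slope of the
    logit-transformed winner proportion.  A zero-length window returns the
    instantaneous rates.
    """
    if not (0.0 < w0 < 1.0):
        raise ValueError("w0 must lie strictly in (0, 1)")
    t_start, t_stop = window
    if t_start < 0 or t_stop > schedule.t_end or t_stop < t_start:
        raise ValueError("window must satisfy 0 <= t_start <= t_stop <= t_end")
    initial = (1.0 - w0, w0)
    if t_stop == t_start:
        times = [t_start] if t_start > 0 else [0.0]
        tr = simulate(params, schedule, initial, times)
        g_L, g_W = net_growth_rates(
            params, tr.L[-1], tr.W[-1], schedule.phase_of(t_start)
        )
        return g_L, g_W, g_W - g_L
    times = sorted({0.0, t_start, t_stop})
    tr = simulate(params, schedule, initial, times)
    i0 = times.index(t_start)
    i1 = times.index(t_stop)
    if tr.L[i0] <= 0 or tr.W[i0] <= 0:
        raise ValueError("population size is zero at the window start")
    dt = t_stop - t_start
    g_L = (math.log(tr.L[i1]) - math.log(tr.L[i0])) / dt
    g_W = (math.log(tr.W[i1]) - math.log(tr.W[i0])) / dt
    return g_L, g_W, g_W - g_L


def _phase3_state_and_gain(
    params: LVParams, schedule: PhaseSchedule, w0: float
) -> tuple[float, float]:
    """Proportion at t2 and mean phase-3 gain, from a seeding at proportion w0."""
    times = [schedule.t2, schedule.t_end]
    tr = simulate(params, schedule, (1.0 - w0, w0), times)
    w_t2 = tr.W[0] / (tr.L[0] + tr.W[0])
    dt = schedule.t_end - schedule.t2
    g_L = (math.log(tr.L[1]) - math.log(tr.L[0])) / dt
    g_W = (math.log(tr.W[1]) - math.log(tr.W[0])) / dt
    return w_t2, g_W - g_L


def crossover_proportion(
    params: LVParams,
    schedule: PhaseSchedule,
    grid: Optional[np.ndarray] = None,
    tol: float = 1e-4,
) -> Optional[float]:
    """Winner proportion at the start of phase 3 where the mean phase-3 gain is zero.

    States at ``t2`` are obtained by simulating from t = 0 across a grid of
    seeding proportions; the gain over ``[t2, t_end]`` is evaluated as a
    function of the proportion at ``t2`` and the sign change is refined by
    bisection (to ``tol`` in proportion).  Returns ``None`` when the gain
    does not change sign over the admissible grid ("no crossover").
    """
    if not params.has_phase3:
        raise ValueError("crossover requires a fitted phase-3 rate r_W3")
    if grid is None:
        grid = np.linspace(0.01, 0.99, 25)
    pts = [_phase3_state_and_gain(params, schedule, w0) for w0 in grid]
    gains = np.array([g for _, g in pts])
    if np.all(np.abs(gains) < 1e-7):
        return None  # gain vanishes identically (up to integrator noise)
    sign = np.sign(gains)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    exact = np.nonzero(gains == 0.0)[0]
    if len(exact):
        return pts[exact[0]][0]
    if len(idx) == 0:
        return None
    i = idx[0]
    lo, hi = grid[i], grid[i + 1]
    w_lo, g_lo = pts[i]
    w_hi, _ = pts[i + 1]
    while abs(w_hi - w_lo) > tol:
        mid = 0.5 * (lo + hi)
        w_mid, g_mid = _phase3_state_and_gain(params, schedule, mid)
        if g_lo * g_mid <= 0:
            hi, w_hi = mid, w_mid
        else:
            lo, w_lo, g_lo = mid, w_mid, g_mid
    return 0.5 * (w_lo + w_hi)
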