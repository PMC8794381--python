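"""Parameter inference from homotypic growth curves and serial competition assays.

The pipeline mirrors the multi-step estimation procedure for the two-subclone
model:

1. normalize each time-lapse curve in log space to its fitted value at 24 h;
2. fit the combined exponential-plus-logistic homotypic model per type by
   least squares, giving the phase-1 rates, phase-2 intrinsic rates and the
   within-type coefficients ``a`` and ``d``;
3. turn each 72-h competition-assay round into a gain point: the mean slope
   of the logit winner proportion over phase 2, after adjusting the seeding
   proportion for the exponential phase-1 growth of both types;
4. regress the gain on the proportion at the start of phase 2 and
   extrapolate to the homotypic limits (proportion 1 and 0);
5. solve the ds/dt expansion at each limit for the between-type coefficients
   ``b`` and ``c``, replacing the population size by its time-average over
   phase 2 (closed-form logistic solution, averaged by quadrature);
6. fit the single phase-3 winner rate ``r_W3`` to whole-round logit changes
   of 96-h assays.

``SubcloneCompetitionModel`` packages the datasets and options;
``SubcloneCompetitionModel.fit()`` runs the pipeline and returns a
``SubcloneCompetitionResults`` with estimates, uncertainties where the
procedure provides them, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.integrate import quad
from scipy.optimize import least_squares, minimize_scalar
from scipy.special import expit, logit

from .model import (
    DerivedQuantities,
    LVParams,
    PhaseSchedule,
    Trajectory,
    derived_quantities,
    logistic_solution,
    simulate,
)
from .synth import CompetitionAssayRecord, GrowthCurve

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceOptions",
    "GainPoint",
    "RegressionFit",
    "InferenceResult",
    "normalize_curve",
    "fit_homotypic",
    "adjust_phase1",
    "compute_gain_points",
    "regress_gain",
    "infer_b",
    "infer_c",
    "infer_r_w3",
    "estimate_net_growth_from_curve",
    "run_full_inference",
    "SubcloneCompetitionModel",
    "SubcloneCompetitionResults",
]


@dataclass(frozen=True)
class InferenceOptions:
    """Switches of the inference pipeline.

    ``exclude_first_round`` drops round-1 assay records from the gain
    regression (they are the least reliable measurements in serial designs).
    ``use_phase2_rates`` switches the phase-1 logit adjustment from the
    phase-1 rate difference (default, internally consistent) to the phase-2
    rate difference.  ``skip_phase3`` tolerates a missing 96-h data set.
    """

    exclude_first_round: bool = True
    use_phase2_rates: bool = False
    skip_phase3: bool = False
    n_starts: int = 3
    start_seed: int = 0


@dataclass(frozen=True)
class GainPoint:
    """One assay round mapped into gain-function space."""

    w_t1: float
    s_t1: float
    gain: float
    round_index: int
    replicate: str
    included: bool


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of gain on the proportion at the start of phase 2."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    gain_at_1: float
    gain_at_0: float
    se_at_1: float
    se_at_0: float
    nobs: int


@dataclass(frozen=True)
class InferenceResult:
    """Full parameter set with derived quantities and per-stage diagnostics."""

    params: LVParams
    derived: DerivedQuantities
    gain_points: tuple
    regression: RegressionFit
    homotypic_sse: dict
    homotypic_se: dict
    phase3_sse: Optional[float]
    n_excluded: int
    n_degenerate: int
    options: InferenceOptions
    schedule: PhaseSchedule

    def params_dict(self) -> dict:
        p, d = self.params, self.derived
        return {
            "r_L1": p.r_L1,
            "r_W1": p.r_W1,
            "r_L2": p.r_L2,
            "r_W2": p.r_W2,
            "r_W3": p.r_W3,
            "a": p.a,
            "b": p.b,
            "c": p.c,
            "d": p.d,
            "K_L": d.K_L,
            "K_W": d.K_W,
            "beta": d.beta_ratio,
            "gamma": d.gamma_ratio,
        }


# ---------------------------------------------------------------------------
# curve normalization and homotypic fitting


def normalize_curve(
    curve: GrowthCurve, schedule: PhaseSchedule = PhaseSchedule(), ref_time: float = 24.0
) -> GrowthCurve:
    """Normalize a curve to its fitted log-linear value at ``ref_time``.

    A straight line is fitted to log signal against time separately on the
    phase-1 segment (up to ``t1``) and the later segment; every signal is
    divided by the exponential of the segment line evaluated at ``ref_time``
    (24 h lies in phase 1).  The output is scale-invariant: multiplying all
    signals by a constant leaves it unchanged.
    """
    t, y = curve.times, np.log(curve.signal)
    if t[0] > ref_time or t[-1] < ref_time:
        raise ValueError(f"curve must span the reference time {ref_time} h")
    seg1 = t <= schedule.t1
    seg2 = t >= schedule.t1
    for name, m in (("phase-1", seg1), ("phase-2", seg2)):
        if m.sum() < 3:
            raise ValueError(f"fewer than 3 points in the {name} segment")
    use = seg1 if ref_time <= schedule.t1 else seg2
    slope, intercept = np.polyfit(t[use], y[use], 1)
    ref = slope * ref_time + intercept
    return replace(curve, signal=curve.signal / math.exp(ref))


def _predict_homotypic_log(
    theta: np.ndarray, times: np.ndarray, schedule: PhaseSchedule, ref_time: float
) -> np.ndarray:
    """Log of the normalized homotypic model curve (closed form).

    The curve starts at size 1 at t = 0, grows exponentially at ``r1`` until
    ``t1`` and logistically (rate ``r2``, self-coefficient ``sc``) after, and
    is divided by its value at ``ref_time``.
    """
    r1, r2, sc = theta
    out = np.empty_like(times)
    m1 = times < schedule.t1
    out[m1] = r1 * times[m1]
    tau = times[~m1] - schedule.t1
    x1 = math.exp(r1 * schedule.t1)
    e = np.exp(r2 * tau)
    den = r2 - x1 * sc * (e - 1.0)
    bad = den <= 1e-12
    den = np.where(bad, 1e-12, den)
    val = np.log(x1 * r2 * e / den)
    val[bad] = 50.0  # finite-time blow-up: huge residual instead of NaN
    out[~m1] = val
    return out - r1 * ref_time


def _fit_one_type(
    curves: Sequence[GrowthCurve],
    schedule: PhaseSchedule,
    ref_time: float,
    options: InferenceOptions,
) -> tuple[np.ndarray, float, np.ndarray]:
    ts, ys = [], []
    for c in curves:
        m = c.times <= schedule.t2
        ts.append(c.times[m])
        ys.append(np.log(c.signal[m]))
    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys)

    # data-driven start: log-linear slopes of the two segments
    m1 = t_all < schedule.t1
    r1_0, _ = np.polyfit(t_all[m1], y_all[m1], 1)
    m2 = ~m1
    r2_0, _ = np.polyfit(t_all[m2], y_all[m2], 1) if m2.sum() >= 2 else (r1_0, 0.0)
    r2_0 = max(r2_0, 1e-3)
    x_end = math.exp(np.max(y_all))
    sc_0 = -max(r2_0, 1e-3) / max(4.0 * x_end, 1.0)

    def resid(theta):
        return _predict_homotypic_log(theta, t_all, schedule, ref_time) - y_all

    rng = np.random.default_rng(options.start_seed)
    best = None
    lb = np.array([1e-4, 1e-4, -1.0])
    ub = np.array([1.0, 1.0, 1.0])
    for k in range(options.n_starts):
        x0 = np.array([max(r1_0, 1e-3), max(2 * r2_0, 1e-3), sc_0])
        if k > 0:
            x0 = x0 * np.exp(rng.normal(0.0, 0.3, size=3))
            x0[2] = -abs(x0[2])
        x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)
        sol = least_squares(resid, x0, bounds=(lb, ub), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.status <= 0:
        raise RuntimeError(f"homotypic fit did not converge: {best and best.message}")
    if best.x[2] >= 0:
        logger.warning(
            "estimated self-interaction coefficient is non-negative (%.4g): "
            "no finite carrying capacity",
            best.x[2],
        )
    # asymptotic standard errors from the Jacobian at the optimum
    dof = max(len(y_all) - 3, 1)
    s2 = 2 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    return best.x, 2 * best.cost, se


def fit_homotypic(
    curves_L: Sequence[GrowthCurve],
    curves_W: Sequence[GrowthCurve],
    schedule: PhaseSchedule = PhaseSchedule(),
    ref_time: float = 24.0,
    options: InferenceOptions = InferenceOptions(),
) -> tuple[dict, dict, dict]:
    """Least-squares fit of the exponential-plus-logistic model to homotypic curves.

    Residuals are taken on the log scale (multiplicative observation error)
    over phases 1 and 2 jointly, with the phase-2 initial condition tied to
    the phase-1 model value at ``t1`` (continuity).  Curves should be
    normalized (see :func:`normalize_curve`); model predictions are
    normalized at the same reference time, so the fit is invariant to an
    overall scale.  Returns ``(params, sse, se)`` dicts with keys
    ``r_L1, r_L2, a, r_W1, r_W2, d``.
    """
    if not curves_L or not curves_W:
        raise ValueError("both homotypic curve sets are required")
    thL, sseL, seL = _fit_one_type(curves_L, schedule, ref_time, options)
    thW, sseW, seW = _fit_one_type(curves_W, schedule, ref_time, options)
    params = {
        "r_L1": thL[0], "r_L2": thL[1], "a": thL[2],
        "r_W1": thW[0], "r_W2": thW[1], "d": thW[2],
    }
    sse = {"L": sseL, "W": sseW}
    se = {
        "r_L1": seL[0], "r_L2": seL[1], "a": seL[2],
        "r_W1": seW[0], "r_W2": seW[1], "d": seW[2],
    }
    return params, sse, se


# ---------------------------------------------------------------------------
# gain points and regression


def adjust_phase1(
    w_start: float,
    params: LVParams,
    schedule: PhaseSchedule = PhaseSchedule(),
    use_phase2_rates: bool = False,
) -> tuple[float, float]:
    """Shift a seeding proportion to the start of phase 2.

    During phase 1 both types grow exponentially, so the logit proportion
    shifts linearly: ``s(t1) = s(0) + t1 (r_W - r_L)`` with the phase-1
    rates by default (``use_phase2_rates`` substitutes the phase-2 intrinsic
    rates for comparison).  Returns ``(s_t1, w_t1)``.
    """
    if not (0.0 < w_start < 1.0):
        raise ValueError("w_start must lie strictly in (0, 1): logit undefined")
    if use_phase2_rates:
        diff = params.r_W2 - params.r_L2
    else:
        diff = params.r_W1 - params.r_L1
    s_t1 = float(logit(w_start)) + schedule.t1 * diff
    return s_t1, float(expit(s_t1))


def compute_gain_points(
    assays: Sequence[CompetitionAssayRecord],
    params: LVParams,
    schedule: PhaseSchedule = PhaseSchedule(),
    exclude_first_round: bool = True,
    use_phase2_rates: bool = False,
) -> list[GainPoint]:
    """Map assay records to phase-2 gain points.

    The gain of a record is ``(s(t2) - s(t1)) / (t2 - t1)`` with
    ``s(t2) = logit(w_end)`` and ``s(t1)`` from the phase-1 adjustment of the
    measured seeding proportion.  Records with degenerate proportions are
    skipped with a warning; round-1 points are marked excluded when the flag
    is set (their values are computed identically either way).
    """
    pts: list[GainPoint] = []
    n_skipped = 0
    dt = schedule.t2 - schedule.t1
    for rec in assays:
        if rec.degenerate:
            n_skipped += 1
            continue
        s_t1, w_t1 = adjust_phase1(rec.w_start, params, schedule, use_phase2_rates)
        gain = (float(logit(rec.w_end)) - s_t1) / dt
        pts.append(
            GainPoint(
                w_t1=w_t1,
                s_t1=s_t1,
                gain=gain,
                round_index=rec.round_index,
                replicate=rec.replicate,
                included=not (exclude_first_round and rec.round_index == 1),
            )
        )
    if n_skipped:
        logger.warning("skipped %d assay record(s) with degenerate proportions", n_skipped)
    return pts


def regress_gain(points: Sequence[GainPoint]) -> RegressionFit:
    """Unweighted OLS of gain on w(t1) over included points, with extrapolations.

    The fitted line is evaluated (with standard errors) at ``w(t1) = 1`` and
    ``w(t1) = 0`` — the homotypic limits used to solve for the between-type
    interaction coefficients.
    """
    inc = [p for p in points if p.included]
    x = np.array([p.w_t1 for p in inc])
    y = np.array([p.gain for p in inc])
    if len(inc) < 3 or len(np.unique(x)) < 2:
        raise ValueError("need >= 3 included gain points with distinct w_t1")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    pred = res.get_prediction(np.array([[1.0, 0.0], [1.0, 1.0]]))
    se0, se1 = pred.se_mean
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        gain_at_1=float(res.params[0] + res.params[1]),
        gain_at_0=float(res.params[0]),
        se_at_1=float(se1),
        se_at_0=float(se0),
        nobs=len(inc),
    )


# ---------------------------------------------------------------------------
# between-type coefficients and the phase-3 rate


def _mean_homotypic_size(
    r2: float, self_coeff: float, r1: float, schedule: PhaseSchedule
) -> float:
    """Time-average over phase 2 of the homotypic logistic solution.

    The curve is seeded with the phase-1 endpoint ``x(t1) = exp(r1 t1)``
    (total initial size 1 in the single-type limit) and averaged by adaptive
    quadrature of the closed-form solution.
    """
    x1 = math.exp(r1 * schedule.t1)
    dt = schedule.t2 - schedule.t1
    val, _ = quad(lambda tau: logistic_solution(r2, self_coeff, x1, tau), 0.0, dt)
    return val / dt


def infer_b(
    fit: RegressionFit, params: LVParams, schedule: PhaseSchedule = PhaseSchedule()
) -> float:
    """Between-type effect of the winner on the loser, from the w -> 1 limit.

    In that limit the ds/dt expansion reduces to
    ``gain = r_W2 - r_L2 + (d - b) W`` with W at its homotypic trajectory;
    replacing W by its phase-2 time-average and solving gives
    ``b = d - (gain_at_1 - r_W2 + r_L2) / mean(W)``.
    """
    if params.d >= 0:
        raise ValueError("requires a negative within-type coefficient d")
    mean_w = _mean_homotypic_size(params.r_W2, params.d, params.r_W1, schedule)
    return params.d - (fit.gain_at_1 - params.r_W2 + params.r_L2) / mean_w


def infer_c(
    fit: RegressionFit, params: LVParams, schedule: PhaseSchedule = PhaseSchedule()
) -> float:
    """Between-type effect of the loser on the winner, from the w -> 0 limit.

    Mirror of :func:`infer_b` with the loser's logistic trajectory; the gain
    is still winner-minus-loser, so the relevant term is ``(c - a) L`` and
    ``c = a + (gain_at_0 - r_W2 + r_L2) / mean(L)``.
    """
    if params.a >= 0:
        raise ValueError("requires a negative within-type coefficient a")
    mean_l = _mean_homotypic_size(params.r_L2, params.a, params.r_L1, schedule)
    return params.a + (fit.gain_at_0 - params.r_W2 + params.r_L2) / mean_l


def infer_r_w3(
    assays_96h: Sequence[CompetitionAssayRecord],
    params: LVParams,
    schedule: PhaseSchedule = PhaseSchedule(),
    bounds: tuple[float, float] = (-0.3, 0.3),
) -> tuple[float, float]:
    """Phase-3 winner rate by 1-d least squares on whole-round logit changes.

    For each 96-h record the model is simulated through all three phases
    from the measured seeding proportion at total size 1; ``r_W3`` minimizes
    the squared differences between observed and predicted ``Δs`` over the
    whole round.  All other parameters stay fixed.  Returns
    ``(r_W3, objective at the minimum)``.
    """
    recs = [r for r in assays_96h if not r.degenerate]
    if not recs:
        raise ValueError("no usable 96-h assay records")
    # phases 1-2 do not involve r_W3: precompute the state at t2 per record
    pre = []
    for r in recs:
        tr = simulate(params.replace(r_W3=params.r_W2), schedule, (1.0 - r.w_start, r.w_start), [schedule.t2])
        ds_obs = float(logit(r.w_end)) - float(logit(r.w_start))
        pre.append((tr.L[0], tr.W[0], ds_obs, r.duration_h, float(logit(r.w_start))))

    from scipy.integrate import solve_ivp

    def obj(r_w3: float) -> float:
        total = 0.0
        for L2, W2, ds_obs, dur, s0 in pre:
            def rhs(t, y):
                L, W = y
                return [
                    L * (params.r_L2 + params.a * L + params.b * W),
                    W * (r_w3 + params.c * L + params.d * W),
                ]
            sol = solve_ivp(
                rhs, (schedule.t2, dur), [L2, W2], method="LSODA",
                rtol=1e-8, atol=1e-10,
            )
            if not sol.success:
                return 1e6
            L_end, W_end = sol.y[:, -1]
            ds_model = math.log(W_end / L_end) - s0
            total += (ds_obs - ds_model) ** 2
        return total

    res = minimize_scalar(obj, bounds=bounds, method="bounded", options={"xatol": 1e-6})
    return float(res.x), float(res.fun)


# ---------------------------------------------------------------------------
# net growth rates from curves (difference quotients)


def estimate_net_growth_from_curve(
    curve: GrowthCurve, smoothing_span: float = 5.0, quotient_span: float = 5.0
) -> pd.DataFrame:
    """Per-capita net growth rates as local gradients of the smoothed log curve.

    The log signal is smoothed by a running median over ``smoothing_span``
    hours, then differentiated by centered difference quotients across
    ``quotient_span`` hours.  Returns a frame with columns ``time_h`` and
    ``rate`` covering the interior of the curve.
    """
    t, y = curve.times, np.log(curve.signal)
    dt = float(np.median(np.diff(t)))
    if smoothing_span > t[-1] - t[0] or quotient_span > t[-1] - t[0]:
        raise ValueError("span exceeds the curve's time extent")
    k = max(1, int(round(smoothing_span / dt)))
    if k % 2 == 0:
        k += 1
    smooth = (
        pd.Series(y).rolling(window=k, center=True, min_periods=1).median().to_numpy()
    )
    m = max(1, int(round(quotient_span / dt / 2)))
    # drop the edge region where the median window is incomplete
    edge = m + k // 2
    idx = np.arange(edge, len(t) - edge)
    if len(idx) == 0:
        raise ValueError("span exceeds the curve's time extent")
    rates = (smooth[idx + m] - smooth[idx - m]) / (t[idx + m] - t[idx - m])
    return pd.DataFrame({"time_h": t[idx], "rate": rates})


# ---------------------------------------------------------------------------
# orchestration


def run_full_inference(
    curves_L: Sequence[GrowthCurve],
    curves_W: Sequence[GrowthCurve],
    assays_72h: Sequence[CompetitionAssayRecord],
    assays_96h: Sequence[CompetitionAssayRecord] = (),
    schedule: PhaseSchedule = PhaseSchedule(),
    options: InferenceOptions = InferenceOptions(),
) -> InferenceResult:
    """Run the whole pipeline: normalize, fit, gain regression, b, c, r_W3."""
    norm_L = [normalize_curve(c, schedule) for c in curves_L]
    norm_W = [normalize_curve(c, schedule) for c in curves_W]
    homo, sse, se = fit_homotypic(norm_L, norm_W, schedule, options=options)

    partial = LVParams(
        r_L1=homo["r_L1"], r_W1=homo["r_W1"], r_L2=homo["r_L2"], r_W2=homo["r_W2"],
        r_W3=math.nan, a=homo["a"], b=0.0, c=0.0, d=homo["d"],
    )
    pts = compute_gain_points(
        assays_72h, partial, schedule,
        exclude_first_round=options.exclude_first_round,
        use_phase2_rates=options.use_phase2_rates,
    )
    n_deg = len(assays_72h) - len(pts)
    fit = regress_gain(pts)
    b = infer_b(fit, partial, schedule)
    c = infer_c(fit, partial, schedule)
    params = partial.replace(b=b, c=c)

    phase3_sse: Optional[float] = None
    if assays_96h:
        r_w3, phase3_sse = infer_r_w3(assays_96h, params, schedule)
        params = params.replace(r_W3=r_w3)
    elif not options.skip_phase3:
        raise ValueError(
            "96-h assay records are required unless options.skip_phase3 is set"
        )
    else:
        logger.warning("phase 3 skipped: r_W3 left unfitted (NaN)")

    n_excluded = sum(1 for p in pts if not p.included)
    if n_excluded:
        logger.info("excluded %d first-round gain point(s) from the regression", n_excluded)
    return InferenceResult(
        params=params,
        derived=derived_quantities(params),
        gain_points=tuple(pts),
        regression=fit,
        homotypic_sse=sse,
        homotypic_se=se,
        phase3_sse=phase3_sse,
        n_excluded=n_excluded,
        n_degenerate=n_deg,
        options=options,
        schedule=schedule,
    )


class SubcloneCompetitionModel:
    """Two-subclone eco-evolutionary model bound to a set of experiments.

    Parameters
    ----------
    curves_L, curves_W
        Homotypic time-lapse curves of the loser and winner lines.
    assays_72h
        Serial competition-assay records whose rounds end at ``t2`` (72 h).
    assays_96h
        Optional records of whole-96-h rounds, used to fit the phase-3 rate.
    schedule
        Phase boundary times (defaults 45 / 72 / 96 h).
    options
        Pipeline switches, see :class:`InferenceOptions`.
    """

    def __init__(
        self,
        curves_L: Sequence[GrowthCurve],
        curves_W: Sequence[GrowthCurve],
        assays_72h: Sequence[CompetitionAssayRecord],
        assays_96h: Sequence[CompetitionAssayRecord] = (),
        schedule: PhaseSchedule = PhaseSchedule(),
        options: InferenceOptions = InferenceOptions(),
    ) -> None:
        self.curves_L = list(curves_L)
        self.curves_W = list(curves_W)
        self.assays_72h = list(assays_72h)
        self.assays_96h = list(assays_96h)
        self.schedule = schedule
        self.options = options

    @classmethod
    def from_csv(
        cls,
        curves_path,
        assays_72h_path,
        assays_96h_path=None,
        schedule: PhaseSchedule = PhaseSchedule(),
        options: InferenceOptions = InferenceOptions(),
    ) -> "SubcloneCompetitionModel":
        """Build the model from the package's CSV dialects (see :mod:`clonecomp.io`)."""
        from .io import read_assays, read_growth_curves

        curves = read_growth_curves(curves_path)
        curves_L = [c for c in curves if c.condition == "homotypic" and c.labeled_type == "L"]
        curves_W = [c for c in curves if c.condition == "homotypic" and c.labeled_type == "W"]
        a72 = read_assays(assays_72h_path)
        a96 = read_assays(assays_96h_path) if assays_96h_path else []
        return cls(curves_L, curves_W, a72, a96, schedule, options)

    def fit(self) -> "SubcloneCompetitionResults":
        result = run_full_inference(
            self.curves_L, self.curves_W, self.assays_72h, self.assays_96h,
            self.schedule, self.options,
        )
        return SubcloneCompetitionResults(self, result)


class SubcloneCompetitionResults:
    """Estimates and diagnostics from a fitted :class:`SubcloneCompetitionModel`."""

    def __init__(self, model: SubcloneCompetitionModel, result: InferenceResult) -> None:
        self.model = model
        self.result = result
        self.params = result.params
        self.derived = result.derived
        self.regression = result.regression

    def params_dict(self) -> dict:
        return self.result.params_dict()

    def gain_points_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.result.gain_points])

    def simulate(self, w0: float, times) -> Trajectory:
        """Trajectory of the fitted model from a seeding at winner proportion w0."""
        return simulate(self.params, self.result.schedule, (1.0 - w0, w0), times)

    def crossover_proportion(self) -> Optional[float]:
        from .model import crossover_proportion

        return crossover_proportion(self.params, self.result.schedule)

    def summary(self) -> str:
        """Parameter table with uncertainties where the procedure provides them."""
        r = self.result
        se = r.homotypic_se
        rows = []
        labels = {
            "r_L1": "loser rate, phase 1 (/h)",
            "r_W1": "winner rate, phase 1 (/h)",
            "r_L2": "loser intrinsic rate, phase 2 (/h)",
            "r_W2": "winner intrinsic rate, phase 2 (/h)",
            "r_W3": "winner intrinsic rate, phase 3 (/h)",
            "a": "effect of loser on loser",
            "b": "effect of winner on loser",
            "c": "effect of loser on winner",
            "d": "effect of winner on winner",
            "K_L": "loser carrying capacity",
            "K_W": "winner carrying capacity",
            "beta": "b/a",
            "gamma": "c/d",
        }
        vals = self.params_dict()
        for key, label in labels.items():
            s = se.get(key)
            se_txt = f"{s:10.4f}" if s is not None and np.isfinite(s) else "          "
            rows.append(f"{key:>6}  {vals[key]:10.4f}  {se_txt}  {label}")
        lines = [
            "Subclone competition model",
            "=" * 66,
            f"{'param':>6}  {'estimate':>10}  {'std err':>10}  interpretation",
            "-" * 66,
            *rows,
            "-" * 66,
            f"gain regression: slope {r.regression.slope:.5f} "
            f"(se {r.regression.slope_se:.5f}), intercept {r.regression.intercept:.5f} "
            f"(se {r.regression.intercept_se:.5f}), n={r.regression.nobs}",
            f"excluded first-round points: {r.n_excluded}; degenerate records: {r.n_degenerate}",
        ]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        r = self.result
        out = self.params_dict()
        out["diagnostics"] = {
            "homotypic_sse": r.homotypic_sse,
            "phase3_sse": r.phase3_sse,
            "regression": {
                "slope": r.regression.slope,
                "intercept": r.regression.intercept,
                "slope_se": r.regression.slope_se,
                "intercept_se": r.regression.intercept_se,
                "gain_at_1": r.regression.gain_at_1,
                "gain_at_0": r.regression.gain_at_0,
                "nobs": r.regression.nobs,
            },
            "n_excluded": r.n_excluded,
            "n_degenerate": r.n_degenerate,
        }
        return out

    def plot_gain_function(self, ax=None):
        """Gain points and the fitted regression line (phase-2 gain vs w(t1))."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.gain_points_frame()
        inc = df[df.included]
        exc = df[~df.included]
        ax.scatter(inc.w_t1, inc.gain, s=18, label="included")
        if len(exc):
            ax.scatter(exc.w_t1, exc.gain, s=18, marker="x", label="round 1 (excluded)")
        xs = np.linspace(0, 1, 50)
        ax.plot(xs, self.regression.intercept + self.regression.slope * xs, "k-")
        ax.set_xlabel("winner proportion at start of phase 2")
        ax.set_ylabel("gain (Δ logit / h)")
        ax.legend()
        return ax

    def plot_trajectory(self, w0: float = 0.25, ax=None):
        """Fitted-model population sizes from a mixed seeding (log scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sched = self.result.schedule
        times = np.linspace(0.5, sched.t_end, 200)
        tr = self.simulate(w0, times)
        ax.semilogy(tr.t, tr.L, label="loser (168)")
        ax.semilogy(tr.t, tr.W, label="winner (4T07)")
        for t in (sched.t1, sched.t2):
            ax.axvline(t, ls="--", c="gray", lw=0.8)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("normalized population size")
        ax.legend()
        return ax
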