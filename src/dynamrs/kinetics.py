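"""Kinetic trace extraction and model fitting.

Glucose kinetics are analysed piecewise on the C1 resonance at 98 ppm (the
only peak assignable uniquely to glucose): an exponential transport function

    S(t) = S_total (1 - B exp(-k_trans t)),   t < t0   (t0 ~ 5 min)

captures perfusion plus import during the bolus, and after complete bolus
passage (t > 5 t0 ~ 25 min) the signal decays through multiple parallel
first-order pathways whose summed rate is reported as glucose *utilization*:

    S(t) = A exp(-k_util t),   k_util = sum_i k_i.

Lactate is handled the same way without a transport term, via the
saturating-rise model ``L(t) = L_max (1 - exp(-r t))`` at 23 ppm; ``r`` is
the lactate *formation* rate (the time-dependent change of lactate in the
field of view).

Hyperpolarized pyruvate uses the two-pool unidirectional flux model with
equal effective relaxation times and Lac(0) = 0:

    Pyr(t) = Pyr(0) exp(-(k + 1/T1) t)
    Lac(t) = Pyr(0) (exp(-t/T1) - exp(-(k + 1/T1) t))

All fits are bounded nonlinear least squares with three data-derived starting
points (ties broken by lowest residual, then smallest rate); confidence
intervals come from the asymptotic covariance of the Jacobian.  Model classes
follow the scikit-learn estimator protocol (``fit(t, y)``, fitted attributes
with trailing underscores); the ``fit_*`` functions are thin wrappers that
return the result dataclasses.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .datatypes import GlucoseFit, KineticTrace, PeakWindow, PyruvateFit, SpectrumSeries

__all__ = [
    "integrate_peak",
    "GlucoseUptakeModel",
    "GlucoseUtilizationModel",
    "LactateFormationModel",
    "PyruvateTwoPoolModel",
    "fit_glucose_uptake",
    "fit_glucose_utilization",
    "fit_lactate_formation",
    "fit_pyruvate_two_pool",
    "glucose_lactate_ratio",
    "auc_ratio",
    "GLUCOSE_WINDOW",
    "LACTATE_WINDOW",
]

GLUCOSE_WINDOW = PeakWindow("glucose", 98.0, 1.5)
LACTATE_WINDOW = PeakWindow("lactate", 23.0, 1.5)


def integrate_peak(spec: SpectrumSeries, window: PeakWindow) -> KineticTrace:
    """Per-frame trapezoidal integral of the real (or magnitude) spectrum
    over a ppm window."""
    sel = spec.window(window.center, window.half_width)
    vals = spec.real_part()[:, sel]
    ppm = spec.ppm[sel]
    # descending axis: integrate against increasing ppm for a positive area
    area = np.trapezoid(vals[:, ::-1], ppm[::-1], axis=1)
    return KineticTrace(window.name, spec.frame_times, area, time_unit="s", units="arb*ppm")


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def _asymptotic_ci(res, names) -> dict[str, tuple[float, float]]:
    """95% intervals from J^T J at the optimum; inf where singular."""
    m, n = res.jac.shape
    dof = max(m - n, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(n, np.inf)
    return {nm: (float(x - 1.96 * s), float(x + 1.96 * s))
            for nm, x, s in zip(names, res.x, se)}


def _multistart_ls(residual, starts, bounds, rate_index=-1):
    best = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), bounds[0], bounds[1])
        try:
            res = optimize.least_squares(residual, x0, bounds=bounds, method="trf")
        except Exception:
            continue
        if res.x is None or not np.all(np.isfinite(res.x)):
            continue
        key = (res.cost, float(res.x[rate_index]))  # lowest residual, then smallest rate
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        raise RuntimeError("all least-squares starts failed")
    return best[1]


class GlucoseUptakeModel(BaseEstimator):
    """Exponential transport fit on the early (t < t0) window.

    Fitted attributes: ``s_total_``, ``b_``, ``k_trans_`` (1/min), ``ci_``,
    ``r_squared_``, ``flags_``.
    """

    def __init__(self, t0: float = 5.0):
        self.t0 = t0

    def fit(self, t, y):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        sel = t < self.t0
        if sel.sum() < 5:
            raise ValueError(f"need >= 5 samples with t < t0={self.t0}")
        t, y = t[sel], y[sel]
        ymax = max(y.max(), 1e-12)

        def model(p):
            s, b, k = p
            return s * (1.0 - b * np.exp(-k * t))

        def residual(p):
            return model(p) - y

        b0 = np.clip(1.0 - y[0] / ymax, 0.0, 1.05)
        starts = [(ymax, b0, 0.2), (ymax, 0.9, 1.0), (1.2 * ymax, 0.5, 3.0)]
        bounds = ([1e-12, 0.0, 0.0], [np.inf, 1.05, np.inf])
        res = _multistart_ls(residual, starts, bounds)
        self.s_total_, self.b_, self.k_trans_ = map(float, res.x)
        self.ci_ = _asymptotic_ci(res, ["s_total", "b", "k_trans"])
        self.r_squared_ = _r_squared(y, model(res.x))
        self.rss_ = float(2.0 * res.cost)
        self.flags_ = ()
        if self.b_ < 1e-3:
            self.flags_ = ("k_trans_unidentifiable",)
        return self


class GlucoseUtilizationModel(BaseEstimator):
    """Single-exponential decay fit after bolus passage (t > t_start).

    ``k_util_`` is the summed first-order loss rate in 1/min.
    """

    def __init__(self, t_start: float = 25.0):
        self.t_start = t_start

    def fit(self, t, y):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        sel = t > self.t_start
        if sel.sum() < 5:
            raise ValueError(f"need >= 5 samples with t > t_start={self.t_start}")
        t, y = t[sel], y[sel]
        self.flags_ = ()
        scale = float(np.max(np.abs(y)))
        if scale == 0.0 or float(np.std(y)) <= 1e-12 * scale:
            # perfectly flat trace: zero decay by definition
            self.amplitude_ = float(np.mean(y))
            self.k_util_ = 0.0
            self.ci_ = {}
            self.r_squared_ = 1.0
            self.rss_ = 0.0
            self.flags_ = ("constant_trace",)
            return self

        def model(p):
            a, k = p
            return a * np.exp(-k * t)

        def residual(p):
            return model(p) - y

        # log-linear initial rate where the trace is positive
        pos = y > 0
        if pos.sum() >= 2:
            slope = -np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        else:
            slope = 0.01
        k0 = float(np.clip(slope, 1e-6, 10.0))
        a0 = float(y[0] * np.exp(k0 * t[0])) if y[0] > 0 else scale
        starts = [(a0, k0), (scale, 0.01), (scale, 0.1)]
        bounds = ([1e-12, 0.0], [np.inf, np.inf])
        res = _multistart_ls(residual, starts, bounds)
        self.amplitude_, self.k_util_ = map(float, res.x)
        self.ci_ = _asymptotic_ci(res, ["amplitude", "k_util"])
        self.r_squared_ = _r_squared(y, model(res.x))
        self.rss_ = float(2.0 * res.cost)
        return self


class LactateFormationModel(BaseEstimator):
    """Saturating-rise fit ``L_max (1 - exp(-r t))``; ``rate_`` in 1/min."""

    def fit(self, t, y):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.size < 5:
            raise ValueError("need >= 5 samples")
        self.flags_ = ()
        scale = float(np.max(np.abs(y)))
        if scale == 0.0:
            self.l_max_ = 0.0
            self.rate_ = 0.0
            self.ci_ = {}
            self.r_squared_ = 1.0
            self.rss_ = 0.0
            self.flags_ = ("zero_trace",)
            return self
        if y[-1] < y[0]:
            self.flags_ = ("non_monotone_trace",)

        def model(p):
            lm, r = p
            return lm * (1.0 - np.exp(-r * t))

        def residual(p):
            return model(p) - y

        lm0 = float(np.max(y))
        # initial rate from the earliest rise
        r0 = float(np.clip((y[1] - y[0]) / (lm0 * (t[1] - t[0]) + 1e-12), 1e-4, 10.0))
        starts = [(lm0, r0), (lm0, 0.05), (1.5 * lm0, 0.01)]
        bounds = ([0.0, 0.0], [np.inf, np.inf])
        res = _multistart_ls(residual, starts, bounds)
        self.l_max_, self.rate_ = map(float, res.x)
        self.ci_ = _asymptotic_ci(res, ["l_max", "rate"])
        self.r_squared_ = _r_squared(y, model(res.x))
        self.rss_ = float(2.0 * res.cost)
        return self


class PyruvateTwoPoolModel(BaseEstimator):
    """Joint fit of the two-pool unidirectional pyruvate->lactate model.

    ``fit(t, y)`` takes ``y`` of shape (n, 2) with columns (pyruvate,
    lactate).  Fitted attributes: ``pyr0_``, ``k_`` (1/s), ``t1_`` (s),
    ``decay_rate_`` (= k + 1/T1, exactly), ``ci_``, ``r_squared_``.

    ``k_scaled_form=True`` fits the alternative form with both pools scaled
    by ``k``.
    """

    def __init__(self, k_scaled_form: bool = False):
        self.k_scaled_form = k_scaled_form

    def _model(self, t, p):
        pyr0, k, t1 = p
        rtot = k + 1.0 / t1
        pyr = pyr0 * np.exp(-rtot * t)
        lac = pyr0 * (np.exp(-t / t1) - np.exp(-rtot * t))
        if self.k_scaled_form:
            pyr, lac = k * pyr, k * lac
        return pyr, lac

    def fit(self, t, y):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be (n, 2): pyruvate and lactate columns")
        pyr, lac = y[:, 0], y[:, 1]

        def residual(p):
            mp, ml = self._model(t, p)
            return np.concatenate([mp - pyr, ml - lac])

        pyr0_0 = max(float(pyr.max()), 1e-9)
        pos = pyr > 0.05 * pyr0_0
        if pos.sum() >= 2:
            rtot0 = float(np.clip(-np.polyfit(t[pos], np.log(pyr[pos]), 1)[0], 1e-4, 10.0))
        else:
            rtot0 = 0.05
        starts = [
            (pyr0_0, 0.1 * rtot0, 1.0 / (0.9 * rtot0)),
            (pyr0_0, 0.5 * rtot0, 1.0 / (0.5 * rtot0)),
            (pyr0_0, 0.9 * rtot0, 1.0 / (0.1 * rtot0)),
        ]
        bounds = ([1e-12, 0.0, 1e-3], [np.inf, np.inf, np.inf])
        res = _multistart_ls(residual, starts, bounds, rate_index=1)
        self.pyr0_, self.k_, self.t1_ = map(float, res.x)
        self.flags_ = ()
        if res.active_mask is not None and np.any(res.active_mask != 0):
            self.flags_ = ("parameter_at_bound",)
        self.ci_ = _asymptotic_ci(res, ["pyr0", "k", "t1"])
        mp, ml = self._model(t, res.x)
        self.r_squared_ = _r_squared(np.concatenate([pyr, lac]), np.concatenate([mp, ml]))
        return self

    @property
    def decay_rate_(self) -> float:
        return self.k_ + 1.0 / self.t1_


# ----------------------------------------------------------------------------
# functional wrappers
# ----------------------------------------------------------------------------

def fit_glucose_uptake(trace: KineticTrace, t0: float = 5.0) -> GlucoseFit:
    """Fit the transport model on ``t < t0`` (times in minutes)."""
    tr = trace.in_minutes()
    m = GlucoseUptakeModel(t0=t0).fit(tr.times, tr.values)
    return GlucoseFit(
        s_total=m.s_total_, b=m.b_, k_trans=m.k_trans_, t0=t0,
        ci=m.ci_, r_squared=m.r_squared_, rss=m.rss_, flags=m.flags_,
    )


def fit_glucose_utilization(trace: KineticTrace, t_start: float = 25.0) -> GlucoseFit:
    """Fit the first-order utilization decay on ``t > t_start`` (minutes)."""
    tr = trace.in_minutes()
    m = GlucoseUtilizationModel(t_start=t_start).fit(tr.times, tr.values)
    return GlucoseFit(
        s_total=m.amplitude_ if m.amplitude_ > 0 else None,
        k_util=m.k_util_, ci=m.ci_, r_squared=m.r_squared_, rss=m.rss_, flags=m.flags_,
    )


def fit_lactate_formation(trace: KineticTrace) -> tuple[float, float, GlucoseFit]:
    """Fit the lactate appearance model; returns ``(rate, l_max, fit_info)``."""
    tr = trace.in_minutes()
    m = LactateFormationModel().fit(tr.times, tr.values)
    info = GlucoseFit(
        s_total=m.l_max_ if m.l_max_ > 0 else None,
        k_util=m.rate_, ci=m.ci_, r_squared=m.r_squared_, rss=m.rss_, flags=m.flags_,
    )
    return m.rate_, m.l_max_, info


def fit_pyruvate_two_pool(
    pyr: KineticTrace,
    lac: KineticTrace,
    k_scaled_form: bool = False,
) -> PyruvateFit:
    """Joint two-pool fit of aligned pyruvate and lactate traces (seconds)."""
    if pyr.times.size != lac.times.size or not np.allclose(pyr.times, lac.times):
        raise ValueError("pyruvate and lactate traces must share a time grid")
    m = PyruvateTwoPoolModel(k_scaled_form=k_scaled_form).fit(
        pyr.times, np.column_stack([pyr.values, lac.values])
    )
    ratios = {"lactate/pyruvate": auc_ratio(lac, pyr)}
    return PyruvateFit(
        pyr0=m.pyr0_, k=m.k_, t1=m.t1_, auc_ratios=ratios,
        ci=m.ci_, r_squared=m.r_squared_, flags=m.flags_,
    )


def _common_support(a: KineticTrace, b: KineticTrace) -> np.ndarray:
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    if hi <= lo:
        raise ValueError("traces share no common time support")
    return np.asarray([lo, hi])


def glucose_lactate_ratio(glucose: KineticTrace, lactate: KineticTrace) -> float:
    """Time-averaged glucose to lactate ratio over the shared window."""
    lo, hi = _common_support(glucose, lactate)

    def mean_on(tr):
        sel = (tr.times >= lo) & (tr.times <= hi)
        t, v = tr.times[sel], tr.values[sel]
        if t.size < 2:
            raise ValueError("too few samples in the shared window")
        return np.trapezoid(v, t) / (t[-1] - t[0])

    denom = mean_on(lactate)
    if denom == 0:
        raise ZeroDivisionError("lactate time average is zero")
    return float(mean_on(glucose) / denom)


def auc_ratio(metabolite: KineticTrace, pyruvate: KineticTrace) -> float:
    """Ratio of trapezoidal areas under the curves on the shared window.

    For the two-pool model this converges to ``k * T1`` as the acquisition
    window grows (the integrated-rate-equation estimate of conversion in the
    absence of lactate efflux or back-conversion).
    """
    lo, hi = _common_support(metabolite, pyruvate)

    def area(tr):
        sel = (tr.times >= lo) & (tr.times <= hi)
        return np.trapezoid(tr.values[sel], tr.times[sel])

    denom = area(pyruvate)
    if denom == 0:
        raise ZeroDivisionError("pyruvate AUC is zero")
    return float(area(metabolite) / denom)
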