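"""Empirical mathematical model (EMM) of hepatic contrast enhancement.

The EMM describes the signal-time course of a hepatocyte-specific
contrast agent (e.g. Gd-EOB-DTPA) in liver parenchyma as

    C(t) = A * (1 - exp(-alpha*t))**q * exp(-beta*t) * (1 + exp(-gamma*t)) / 2

with ``t`` in minutes after contrast injection.  ``A`` is the upper limit
of enhancement (arbitrary signal units), ``alpha`` the contrast-uptake
rate (1/min), ``beta`` the wash-out rate (1/min), ``gamma`` the initial
wash-out rate (1/min) and ``q`` a dimensionless shape exponent governing
the early-uptake slope and the uptake-to-wash-out transition.

This module is pure curve mathematics: model evaluation, the time of
peak enhancement, and the model-side reference integral.  Fitting and
sampled-data quantities live in :mod:`hepamri.dce`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = ["EMMParams", "NoFinitePeakError", "emm_value", "emm_tpeak", "emm_auc"]

#: open-bound epsilon used when validating strictly positive parameters
PARAM_EPS = 1e-9

#: upper end of the peak-search bracket, minutes (span of the acquisition)
TPEAK_BRACKET_MAX = 90.0


class NoFinitePeakError(ValueError):
    """The enhancement curve has no interior maximum on the search bracket."""


@dataclass(frozen=True)
class EMMParams:
    """The five EMM coefficients of one fitted enhancement curve.

    Attributes
    ----------
    A : float
        Signal amplitude, arbitrary units; upper limit of enhancement.
    alpha : float
        Contrast-uptake rate, 1/min.
    beta : float
        Wash-out rate, 1/min.
    gamma : float
        Initial wash-out rate, 1/min.
    q : float
        Dimensionless shape exponent.
    """

    A: float
    alpha: float
    beta: float
    gamma: float
    q: float

    def __post_init__(self) -> None:
        if not (self.A > 0):
            raise ValueError(f"A must be > 0, got {self.A}")
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not (self.q > 0):
            raise ValueError(f"q must be > 0, got {self.q}")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "EMMParams":
        return cls(A=d["A"], alpha=d["alpha"], beta=d["beta"],
                   gamma=d["gamma"], q=d["q"])


def emm_value(params: EMMParams, t):
    """Evaluate the EMM at time(s) ``t`` (minutes since injection).

    Accepts a scalar or array ``t >= 0``; returns the same shape.
    C(0) = 0 exactly and C(t) >= 0 everywhere.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0 (minutes since injection)")
    # -expm1(-a t) = 1 - exp(-a t), accurate near t = 0
    uptake = np.power(-np.expm1(-params.alpha * t_arr), params.q)
    washout = np.exp(-params.beta * t_arr)
    initial = 0.5 * (1.0 + np.exp(-params.gamma * t_arr))
    out = params.A * uptake * washout * initial
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def _dlog_dt(params: EMMParams, t: float) -> float:
    """d/dt of log C(t) for t > 0; positive while rising, negative past the peak."""
    a, b, g, q = params.alpha, params.beta, params.gamma, params.q
    # q*a*exp(-a t)/(1-exp(-a t)) = q*a/expm1(a t)
    term_up = q * a / np.expm1(a * t)
    term_init = g / (np.exp(g * t) + 1.0) if g > 0 else 0.0
    return term_up - b - term_init


def emm_tpeak(params: EMMParams, bracket: tuple[float, float] = (1e-6, TPEAK_BRACKET_MAX)) -> float:
    """Time of maximal enhancement, minutes after injection.

    Computed as the root of d(log C)/dt by bracketed root-finding on
    ``bracket`` (the log-derivative is strictly decreasing from +inf, so
    the root is the unique interior maximum).  For gamma = 0 this equals
    the closed form (1/alpha)*ln(1 + q*alpha/beta).

    Raises
    ------
    NoFinitePeakError
        If the curve is non-decreasing on the bracket (e.g. beta = 0 and
        gamma = 0: the curve rises monotonically towards A).
    """
    lo, hi = bracket
    if params.beta == 0 and params.gamma == 0:
        raise NoFinitePeakError("no finite peak: curve is monotonically increasing")
    g_hi = _dlog_dt(params, hi)
    if g_hi >= 0:
        raise NoFinitePeakError(
            f"no finite peak on [{lo}, {hi}] min: curve still rising at {hi} min")
    g_lo = _dlog_dt(params, lo)
    if g_lo <= 0:
        # peak earlier than the bracket floor; clamp to the floor
        return lo
    return float(brentq(lambda t: _dlog_dt(params, t), lo, hi,
                        xtol=1e-12, rtol=8.9e-16))


def emm_auc(params: EMMParams, t_end: float) -> float:
    """Reference integral of the model, ∫₀^t_end C(t) dt, signal·min.

    Adaptive quadrature to 1e-8 relative tolerance.  The pipeline-side
    AUC on sampled data (trapezoid on measurements) lives in
    :mod:`hepamri.dce`.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    val, _ = quad(lambda t: emm_value(params, t), 0.0, t_end,
                  epsrel=1e-8, epsabs=0.0, limit=200)
    return float(val)


def tpeak_closed_form_gamma0(params: EMMParams) -> float:
    """Closed-form peak time for gamma = 0: (1/alpha)*ln(1 + q*alpha/beta)."""
    if params.beta <= 0:
        raise NoFinitePeakError("closed form requires beta > 0")
    return float(np.log1p(params.q * params.alpha / params.beta) / params.alpha)
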