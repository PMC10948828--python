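"""Sample-level imputation rules and point estimators.

Given a partially observed SRSWOR sample — ``r`` responding (y, x) pairs,
``n - r`` nonresponding units with observed x only, and the known auxiliary
population mean Xbar — each method defines a per-unit imputation recipe
``y_.i`` (observed y kept or transformed for respondents, a model-based value
substituted for nonrespondents) whose completed-sample mean IS the method's
closed-form point estimator:

    t = (1/n) [ sum_R y_.i + sum_{R^c} y~_i ].

That identity is the defining contract of :func:`impute` and holds to
floating-point accuracy for every method with an imputation rule.  The
regression-type estimators t3/t4/t5 are defined only as point estimators (no
per-unit rule); :func:`impute` returns an estimator-only result flagged
``no_imputation_rule`` for them.

Tuning constants (lam, beta_exp, alpha, delta, m, kappa1, kappa2) may be
passed explicitly, or resolved as plug-ins of the optimal values from a
:class:`~imputemean.params.PopulationParams` (the design used by the Monte
Carlo study, where the true moments of the simulated population are known).
Estimating them from the respondents themselves is available through
:func:`respondent_plugin_constants` and is an explicit opt-in: it is not the
behaviour any of the closed-form theory describes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .params import DesignParams, PopulationParams
from .theory import ESTIMATORS, UndefinedConstantError, optimal_constants

#: Methods with a per-unit imputation rule (everything but t3/t4/t5).
RULE_METHODS: tuple[str, ...] = (
    "t0", "tr", "t1", "t2", "t6", "t7", "t8", "t9", "t10", "tp",
)

#: Required tuning-constant names per method.
REQUIRED_CONSTANTS: dict[str, tuple[str, ...]] = {
    "t1": ("lam",),
    "t2": ("beta_exp",),
    "t6": ("alpha",),
    "t7": ("alpha",),
    "t8": ("delta",),
    "t9": ("m",),
    "t10": ("alpha",),
    "tp": ("kappa1", "kappa2"),
}


class DegenerateSampleError(ZeroDivisionError):
    """A method's denominator vanishes on this sample configuration."""

    def __init__(self, method: str, detail: str):
        self.method = method
        super().__init__(f"{method}: degenerate configuration ({detail})")


@dataclass(frozen=True)
class SampleData:
    """A partially observed sample: respondents, nonrespondent x, known Xbar.

    The closed-form theory assumes x > 0 for every sampled unit, enforced by
    default.  ``require_positive_x=False`` relaxes the check (used by the
    Monte Carlo engine, whose normal superpopulation with a large auxiliary
    coefficient of variation inevitably realizes some negative x); the
    per-method denominator guards still apply.
    """

    y_resp: np.ndarray
    x_resp: np.ndarray
    x_nonresp: np.ndarray
    Xbar: float
    require_positive_x: bool = True

    def __post_init__(self) -> None:
        y = np.asarray(self.y_resp, dtype=float)
        xr = np.asarray(self.x_resp, dtype=float)
        xm = np.asarray(self.x_nonresp, dtype=float)
        object.__setattr__(self, "y_resp", y)
        object.__setattr__(self, "x_resp", xr)
        object.__setattr__(self, "x_nonresp", xm)
        if y.size < 1:
            raise ValueError("need at least one respondent")
        if y.size != xr.size:
            raise ValueError("y_resp and x_resp must be paired (equal length)")
        if self.require_positive_x and (np.any(xr <= 0) or np.any(xm <= 0)):
            raise ValueError("auxiliary values must be positive for all sampled units")

    @property
    def r(self) -> int:
        return int(self.y_resp.size)

    @property
    def n(self) -> int:
        return int(self.y_resp.size + self.x_nonresp.size)

    @property
    def ybar_r(self) -> float:
        return float(self.y_resp.mean())

    @property
    def xbar_r(self) -> float:
        return float(self.x_resp.mean())

    @property
    def xbar_n(self) -> float:
        # mean over all n sampled auxiliary values (respondents + nonrespondents)
        return float(
            (self.x_resp.sum() + self.x_nonresp.sum()) / self.n
        )


@dataclass(frozen=True)
class CompletedSample:
    """Result of applying an imputation rule to a sample.

    ``y_completed`` lists respondent entries first (possibly transformed by
    the rule) then the imputed nonrespondent entries, matching ``provenance``;
    it is None for estimator-only methods (t3/t4/t5).
    """

    method: str
    point_estimate: float
    constants_used: Mapping[str, float]
    y_completed: np.ndarray | None = None
    provenance: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()


def beta_hat(s: SampleData) -> float:
    """Respondent ratio-slope estimate: sum of y over sum of x among respondents."""
    denom = float(s.x_resp.sum())
    if denom == 0.0:
        raise DegenerateSampleError("beta_hat", "sum of respondent x is zero")
    return float(s.y_resp.sum()) / denom


def resolve_constants(
    method: str,
    constants: Mapping[str, float] | None = None,
    params: PopulationParams | None = None,
    design: DesignParams | None = None,
    b_sign: str = "printed_minus",
) -> dict[str, float]:
    """Merge user-supplied constants with plug-in optima from known moments.

    Explicit entries in ``constants`` win; missing required constants are
    filled from ``params`` (and ``design``, needed for tp) when given,
    otherwise a ValueError names the gap.
    """
    if method not in ESTIMATORS:
        raise ValueError(f"unknown estimator id {method!r}")
    out = dict(constants or {})
    needed = REQUIRED_CONSTANTS.get(method, ())
    missing = [k for k in needed if k not in out]
    if missing and params is not None:
        out = {**optimal_constants(method, params, d=design, b_sign=b_sign), **out}
        missing = [k for k in needed if k not in out]
    if missing:
        raise ValueError(
            f"{method} requires constant(s) {missing}; pass them explicitly or "
            "supply PopulationParams (and DesignParams for tp)"
        )
    return out


def _exp_factor(s: SampleData) -> float:
    denom = s.Xbar + s.xbar_r
    if denom == 0.0:
        raise DegenerateSampleError("exp factor", "Xbar + xbar_r is zero")
    return math.exp((s.Xbar - s.xbar_r) / denom)


def point_estimate(
    method: str,
    s: SampleData,
    constants: Mapping[str, float] | None = None,
    params: PopulationParams | None = None,
    design: DesignParams | None = None,
) -> float:
    """Closed-form value of an estimator on one sample.

    Each vanishing denominator raises a :class:`DegenerateSampleError`
    naming the method.
    """
    c = resolve_constants(method, constants, params, design)
    yb, xr, xn, Xb = s.ybar_r, s.xbar_r, s.xbar_n, s.Xbar

    if method == "t0":
        return yb
    if method == "tr":
        if xr == 0.0:
            raise DegenerateSampleError("tr", "xbar_r is zero")
        return yb / xr * xn
    if method == "t1":
        lam = c["lam"]
        if xr == 0.0:
            raise DegenerateSampleError("t1", "xbar_r is zero")
        return yb * (lam + (1.0 - lam) * xn / xr)
    if method == "t2":
        if xr == 0.0:
            raise DegenerateSampleError("t2", "xbar_r is zero")
        ratio = xn / xr
        if ratio <= 0.0:
            raise DegenerateSampleError("t2", "xbar_n/xbar_r not positive (power undefined)")
        return yb * ratio ** c["beta_exp"]
    if method == "t3":
        if xr == 0.0:
            raise DegenerateSampleError("t3", "xbar_r is zero")
        return (yb + beta_hat(s) * (Xb - xr)) * Xb / xr
    if method == "t4":
        if xn == 0.0:
            raise DegenerateSampleError("t4", "xbar_n is zero")
        return (yb + beta_hat(s) * (Xb - xn)) * Xb / xn
    if method == "t5":
        if xr == 0.0:
            raise DegenerateSampleError("t5", "xbar_r is zero")
        return (yb + beta_hat(s) * (Xb - xn)) * xn / xr
    if method == "t6":
        a = c["alpha"]
        denom = a * xr + (1.0 - a) * xn
        if denom == 0.0:
            raise DegenerateSampleError("t6", "alpha*xbar_r + (1-alpha)*xbar_n is zero")
        return yb * xn / denom
    if method == "t7":
        a = c["alpha"]
        return a * yb + (1.0 - a) * yb * _exp_factor(s)
    if method == "t8":
        delta = c["delta"]
        if delta == xn:
            raise DegenerateSampleError("t8", "delta equals xbar_n")
        return yb * (delta - xr) / (delta - xn)
    if method == "t9":
        m = c["m"]
        denom = m * xn + (1.0 - m) * xr
        if denom == 0.0:
            raise DegenerateSampleError("t9", "m*xbar_n + (1-m)*xbar_r is zero")
        return yb * (m * xr + (1.0 - m) * xn) / denom
    if method == "t10":
        a = c["alpha"]
        if Xb == 0.0:
            raise DegenerateSampleError("t10", "Xbar is zero")
        return (a * yb + (1.0 - a) * yb * xr / Xb) * _exp_factor(s)
    if method == "tp":
        k1, k2 = c["kappa1"], c["kappa2"]
        if Xb == 0.0:
            raise DegenerateSampleError("tp", "Xbar is zero")
        return (k1 * yb + k2 * yb * xr / Xb) * _exp_factor(s)
    raise ValueError(f"unknown estimator id {method!r}")


def impute(
    method: str,
    s: SampleData,
    constants: Mapping[str, float] | None = None,
    params: PopulationParams | None = None,
    design: DesignParams | None = None,
) -> CompletedSample:
    """Apply an imputation rule, returning the completed sample.

    The completed-sample mean equals :func:`point_estimate` by algebraic
    identity (asserted in the test suite to 1e-10 relative over randomized
    samples).  With no nonrespondents, rules defined only on R^c reduce to
    the identity completion of the observed data.
    """
    c = resolve_constants(method, constants, params, design)
    est = point_estimate(method, s, c)
    n, r = s.n, s.r
    yb = s.ybar_r

    if method not in RULE_METHODS:
        return CompletedSample(
            method=method, point_estimate=est, constants_used=c,
            y_completed=None, provenance=(), flags=("no_imputation_rule",),
        )

    n_miss = n - r
    resp = s.y_resp.astype(float, copy=True)
    prov_resp = ["observed"] * r

    if method == "t0":
        imputed = np.full(n_miss, yb)
    elif method == "tr":
        imputed = beta_hat(s) * s.x_nonresp
    elif method == "t1":
        lam = c["lam"]
        bh = beta_hat(s)
        resp = lam * (n / r) * s.y_resp + (1.0 - lam) * bh * s.x_resp
        prov_resp = ["transformed"] * r
        imputed = (1.0 - lam) * bh * s.x_nonresp
    elif method == "t7":
        a = c["alpha"]
        shrink = (1.0 - a) * yb * _exp_factor(s)
        resp = a * (n / r) * s.y_resp + shrink
        prov_resp = ["transformed"] * r
        imputed = np.full(n_miss, shrink)
    elif method in ("t2", "t6", "t8", "t9"):
        # proportional-to-x rules: the bracketed total n*t - r*ybar_r is
        # spread over R^c with weights x_i / sum_{R^c} x_j
        if n_miss > 0:
            x_sum = float(s.x_nonresp.sum())
            if x_sum <= 0.0:
                raise DegenerateSampleError(method, "sum of nonrespondent x is not positive")
            imputed = (n * est - r * yb) * s.x_nonresp / x_sum
        else:
            imputed = np.empty(0)
    else:  # t10, tp: equal-share rule on R^c
        if n_miss > 0:
            imputed = np.full(n_miss, (n * est - r * yb) / n_miss)
        else:
            imputed = np.empty(0)

    flags: tuple[str, ...] = ()
    if n_miss == 0 and method in ("t10", "tp"):
        # R^c-only rules with no missing units: identity completion of the
        # observed data; its mean is ybar_r, not the closed-form compromise
        flags = ("identity_completion",)

    y_completed = np.concatenate([resp, imputed])
    provenance = tuple(prov_resp + ["imputed"] * n_miss)
    return CompletedSample(
        method=method, point_estimate=est, constants_used=c,
        y_completed=y_completed, provenance=provenance, flags=flags,
    )
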