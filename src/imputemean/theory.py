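"""First-order bias/MSE theory for imputation-based mean estimators.

Thirteen estimators of the population mean Ybar are covered, labelled by the
identifiers ``t0, tr, t1, ..., t10, tp``:

====  =============================================================
id    estimator
====  =============================================================
t0    respondent mean (mean imputation)
tr    ratio estimator, ratio imputation
t1    Singh–Horn compromised imputation (constant ``lam``)
t2    Singh–Deo power-transformed ratio (exponent ``beta_exp``)
t3–t5 Kadilar–Cingi regression-type estimators
t6    Singh weighted-denominator ratio (constant ``alpha``)
t7    exponential-ratio compromise (constant ``alpha``)
t8    Gira shifted-ratio (constant ``delta``)
t9    Singh et al. symmetric-weight ratio (constant ``m``)
t10   Aliyu et al. exponential-product compromise (constant ``alpha``)
tp    Searls-type two-constant exponential estimator (``kappa1, kappa2``)
====  =============================================================

The source expressions for several estimators are internally inconsistent:
evaluated literally they can return negative "MSEs" and disagree with the
reference numerical tables they accompany.  Two theory modes are therefore
provided:

``as_printed``
    the literal published formulas, with negative results flagged rather than
    silently returned;
``table_consistent``
    the repaired formulas (default), under which the published numerical
    tables reproduce to two decimals.  The repairs are: theta_rN on the Cy^2
    term of MSE(tr) and MSE_min(t1); base V(t0) + <term> for t3/t4/t5; and
    MSE_min(t2) = MSE_min(t6) = MSE_min(t7) = MSE_min(t10) = MSE_min(t1).

The Searls estimator's quadratic MSE form carries an analogous ambiguity in
the sign of its ``B`` scalar (``b_sign``) and in the closed-form minimum
(``stationary`` vs ``literal``); see :func:`searls_coefficients` and
:func:`min_mse_tp`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import DesignParams, ParameterError, PopulationParams

#: Closed enumeration of estimator identifiers.
ESTIMATORS: tuple[str, ...] = (
    "t0", "tr", "t1", "t2", "t3", "t4", "t5",
    "t6", "t7", "t8", "t9", "t10", "tp",
)

#: Valid theory modes.
THEORY_MODES: tuple[str, ...] = ("as_printed", "table_consistent")

#: Valid signs for the Searls B scalar.
B_SIGNS: tuple[str, ...] = ("printed_minus", "expansion_plus")

#: Valid minimum-MSE formulas for tp.
MIN_MSE_FORMULAS: tuple[str, ...] = ("stationary", "literal")

#: Estimators whose profile MSE is a quadratic in a single tuning constant.
TUNABLE: tuple[str, ...] = ("t1", "t2", "t6", "t7", "t9", "t10")


class SingularSystemError(ArithmeticError):
    """The Searls normal equations are singular (M = AB - C^2 = 0)."""


class UndefinedConstantError(ValueError):
    """An optimal tuning constant is undefined for the given parameters."""


def _check_estimator(est: str) -> str:
    if est not in ESTIMATORS:
        raise ValueError(f"unknown estimator id {est!r}; expected one of {ESTIMATORS}")
    return est


def _check_mode(mode: str) -> str:
    if mode not in THEORY_MODES:
        raise ValueError(f"unknown theory mode {mode!r}; expected one of {THEORY_MODES}")
    return mode


@dataclass(frozen=True)
class SearlsCoefficients:
    """Scalars of the Searls estimator's quadratic MSE form.

    MSE(tp)/Ybar^2 = 1 + k1^2 A + k2^2 B + 2 k1 k2 C - 2 k1 D - 2 k2 F.

    ``M = AB - C^2`` is the determinant of the coefficient matrix
    ``[[A, C], [C, B]]``; ``u = BD - CF`` and ``v = AF - DC`` are the adjugate
    products so that the stationary point is ``(kappa1, kappa2) = (u/M, v/M)``.

    ``b_sign`` records which definition of B was used: the literal published
    one (``printed_minus``, ``B = 1 + theta_rN (Cy^2 - 2 Cyx)``) or the one
    implied by the underlying series expansion (``expansion_plus``,
    ``+ 2 Cyx``).  Note the printed sign makes the matrix indefinite for
    typical positively correlated populations, so the stationary point is a
    saddle of the printed quadratic.
    """

    A: float
    B: float
    C: float
    D: float
    F: float
    b_sign: str
    M: float = field(init=False)
    u: float = field(init=False)
    v: float = field(init=False)
    kappa1: float | None = field(init=False)
    kappa2: float | None = field(init=False)

    def __post_init__(self) -> None:
        M = self.A * self.B - self.C**2
        u = self.B * self.D - self.C * self.F
        v = self.A * self.F - self.D * self.C
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)
        if M == 0.0:
            object.__setattr__(self, "kappa1", None)
            object.__setattr__(self, "kappa2", None)
        else:
            object.__setattr__(self, "kappa1", u / M)
            object.__setattr__(self, "kappa2", v / M)

    @property
    def is_positive_definite(self) -> bool:
        """True when [[A, C], [C, B]] is positive definite (true minimum)."""
        return self.A > 0 and self.M > 0

    def require_nonsingular(self) -> None:
        if self.M == 0.0:
            raise SingularSystemError(
                "Searls normal equations are singular (M = AB - C^2 = 0); "
                "kappa1/kappa2 are undefined"
            )


@dataclass(frozen=True)
class TheoryResult:
    """Theoretical MSE (and optionally bias) of one estimator."""

    estimator: str
    mse: float
    mode: str
    optimal_constants: Mapping[str, float]
    bias: float | None = None
    flags: tuple[str, ...] = ()

    @property
    def is_negative(self) -> bool:
        return "negative_mse" in self.flags


def searls_coefficients(
    p: PopulationParams, d: DesignParams, b_sign: str = "printed_minus"
) -> SearlsCoefficients:
    """Compute the Searls scalars A, B, C, D, F and solve for (kappa1, kappa2).

    Raises :class:`SingularSystemError` through ``require_nonsingular`` only
    when the kappas are demanded; a census design (theta_rN = 0) yields the
    degenerate A = B = C = D = F = 1, M = 0 with the kappas left unset.
    """
    if b_sign not in B_SIGNS:
        raise ValueError(f"unknown b_sign {b_sign!r}; expected one of {B_SIGNS}")
    th = d.theta_rN
    Cy2, Cx2, Cyx = p.Cy**2, p.Cx**2, p.Cyx
    A = 1.0 + th * (Cy2 + Cx2 - 2.0 * Cyx)
    if b_sign == "printed_minus":
        B = 1.0 + th * (Cy2 - 2.0 * Cyx)
    else:
        B = 1.0 + th * (Cy2 + 2.0 * Cyx)
    C = 1.0 + th * Cy2
    D = 1.0 - 0.5 * th * Cyx + 0.375 * th * Cx2
    F = 1.0 - 0.5 * th * Cyx - 0.125 * th * Cx2
    return SearlsCoefficients(A=A, B=B, C=C, D=D, F=F, b_sign=b_sign)


def mse_tp_at(kappa1: float, kappa2: float, c: SearlsCoefficients, Ybar: float) -> float:
    """Evaluate the Searls quadratic MSE form at an arbitrary (kappa1, kappa2)."""
    return Ybar**2 * (
        1.0
        + kappa1**2 * c.A
        + kappa2**2 * c.B
        + 2.0 * kappa1 * kappa2 * c.C
        - 2.0 * kappa1 * c.D
        - 2.0 * kappa2 * c.F
    )


def min_mse_tp(c: SearlsCoefficients, Ybar: float, formula: str = "stationary") -> float:
    """Minimum (stationary-point) MSE of the Searls estimator.

    ``formula="stationary"`` (default) returns Ybar^2 [1 - (D u + F v)/M],
    the exact value of the quadratic at the solved optimum.  The published
    closed form Ybar^2 [1 - L/M^2] (``formula="literal"``) algebraically
    equals Ybar^2 [1 - t(2 - M)] with t = (D u + F v)/M and so coincides with
    the stationary value only when M = 1; it is retained for audit.
    """
    if formula not in MIN_MSE_FORMULAS:
        raise ValueError(f"unknown formula {formula!r}; expected one of {MIN_MSE_FORMULAS}")
    c.require_nonsingular()
    if formula == "stationary":
        return Ybar**2 * (1.0 - (c.D * c.u + c.F * c.v) / c.M)
    L = (
        2.0 * c.v * c.F
        + 2.0 * c.u * c.D
        - 2.0 * c.u * c.v * c.C
        - c.u**2 * c.A
        - c.v**2 * c.B
    )
    return Ybar**2 * (1.0 - L / c.M**2)


def optimal_constants(
    est: str,
    p: PopulationParams,
    d: DesignParams | None = None,
    b_sign: str = "printed_minus",
) -> dict[str, float]:
    """Optimal tuning constants of an estimator, from population moments.

    Returns an empty map for the constant-free estimators (t0, tr, t3, t4,
    t5).  For ``tp`` the kappas depend on the design fractions, so ``d`` is
    required.  ``t8``'s delta is undefined at rho = 0.
    """
    _check_estimator(est)
    Cy, Cx, rho, Cyx = p.Cy, p.Cx, p.rho, p.Cyx
    if est == "t1":
        return {"lam": 1.0 - Cyx / Cx**2}
    if est == "t2":
        return {"beta_exp": rho * Cy / Cx}
    if est == "t6":
        return {"alpha": rho * Cy / Cx}
    if est == "t7":
        return {"alpha": 1.0 - 2.0 * Cyx / Cx**2}
    if est == "t8":
        if rho == 0.0:
            raise UndefinedConstantError(
                "delta for t8 is undefined at rho = 0 (division by rho*Cy)"
            )
        return {"delta": p.Xbar * (Cx / (rho * Cy) - 1.0)}
    if est == "t9":
        return {"m": 0.5 * (1.0 - rho * Cy / Cx)}
    if est == "t10":
        return {"alpha": 0.5 + rho * Cy / Cx}
    if est == "tp":
        if d is None:
            raise ValueError("tp optimal constants require DesignParams")
        c = searls_coefficients(p, d, b_sign=b_sign)
        c.require_nonsingular()
        return {"kappa1": c.kappa1, "kappa2": c.kappa2}
    return {}


def _v_t0(p: PopulationParams, d: DesignParams) -> float:
    return d.theta_rN * p.Ybar**2 * p.Cy**2


def _mse_min_t1(p: PopulationParams, d: DesignParams) -> float:
    return p.Ybar**2 * p.Cy**2 * (d.theta_rN - d.theta_rn * p.rho**2)


def _ratio_gap_term(p: PopulationParams, d: DesignParams) -> float:
    # theta_rn * Sx^2 * (beta - R)^2, the subtracted term of the literal
    # t2/t6/t7 minimum-MSE displays
    return d.theta_rn * p.Sx2 * (p.beta - p.R) ** 2


def theoretical_mse(
    est: str,
    p: PopulationParams,
    d: DesignParams,
    mode: str = "table_consistent",
    b_sign: str = "printed_minus",
    min_mse_formula: str = "stationary",
) -> TheoryResult:
    """First-order (minimum) MSE of an estimator at its optimal constants.

    In ``as_printed`` mode the literal published expressions are evaluated;
    a negative value is returned carrying the ``negative_mse`` flag (and a
    warning), never silently fed into efficiency ratios.
    """
    _check_estimator(est)
    _check_mode(mode)
    Yb = p.Ybar
    th_rN, th_rn, th_nN = d.theta_rN, d.theta_rn, d.theta_nN
    Cy2, Cx2, Cyx = p.Cy**2, p.Cx**2, p.Cyx
    flags: list[str] = []
    constants: dict[str, float] = {}

    if est == "t0":
        mse = _v_t0(p, d)
    elif est == "tr":
        if mode == "as_printed":
            mse = th_rn * Yb**2 * (Cy2 + Cx2 - 2.0 * Cyx)
        else:
            mse = Yb**2 * (th_rN * Cy2 + th_rn * (Cx2 - 2.0 * Cyx))
    elif est in ("t1", "t8", "t9"):
        mse = _mse_min_t1(p, d)
        try:
            constants = optimal_constants(est, p)
        except UndefinedConstantError:
            # t8's delta is undefined at rho = 0; the MSE value itself is not
            constants = {}
            flags.append("constant_undefined")
    elif est in ("t2", "t6", "t7"):
        constants = optimal_constants(est, p)
        if mode == "as_printed":
            mse = _mse_min_t1(p, d) - _ratio_gap_term(p, d)
        else:
            mse = _mse_min_t1(p, d)
    elif est in ("t3", "t4", "t5"):
        if est == "t3":
            term = th_rN * p.Sx2 * (p.R**2 - p.beta**2)
        elif est == "t4":
            term = th_nN * p.Sx2 * (p.R**2 - p.beta**2)
        else:
            term = th_rn * ((p.R + p.beta) ** 2 * p.Sx2 - 2.0 * (p.R + p.beta) * p.Syx)
        if mode == "as_printed":
            mse = _mse_min_t1(p, d) - term
        else:
            mse = _v_t0(p, d) + term
    elif est == "t10":
        constants = optimal_constants("t10", p)
        if mode == "as_printed":
            mse = th_rN * Yb**2 * Cy2 * (1.0 - p.rho**2)
        else:
            mse = _mse_min_t1(p, d)
    else:  # tp
        c = searls_coefficients(p, d, b_sign=b_sign)
        c.require_nonsingular()
        constants = {"kappa1": c.kappa1, "kappa2": c.kappa2}
        mse = min_mse_tp(c, Yb, formula=min_mse_formula)
        if not c.is_positive_definite:
            flags.append("saddle_point")

    if mse < 0:
        flags.append("negative_mse")
        warnings.warn(
            f"literal formula for {est} yields negative MSE ({mse:.6g}); "
            "value flagged, not usable as an MSE",
            RuntimeWarning,
            stacklevel=2,
        )
    return TheoryResult(
        estimator=est, mse=mse, mode=mode, optimal_constants=constants, flags=tuple(flags)
    )


def theoretical_bias(
    est: str,
    p: PopulationParams,
    d: DesignParams,
    constants: Mapping[str, float] | None = None,
) -> float:
    """First-order bias of an estimator at given tuning constants.

    ``constants`` must supply the estimator's constant(s) where the bias
    depends on them (``lam`` for t1, ``beta_exp`` for t2, ``alpha`` for
    t6/t7/t10, ``delta`` for t8, ``m`` for t9, ``kappa1``/``kappa2`` for tp);
    t0 is unbiased and t3/t4/t5 have constant-free biases.
    """
    _check_estimator(est)
    constants = dict(constants or {})
    Yb, Xb = p.Ybar, p.Xbar
    th_rN, th_rn, th_nN = d.theta_rN, d.theta_rn, d.theta_nN
    Cy2, Cx2, Cyx = p.Cy**2, p.Cx**2, p.Cyx

    def need(name: str) -> float:
        if name not in constants:
            raise ValueError(f"bias of {est} requires constant {name!r}")
        return float(constants[name])

    if est == "t0":
        return 0.0
    if est == "tr":
        return th_rn * Yb * (Cx2 - Cyx)
    if est == "t1":
        lam = need("lam")
        return (1.0 - lam) * th_rn * Yb * (Cx2 - Cyx)
    if est == "t2":
        b = need("beta_exp")
        return th_rn * Yb * (0.5 * b * (b - 1.0) * Cx2 - b * Cyx)
    if est == "t3":
        return th_nN * Yb * Cx2
    if est == "t4":
        return th_rN * Yb * Cx2
    if est == "t5":
        return th_rn * Yb * Cyx
    if est == "t6":
        a = need("alpha")
        return Yb * (
            th_nN * Cyx
            + a**2 * th_rn * Cx2
            + (1.0 - a) ** 2 * th_nN * Cx2
            - a * (th_rn * Cyx + th_nN * Cx2)
            + 2.0 * a * (a - 1.0) * th_nN * Cx2
            - (1.0 - a) * th_nN * (Cyx + Cx2)
        )
    if est == "t7":
        a = need("alpha")
        return (1.0 - a) * th_rN * Yb * (0.375 * Cx2 - 0.5 * Cyx)
    if est == "t8":
        delta = need("delta")
        if delta == Xb:
            raise ZeroDivisionError("bias of t8 undefined at delta = Xbar")
        return -th_rn * Xb * Yb * Cyx / (delta - Xb)
    if est == "t9":
        m = need("m")
        return th_rn * Yb * ((2.0 * m**2 - 3.0 * m + 1.0) * Cx2 + (2.0 * m - 1.0) * Cyx)
    if est == "t10":
        a = need("alpha")
        return th_rN * Yb * (-(0.125 - a) * Cx2 + (0.5 + a) * Cyx)
    # tp: the published bias display (note its kappa2 coefficient differs in
    # the Cyx sign from the MSE's F scalar; kept exactly as published)
    k1, k2 = need("kappa1"), need("kappa2")
    return Yb * (
        k1 * (1.0 - 0.5 * th_rN * Cyx + 0.375 * th_rN * Cx2)
        + k2 * (1.0 + 0.5 * th_rN * Cyx - 0.125 * th_rN * Cx2)
        - 1.0
    )


def mse_profile(
    est: str, constant: float, p: PopulationParams, d: DesignParams
) -> float:
    """Pre-optimization MSE of a tunable estimator as a function of its constant.

    These are the quadratic profiles whose minimizers are the published
    optimal constants, written with theta_rN on the Cy^2 term (the convention
    under which the minimized values reproduce the published closed forms).
    For t7 and t10 the published profiles place theta_rN on every term and
    are kept that way.
    """
    if est not in TUNABLE:
        raise ValueError(f"{est!r} has no single-constant MSE profile; tunable: {TUNABLE}")
    Yb = p.Ybar
    th_rN, th_rn = d.theta_rN, d.theta_rn
    Cy2, Cx2, Cyx = p.Cy**2, p.Cx**2, p.Cyx
    c = float(constant)
    if est == "t1":
        u = 1.0 - c
        return Yb**2 * (th_rN * Cy2 + th_rn * (u**2 * Cx2 - 2.0 * u * Cyx))
    if est == "t2":
        return Yb**2 * (th_rN * Cy2 + th_rn * (c**2 * Cx2 - 2.0 * c * Cyx))
    if est == "t6":
        return Yb**2 * (th_rN * Cy2 + th_rn * (c**2 * Cx2 - 2.0 * c * Cyx))
    if est == "t7":
        u = 1.0 - c
        return th_rN * Yb**2 * (Cy2 + 0.25 * u**2 * Cx2 - u * Cyx)
    if est == "t9":
        u = 1.0 - 2.0 * c
        return Yb**2 * (th_rN * Cy2 + th_rn * (u**2 * Cx2 - 2.0 * u * Cyx))
    # t10
    u = 0.5 - c
    return th_rN * Yb**2 * (Cy2 + u**2 * Cx2 + 2.0 * u * Cyx)


def profile_min_closed_form(est: str, p: PopulationParams, d: DesignParams) -> float:
    """Closed-form minimum of :func:`mse_profile` over the tuning constant.

    t1/t2/t6/t9 profiles minimize to Ybar^2 Cy^2 [theta_rN - theta_rn rho^2];
    the t7/t10 profiles (theta_rN throughout) minimize to
    theta_rN Ybar^2 Cy^2 (1 - rho^2).
    """
    if est not in TUNABLE:
        raise ValueError(f"{est!r} has no single-constant MSE profile")
    if est in ("t7", "t10"):
        return d.theta_rN * p.Ybar**2 * p.Cy**2 * (1.0 - p.rho**2)
    return _mse_min_t1(p, d)


def pre_percent(mse_ref: float, mse_est: float) -> float:
    """Percentage relative efficiency, 100 * MSE(reference) / MSE(candidate)."""
    if mse_est <= 0:
        raise ValueError(f"PRE undefined for nonpositive candidate MSE ({mse_est})")
    return 100.0 * mse_ref / mse_est


@dataclass(frozen=True)
class EfficiencyReport:
    """Pairwise MSE comparison of every competitor against the Searls estimator.

    ``table`` has one row per competitor with its theoretical MSE, the
    difference MSE(competitor) - MSE(tp) and a boolean ``tp_better`` which is
    true iff the difference is strictly positive.  All comparisons are made on
    actual MSE values in squared y units.
    """

    mse_tp: float
    table: pd.DataFrame
    mode: str


def efficiency_report(
    p: PopulationParams,
    d: DesignParams,
    mode: str = "table_consistent",
    b_sign: str = "printed_minus",
    min_mse_formula: str = "stationary",
) -> EfficiencyReport:
    """Evaluate the efficiency conditions of tp over all twelve competitors."""
    tp = theoretical_mse(est="tp", p=p, d=d, mode=mode, b_sign=b_sign,
                         min_mse_formula=min_mse_formula)
    rows = []
    for est in ESTIMATORS:
        if est == "tp":
            continue
        res = theoretical_mse(est=est, p=p, d=d, mode=mode)
        diff = res.mse - tp.mse
        rows.append({
            "estimator": est,
            "mse": res.mse,
            "mse_diff_vs_tp": diff,
            "tp_better": bool(diff > 0),
            "flags": ",".join(res.flags),
        })
    table = pd.DataFrame(rows).set_index("estimator")
    return EfficiencyReport(mse_tp=tp.mse, table=table, mode=mode)


def build_table(
    populations: Sequence[tuple[PopulationParams, DesignParams]],
    mode: str = "table_consistent",
    b_sign: str = "printed_minus",
    min_mse_formula: str = "stationary",
    labels: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Theoretical MSE/PRE grid over populations (reference estimator: t0).

    Returns a DataFrame indexed by estimator with a two-level column index
    (population label, {"mse", "pre"}) holding unrounded values; use
    :func:`round_table` for a two-decimal display copy.  PRE cells of flagged
    (negative) MSEs are NaN.
    """
    populations = list(populations)
    if not populations:
        raise ValueError("build_table requires at least one population")
    labels = list(labels) if labels is not None else [
        f"pop{i + 1}" for i in range(len(populations))
    ]
    if len(labels) != len(populations):
        raise ValueError("labels and populations length mismatch")
    cols: dict[tuple[str, str], list[float]] = {}
    for lab, (p, d) in zip(labels, populations):
        ref = theoretical_mse("t0", p, d, mode=mode).mse
        mses, pres = [], []
        for est in ESTIMATORS:
            res = theoretical_mse(est, p, d, mode=mode, b_sign=b_sign,
                                  min_mse_formula=min_mse_formula)
            mses.append(res.mse)
            pres.append(pre_percent(ref, res.mse) if res.mse > 0 else math.nan)
        cols[(lab, "mse")] = mses
        cols[(lab, "pre")] = pres
    return pd.DataFrame(cols, index=pd.Index(ESTIMATORS, name="estimator"))


def round_table(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Round half away from zero to ``decimals`` for display."""
    factor = 10.0**decimals
    arr = table.to_numpy(dtype=float)
    rounded = np.sign(arr) * np.floor(np.abs(arr) * factor + 0.5) / factor
    return pd.DataFrame(rounded, index=table.index, columns=table.columns)
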