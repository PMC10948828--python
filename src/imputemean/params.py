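"""Population and sampling-design parameters for finite-population mean estimation.

A finite population of ``N`` units carries a study variable ``y`` (whose mean
``Ybar`` is the estimand) and a fully known auxiliary variable ``x`` with mean
``Xbar``.  All first-order bias/MSE theory in this package is expressed through
the moment parameters (coefficients of variation ``Cy``, ``Cx``, correlation
``rho``) and through the finite-population fractions

    theta_{a,b} = 1/a - 1/b

arising from the two-phase nesting respondents (r) < sample (n) < population (N)
under SRSWOR with MCAR item nonresponse.

Variance-type quantities use the N-1 divisor (``S``-quantities), which is the
convention every closed-form expression here relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ParameterError(ValueError):
    """Raised for invalid population or design parameters."""


@dataclass(frozen=True)
class PopulationParams:
    """Moment parameters of a finite bivariate population.

    Parameters
    ----------
    N : int
        Population size (>= 2).
    Ybar, Xbar : float
        Population means of the study and auxiliary variables; ``Xbar != 0``.
    Cy, Cx : float
        Coefficients of variation ``S_y/Ybar`` and ``S_x/Xbar`` (> 0).
    rho : float
        Product-moment correlation of y and x, ``|rho| <= 1``.

    Derived attributes (populated on construction): ``Sy``, ``Sx``, ``Syx``,
    ``Cyx = rho*Cy*Cx``, the ratio ``R = Ybar/Xbar`` and the regression slope
    ``beta = Syx/Sx**2``.
    """

    N: int
    Ybar: float
    Xbar: float
    Cy: float
    Cx: float
    rho: float
    Sy: float = field(init=False)
    Sx: float = field(init=False)
    Syx: float = field(init=False)
    Cyx: float = field(init=False)
    R: float = field(init=False)
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ParameterError(f"population size N must be >= 2, got {self.N}")
        if self.Xbar == 0:
            raise ParameterError("auxiliary mean Xbar must be nonzero")
        if self.Cy <= 0 or self.Cx <= 0:
            raise ParameterError(
                f"coefficients of variation must be positive, got Cy={self.Cy}, Cx={self.Cx}"
            )
        if abs(self.rho) > 1:
            raise ParameterError(f"correlation must satisfy |rho| <= 1, got {self.rho}")
        Sy = self.Cy * self.Ybar
        Sx = self.Cx * self.Xbar
        Syx = self.rho * Sy * Sx
        object.__setattr__(self, "Sy", Sy)
        object.__setattr__(self, "Sx", Sx)
        object.__setattr__(self, "Syx", Syx)
        object.__setattr__(self, "Cyx", self.rho * self.Cy * self.Cx)
        object.__setattr__(self, "R", self.Ybar / self.Xbar)
        object.__setattr__(self, "beta", Syx / Sx**2)

    @property
    def Sy2(self) -> float:
        return self.Sy**2

    @property
    def Sx2(self) -> float:
        return self.Sx**2


@dataclass(frozen=True)
class DesignParams:
    """Sample sizes and the finite-population fractions they induce.

    ``n`` units are drawn by SRSWOR from ``N``; ``r`` of them respond (MCAR).
    The three variance fractions satisfy ``theta_rN = theta_rn + theta_nN``.
    """

    N: int
    n: int
    r: int
    theta_rN: float = field(init=False)
    theta_rn: float = field(init=False)
    theta_nN: float = field(init=False)

    def __post_init__(self) -> None:
        if self.r < 2:
            raise ParameterError(f"respondent count r must be >= 2, got {self.r}")
        if self.r > self.n:
            raise ParameterError(f"r={self.r} exceeds sample size n={self.n}")
        if self.n > self.N:
            raise ParameterError(f"n={self.n} exceeds population size N={self.N}")
        object.__setattr__(self, "theta_rN", 1.0 / self.r - 1.0 / self.N)
        object.__setattr__(self, "theta_rn", 1.0 / self.r - 1.0 / self.n)
        object.__setattr__(self, "theta_nN", 1.0 / self.n - 1.0 / self.N)


def derive_params(
    N: int, Ybar: float, Xbar: float, Cy: float, Cx: float, rho: float
) -> PopulationParams:
    """Build a :class:`PopulationParams`, populating all derived moments."""
    return PopulationParams(N=N, Ybar=Ybar, Xbar=Xbar, Cy=Cy, Cx=Cx, rho=rho)


def thetas(N: int, n: int, r: int) -> DesignParams:
    """Build a :class:`DesignParams` with the three finite-population fractions."""
    return DesignParams(N=N, n=n, r=r)
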