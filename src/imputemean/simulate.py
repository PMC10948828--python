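"""Monte Carlo evaluation of the imputation estimators.

Protocol: generate one finite bivariate-normal population of size N, compute
its exact moments (these, not the generator inputs, parameterize all plug-in
constants and the target mean), then repeat m times — draw an SRSWOR sample
of size n, select r respondents completely at random (MCAR), evaluate every
estimator — and report the empirical MSE about the realized population mean
together with PRE relative to t0 and a Monte Carlo standard error.

A single seeded numpy Generator drives population generation, sampling and
response in that order, so every sub-result is reproducible from
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import DegenerateSampleError, SampleData, point_estimate, resolve_constants
from .params import DesignParams, PopulationParams, derive_params, thetas
from .theory import ESTIMATORS, theoretical_mse


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one Monte Carlo study.

    ``mu_y, mu_x`` and the 2x2 covariance (``var_y, var_x, cov_yx``)
    parameterize the bivariate-normal superpopulation; ``N, n, r`` give the
    finite-population design, ``m`` the replicate count and ``seed`` the RNG
    seed.
    """

    mu_y: float
    mu_x: float
    var_y: float
    var_x: float
    cov_yx: float
    N: int
    n: int
    r: int
    m: int
    seed: int

    def __post_init__(self) -> None:
        if self.var_y < 0 or self.var_x < 0:
            raise ValueError("variances must be nonnegative")
        if self.cov_yx**2 > self.var_y * self.var_x:
            raise ValueError("covariance matrix is not positive semidefinite")
        if not (2 <= self.r <= self.n <= self.N):
            raise ValueError(f"need 2 <= r <= n <= N, got r={self.r}, n={self.n}, N={self.N}")
        if self.m < 1:
            raise ValueError("replicate count m must be >= 1")

    @property
    def cov(self) -> np.ndarray:
        return np.array([[self.var_y, self.cov_yx], [self.cov_yx, self.var_x]])


@dataclass(frozen=True)
class FinitePopulation:
    """A realized finite population with cached exact moments."""

    y: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        x = np.asarray(self.x, dtype=float)
        if y.shape != x.shape or y.ndim != 1:
            raise ValueError("y and x must be paired 1-d arrays")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "x", x)

    @property
    def N(self) -> int:
        return int(self.y.size)

    def params(self) -> PopulationParams:
        """Exact moment parameters of the realized values (N-1 divisors)."""
        Ybar = float(self.y.mean())
        Xbar = float(self.x.mean())
        Sy = float(self.y.std(ddof=1))
        Sx = float(self.x.std(ddof=1))
        Syx = float(np.cov(self.y, self.x, ddof=1)[0, 1])
        rho = Syx / (Sy * Sx)
        return derive_params(
            N=self.N, Ybar=Ybar, Xbar=Xbar, Cy=Sy / Ybar, Cx=Sx / Xbar, rho=rho
        )


def generate_population(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> FinitePopulation:
    """Draw N paired values from the configured bivariate normal."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    draws = rng.multivariate_normal(
        mean=[cfg.mu_y, cfg.mu_x], cov=cfg.cov, size=cfg.N, method="cholesky"
    )
    return FinitePopulation(y=draws[:, 0], x=draws[:, 1])


def draw_srswor(pop: FinitePopulation, n: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct unit indices, uniform over size-n subsets (SRSWOR)."""
    if n > pop.N:
        raise ValueError(f"sample size n={n} exceeds population size N={pop.N}")
    return rng.choice(pop.N, size=n, replace=False)


def mcar_respond(
    sample_indices: np.ndarray, r: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Partition a drawn sample into (respondents, nonrespondents) under MCAR.

    The r responding positions are chosen uniformly without replacement,
    independent of y and x.
    """
    sample_indices = np.asarray(sample_indices)
    n = sample_indices.size
    if r > n:
        raise ValueError(f"respondent count r={r} exceeds sample size n={n}")
    pos = rng.choice(n, size=r, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[pos] = True
    return sample_indices[mask], sample_indices[~mask]


@dataclass(frozen=True)
class MCResult:
    """Empirical MSE/PRE of each estimator over m Monte Carlo replicates.

    ``table`` rows are estimators; columns: ``mse`` (mean squared deviation
    from the realized population mean), ``pre`` (vs t0; exactly 100 for t0),
    ``mc_se`` (standard error of the empirical MSE), ``mse_theory`` and
    ``pre_theory`` (first-order values at the realized moments, for
    comparison).  ``degenerate_redraws`` counts replicates redrawn because a
    method's denominator vanished.
    """

    table: pd.DataFrame
    config: SimConfig
    population_params: PopulationParams
    constants_source: str
    degenerate_redraws: int
    estimates: np.ndarray = field(repr=False)


def run_monte_carlo(
    cfg: SimConfig,
    estimators: Sequence[str] | None = None,
    constants: Mapping[str, Mapping[str, float]] | None = None,
    constants_source: str = "population",
    degenerate_policy: str = "redraw",
    max_redraws: int = 1000,
) -> MCResult:
    """Run the full Monte Carlo protocol.

    Plug-in tuning constants are resolved once from the realized population's
    exact moments (``constants_source="population"``, the default, matching a
    study where the simulated population's parameters are known) or estimated
    from each replicate's respondents (``"respondent"``, an explicit opt-in
    beyond any closed-form theory here).  Replicates on which any requested
    method is degenerate are redrawn (``degenerate_policy="redraw"``) or
    dropped (``"drop"``); either way the count is reported.
    """
    if estimators is None:
        estimators = list(ESTIMATORS)
    unknown = [e for e in estimators if e not in ESTIMATORS]
    if unknown:
        raise ValueError(f"unknown estimator ids {unknown}")
    if constants_source not in ("population", "respondent"):
        raise ValueError("constants_source must be 'population' or 'respondent'")
    if degenerate_policy not in ("redraw", "drop"):
        raise ValueError("degenerate_policy must be 'redraw' or 'drop'")

    rng = np.random.default_rng(cfg.seed)
    pop = generate_population(cfg, rng)
    p = pop.params()
    d = thetas(cfg.N, cfg.n, cfg.r)
    Ybar = p.Ybar

    fixed_constants: dict[str, dict[str, float]] = {}
    if constants_source == "population":
        for est in estimators:
            user = dict((constants or {}).get(est, {}))
            fixed_constants[est] = resolve_constants(est, user, params=p, design=d)

    vals = np.empty((len(estimators), cfg.m))
    n_degen = 0
    j = 0
    while j < cfg.m:
        idx = draw_srswor(pop, cfg.n, rng)
        resp, nonresp = mcar_respond(idx, cfg.r, rng)
        s = SampleData(
            y_resp=pop.y[resp], x_resp=pop.x[resp],
            x_nonresp=pop.x[nonresp], Xbar=p.Xbar,
            require_positive_x=False,
        )
        try:
            row = np.empty(len(estimators))
            for i, est in enumerate(estimators):
                if constants_source == "population":
                    c = fixed_constants[est]
                else:
                    c = _respondent_constants(est, s, d, constants)
                row[i] = point_estimate(est, s, c)
        except DegenerateSampleError:
            n_degen += 1
            if n_degen > max_redraws:
                raise RuntimeError(
                    f"exceeded {max_redraws} degenerate replicates; "
                    "check the configuration"
                )
            if degenerate_policy == "redraw":
                continue
            vals[:, j] = np.nan
            j += 1
            continue
        vals[:, j] = row
        j += 1

    dev2 = (vals - Ybar) ** 2
    mse = np.nanmean(dev2, axis=1)
    m_eff = np.sum(~np.isnan(dev2), axis=1)
    mc_se = np.nanstd(dev2, axis=1, ddof=1) / np.sqrt(np.maximum(m_eff, 1)) \
        if cfg.m > 1 else np.zeros(len(estimators))

    i_ref = estimators.index("t0") if "t0" in estimators else None
    pre = np.full(len(estimators), np.nan)
    if i_ref is not None:
        pre = 100.0 * mse[i_ref] / mse
        pre[i_ref] = 100.0  # exact by definition

    theory_mse, theory_pre = [], []
    ref_theory = theoretical_mse("t0", p, d).mse
    for est in estimators:
        tm = theoretical_mse(est, p, d).mse
        theory_mse.append(tm)
        theory_pre.append(100.0 * ref_theory / tm if tm > 0 else np.nan)

    table = pd.DataFrame(
        {
            "mse": mse,
            "pre": pre,
            "mc_se": mc_se,
            "mse_theory": theory_mse,
            "pre_theory": theory_pre,
        },
        index=pd.Index(list(estimators), name="estimator"),
    )
    return MCResult(
        table=table, config=cfg, population_params=p,
        constants_source=constants_source, degenerate_redraws=n_degen,
        estimates=vals,
    )


def _respondent_constants(
    est: str,
    s: SampleData,
    d: DesignParams,
    user: Mapping[str, Mapping[str, float]] | None,
) -> dict[str, float]:
    """Per-replicate respondent-moment plug-in constants (opt-in behaviour)."""
    p_hat = respondent_params(s, d.N)
    return resolve_constants(est, dict((user or {}).get(est, {})), params=p_hat, design=d)


def respondent_params(s: SampleData, N: int) -> PopulationParams:
    """Moment parameters estimated from the responding pairs only.

    A labelled non-closed-form convenience: the bias/MSE theory in
    :mod:`imputemean.theory` assumes known population moments, not these
    respondent-based estimates.
    """
    if s.r < 3:
        raise ValueError("need at least 3 respondents to estimate moments")
    y, x = s.y_resp, s.x_resp
    Sy = float(y.std(ddof=1))
    Sx = float(x.std(ddof=1))
    Syx = float(np.cov(y, x, ddof=1)[0, 1])
    return derive_params(
        N=N, Ybar=float(y.mean()), Xbar=s.Xbar,
        Cy=Sy / float(y.mean()), Cx=Sx / s.Xbar,
        rho=min(1.0, max(-1.0, Syx / (Sy * Sx))),
    )
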