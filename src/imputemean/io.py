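"""Configuration files, sample CSV I/O, report writing and run manifests.

File conventions:

* parameter-set files — INI-style, one section per population, flat keys
  ``N, n, r, Ybar, Xbar, Cy, Cx, rho``;
* simulation configs — INI sections with keys ``mu_y, mu_x, var_y, var_x,
  cov_yx, N, n, r, m, seed``;
* sample data — two-column CSV with header ``y,x``; a blank or ``NA``
  (case-insensitive) y field marks a nonrespondent, x must be complete and
  positive;
* reports — CSV plus a fixed-width text rendering, each accompanied by a
  JSON run manifest capturing the resolved modes and seed.
"""

from __future__ import annotations

import configparser
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .estimators import CompletedSample, SampleData
from .params import DesignParams, PopulationParams, derive_params, thetas
from .simulate import FinitePopulation, SimConfig

_POP_KEYS = ("N", "n", "r", "Ybar", "Xbar", "Cy", "Cx", "rho")
_SIM_KEYS = ("mu_y", "mu_x", "var_y", "var_x", "cov_yx", "N", "n", "r", "m", "seed")
_NA_TOKENS = {"", "na", "nan"}


class ConfigError(ValueError):
    """Malformed or incomplete configuration file."""


def read_population_config(path: str | Path) -> dict[str, tuple[PopulationParams, DesignParams]]:
    """Parse a parameter-set file into {section: (PopulationParams, DesignParams)}."""
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keys are case-sensitive (N vs n)
    path = Path(path)
    if not cp.read(path):
        raise ConfigError(f"cannot read parameter file {path}")
    out: dict[str, tuple[PopulationParams, DesignParams]] = {}
    for section in cp.sections():
        sec = cp[section]
        missing = [k for k in _POP_KEYS if k not in sec]
        if missing:
            raise ConfigError(f"section [{section}] of {path.name} is missing key(s) {missing}")
        try:
            p = derive_params(
                N=int(sec["N"]), Ybar=float(sec["Ybar"]), Xbar=float(sec["Xbar"]),
                Cy=float(sec["Cy"]), Cx=float(sec["Cx"]), rho=float(sec["rho"]),
            )
            d = thetas(N=int(sec["N"]), n=int(sec["n"]), r=int(sec["r"]))
        except ValueError as exc:
            raise ConfigError(f"section [{section}] of {path.name}: {exc}") from exc
        out[section] = (p, d)
    return out


def read_sim_config(path: str | Path, section: str) -> SimConfig:
    """Parse one simulation-config section into a :class:`SimConfig`."""
    cp = configparser.ConfigParser()
    cp.optionxform = str
    path = Path(path)
    if not cp.read(path):
        raise ConfigError(f"cannot read simulation config {path}")
    if section not in cp:
        raise ConfigError(f"no section [{section}] in {path.name}")
    sec = cp[section]
    missing = [k for k in _SIM_KEYS if k not in sec]
    if missing:
        raise ConfigError(f"section [{section}] of {path.name} is missing key(s) {missing}")
    return SimConfig(
        mu_y=float(sec["mu_y"]), mu_x=float(sec["mu_x"]),
        var_y=float(sec["var_y"]), var_x=float(sec["var_x"]),
        cov_yx=float(sec["cov_yx"]),
        N=int(sec["N"]), n=int(sec["n"]), r=int(sec["r"]),
        m=int(sec["m"]), seed=int(sec["seed"]),
    )


def read_sample_csv(path: str | Path, Xbar: float) -> SampleData:
    """Read a partially observed sample from a two-column ``y,x`` CSV.

    Blank or NA y fields mark nonrespondents; any other non-numeric y token
    is a parse error.  x must be numeric, complete and positive.
    """
    df = pd.read_csv(path, dtype={"y": str, "x": float})
    if list(df.columns) != ["y", "x"]:
        raise ConfigError(f"{path}: expected header 'y,x', got {list(df.columns)}")
    if df["x"].isna().any():
        raise ConfigError(f"{path}: x must be complete (auxiliary values known for all units)")
    y_raw = df["y"].fillna("").str.strip()
    is_missing = y_raw.str.lower().isin(_NA_TOKENS)
    try:
        y_obs = y_raw[~is_missing].astype(float).to_numpy()
    except ValueError as exc:
        raise ConfigError(f"{path}: unparseable y value ({exc})") from exc
    if is_missing.all():
        raise ConfigError(f"{path}: all y values missing; nothing to estimate from")
    return SampleData(
        y_resp=y_obs,
        x_resp=df.loc[~is_missing, "x"].to_numpy(),
        x_nonresp=df.loc[is_missing, "x"].to_numpy(),
        Xbar=Xbar,
    )


def write_completed_csv(
    path: str | Path, completed: CompletedSample, sample: SampleData
) -> None:
    """Write the completed sample with a provenance column."""
    if completed.y_completed is None:
        raise ValueError(
            f"{completed.method} has no imputation rule; only a point estimate is defined"
        )
    x_all = np.concatenate([sample.x_resp, sample.x_nonresp])
    pd.DataFrame(
        {
            "y": completed.y_completed,
            "x": x_all,
            "provenance": list(completed.provenance),
        }
    ).to_csv(path, index=False)


def write_population_csv(path: str | Path, pop: FinitePopulation) -> None:
    pd.DataFrame({"y": pop.y, "x": pop.x}).to_csv(path, index=False)


def read_population_csv(path: str | Path) -> FinitePopulation:
    df = pd.read_csv(path)
    if list(df.columns) != ["y", "x"]:
        raise ConfigError(f"{path}: expected header 'y,x'")
    return FinitePopulation(y=df["y"].to_numpy(), x=df["x"].to_numpy())


@dataclass(frozen=True)
class RunManifest:
    """Provenance record attached to every written report."""

    command: str
    config: Mapping[str, object]
    mode: str = "table_consistent"
    b_sign: str = "printed_minus"
    min_mse_formula: str = "stationary"
    seed: int | None = None
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def write_report(
    table: pd.DataFrame, out_prefix: str | Path, manifest: RunManifest
) -> tuple[Path, Path, Path]:
    """Write a report as <prefix>.csv, <prefix>.txt and <prefix>.manifest.json."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = out_prefix.with_suffix(".csv")
    txt_path = out_prefix.with_suffix(".txt")
    man_path = out_prefix.with_suffix(".manifest.json")
    table.to_csv(csv_path)
    txt_path.write_text(table.to_string() + "\n")
    man_path.write_text(manifest.to_json() + "\n")
    return csv_path, txt_path, man_path
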