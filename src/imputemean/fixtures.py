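"""Shipped benchmark fixtures: the three natural populations and the
simulation configurations, loaded from the packaged INI files."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import read_population_config, read_sim_config
from .params import DesignParams, PopulationParams
from .simulate import SimConfig


def _data_path(name: str) -> Path:
    return Path(str(resources.files("imputemean").joinpath("data", name)))


def load_table1_populations() -> dict[str, tuple[PopulationParams, DesignParams]]:
    """The POP1/POP2/POP3 benchmark parameter sets."""
    return read_population_config(_data_path("table1_populations.ini"))


def load_sim_config(name: str = "SIM-DESK") -> SimConfig:
    """A shipped Monte Carlo configuration: ``SIM-PAPER`` or ``SIM-DESK``."""
    return read_sim_config(_data_path("simulation.ini"), name)
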