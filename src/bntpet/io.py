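"""Delimited-text TAC tables and run configuration.

A TAC table is a tab- or comma-separated file with a header row and columns
``frame_start`` and ``frame_end`` (minutes) plus one numeric activity column
per region.  Extra columns are preserved on round-trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes import McmcConfig, PriorSpec
from .kinetics import FrameSchedule, TimeActivityCurve
from .lp_ntpet import BasisGrid
from .presets import PRESETS, preset_grid, preset_priors
from .simulate import NoiseSpec, noise_preset

__all__ = ["TacTable", "RunConfig", "read_tac_table", "write_tac_table",
           "load_config"]

_FRAME_COLS = ("frame_start", "frame_end")


@dataclass
class TacTable:
    """A frame schedule plus one or more named activity columns."""

    table: pd.DataFrame
    schedule: FrameSchedule = field(init=False)

    def __post_init__(self):
        for col in _FRAME_COLS:
            if col not in self.table.columns:
                raise ValueError(f"TAC table is missing required column {col!r}")
        for col in self.table.columns:
            if not np.issubdtype(self.table[col].dtype, np.number):
                raise ValueError(f"TAC table column {col!r} is not numeric")
        try:
            self.schedule = FrameSchedule(self.table["frame_start"].to_numpy(),
                                          self.table["frame_end"].to_numpy())
        except ValueError as exc:
            raise ValueError(f"invalid frame schedule: {exc}") from exc

    @property
    def regions(self) -> list:
        return [c for c in self.table.columns if c not in _FRAME_COLS]

    def tac(self, region: str) -> TimeActivityCurve:
        if region not in self.table.columns:
            raise KeyError(f"no region column {region!r} in TAC table")
        return TimeActivityCurve(self.schedule,
                                 self.table[region].to_numpy(dtype=float),
                                 label=region)

    @classmethod
    def from_tacs(cls, **tacs) -> "TacTable":
        first = next(iter(tacs.values()))
        data = {"frame_start": first.schedule.start,
                "frame_end": first.schedule.end}
        for name, tac in tacs.items():
            data[name] = tac.activity
        return cls(pd.DataFrame(data))


def read_tac_table(path) -> TacTable:
    """Parse a delimited TAC table; the separator (tab or comma) is
    auto-detected from the header.  Values are parsed with correctly
    rounded float conversion so tables round-trip bit-exactly."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return TacTable(df)


def write_tac_table(table: TacTable | pd.DataFrame, path, sep: str = "\t"):
    df = table.table if isinstance(table, TacTable) else table
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


@dataclass(frozen=True)
class RunConfig:
    priors: PriorSpec
    mcmc: McmcConfig
    grid: BasisGrid
    noise: NoiseSpec | None = None
    preset: str | None = None


_KNOWN_SECTIONS = {"preset", "priors", "mcmc", "grid", "noise"}
_PRIOR_KEYS = ("r1", "k2", "k2a", "gamma", "t_d", "delta_t", "alpha")


def load_config(path) -> RunConfig:
    """Load a YAML run configuration.

    A config names a ``preset`` (raclopride_sim, mppf_cat, raclopride_tdcs)
    and may override prior bounds, sampler settings, basis-grid steps and the
    noise model.  Unknown sections raise a warning; reversed bounds raise.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of sections")
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        warnings.warn(f"ignoring unknown config sections: {sorted(unknown)}")
    preset = raw.get("preset", "raclopride_sim")
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")

    bounds = {k: tuple(v) for k, v in PRESETS[preset].items()}
    for key, val in (raw.get("priors") or {}).items():
        if key in ("a0", "b0"):
            continue
        if key not in _PRIOR_KEYS:
            warnings.warn(f"ignoring unknown prior key {key!r}")
            continue
        lo, hi = float(val[0]), float(val[1])
        if lo >= hi:
            raise ValueError(f"prior bounds for {key!r} are out of order")
        bounds[key] = (lo, hi)
    prior_extra = {k: (raw.get("priors") or {}).get(k) for k in ("a0", "b0")}
    priors = PriorSpec.from_bounds(**bounds, **prior_extra)

    mcmc_raw = raw.get("mcmc") or {}
    mcmc = McmcConfig(**{k: mcmc_raw[k] for k in mcmc_raw})

    grid_raw = raw.get("grid") or {}
    grid = preset_grid(preset, step_t=float(grid_raw.get("step_t", 0.5)),
                       step_alpha=float(grid_raw.get("step_alpha", 0.5)))

    noise_raw = raw.get("noise")
    noise = None
    if noise_raw:
        if "preset" in noise_raw:
            noise = noise_preset(noise_raw["preset"],
                                 seed=noise_raw.get("seed"))
        else:
            noise = NoiseSpec(
                omega2=float(noise_raw["omega2"]),
                decay_half_life=noise_raw.get("decay_half_life", 20.4),
                seed=noise_raw.get("seed"))
    return RunConfig(priors=priors, mcmc=mcmc, grid=grid, noise=noise,
                     preset=preset)
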