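"""Flat TOML configuration for sweep runs.

Every key is optional; defaults reproduce the reference model conditions
(DIC 993 umol L-1, reference pH 7.59, K 44 umol L-1, T 298.15 K, S 35).
Unknown keys are rejected so typos fail loudly, and the fully resolved
configuration (defaults included) is what lands in the provenance sidecar.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .carbonate import SeawaterConditions
from .scan import ScanConfig

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key."""


# key -> (type, default); pH/ratio grids are expressed as range triples
_SCHEMA: dict[str, tuple[type, object]] = {
    "dic": (float, 993.0),
    "reference_ph": (float, 7.59),
    "k_half": (float, 44.0),
    "temperature_k": (float, 298.15),
    "salinity": (float, 35.0),
    "ph_min": (float, 5.0),
    "ph_max": (float, 8.0),
    "ph_step": (float, 0.05),
    "vmax_over_d": (list, [0.1, 0.68129206905796, 4.641588833612778,
                           31.622776601683793, 215.44346900318823,
                           1467.7992676220695, 10000.0]),
    "outdir": (str, "."),
    "prefix": (str, "scan"),
    "seed": (int, 0),
    "verbosity": (int, 1),
}

_RANGE_CHECKS = {
    "dic": lambda v: v >= 0,
    "k_half": lambda v: v > 0,
    "temperature_k": lambda v: v > 0,
    "salinity": lambda v: 0 <= v <= 50,
    "ph_step": lambda v: v > 0,
    "vmax_over_d": lambda v: len(v) > 0 and all(x >= 0 for x in v),
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run settings: sweep parameters plus output/plumbing knobs.

    ``seed`` only feeds randomized test-fixture generation; the model
    itself is deterministic.
    """

    dic: float = 993.0
    reference_ph: float = 7.59
    k_half: float = 44.0
    temperature_k: float = 298.15
    salinity: float = 35.0
    ph_min: float = 5.0
    ph_max: float = 8.0
    ph_step: float = 0.05
    vmax_over_d: tuple[float, ...] = tuple(_SCHEMA["vmax_over_d"][1])  # type: ignore[arg-type]
    outdir: str = "."
    prefix: str = "scan"
    seed: int = 0
    verbosity: int = 1

    def ph_grid(self) -> tuple[float, ...]:
        n = int(round((self.ph_max - self.ph_min) / self.ph_step)) + 1
        return tuple(np.round(np.linspace(self.ph_min, self.ph_max, n), 10))

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            DIC_m=self.dic,
            reference_pH=self.reference_ph,
            pH_grid=self.ph_grid(),
            vmax_over_d=tuple(sorted(set(self.vmax_over_d))),
            K=self.k_half,
            conditions=SeawaterConditions(T=self.temperature_k, S=self.salinity),
        )

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in _SCHEMA}
        d["vmax_over_d"] = list(d["vmax_over_d"])
        return d


def _coerce(key: str, value: object) -> object:
    typ, _ = _SCHEMA[key]
    if typ is float:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"config key '{key}' must be a number, got {value!r}")
        value = float(value)
        if not math.isfinite(value):
            raise ConfigError(f"config key '{key}' must be finite, got {value!r}")
    elif typ is int:
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"config key '{key}' must be an integer, got {value!r}")
    elif typ is list:
        if not isinstance(value, list) or not all(
            isinstance(x, (int, float)) and not isinstance(x, bool) for x in value
        ):
            raise ConfigError(f"config key '{key}' must be a list of numbers, got {value!r}")
        value = [float(x) for x in value]
    elif typ is str:
        if not isinstance(value, str):
            raise ConfigError(f"config key '{key}' must be a string, got {value!r}")
    check = _RANGE_CHECKS.get(key)
    if check is not None and not check(value):
        raise ConfigError(f"config key '{key}' is out of range: {value!r}")
    return value


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a flat TOML config file, applying defaults.

    Raises ``ConfigError`` naming the offending key for unknown keys,
    wrong types, or out-of-range values.
    """
    raw = tomllib.loads(Path(path).read_text())
    unknown = sorted(set(raw) - set(_SCHEMA))
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    resolved = {k: _coerce(k, v) for k, v in raw.items()}
    if "vmax_over_d" in resolved:
        resolved["vmax_over_d"] = tuple(resolved["vmax_over_d"])
    cfg = RunConfig(**resolved)  # type: ignore[arg-type]
    if cfg.ph_max < cfg.ph_min:
        raise ConfigError("config key 'ph_max' must be >= 'ph_min'")
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a RunConfig back out as flat TOML (round-trips with load_config)."""
    lines = []
    for key, value in cfg.as_dict().items():
        if isinstance(value, str):
            lines.append(f'{key} = "{value}"')
        elif isinstance(value, list):
            lines.append(f"{key} = [{', '.join(repr(v) for v in value)}]")
        else:
            lines.append(f"{key} = {value!r}")
    Path(path).write_text("\n".join(lines) + "\n")
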