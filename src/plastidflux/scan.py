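"""Parameter sweep over middle-space pH and Vmax/D.

Reproduces the model's central result: a grid of middle-space CO2,
plastid CO2, fixation rate, and fold change in fixation relative to a
reference pH (default 7.59, the one mean intracellular pH reported for a
diatom), for a family of Vmax/D values.  The middle-space CO2 column
depends on pH only; the plastid columns depend on both grid axes.

The two asymptotic regimes give closed-form bounds on the fold change at
any pH: the uptake-limited limit (ratio of Michaelis-Menten terms in
[CO2]_m) and the diffusion-limited limit (plain ratio of [CO2]_m), which
sandwich the exact steady-state fold change for every finite Vmax/D.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .carbonate import SeawaterConditions, co2_from_dic
from .steadystate import DEFAULT_K_HALF, KineticParams, solve_steady_state

__all__ = [
    "ScanConfig",
    "ScanTable",
    "run_scan",
    "fold_change_bounds",
    "panel_tables",
    "write_tables",
]

DEFAULT_DIC = 993.0  # umol L-1, middle-space DIC
DEFAULT_REFERENCE_PH = 7.59


def _default_ph_grid() -> tuple[float, ...]:
    # 5.0 .. 8.0 step 0.05, hitting 5, 6, 7, and (inserted) 7.59 exactly
    return tuple(np.round(np.arange(5.0, 8.0 + 1e-9, 0.05), 10))


def _default_ratio_grid() -> tuple[float, ...]:
    # log-spaced Vmax/D spanning uptake- to diffusion-limited behaviour
    return tuple(np.logspace(-1, 4, 7))


@dataclass(frozen=True)
class ScanConfig:
    """Grid and parameter settings for the pH x Vmax/D sweep."""

    DIC_m: float = DEFAULT_DIC
    reference_pH: float = DEFAULT_REFERENCE_PH
    pH_grid: tuple[float, ...] = field(default_factory=_default_ph_grid)
    vmax_over_d: tuple[float, ...] = field(default_factory=_default_ratio_grid)
    K: float = DEFAULT_K_HALF
    conditions: SeawaterConditions = field(default_factory=SeawaterConditions)

    def __post_init__(self) -> None:
        if self.DIC_m < 0 or not math.isfinite(self.DIC_m):
            raise ValueError(f"DIC_m must be non-negative and finite, got {self.DIC_m!r}")
        if self.K <= 0 or not math.isfinite(self.K):
            raise ValueError(f"K must be positive and finite, got {self.K!r}")
        for name in ("pH_grid", "vmax_over_d"):
            grid = tuple(float(v) for v in getattr(self, name))
            if len(grid) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, grid)
        if any(v < 0 for v in self.vmax_over_d):
            raise ValueError("vmax_over_d values must be non-negative")
        # the reference pH must be a grid point so fold changes normalize exactly
        if not any(math.isclose(p, self.reference_pH, abs_tol=1e-12) for p in self.pH_grid):
            merged = tuple(sorted(set(self.pH_grid) | {self.reference_pH}))
            object.__setattr__(self, "pH_grid", merged)

    def as_dict(self) -> dict:
        return {
            "DIC_m": self.DIC_m,
            "reference_pH": self.reference_pH,
            "pH_grid": list(self.pH_grid),
            "vmax_over_d": list(self.vmax_over_d),
            "K": self.K,
            "temperature_K": self.conditions.T,
            "salinity": self.conditions.S,
        }


@dataclass(frozen=True)
class ScanTable:
    """Long-format sweep results plus a provenance block."""

    records: pd.DataFrame  # columns pH_m, Vmax_over_D, CO2_m, CO2_p, VCfix, fold_change
    provenance: dict

    def panel(self, name: str) -> pd.DataFrame:
        return panel_tables_from_records(self.records)[name]


def run_scan(config: ScanConfig | None = None) -> ScanTable:
    """Evaluate the steady-state model at every (pH, Vmax/D) grid point.

    ``fold_change`` is Vcfix(pH) / Vcfix(reference pH) at equal Vmax/D;
    when the reference rate is zero (Vmax/D = 0) it is reported as NaN
    rather than infinity.
    """
    config = config or ScanConfig()
    co2_m = {
        ph: co2_from_dic(config.DIC_m, ph, config.conditions) for ph in config.pH_grid
    }
    rows = []
    for ratio in config.vmax_over_d:
        params = KineticParams.from_ratio(ratio, K=config.K)
        ref = solve_steady_state(co2_m[_reference_key(config)], params)
        for ph in config.pH_grid:
            ss = solve_steady_state(co2_m[ph], params)
            if ref.VCfix > 0:
                fold = ss.VCfix / ref.VCfix
            else:
                fold = math.nan
            rows.append(
                {
                    "pH_m": ph,
                    "Vmax_over_D": ratio,
                    "CO2_m": co2_m[ph],
                    "CO2_p": ss.CO2_p,
                    "VCfix": ss.VCfix,
                    "fold_change": fold,
                }
            )
    records = pd.DataFrame(rows)
    provenance = {"config": config.as_dict(), "package_version": __version__}
    return ScanTable(records=records, provenance=provenance)


def _reference_key(config: ScanConfig) -> float:
    for p in config.pH_grid:
        if math.isclose(p, config.reference_pH, abs_tol=1e-12):
            return p
    raise AssertionError("reference pH missing from grid")  # unreachable


def fold_change_bounds(pH: float, config: ScanConfig | None = None) -> tuple[float, float]:
    """Asymptotic (low, high) bounds on the fixation fold change at ``pH``.

    low:  uptake-limited (Vmax << D) ratio of Michaelis-Menten terms,
          [C/(C+K)] / [Cref/(Cref+K)].
    high: diffusion-limited (Vmax >> D) ratio of middle-space CO2, C/Cref.

    For acidification below the reference pH, C > Cref and low <= high.
    """
    config = config or ScanConfig()
    c = co2_from_dic(config.DIC_m, pH, config.conditions)
    c_ref = co2_from_dic(config.DIC_m, config.reference_pH, config.conditions)
    if c_ref == 0:
        return (math.nan, math.nan)
    K = config.K
    low = (c / (c + K)) / (c_ref / (c_ref + K))
    high = c / c_ref
    return (low, high)


def panel_tables_from_records(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pivot long-format scan records into the three panel tables."""
    panel_a = (
        records.drop_duplicates("pH_m")[["pH_m", "CO2_m"]]
        .sort_values("pH_m")
        .reset_index(drop=True)
    )
    panel_b = records.pivot(index="pH_m", columns="Vmax_over_D", values="CO2_p").sort_index()
    panel_c = records.pivot(index="pH_m", columns="Vmax_over_D", values="fold_change").sort_index()
    return {"A": panel_a, "B": panel_b, "C": panel_c}


def panel_tables(config: ScanConfig | None = None) -> dict[str, pd.DataFrame]:
    """Panel tables: A = CO2_m vs pH; B = CO2_p, C = relative fixation rate,
    each vs pH with one column per Vmax/D.  All derive from a single sweep.
    """
    return panel_tables_from_records(run_scan(config).records)


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    # fixed 10-significant-digit formatting keeps CSV output byte-stable
    return df.map(lambda v: f"{v:.10g}" if isinstance(v, float) else v)


def write_tables(table: ScanTable, outdir: str | Path, prefix: str = "scan") -> list[Path]:
    """Write panel CSVs, the long-format table, and a provenance sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    panels = panel_tables_from_records(table.records)
    for name, df in panels.items():
        path = outdir / f"{prefix}_panel_{name}.csv"
        out = df.reset_index() if name in ("B", "C") else df
        _format_frame(out).to_csv(path, index=False, lineterminator="\r\n")
        written.append(path)
    long_path = outdir / f"{prefix}_long.csv"
    _format_frame(table.records).to_csv(long_path, index=False, lineterminator="\r\n")
    written.append(long_path)
    sidecar = outdir / f"{prefix}_provenance.json"
    sidecar.write_text(json.dumps(table.provenance, indent=2, sort_keys=True) + "\n")
    written.append(sidecar)
    return written
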