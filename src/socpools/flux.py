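"""Chamber headspace CO2 records to cumulative C-CO2 curves.

Soils are incubated in sealed bottles; at each sampling event the headspace
CO2 concentration is measured, the bottle is flushed with air, resealed and
re-sampled for the new initial concentration.  The CO2-C accumulated during
one sealed interval therefore follows from the concentration difference over
that interval via the ideal gas law at Standard Ambient Temperature and
Pressure (SATP, 298.15 K / 100 kPa), and the per-gram cumulative curve is
the running sum over intervals divided by dry soil mass.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .curves import CumulativeCurve

__all__ = [
    "SATP_TEMPERATURE_K",
    "SATP_PRESSURE_KPA",
    "IncubationSeries",
    "interval_c_mass",
    "accumulate_series",
    "read_chambers_csv",
    "write_curves_csv",
]

R_GAS = 8.314462618        # J mol^-1 K^-1
MOLAR_MASS_C = 12.011      # g mol^-1
SATP_TEMPERATURE_K = 298.15
SATP_PRESSURE_KPA = 100.0


@dataclass
class IncubationSeries:
    """Flush-resample headspace record for one incubated soil.

    ``records`` holds one row per sealed interval: the day the interval
    ended, the post-flush concentration at its start and the concentration
    measured at its end (ppm CO2).  The day-0 row records the initial
    sampling event and carries no accumulated flux.
    """

    sample_id: str
    dry_soil_mass: float                 # g
    records: pd.DataFrame                # columns: day, co2_start_ppm, co2_end_ppm
    chamber_volume: float = 0.5          # L
    bulk_density: float | None = None    # g cm^-3, for headspace correction

    def __post_init__(self) -> None:
        if self.dry_soil_mass <= 0:
            raise ValueError("dry_soil_mass must be positive")
        if self.chamber_volume <= 0:
            raise ValueError("chamber_volume must be positive")
        req = {"day", "co2_start_ppm", "co2_end_ppm"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(req)}")
        self.records = self.records.sort_values("day").reset_index(drop=True)
        days = self.records["day"].to_numpy()
        if np.any(np.diff(days) == 0):
            raise ValueError(f"duplicate sampling days for {self.sample_id}")
        if np.any(self.records["co2_end_ppm"] < 0):
            raise ValueError("negative CO2 concentration")

    @property
    def headspace_volume(self) -> float:
        """Headspace (L): chamber volume minus soil volume when the bulk
        density is known, otherwise the nominal chamber volume."""
        if self.bulk_density is None:
            return self.chamber_volume
        soil_volume_l = self.dry_soil_mass / (self.bulk_density * 1000.0)
        hs = self.chamber_volume - soil_volume_l
        if hs <= 0:
            raise ValueError("soil volume exceeds chamber volume")
        return hs


def interval_c_mass(
    delta_ppm: float,
    headspace_volume: float,
    temperature: float = SATP_TEMPERATURE_K,
    pressure: float = SATP_PRESSURE_KPA,
) -> float:
    """Carbon mass (ug C) of a headspace CO2 concentration change.

    mass = delta_ppm * 1e-6 * n_total * M_C with n_total = P V / (R T);
    volume in litres, temperature in kelvin, pressure in kPa.  Negative
    ``delta_ppm`` (measurement noise) yields a negative mass.
    """
    if headspace_volume <= 0 or temperature <= 0 or pressure <= 0:
        raise ValueError("volume, temperature and pressure must be positive")
    n_total = (pressure * 1e3) * (headspace_volume * 1e-3) / (R_GAS * temperature)
    return float(delta_ppm) * 1e-6 * n_total * MOLAR_MASS_C * 1e6


def accumulate_series(
    series: IncubationSeries,
    clamp_negative: bool = True,
    temperature: float = SATP_TEMPERATURE_K,
    pressure: float = SATP_PRESSURE_KPA,
) -> CumulativeCurve:
    """Accumulate sealed-interval fluxes into a cumulative C-CO2 curve.

    Each row at day d > 0 contributes
    ``interval_c_mass(co2_end - co2_start) / dry_soil_mass``; the day-0 row
    defines the start of the first interval and contributes zero.  Negative
    increments are clamped to zero with a warning by default (the fitted
    curves must be non-decreasing); ``clamp_negative=False`` preserves them
    for auditing.
    """
    rec = series.records
    days = rec["day"].to_numpy(dtype=float)
    if days[0] != 0:
        raise ValueError(f"missing day-0 record for {series.sample_id}")
    delta = (rec["co2_end_ppm"] - rec["co2_start_ppm"]).to_numpy(dtype=float)
    incr = np.array([
        interval_c_mass(d, series.headspace_volume, temperature, pressure)
        for d in delta
    ]) / series.dry_soil_mass
    incr[0] = 0.0
    if clamp_negative and np.any(incr < 0):
        warnings.warn(
            f"{series.sample_id}: {(incr < 0).sum()} negative interval "
            "increment(s) clamped to zero", stacklevel=2)
        incr = np.clip(incr, 0.0, None)
    return CumulativeCurve(sample_id=series.sample_id, days=days,
                           values=np.cumsum(incr))


# -- CSV interfaces --------------------------------------------------------

def read_chambers_csv(path: str | Path) -> list[IncubationSeries]:
    """Read chamber records (one row per sample x sealed interval)."""
    df = pd.read_csv(path)
    required = {"sample_id", "day", "co2_start_ppm", "co2_end_ppm",
                "dry_soil_mass_g", "chamber_volume_l"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chambers CSV missing columns: {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        bd = None
        if "bulk_density_g_cm3" in grp.columns:
            val = grp["bulk_density_g_cm3"].iloc[0]
            bd = None if pd.isna(val) else float(val)
        out.append(IncubationSeries(
            sample_id=str(sid),
            dry_soil_mass=float(grp["dry_soil_mass_g"].iloc[0]),
            chamber_volume=float(grp["chamber_volume_l"].iloc[0]),
            bulk_density=bd,
            records=grp[["day", "co2_start_ppm", "co2_end_ppm"]].copy(),
        ))
    return out


def write_curves_csv(curves: Iterable[CumulativeCurve], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"sample_id": c.sample_id, "day": c.days,
                      "cum_c_co2_ug_per_g": c.values})
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves_csv(path: str | Path) -> list[CumulativeCurve]:
    df = pd.read_csv(path)
    required = {"sample_id", "day", "cum_c_co2_ug_per_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curves CSV missing columns: {sorted(missing)}")
    return [
        CumulativeCurve(sample_id=str(sid),
                        days=grp["day"].to_numpy(dtype=float),
                        values=grp["cum_c_co2_ug_per_g"].to_numpy(dtype=float))
        for sid, grp in df.groupby("sample_id", sort=False)
    ]
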