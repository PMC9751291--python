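"""Column registry for soil-horizon property tables.

The 44 physicochemical predictors screened against each carbon response:
nine selective-dissolution metals (citrate/dithionite "c" = total free
oxides, hydroxylamine "h" = amorphous, pyrophosphate "p" = organo-complexed
Fe/Al/Si), crystalline Fe, the three "reactive metal" Al + 0.5 Fe sums, the
stable organo-complex fraction, nine metal ratios, and the physical/chemical
suite (texture, aggregates, roots, exchange capacities, cations, ...).
"""
from __future__ import annotations

import pandas as pd

#: grouping / identifier columns
PIT_COLUMN = "pit_id"

#: climate covariates (soil-forming factors; never fixed effects)
CLIMATE = ["Rainfall", "RH", "Temperature"]

#: carbon responses
RESPONSES = ["SOC", "k2", "k1"]

_METALS = [f"{m}_{e}" for e in ("c", "h", "p") for m in ("Fe", "Al", "Si")]

_DERIVED = [
    "Fe_c-h",
    "Al_c+0.5Fe_c", "Al_h+0.5Fe_h", "Al_p+0.5Fe_p",
    "(Fe_p+Si_p)/(Fe_p+Si_p+Al_p)",
    "Fe_c/Al_c", "Fe_h/Al_h", "Fe_p/Al_p",
    "Si_c/Al_c", "Si_h/Al_h", "Si_p/Al_p",
    "Fe_c/Si_c", "Fe_h/Si_h", "Fe_p/Si_p",
]

_PHYSICOCHEMICAL = [
    "Depth", "BD", "pH", "Phos",
    "Clay", "Silt", "Sand", "Clay+Silt",
    "Macro_agg", "Micro_agg", "WS_agg", "NWS_agg",
    "Roots", "Rocks", "WC_15kPa",
    "CEC", "AEC", "Ca", "K", "Na", "Mg",
]

#: the 44 candidate predictors, in registry order
PREDICTORS: list[str] = _METALS + _DERIVED + _PHYSICOCHEMICAL

assert len(PREDICTORS) == 44, "predictor registry must have 44 entries"


def derive_ratio_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Fill in derived metal columns that are absent but computable."""
    table = table.copy()
    recipes = {
        "Fe_c-h": lambda t: t["Fe_c"] - t["Fe_h"],
        "Al_c+0.5Fe_c": lambda t: t["Al_c"] + 0.5 * t["Fe_c"],
        "Al_h+0.5Fe_h": lambda t: t["Al_h"] + 0.5 * t["Fe_h"],
        "Al_p+0.5Fe_p": lambda t: t["Al_p"] + 0.5 * t["Fe_p"],
        "(Fe_p+Si_p)/(Fe_p+Si_p+Al_p)":
            lambda t: (t["Fe_p"] + t["Si_p"])
            / (t["Fe_p"] + t["Si_p"] + t["Al_p"]),
        "Clay+Silt": lambda t: t["Clay"] + t["Silt"],
    }
    for num, den in [("Fe", "Al"), ("Si", "Al"), ("Fe", "Si")]:
        for ext in ("c", "h", "p"):
            name = f"{num}_{ext}/{den}_{ext}"
            recipes[name] = (
                lambda t, n=f"{num}_{ext}", d=f"{den}_{ext}": t[n] / t[d])
    for name, fn in recipes.items():
        if name not in table.columns:
            try:
                table[name] = fn(table)
            except KeyError:
                pass
    return table


def validate_horizon_table(table: pd.DataFrame,
                           require_responses: bool = True) -> None:
    """Check the horizon table has every column the analysis needs."""
    required = [PIT_COLUMN] + PREDICTORS + CLIMATE
    if require_responses:
        required += RESPONSES
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"horizon table missing columns: {missing}")
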