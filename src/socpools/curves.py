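"""Shared container for cumulative respiration curves.

A :class:`CumulativeCurve` is the common currency of the package: the
compartment model predicts one, the chamber-flux processor produces one from
headspace records, and the kinetic fitter consumes one.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Incubation sampling schedule (days): 25 sampling events over 90 days.
SAMPLING_DAYS = np.array(
    [0, 2, 4, 6, 8, 10, 12, 14, 17, 20, 23, 26, 30, 35, 40, 45, 50, 55, 60,
     65, 70, 75, 80, 85, 90],
    dtype=float,
)


@dataclass
class CumulativeCurve:
    """Cumulative respired carbon versus time for one soil sample.

    Attributes
    ----------
    sample_id : str
        Identifier of the incubated soil (pit/horizon label).
    days : ndarray
        Sampling days, strictly increasing, starting at 0.
    values : ndarray
        Cumulative C-CO2 in ug C per g dry soil; ``values[0] == 0``.
    """

    sample_id: str
    days: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.shape != self.values.shape:
            raise ValueError("days and values must have equal length")
        if self.days.size == 0:
            raise ValueError("empty curve")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")

    def __len__(self) -> int:
        return self.days.size
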