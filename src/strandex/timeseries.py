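"""In-memory containers for assay time series and titrations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeCourseData", "TitrationData"]


@dataclass
class TimeCourseData:
    """One observed or synthetic assay time series.

    ``values`` are percent (strand-exchange assays) or anisotropy
    (filament assays), on a strictly increasing time grid in seconds.
    ``assay`` is a free tag ("pairing", "displacement", "two_AP",
    "association", "dissociation").  ``truth`` optionally carries the
    generating parameters of a synthetic dataset.
    """

    times: np.ndarray
    values: np.ndarray
    assay: str = "pairing"
    A0: float = 36.0
    B0: float = 36.0
    condition: dict = field(default_factory=dict)
    replicate_id: int = 0
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.shape != self.times.shape:
            raise ValueError("times and values must be 1-D and equally long")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class TitrationData:
    """Steady-state binding titration: anisotropy vs recombinase (uM)."""

    concentrations_uM: np.ndarray
    anisotropy: np.ndarray
    condition: dict = field(default_factory=dict)
    replicate_id: int = 0
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.concentrations_uM = np.asarray(self.concentrations_uM, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if self.concentrations_uM.shape != self.anisotropy.shape:
            raise ValueError("concentration and anisotropy lengths differ")
        if np.any(self.concentrations_uM < 0):
            raise ValueError("concentrations must be >= 0")

    def __len__(self) -> int:
        return self.concentrations_uM.size
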