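"""Assay readouts: FRET/2AP signal calibration and intermediate quantification.

Two real-time FRET assays monitor strand exchange.  In the pairing assay a
fluorescein-labelled filament is quenched by rhodamine on the captured
donor, so fluorescence tracks free substrate.  In the displacement assay a
doubly labelled donor brightens when the displaced strand leaves, so
fluorescence tracks product.  A 2-aminopurine (2AP) variant reports
heteroduplex formation through base-pairing quench.  An SDS-quench
("abortive") protocol collapses C1 back to substrates and C2 forward to
products, separating the two intermediate pools.

Signal maps are affine and anchored by the maximum FRET efficiency E_max
(fraction of donor emission lost when fully complexed) or, for 2AP, by the
fully-paired quench fraction.  Percentages are on the 0-100 scale.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .reactions import Trajectory

__all__ = [
    "AssayKind",
    "FretCalibration",
    "QuenchCalibration2AP",
    "CalibrationError",
    "InconsistentMeasurementWarning",
    "trajectory_to_percent",
    "fluorescence_to_percent",
    "percent_to_fluorescence",
    "two_AP_to_substrate_percent",
    "substrate_percent_to_two_AP",
    "abortive_quantify",
    "predict_intermediates",
]


class CalibrationError(ValueError):
    """A signal calibration constant is outside its valid domain."""


class InconsistentMeasurementWarning(UserWarning):
    """Quantified intermediate fractions fall outside [0, 100]."""


class AssayKind(str, enum.Enum):
    PAIRING = "pairing"
    DISPLACEMENT = "displacement"
    TWO_AP = "two_AP"


@dataclass(frozen=True)
class FretCalibration:
    """FRET signal calibration: maximum quench efficiency and F(t=0).

    E_max is the fraction of fluorescein emission lost when every filament
    is complexed with a rhodamine-labelled donor; F0 is the fluorescence at
    reaction start (all substrate free in pairing, fully quenched donor in
    displacement), in arbitrary instrument units.
    """

    E_max: float = 0.6
    F0: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.E_max <= 1):
            raise CalibrationError(f"E_max={self.E_max!r} must be in (0, 1]")
        if not (self.F0 > 0 and math.isfinite(self.F0)):
            raise CalibrationError(f"F0={self.F0!r} must be finite and > 0")


@dataclass(frozen=True)
class QuenchCalibration2AP:
    """2AP calibration: fully base-paired emission relative to the filament.

    Heteroduplex formation quenches 2AP fluorescence to ``quench_fraction``
    of the initial filament emission (default 0.601, i.e. 60.1%).
    """

    quench_fraction: float = 0.601

    def __post_init__(self) -> None:
        if not (0 < self.quench_fraction < 1):
            raise CalibrationError(
                f"quench_fraction={self.quench_fraction!r} must be in (0, 1)"
            )


def trajectory_to_percent(traj: Trajectory, assay: "AssayKind | str") -> np.ndarray:
    """Ideal (noise-free) percent readout of a simulated trajectory.

    pairing: substrate% = 100*A(t)/A0; displacement: product% = 100*E(t)/B0.
    The 2AP assay tracks free substrate like pairing (heteroduplex quenches).
    """
    assay = AssayKind(assay)
    A0 = traj.initial_state.A_total
    B0 = traj.initial_state.B_total
    if assay in (AssayKind.PAIRING, AssayKind.TWO_AP):
        if A0 == 0:
            raise ValueError("A0 is zero; substrate percent undefined")
        return 100.0 * traj.A / A0
    if B0 == 0:
        raise ValueError("B0 is zero; product percent undefined")
    return 100.0 * traj.E / B0


def fluorescence_to_percent(
    F, calib: FretCalibration, assay: "AssayKind | str", clip: bool = True
) -> np.ndarray:
    """Convert raw fluorescence into substrate% (pairing) or product%.

    The maps are affine in F/F0 and anchored so that in pairing F = F0 is
    100% free substrate and F = (1 - E_max)*F0 is 0%, while in displacement
    F = F0 (fully quenched donor) is 0% product and complete displacement
    raises emission by a factor 1/(1 - E_max).
    """
    assay = AssayKind(assay)
    F = np.asarray(F, dtype=float)
    if np.any(F <= 0):
        raise ValueError("fluorescence values must be > 0")
    rel = F / calib.F0
    if assay in (AssayKind.PAIRING, AssayKind.TWO_AP):
        pct = 100.0 * (rel - (1.0 - calib.E_max)) / calib.E_max
    else:
        pct = 100.0 * (rel - 1.0) * (1.0 - calib.E_max) / calib.E_max
    if clip:
        pct = np.clip(pct, 0.0, 100.0)
    return pct


def percent_to_fluorescence(
    pct, calib: FretCalibration, assay: "AssayKind | str"
) -> np.ndarray:
    """Inverse of :func:`fluorescence_to_percent` (exact on [0, 100])."""
    assay = AssayKind(assay)
    pct = np.asarray(pct, dtype=float)
    if assay in (AssayKind.PAIRING, AssayKind.TWO_AP):
        rel = (1.0 - calib.E_max) + calib.E_max * pct / 100.0
    else:
        rel = 1.0 + calib.E_max / (1.0 - calib.E_max) * pct / 100.0
    return rel * calib.F0


def two_AP_to_substrate_percent(
    F_rel, calib: QuenchCalibration2AP | None = None
) -> np.ndarray:
    """Substrate% from 2AP fluorescence relative to the initial filament.

    Affine map anchored at F_rel = 1 (all substrate free, 100%) and
    F_rel = quench_fraction (all substrate base-paired, 0%).  F_rel values
    slightly outside (0, 1] are clipped into [0, 1].
    """
    calib = calib or QuenchCalibration2AP()
    q = calib.quench_fraction
    F_rel = np.clip(np.asarray(F_rel, dtype=float), 0.0, 1.0)
    return 100.0 * (F_rel - q) / (1.0 - q)


def substrate_percent_to_two_AP(
    pct, calib: QuenchCalibration2AP | None = None
) -> np.ndarray:
    """Inverse 2AP map: relative fluorescence from substrate%."""
    calib = calib or QuenchCalibration2AP()
    q = calib.quench_fraction
    pct = np.asarray(pct, dtype=float)
    return q + (1.0 - q) * pct / 100.0


def abortive_quantify(
    substrate_pct_before_SDS,
    substrate_pct_after_SDS=None,
    product_pct_after_SDS=None,
    mode: str = "DSP",
    clamp_tolerance: float = 2.0,
):
    """Intermediate fractions from an SDS-quench (abortive) measurement.

    SDS collapses C1 back into free substrates and C2 into final products,
    so the post-SDS signal partitions the complexed material:

    * DSP (pairing-initiated):  C2+product% = 100 - substrate%_after
    * DSD (displacement-initiated):  C2+product% = product%_after
    * both modes:  C1% = (100 - substrate%_before) - C2+product%

    i.e. C1 is the complexed fraction just before SDS minus the part that
    ends up as C2 or product; in DSP mode this equals the substrate gain
    across SDS addition.  Returns ``(C1_pct, C2_plus_product_pct)``.
    Small negative C1 (within ``clamp_tolerance`` percentage points) is
    clamped to 0; values outside [0, 100] raise an
    :class:`InconsistentMeasurementWarning`.
    """
    before = np.asarray(substrate_pct_before_SDS, dtype=float)
    mode = mode.upper()
    if mode == "DSP":
        if substrate_pct_after_SDS is None:
            raise ValueError("DSP mode requires substrate_pct_after_SDS")
        after = np.asarray(substrate_pct_after_SDS, dtype=float)
        c2_plus_product = 100.0 - after
    elif mode == "DSD":
        if product_pct_after_SDS is None:
            raise ValueError("DSD mode requires product_pct_after_SDS")
        c2_plus_product = np.asarray(product_pct_after_SDS, dtype=float)
    else:
        raise ValueError(f"mode must be 'DSP' or 'DSD', got {mode!r}")

    c1 = (100.0 - before) - c2_plus_product
    out_of_range = (
        np.any(c1 > 100.0 + clamp_tolerance)
        or np.any(c1 < -clamp_tolerance)
        or np.any(c2_plus_product > 100.0 + clamp_tolerance)
        or np.any(c2_plus_product < -clamp_tolerance)
    )
    if out_of_range:
        warnings.warn(
            "quantified intermediate fractions outside [0, 100]; the "
            "before/after measurements are mutually inconsistent",
            InconsistentMeasurementWarning,
            stacklevel=2,
        )
    c1 = np.where((c1 < 0) & (c1 >= -clamp_tolerance), 0.0, c1)
    if c1.ndim == 0:
        return float(c1), float(c2_plus_product)
    return c1, np.asarray(c2_plus_product, dtype=float)


def predict_intermediates(traj: Trajectory):
    """Model-predicted (C1%, C2+product%) time series from a trajectory.

    C1% = 100*C1(t)/A0 and C2+product% = 100*(C2(t)+D(t))/A0, so that
    substrate% + C1% + C2+product% = 100 at every time by conservation.
    """
    A0 = traj.initial_state.A_total
    if A0 == 0:
        raise ValueError("A0 is zero; intermediate percentages undefined")
    c1 = 100.0 * traj.C1 / A0
    c2p = 100.0 * (traj.C2 + traj.D) / A0
    return c1, c2p
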