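"""Synthetic assay data with attached ground truth.

Each generator runs the forward model (mass-action simulation plus signal
calibration, or the closed-form binding/association/dissociation curves),
adds seeded homoscedastic Gaussian noise on the reported signal, and
attaches the generating parameters under ``.truth`` so every estimator can
be validated against a known answer.  Defaults mirror the standard assay
conditions: 36 nM substrates observed over 0-1000 s for strand exchange,
0.5 s anisotropy sampling, SDS quenches at 150/300/600/900 s, and noise of
1% of the dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reactions import (
    RateConstants,
    ReactionScheme,
    ReactionState,
    simulate,
)
from .observables import (
    AssayKind,
    FretCalibration,
    QuenchCalibration2AP,
    percent_to_fluorescence,
    fluorescence_to_percent,
    predict_intermediates,
    substrate_percent_to_two_AP,
    two_AP_to_substrate_percent,
    trajectory_to_percent,
)
from .timeseries import TimeCourseData, TitrationData

__all__ = [
    "NoiseModel",
    "AbortiveExperiment",
    "generate_exchange_course",
    "generate_abortive_experiment",
    "generate_titration",
    "generate_association",
    "generate_dissociation",
    "DEFAULT_QUENCH_TIMES",
]

DEFAULT_QUENCH_TIMES = (150.0, 300.0, 600.0, 900.0)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian instrument noise on the reported signal.

    ``sd`` is in the units of the reported signal (percentage points for
    strand-exchange assays, anisotropy units for filament assays).
    """

    sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _default_grid() -> np.ndarray:
    # 1 Hz real-time fluorometer sampling over the standard 1000 s window
    return np.arange(0.0, 1001.0, 1.0)


def generate_exchange_course(
    scheme: ReactionScheme | str = ReactionScheme.THREE_STEP,
    rates: RateConstants | None = None,
    A0: float = 36.0,
    B0: float = 36.0,
    times=None,
    calib: FretCalibration | None = None,
    assay: AssayKind | str = AssayKind.PAIRING,
    noise: NoiseModel | None = None,
) -> TimeCourseData:
    """Simulated pairing/displacement/2AP time course with raw fluorescence.

    The pipeline is simulate -> percent -> inverse calibration to
    fluorescence -> additive Gaussian noise in signal space -> noisy
    percent via the forward calibration (unclipped, so the percent noise is
    exactly Gaussian with the requested sd).  Returns a
    :class:`TimeCourseData` whose ``truth`` carries the generating rates,
    trajectory, noiseless percent and both clean and noisy fluorescence.
    """
    from .reactions import DEFAULT_THREE_STEP_RATES, DEFAULT_TWO_STEP_RATES

    scheme = ReactionScheme(scheme)
    assay = AssayKind(assay)
    if rates is None:
        rates = (
            DEFAULT_THREE_STEP_RATES
            if scheme is ReactionScheme.THREE_STEP
            else DEFAULT_TWO_STEP_RATES
        )
    times = _default_grid() if times is None else np.asarray(times, dtype=float)
    noise = noise or NoiseModel()

    traj = simulate(scheme, rates, ReactionState(A=A0, B=B0), times)
    pct = trajectory_to_percent(traj, assay)

    if assay is AssayKind.TWO_AP:
        calib2 = QuenchCalibration2AP()
        fluor = substrate_percent_to_two_AP(pct, calib2)
        # percent-space sd maps to relative-fluorescence sd through the
        # affine slope (1 - quench_fraction)/100
        sd_f = noise.sd * (1.0 - calib2.quench_fraction) / 100.0
        if noise.sd == 0:
            noisy_f, noisy_pct = fluor.copy(), pct.copy()
        else:
            noisy_f = fluor + noise.rng().normal(0.0, sd_f, size=fluor.shape)
            noisy_pct = np.asarray(
                two_AP_to_substrate_percent(np.clip(noisy_f, 1e-9, 1.0), calib2)
            )
    else:
        calib = calib or FretCalibration()
        fluor = percent_to_fluorescence(pct, calib, assay)
        if assay is AssayKind.PAIRING:
            slope = calib.E_max * calib.F0 / 100.0
        else:
            slope = calib.E_max / (1.0 - calib.E_max) * calib.F0 / 100.0
        sd_f = noise.sd * slope
        if noise.sd == 0:
            noisy_f, noisy_pct = fluor.copy(), pct.copy()
        else:
            noisy_f = fluor + noise.rng().normal(0.0, sd_f, size=fluor.shape)
            noisy_pct = fluorescence_to_percent(
                np.clip(noisy_f, 1e-9, None), calib, assay, clip=False
            )

    return TimeCourseData(
        times=times,
        values=noisy_pct,
        assay=assay.value,
        A0=A0,
        B0=B0,
        condition={"scheme": scheme.value, "noise_sd": noise.sd, "seed": noise.seed},
        truth={
            "scheme": scheme,
            "rates": rates,
            "trajectory": traj,
            "percent": pct,
            "fluorescence": fluor,
            "noisy_fluorescence": noisy_f,
        },
    )


@dataclass
class AbortiveExperiment:
    """SDS-quench experiment in DSP and DSD modes with ground truth.

    For each quench time the reaction is collapsed instantaneously
    (C1 -> free substrates, C2 -> final products) and the flat post-SDS
    signal is read ``readout_delay`` seconds later.  ``substrate_before``
    is the pairing readout just before SDS; ``substrate_after`` the
    pairing readout post-collapse (DSP mode); ``product_after`` the
    displacement readout post-collapse (DSD mode).  ``truth_C1`` and
    ``truth_C2_plus_product`` come from the intermediate prediction of the
    uncollapsed trajectory at the quench times.
    """

    quench_times: np.ndarray
    readout_delay: float
    substrate_before: np.ndarray
    substrate_after: np.ndarray
    product_after: np.ndarray
    truth_C1: np.ndarray
    truth_C2_plus_product: np.ndarray


def generate_abortive_experiment(
    scheme: ReactionScheme | str = ReactionScheme.THREE_STEP,
    rates: RateConstants | None = None,
    A0: float = 36.0,
    B0: float = 36.0,
    quench_times=None,
    readout_delay: float = 150.0,
    noise: NoiseModel | None = None,
) -> AbortiveExperiment:
    """Paired DSP/DSD abortive datasets from one simulated reaction."""
    from .reactions import DEFAULT_THREE_STEP_RATES, DEFAULT_TWO_STEP_RATES

    scheme = ReactionScheme(scheme)
    if rates is None:
        rates = (
            DEFAULT_THREE_STEP_RATES
            if scheme is ReactionScheme.THREE_STEP
            else DEFAULT_TWO_STEP_RATES
        )
    quench = np.asarray(
        DEFAULT_QUENCH_TIMES if quench_times is None else quench_times, dtype=float
    )
    noise = noise or NoiseModel(sd=0.0)
    rng = noise.rng()

    grid = np.unique(np.concatenate(([0.0], quench)))
    traj = simulate(scheme, rates, ReactionState(A=A0, B=B0), grid)
    c1_pct, c2p_pct = predict_intermediates(traj)

    sub_before = np.empty(quench.shape)
    sub_after = np.empty(quench.shape)
    prod_after = np.empty(quench.shape)
    truth_c1 = np.empty(quench.shape)
    truth_c2p = np.empty(quench.shape)
    for i, tq in enumerate(quench):
        j = int(np.flatnonzero(np.isclose(grid, tq))[0])
        state = traj.states[j]
        A, B, C1, C2, D, E = state
        sub_before[i] = 100.0 * A / A0
        # instantaneous collapse: C1 joins the free substrates, C2 the products
        sub_after[i] = 100.0 * (A + C1) / A0
        prod_after[i] = 100.0 * (E + C2) / B0
        truth_c1[i] = c1_pct[j]
        truth_c2p[i] = c2p_pct[j]

    if noise.sd > 0:
        sub_before = sub_before + rng.normal(0.0, noise.sd, sub_before.shape)
        sub_after = sub_after + rng.normal(0.0, noise.sd, sub_after.shape)
        prod_after = prod_after + rng.normal(0.0, noise.sd, prod_after.shape)

    return AbortiveExperiment(
        quench_times=quench,
        readout_delay=readout_delay,
        substrate_before=sub_before,
        substrate_after=sub_after,
        product_after=prod_after,
        truth_C1=truth_c1,
        truth_C2_plus_product=truth_c2p,
    )


def generate_titration(
    K_D_uM: float = 1.22,
    n: float = 3.0,
    baseline: float = 0.05,
    amplitude: float = 0.10,
    concentrations_uM=None,
    noise: NoiseModel | None = None,
) -> TitrationData:
    """Hill-model anisotropy titration (defaults: 12 log-spaced points
    spanning 0.05-5 uM around the ATP-condition Dmc1 affinity)."""
    conc = (
        np.logspace(np.log10(0.05), np.log10(5.0), 12)
        if concentrations_uM is None
        else np.asarray(concentrations_uM, dtype=float)
    )
    noise = noise or NoiseModel(sd=0.0)
    cn = np.where(conc > 0, conc, np.nan) ** n
    clean = np.where(
        conc > 0, baseline + amplitude * cn / (K_D_uM**n + cn), baseline
    )
    values = clean + noise.rng().normal(0.0, noise.sd, clean.shape)
    return TitrationData(
        concentrations_uM=conc,
        anisotropy=values,
        truth={
            "K_D": K_D_uM,
            "n": n,
            "baseline": baseline,
            "amplitude": amplitude,
            "anisotropy": clean,
        },
    )


def generate_association(
    T_half: float = 20.7,
    n: float = 3.0,
    baseline: float = 0.15,
    amplitude: float = 0.10,
    times=None,
    noise: NoiseModel | None = None,
) -> TimeCourseData:
    """Sigmoidal filament association curve, 0.5 s sampling to 120 s."""
    t = np.arange(0.0, 120.5, 0.5) if times is None else np.asarray(times, dtype=float)
    noise = noise or NoiseModel(sd=0.0)
    tn = np.where(t > 0, t, np.nan) ** n
    clean = np.where(t > 0, baseline + amplitude * tn / (T_half**n + tn), baseline)
    values = clean + noise.rng().normal(0.0, noise.sd, clean.shape)
    return TimeCourseData(
        times=t,
        values=values,
        assay="association",
        condition={"noise_sd": noise.sd, "seed": noise.seed},
        truth={
            "T_half": T_half,
            "n": n,
            "baseline": baseline,
            "amplitude": amplitude,
            "anisotropy": clean,
        },
    )


def generate_dissociation(
    k_off: float = 0.133,
    amplitude: float = 0.10,
    baseline: float = 0.20,
    times=None,
    noise: NoiseModel | None = None,
) -> TimeCourseData:
    """Single-exponential filament dissociation, 0.5 s sampling to 600 s."""
    t = np.arange(0.0, 600.5, 0.5) if times is None else np.asarray(times, dtype=float)
    noise = noise or NoiseModel(sd=0.0)
    clean = amplitude * np.exp(-k_off * t) + baseline
    values = clean + noise.rng().normal(0.0, noise.sd, clean.shape)
    return TimeCourseData(
        times=t,
        values=values,
        assay="dissociation",
        condition={"noise_sd": noise.sd, "seed": noise.seed},
        truth={
            "k_off": k_off,
            "amplitude": amplitude,
            "baseline": baseline,
            "anisotropy": clean,
        },
    )
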