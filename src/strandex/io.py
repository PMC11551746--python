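"""CSV time-series format, structured configuration, and result records.

Time series are plain CSV with a commented preamble::

    # assay: pairing
    # A0_nM: 36
    # B0_nM: 36
    # replicate_id: 0
    # condition: nucleotide=ATP cation=Mg
    time_s,value
    0,100
    ...

Times are seconds, percent values on the 0-100 scale, anisotropy
dimensionless.  Configuration files are YAML (JSON being a YAML subset).
Results are emitted as CSV records ``parameter,value,unit,standard_error``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .timeseries import TimeCourseData

__all__ = [
    "ParseError",
    "ExperimentConfig",
    "read_timecourse",
    "write_timecourse",
    "load_config",
    "write_results",
]


class ParseError(ValueError):
    """A time-series file violates the expected format."""


_NUMERIC_META = {"A0_nM", "B0_nM", "replicate_id"}


def read_timecourse(path) -> TimeCourseData:
    """Read a CSV time course; preamble keys populate the metadata."""
    path = Path(path)
    meta: dict = {}
    body_lines: list[str] = []
    body_start = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("#"):
                entry = stripped.lstrip("#").strip()
                if ":" in entry:
                    key, _, val = entry.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if not body_lines:
                body_start = lineno
            body_lines.append(line)
    if not body_lines:
        raise ParseError(f"{path}: no data rows found")
    try:
        frame = pd.read_csv(_io.StringIO("".join(body_lines)))
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV body: {exc}") from exc
    for col in ("time_s", "value"):
        if col not in frame.columns:
            raise ParseError(
                f"{path}:{body_start}: missing required column {col!r}"
            )
    for col in ("time_s", "value"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna() & frame[col].notna())
        if bad.size:
            raise ParseError(
                f"{path}:{body_start + 1 + int(bad[0])}: non-numeric value "
                f"{frame[col].iloc[int(bad[0])]!r} in column {col!r}"
            )
        frame[col] = coerced
    if frame[["time_s", "value"]].isna().any().any():
        raise ParseError(f"{path}: missing cells in time_s/value columns")
    times = frame["time_s"].to_numpy(dtype=float)
    nonmono = np.flatnonzero(np.diff(times) <= 0)
    if nonmono.size:
        raise ParseError(
            f"{path}:{body_start + 2 + int(nonmono[0])}: time_s is not "
            "strictly increasing"
        )
    condition = {}
    if "condition" in meta:
        for token in str(meta["condition"]).split():
            if "=" in token:
                k, _, v = token.partition("=")
                condition[k] = v
    return TimeCourseData(
        times=times,
        values=frame["value"].to_numpy(dtype=float),
        assay=str(meta.get("assay", "pairing")),
        A0=float(meta.get("A0_nM", 36.0)),
        B0=float(meta.get("B0_nM", 36.0)),
        condition=condition,
        replicate_id=int(meta.get("replicate_id", 0)),
    )


def write_timecourse(data: TimeCourseData, path) -> None:
    """Write a CSV time course (12 significant digits; lossless round trip)."""
    path = Path(path)
    lines = [
        f"# assay: {data.assay}",
        f"# A0_nM: {data.A0:.12g}",
        f"# B0_nM: {data.B0:.12g}",
        f"# replicate_id: {data.replicate_id}",
    ]
    if data.condition:
        tokens = " ".join(f"{k}={v}" for k, v in data.condition.items())
        lines.append(f"# condition: {tokens}")
    lines.append("time_s,value")
    for t, v in zip(data.times, data.values):
        lines.append(f"{t:.12g},{v:.12g}")
    path.write_text("\n".join(lines) + "\n")


@dataclass
class ExperimentConfig:
    """Structured description of an assay and its analysis settings."""

    assay: str = "pairing"
    scheme: str = "three_step"
    A0_nM: float = 36.0
    B0_nM: float = 36.0
    E_max: float = 0.6
    quench_fraction_2AP: float = 0.601
    n_starts: int = 20
    seed: int = 0
    rtol: float = 1e-8
    atol: float = 1e-10
    bounds: list | None = None
    noise_sd: float = 1.0
    quench_times: list = field(default_factory=lambda: [150.0, 300.0, 600.0, 900.0])
    readout_delay_s: float = 150.0
    nucleation_window_s: float = 10.0

    def __post_init__(self) -> None:
        from .reactions import ReactionScheme
        from .observables import FretCalibration, QuenchCalibration2AP

        ReactionScheme(self.scheme)
        FretCalibration(E_max=self.E_max)
        QuenchCalibration2AP(quench_fraction=self.quench_fraction_2AP)
        if self.A0_nM <= 0 or self.B0_nM <= 0:
            raise ValueError("initial concentrations must be > 0")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.nucleation_window_s <= 0:
            raise ValueError("nucleation_window_s must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from YAML/JSON."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping")
    known = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    return ExperimentConfig(**raw)


def write_results(records, path) -> None:
    """Write fit results as ``parameter,value,unit,standard_error`` CSV.

    ``records`` is an iterable of (parameter, value, unit, standard_error).
    """
    path = Path(path)
    lines = ["parameter,value,unit,standard_error"]
    for name, value, unit, se in records:
        se_txt = "" if se is None or (isinstance(se, float) and np.isnan(se)) else f"{se:.12g}"
        lines.append(f"{name},{value:.12g},{unit},{se_txt}")
    path.write_text("\n".join(lines) + "\n")
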