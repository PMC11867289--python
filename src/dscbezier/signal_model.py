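"""Signal-to-concentration conversion and the tracer-kinetic forward model.

Dynamic susceptibility contrast (DSC) MRI tracks a gadolinium bolus through
brain tissue with fast T2*-weighted imaging.  The measured signal drop is
converted to a contrast-agent concentration estimate

    C_m(t) = -ln[S(t) / S0] / (TE * r2*),

where S0 is the pre-contrast baseline signal, TE the echo time and r2* the
transverse relaxivity.  Tissue and arterial concentration curves are then
linked by the tracer-kinetic convolution

    k_H * C_m(t) = CBF * [R(t) (x) C_a(t - delta)],

with R(t) the tissue residue function, C_a the arterial input function (AIF),
delta the bolus delay from the AIF measurement site to the tissue inlet and
k_H a haematocrit/density correction factor.  Because r2* is rarely known
absolutely, concentration is carried in arbitrary relaxivity-scaled units;
every derived timing parameter (MTT, CTH, delta) and the extraction index are
unaffected by that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AcquisitionConfig",
    "SignalTimeSeries",
    "ConcentrationTimeSeries",
    "signal_to_concentration",
    "shift_aif",
    "forward_model",
    "read_timeseries_csv",
    "write_timeseries_csv",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition parameters of a dynamic gradient-echo EPI bolus scan.

    Parameters
    ----------
    te : float
        Echo time in seconds.
    dt : float
        Frame interval (temporal resolution) in seconds.
    n_frames : int
        Number of dynamic frames.
    n_baseline : int
        Number of pre-contrast (baseline) frames used to estimate S0.
    r2star : float
        Transverse relaxivity in 1/(concentration unit * s).  Concentration
        units are arbitrary; the default 1.0 makes concentration equal to
        the measured Delta-R2* in 1/s.
    k_h : float
        Haematocrit / brain-density correction factor multiplying the tissue
        concentration.  It rescales CBF and CBV only and cancels from MTT,
        CTH, delay and the oxygen extraction index.
    """

    te: float = 0.054
    dt: float = 1.65
    n_frames: int = 46
    n_baseline: int = 11
    r2star: float = 1.0
    k_h: float = 1.0

    def __post_init__(self) -> None:
        if self.te <= 0:
            raise ValueError("te must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_baseline < 1:
            raise ValueError("n_baseline must be >= 1")
        if self.n_baseline >= self.n_frames:
            raise ValueError("n_baseline must be < n_frames")
        if self.r2star <= 0:
            raise ValueError("r2star must be > 0")
        if self.k_h <= 0:
            raise ValueError("k_h must be > 0")

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.dt

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.dt

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AcquisitionConfig":
        """Load acquisition parameters from a YAML file.

        Recognised keys: ``te_s, dt_s, n_frames, n_baseline, r2star, k_h``
        (optionally nested under an ``acquisition:`` block).
        """
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "acquisition" in doc:
            doc = doc["acquisition"]
        return cls(
            te=float(doc["te_s"]),
            dt=float(doc["dt_s"]),
            n_frames=int(doc["n_frames"]),
            n_baseline=int(doc["n_baseline"]),
            r2star=float(doc.get("r2star", 1.0)),
            k_h=float(doc.get("k_h", 1.0)),
        )

    def replace(self, **kwargs) -> "AcquisitionConfig":
        return replace(self, **kwargs)


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-D array with at least 2 samples")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times


@dataclass(frozen=True)
class SignalTimeSeries:
    """Measured MRI signal S(t) for one voxel or region."""

    times: np.ndarray
    values: np.ndarray
    baseline_count: int = 11

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", _check_times(self.times))
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.times.shape:
            raise ValueError("times and values must have the same shape")
        object.__setattr__(self, "values", values)
        if self.baseline_count < 1:
            raise ValueError("baseline_count must be >= 1")
        if self.baseline_count > values.size:
            raise ValueError("baseline_count exceeds number of frames")
        bad = np.flatnonzero(values <= 0)
        if bad.size:
            raise ValueError(f"non-positive signal value at frame {bad[0]}")

    @property
    def s0(self) -> float:
        """Baseline signal: arithmetic mean of the pre-contrast frames."""
        return float(np.mean(self.values[: self.baseline_count]))


@dataclass(frozen=True)
class ConcentrationTimeSeries:
    """Contrast-agent concentration curve in relaxivity-scaled units.

    ``role`` distinguishes the tissue curve C_m from the arterial input
    function C_a; it is informational only.
    """

    times: np.ndarray
    values: np.ndarray
    role: str = "tissue"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", _check_times(self.times))
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.times.shape:
            raise ValueError("times and values must have the same shape")
        if not np.all(np.isfinite(values)):
            raise ValueError("concentration values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def dt(self) -> float:
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
            raise ValueError("time series is not uniformly sampled")
        return float(steps[0])

    def area(self) -> float:
        """Trapezoid area under the curve."""
        return float(np.trapezoid(self.values, self.times))


def signal_to_concentration(
    signal: SignalTimeSeries, acq: AcquisitionConfig
) -> ConcentrationTimeSeries:
    """Convert a signal curve to concentration: C = -ln(S/S0)/(TE*r2*).

    S0 is the arithmetic mean of the first ``baseline_count`` frames.
    """
    s0 = signal.s0
    conc = -np.log(signal.values / s0) / (acq.te * acq.r2star)
    return ConcentrationTimeSeries(signal.times, conc, role="tissue")


def shift_aif(aif: ConcentrationTimeSeries, delta: float) -> ConcentrationTimeSeries:
    """Evaluate the AIF at t - delta on its own grid by linear interpolation.

    ``delta`` is the bolus arrival delay (seconds) between the AIF
    measurement site and the tissue inlet; it must be non-negative.  Samples
    that fall before the shifted curve's support are zero.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0 (delays are physical lags)")
    if delta == 0:
        return aif
    shifted = np.interp(aif.times - delta, aif.times, aif.values, left=0.0)
    return ConcentrationTimeSeries(aif.times, shifted, role=aif.role)


def forward_model(
    residue,
    cbf: float,
    delta: float,
    aif: ConcentrationTimeSeries,
    acq: AcquisitionConfig,
) -> ConcentrationTimeSeries:
    """Tissue concentration predicted by the tracer-kinetic convolution.

    Computes C_m(t) = (CBF / k_H) * sum_j R(t_j) C_a(t - delta - t_j) dt,
    a rectangle-rule discretisation of CBF * [R (x) C_a(t - delta)] / k_H.
    ``residue`` is any object exposing ``evaluate(t)`` (e.g.
    :class:`~dscbezier.residue.BezierResidue`).  Sub-grid delays are handled
    by linear interpolation of the AIF, not by rounding to whole frames.
    """
    dt = aif.dt
    aif_shifted = shift_aif(aif, delta)
    # residue sampled on the lag grid starting at lag 0
    lags = np.arange(aif.times.size) * dt
    r = residue.evaluate(lags)
    conv = np.convolve(r, aif_shifted.values)[: aif.times.size] * dt
    return ConcentrationTimeSeries(aif.times, (cbf / acq.k_h) * conv, role="tissue")


def read_timeseries_csv(path: str | Path, role: str = "tissue") -> ConcentrationTimeSeries:
    """Read a time series from CSV with header columns ``time_s,value``."""
    df = pd.read_csv(path)
    if not {"time_s", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s,value")
    return ConcentrationTimeSeries(df["time_s"].to_numpy(), df["value"].to_numpy(), role=role)


def write_timeseries_csv(series, path: str | Path) -> None:
    """Write a time series to CSV with header ``time_s,value``."""
    pd.DataFrame({"time_s": series.times, "value": series.values}).to_csv(path, index=False)
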