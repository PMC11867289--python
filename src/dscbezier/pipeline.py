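"""Voxel-wise perfusion mapping and whole-brain summaries.

Applies the signal conversion, Bezier deconvolution and oxygen-extraction
model to every voxel inside a brain mask of a 4D dynamic volume, producing
parameter maps (MTT, CTH, AOEF, delay, CBF, CBV) and the whole-brain summary
values: means over non-zero in-mask voxels, with the arterial delay
additionally cleaned by a +-3 scaled-MAD outlier gate before averaging.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .deconvolve import FitOptions, fit_voxel
from .oxygen import CapillaryOxygenModel, OxygenModelParams
from .signal_model import (
    AcquisitionConfig,
    ConcentrationTimeSeries,
    SignalTimeSeries,
    signal_to_concentration,
)

__all__ = [
    "PerfusionMaps",
    "RoiSnr",
    "compute_cbv",
    "mad_outlier_filter",
    "whole_brain_mean",
    "roi_snr",
    "run_pipeline",
]

logger = logging.getLogger("dscbezier")

MAD_SCALE = 1.4826  # normal-consistency constant for the scaled MAD


@dataclass
class PerfusionMaps:
    """Per-voxel parameter maps sharing the mask's 3D shape.

    Values outside the mask (and voxels whose fit failed) are zero, which
    makes them invisible to the "non-zero in-mask mean" summary rule.
    """

    mtt_s: np.ndarray
    cth: np.ndarray
    aoef: np.ndarray
    delta_s: np.ndarray
    cbf: np.ndarray
    cbv: np.ndarray
    mask: np.ndarray
    converged: np.ndarray

    def as_dict(self) -> dict:
        return {
            "mtt_s": self.mtt_s,
            "cth": self.cth,
            "aoef": self.aoef,
            "delta_s": self.delta_s,
            "cbf": self.cbf,
            "cbv": self.cbv,
        }

    def write(self, outdir: str | Path, affine=None) -> None:
        import nibabel as nib

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        affine = np.eye(4) if affine is None else affine
        for name, vol in self.as_dict().items():
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), outdir / f"{name}.nii.gz")
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine), outdir / "mask.nii.gz")


@dataclass(frozen=True)
class RoiSnr:
    """Baseline signal-to-noise ratio of an ROI-mean signal curve."""

    roi: str
    snr: float

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be > 0")


def compute_cbv(
    tissue: ConcentrationTimeSeries, aif: ConcentrationTimeSeries, acq: AcquisitionConfig
) -> float:
    """Relative cerebral blood volume: k_H * area(C_m) / area(C_a).

    Areas are trapezoid integrals; no deconvolution involved.
    """
    aif_area = aif.area()
    if aif_area <= 0:
        raise ValueError("AIF area must be > 0")
    return float(acq.k_h * tissue.area() / aif_area)


def mad_outlier_filter(values, n_mads: float = 3.0) -> np.ndarray:
    """Drop values more than ``n_mads`` scaled MADs from the median.

    The scaled MAD is 1.4826 * median(|x - median|), a robust estimate of
    the standard deviation under normality.  Input order is preserved; a
    zero MAD keeps exactly the values equal to the median.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot filter an empty list")
    med = float(np.median(values))
    mad = MAD_SCALE * float(np.median(np.abs(values - med)))
    return values[np.abs(values - med) <= n_mads * mad]


def whole_brain_mean(volume: np.ndarray, mask: np.ndarray, apply_mad: bool = False) -> float:
    """Mean of non-zero in-mask voxel values; optional scaled-MAD gate.

    The MAD filter (used for the arterial delay, which shows sporadic
    spuriously high voxels) is applied to the non-zero in-mask values
    before averaging.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = np.asarray(volume, dtype=float)[mask]
    vals = vals[np.abs(vals) > 0]
    if vals.size == 0:
        raise ValueError("no non-zero in-mask voxels")
    if apply_mad:
        vals = mad_outlier_filter(vals)
    return float(np.mean(vals))


def roi_snr(signals: np.ndarray, n_baseline: int, roi: str = "venous") -> RoiSnr:
    """Baseline SNR of an ROI from the pre-contrast frames.

    ``signals`` is a 1-D signal time series (SNR = temporal mean / sample
    SD over the first ``n_baseline`` frames) or a 2-D (voxel, time) stack,
    for which mean and SD are pooled over all voxels and baseline frames so
    the SD estimates the per-voxel noise level.
    """
    if n_baseline < 2:
        raise ValueError("n_baseline must be >= 2")
    signals = np.asarray(signals, dtype=float)
    base = signals[..., :n_baseline]
    sd = float(np.std(base, ddof=1))
    if sd == 0:
        raise ValueError("zero variance in baseline frames")
    return RoiSnr(roi=roi, snr=float(np.mean(base)) / sd)


def run_pipeline(
    volume_4d: np.ndarray,
    mask: np.ndarray,
    aif: ConcentrationTimeSeries,
    acq: AcquisitionConfig,
    oxygen_params: OxygenModelParams | None = None,
    options: FitOptions | None = None,
    outdir: str | Path | None = None,
    affine=None,
) -> tuple[PerfusionMaps, pd.DataFrame]:
    """Full voxel-wise analysis of a masked 4D signal volume.

    For each in-mask voxel: signal -> concentration, Bezier deconvolution,
    MTT/CTH/delay/CBF from the fit, CBV from the curve areas and, if
    ``oxygen_params`` is given, AOEF (reported x100 as an arbitrary-unit
    index).  Returns the maps plus a one-row summary table of whole-brain
    means (delay with the scaled-MAD gate).  With ``outdir`` set, maps
    (NIfTI) and the summary (CSV) are written.  Fully deterministic for a
    fixed :class:`FitOptions` seed.
    """
    volume_4d = np.asarray(volume_4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume_4d.ndim != 4:
        raise ValueError("volume must be 4-D (x, y, z, time)")
    if mask.shape != volume_4d.shape[:3]:
        raise ValueError("mask shape does not match volume")
    if volume_4d.shape[3] != aif.times.size:
        raise ValueError("AIF grid does not match the volume's time axis")
    if not mask.any():
        raise ValueError("mask is empty")
    options = options or FitOptions()

    shape3 = mask.shape
    maps = PerfusionMaps(
        mtt_s=np.zeros(shape3),
        cth=np.zeros(shape3),
        aoef=np.zeros(shape3),
        delta_s=np.zeros(shape3),
        cbf=np.zeros(shape3),
        cbv=np.zeros(shape3),
        mask=mask,
        converged=np.zeros(shape3, dtype=bool),
    )

    oxy_model = None
    t_end_max = max(options.t_end_frac * acq.duration, 2 * acq.dt)
    if oxygen_params is not None:
        oxy_model = CapillaryOxygenModel(oxygen_params, tau_max=t_end_max)

    t0 = time.perf_counter()
    n_fit = 0
    # voxel order is fixed by argwhere (C order); fits are independent, so
    # output is invariant to it anyway
    for idx in map(tuple, np.argwhere(mask)):
        series = SignalTimeSeries(aif.times, volume_4d[idx], baseline_count=acq.n_baseline)
        conc = signal_to_concentration(series, acq)
        try:
            fit = fit_voxel(conc, aif, acq, options)
        except Exception:
            logger.warning("voxel %s: fit failed; flagged as zero", idx)
            continue
        if not fit.converged:
            continue
        maps.converged[idx] = True
        maps.mtt_s[idx] = fit.mtt
        maps.cth[idx] = fit.cth
        maps.delta_s[idx] = fit.delta
        maps.cbf[idx] = fit.cbf
        maps.cbv[idx] = compute_cbv(conc, aif, acq)
        if oxy_model is not None:
            maps.aoef[idx] = 100.0 * oxy_model.aoef(fit.residue)
        n_fit += 1
    logger.info("fitted %d voxels in %.1f s", n_fit, time.perf_counter() - t0)

    summary = {
        "n_voxels": int(mask.sum()),
        "n_fitted": n_fit,
        "mtt_s": whole_brain_mean(maps.mtt_s, mask),
        "cth": whole_brain_mean(maps.cth, mask),
        "delta_s": whole_brain_mean(maps.delta_s, mask, apply_mad=True),
        "cbf": whole_brain_mean(maps.cbf, mask),
        "cbv": whole_brain_mean(maps.cbv, mask),
    }
    if oxy_model is not None:
        summary["aoef"] = whole_brain_mean(maps.aoef, mask)
    table = pd.DataFrame([summary])

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        maps.write(outdir, affine=affine)
        table.to_csv(outdir / "summary.csv", index=False, float_format="%.10g")
    return maps, table
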