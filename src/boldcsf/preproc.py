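"""Temporal/spatial preprocessing and mean time-series extraction.

Two branches produce the per-subject signals:

* grey-matter branch: discard initial volumes, polynomial detrend,
  zero-phase band-pass (0.01-0.1 Hz), 4 mm FWHM Gaussian smoothing,
  mask-mean extraction, z-scoring;
* CSF branch: the same temporal steps but NO spatial smoothing, with the
  mean taken over CSF voxels in the designated bottom acquisition slice
  only (subjects whose bottom slice lacks CSF coverage are excluded).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as sps

from .io import MaskVolume, MotionTrace, QcPolicy, QcReport, Volume4D, discard_initial_volumes, motion_qc

__all__ = [
    "TimeSeries",
    "FilterSpec",
    "SmoothSpec",
    "CsfRoiSpec",
    "PipelineConfig",
    "SliceCoverageError",
    "detrend",
    "detrend_volume",
    "bandpass",
    "bandpass_volume",
    "smooth_gaussian",
    "extract_mean_series",
    "extract_csf_series",
    "zscore",
    "negative_derivative",
    "subject_pipeline",
]

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class SliceCoverageError(ValueError):
    """Raised when the designated CSF slice is not covered by the mask."""


@dataclass
class TimeSeries:
    """A regularly sampled 1D signal.

    ``t0`` records the time stamp of the first sample relative to the
    original series (the forward-difference derivative shifts it by dt/2).
    """

    values: np.ndarray
    dt: float
    standardized: bool = False
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 3:
            raise ValueError(f"time series needs >= 3 samples, got {self.values.size}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.standardized:
            if abs(self.values.mean()) > 1e-9 or abs(self.values.std() - 1.0) > 1e-9:
                raise ValueError("series flagged standardized is not z-scored")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class FilterSpec:
    """Band-pass edges and filter settings (Butterworth, zero-phase)."""

    low_hz: float = 0.01
    high_hz: float = 0.1
    order: int = 4
    zero_phase: bool = True

    def validate_for_dt(self, dt: float) -> None:
        nyquist = 0.5 / dt
        if not (0 < self.low_hz < self.high_hz < nyquist):
            raise ValueError(
                f"passband ({self.low_hz}, {self.high_hz}) Hz invalid for "
                f"Nyquist {nyquist} Hz"
            )


@dataclass
class SmoothSpec:
    fwhm_mm: float = 4.0

    def __post_init__(self) -> None:
        if not self.fwhm_mm > 0:
            raise ValueError("fwhm_mm must be positive")


@dataclass
class CsfRoiSpec:
    """Which acquisition slice holds the CSF ROI and its coverage threshold."""

    slice_index: int = 0
    min_voxels: int = 1
    flip_slice_order: bool = False

    def __post_init__(self) -> None:
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")


def detrend(ts: TimeSeries, degree: int = 2) -> TimeSeries:
    """Remove a least-squares polynomial of the given degree (default
    quadratic, i.e. constant + linear + quadratic)."""
    if degree not in (1, 2):
        raise ValueError(f"degree must be 1 or 2, got {degree}")
    n = len(ts)
    if n <= degree + 1:
        raise ValueError(f"series of length {n} too short for degree-{degree} detrend")
    t = np.arange(n, dtype=float)
    coefs = np.polynomial.polynomial.polyfit(t, ts.values, degree)
    fit = np.polynomial.polynomial.polyval(t, coefs)
    return dataclasses.replace(ts, values=ts.values - fit, standardized=False)


def detrend_volume(vol: Volume4D, degree: int = 2) -> Volume4D:
    """Voxelwise polynomial detrend along the time axis."""
    if degree not in (1, 2):
        raise ValueError(f"degree must be 1 or 2, got {degree}")
    n = vol.n_volumes
    t = np.arange(n, dtype=float)
    flat = vol.data.reshape(-1, n).T  # (time, voxel)
    coefs = np.polynomial.polynomial.polyfit(t, flat, degree)  # (degree+1, voxel)
    fit = np.polynomial.polynomial.polyval(t, coefs)  # (voxel, time)
    resid = (flat - fit.T).T.reshape(vol.data.shape)
    return dataclasses.replace(vol, data=resid)


def _butter_sos(spec: FilterSpec, dt: float):
    spec.validate_for_dt(dt)
    return sps.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=1.0 / dt, output="sos"
    )


def _apply_filter(values: np.ndarray, spec: FilterSpec, dt: float, axis: int = -1) -> np.ndarray:
    sos = _butter_sos(spec, dt)
    if spec.zero_phase:
        # default padlen is far too short for a 0.01 Hz low edge (settling
        # time ~ 1/low_hz); extend padding to suppress edge transients
        n = values.shape[axis]
        padlen = min(n - 1, int(np.ceil(3.0 / (spec.low_hz * dt))))
        return sps.sosfiltfilt(sos, values, axis=axis, padlen=padlen)
    return sps.sosfilt(sos, values, axis=axis)


def bandpass(ts: TimeSeries, spec: FilterSpec) -> TimeSeries:
    """Zero-phase Butterworth band-pass (forward-backward application)."""
    return dataclasses.replace(
        ts, values=_apply_filter(ts.values, spec, ts.dt), standardized=False
    )


def bandpass_volume(vol: Volume4D, spec: FilterSpec) -> Volume4D:
    return dataclasses.replace(vol, data=_apply_filter(vol.data, spec, vol.tr, axis=-1))


def smooth_gaussian(vol: Volume4D, spec: SmoothSpec | None) -> Volume4D:
    """Spatial Gaussian smoothing with the FWHM given in mm.

    ``spec=None`` disables smoothing (identity).  Sigma per axis is
    ``fwhm / (2*sqrt(2*ln 2))`` divided by the voxel size on that axis.
    """
    if spec is None:
        return vol
    sigma_vox = [spec.fwhm_mm / FWHM_PER_SIGMA / v for v in vol.voxel_size]
    smoothed = ndimage.gaussian_filter(vol.data, sigma=(*sigma_vox, 0.0), mode="nearest")
    return dataclasses.replace(vol, data=smoothed)


def extract_mean_series(vol: Volume4D, mask: MaskVolume) -> TimeSeries:
    """Arithmetic mean over selected voxels at each time point."""
    if mask.data.shape != vol.spatial_shape:
        raise ValueError(
            f"mask shape {mask.data.shape} != volume spatial shape {vol.spatial_shape}"
        )
    if mask.n_selected == 0:
        raise ValueError("empty mask")
    return TimeSeries(values=vol.data[mask.data].mean(axis=0), dt=vol.tr)


def extract_csf_series(vol: Volume4D, csf_mask: MaskVolume, spec: CsfRoiSpec) -> TimeSeries:
    """Mean series over CSF voxels within the designated acquisition slice.

    Raises :class:`SliceCoverageError` when fewer than ``min_voxels`` CSF
    voxels fall in the slice, mirroring the participant-exclusion rule for
    scans whose bottom slice is not covered.
    """
    n_slices = vol.spatial_shape[vol.slice_axis]
    idx = spec.slice_index
    if spec.flip_slice_order:
        idx = n_slices - 1 - idx
    if not 0 <= idx < n_slices:
        raise ValueError(f"slice index {idx} out of range for {n_slices} slices")
    slice_sel = np.zeros(vol.spatial_shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[vol.slice_axis] = idx
    slice_sel[tuple(sl)] = True
    roi = csf_mask.data & slice_sel
    n_roi = int(roi.sum())
    if n_roi < spec.min_voxels:
        raise SliceCoverageError(
            f"slice not covered: {n_roi} CSF voxel(s) in slice {idx}, "
            f"need >= {spec.min_voxels}"
        )
    return TimeSeries(values=vol.data[roi].mean(axis=0), dt=vol.tr)


def zscore(ts: TimeSeries) -> TimeSeries:
    """Standardize to mean 0, population SD 1 (divisor N)."""
    sd = ts.values.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant series")
    return dataclasses.replace(
        ts, values=(ts.values - ts.values.mean()) / sd, standardized=True
    )


def negative_derivative(ts: TimeSeries) -> TimeSeries:
    """Negative forward-difference derivative, length N-1.

    Sample i is ``-(x[i+1] - x[i]) / dt`` and is time-stamped half a sample
    after x[i] (recorded in ``t0``).
    """
    if len(ts) < 2:
        raise ValueError("need >= 2 samples for a derivative")
    vals = -np.diff(ts.values) / ts.dt
    return TimeSeries(values=vals, dt=ts.dt, standardized=False, t0=ts.t0 + ts.dt / 2.0)


@dataclass
class PipelineConfig:
    """Knobs for the per-subject preprocessing chain."""

    qc: QcPolicy = field(default_factory=QcPolicy)
    bandpass: FilterSpec = field(default_factory=FilterSpec)
    smooth: SmoothSpec | None = field(default_factory=SmoothSpec)
    csf_roi: CsfRoiSpec = field(default_factory=CsfRoiSpec)
    detrend_degree: int = 2


@dataclass
class SubjectSignals:
    gbold: TimeSeries
    csf: TimeSeries
    qc: QcReport


def subject_pipeline(
    vol: Volume4D,
    gm_mask: MaskVolume,
    csf_mask: MaskVolume,
    motion: MotionTrace | None,
    config: PipelineConfig | None = None,
) -> SubjectSignals:
    """Run both preprocessing branches for one subject.

    gBOLD branch: discard -> detrend -> band-pass -> smooth -> GM mean ->
    z-score.  CSF branch: discard -> detrend -> band-pass -> slice-CSF
    mean -> z-score (no smoothing).  A motion-QC failure flags the subject
    excluded but does not abort signal extraction; a CSF-coverage failure
    propagates as :class:`SliceCoverageError`.
    """
    config = config or PipelineConfig()
    if motion is not None:
        qc = motion_qc(motion, config.qc)
    else:
        qc = QcReport(passed=True, max_trans_mm=0.0, max_rot_deg=0.0)

    vol = discard_initial_volumes(vol, config.qc)
    vol = detrend_volume(vol, config.detrend_degree)
    vol = bandpass_volume(vol, config.bandpass)

    gm_vol = smooth_gaussian(vol, config.smooth)
    gbold = zscore(extract_mean_series(gm_vol, gm_mask))
    csf = zscore(extract_csf_series(vol, csf_mask, config.csf_roi))
    return SubjectSignals(gbold=gbold, csf=csf, qc=qc)
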