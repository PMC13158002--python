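"""NIfTI volume/mask I/O, motion-parameter files, and scan-level quality control.

Volumes are NIfTI-1 images with the time axis last.  Motion parameters are
6-column whitespace text in the SPM ``rp_*.txt`` dialect (three translations
in mm followed by three rotations, radians by default).  QC applies the
initial-volume discard and the maximum translation/rotation exclusion rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume4D",
    "MaskVolume",
    "MotionTrace",
    "QcPolicy",
    "QcReport",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_motion_params",
    "write_motion_params",
    "discard_initial_volumes",
    "motion_qc",
    "write_qc_table",
]


@dataclass
class Volume4D:
    """A 4D fMRI intensity grid (x, y, slice, time).

    Parameters
    ----------
    data
        4D float array; the last axis indexes time.
    voxel_size
        Voxel edge lengths in mm for the three spatial axes.
    tr
        Repetition time (sampling interval of the time axis), seconds.
    slice_axis
        Spatial axis that indexes acquisition slices (default 2, i.e. the
        third spatial axis; slice 0 is the bottom slice).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    tr: float
    slice_axis: int = 2
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if any(s < 1 for s in self.data.shape[:3]):
            raise ValueError(f"all spatial dims must be >= 1, got {self.data.shape[:3]}")
        if self.data.shape[3] < 2:
            raise ValueError(f"time dim must be >= 2, got {self.data.shape[3]}")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be strictly positive, got {self.voxel_size}")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError(f"slice_axis must be a spatial axis 0..2, got {self.slice_axis}")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class MaskVolume:
    """A 3D boolean voxel-selection mask on the same grid as its volume."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def n_selected(self) -> int:
        return int(self.data.sum())


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion parameters.

    ``translations`` are (n, 3) in mm; ``rotations_deg`` are (n, 3) in
    degrees (converted on read when the file stores radians).  Values are
    displacements relative to the realignment reference image.
    """

    translations: np.ndarray
    rotations_deg: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations_deg = np.atleast_2d(np.asarray(self.rotations_deg, dtype=float))
        if self.translations.shape != self.rotations_deg.shape or self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be (n, 3)")
        if not (np.isfinite(self.translations).all() and np.isfinite(self.rotations_deg).all()):
            raise ValueError("motion parameters must be finite")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]


@dataclass
class QcPolicy:
    """Discard count and motion-exclusion thresholds."""

    n_discard: int = 10
    trans_limit_mm: float = 1.5
    rot_limit_deg: float = 1.5

    def __post_init__(self) -> None:
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        if self.trans_limit_mm <= 0 or self.rot_limit_deg <= 0:
            raise ValueError("motion limits must be positive")


@dataclass
class QcReport:
    passed: bool
    max_trans_mm: float
    max_rot_deg: float
    reason: str | None = None


def read_volume(path: str | Path, tr: float | None = None) -> Volume4D:
    """Read a 4D NIfTI-1 image.

    TR is taken from the header time step unless ``tr`` overrides it; a
    non-positive header TR without an explicit override is an error.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected 4D image, got {img.ndim}D: {path}")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr is None:
        if header_tr <= 0:
            raise ValueError(
                f"non-positive TR ({header_tr}) in header of {path}; pass tr explicitly"
            )
        tr = header_tr
    return Volume4D(
        data=np.asarray(img.dataobj, dtype=float),
        voxel_size=tuple(float(z) for z in zooms[:3]),
        tr=float(tr),
        affine=np.asarray(img.affine),
    )


def write_volume(vol: Volume4D, path: str | Path) -> None:
    affine = vol.affine if vol.affine is not None else np.diag([*vol.voxel_size, 1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms((*vol.voxel_size, vol.tr))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_mask(path: str | Path, reference: Volume4D) -> MaskVolume:
    """Read a 3D label/binary image as a mask; nonzero voxels are selected."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D mask image, got {data.ndim}D: {path}")
    if data.shape != reference.spatial_shape:
        raise ValueError(
            f"mask shape {data.shape} does not match reference spatial shape "
            f"{reference.spatial_shape}"
        )
    mask = MaskVolume(data=data != 0, voxel_size=reference.voxel_size)
    if mask.n_selected == 0:
        raise ValueError(f"mask selects no voxels: {path}")
    return mask


def write_mask(mask: MaskVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), np.diag([*mask.voxel_size, 1.0]))
    nib.save(img, str(path))


def read_motion_params(path: str | Path, dialect: str = "rp-radians") -> MotionTrace:
    """Read a 6-column motion-parameter text file.

    Columns 1-3 are translations (mm); columns 4-6 rotations.  With the
    default ``rp-radians`` dialect (SPM/DPABI ``rp_*.txt``) rotations are
    stored in radians and converted to degrees; ``rp-degrees`` reads them
    as-is.
    """
    if dialect not in ("rp-radians", "rp-degrees"):
        raise ValueError(f"unknown motion dialect: {dialect!r}")
    try:
        arr = np.loadtxt(str(path), ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric motion parameter file {path}: {exc}") from exc
    if arr.shape[1] != 6:
        raise ValueError(f"expected 6 columns in {path}, got {arr.shape[1]}")
    rotations = arr[:, 3:6]
    if dialect == "rp-radians":
        rotations = np.degrees(rotations)
    return MotionTrace(translations=arr[:, 0:3], rotations_deg=rotations)


def write_motion_params(trace: MotionTrace, path: str | Path, dialect: str = "rp-radians") -> None:
    rot = trace.rotations_deg
    if dialect == "rp-radians":
        rot = np.radians(rot)
    elif dialect != "rp-degrees":
        raise ValueError(f"unknown motion dialect: {dialect!r}")
    np.savetxt(str(path), np.hstack([trace.translations, rot]), fmt="%.8f")


def discard_initial_volumes(vol: Volume4D, policy: QcPolicy) -> Volume4D:
    """Drop the first ``policy.n_discard`` volumes; TR is unchanged."""
    if policy.n_discard >= vol.n_volumes:
        raise ValueError(
            f"cannot discard {policy.n_discard} of {vol.n_volumes} volumes"
        )
    if policy.n_discard == 0:
        return vol
    return dataclasses.replace(vol, data=vol.data[..., policy.n_discard :])


def motion_qc(trace: MotionTrace, policy: QcPolicy) -> QcReport:
    """Apply the maximum-motion exclusion rule.

    Fails iff max |translation| > ``trans_limit_mm`` or max |rotation| >
    ``rot_limit_deg`` (strict inequality: a maximum exactly at the limit
    passes).  Maxima are over all volumes and all three axes.
    """
    if trace.n_volumes == 0:
        raise ValueError("empty motion trace")
    max_trans = float(np.abs(trace.translations).max())
    max_rot = float(np.abs(trace.rotations_deg).max())
    reasons = []
    if max_trans > policy.trans_limit_mm:
        reasons.append(f"translation {max_trans:.3f} mm > {policy.trans_limit_mm} mm")
    if max_rot > policy.rot_limit_deg:
        reasons.append(f"rotation {max_rot:.3f} deg > {policy.rot_limit_deg} deg")
    return QcReport(
        passed=not reasons,
        max_trans_mm=max_trans,
        max_rot_deg=max_rot,
        reason="; ".join(reasons) or None,
    )


def write_qc_table(reports: dict[str, QcReport], path: str | Path) -> None:
    """Write a per-subject QC table as TSV."""
    rows = [
        {
            "subject_id": sid,
            "max_trans_mm": rep.max_trans_mm,
            "max_rot_deg": rep.max_rot_deg,
            "pass": rep.passed,
            "reason": rep.reason or "",
        }
        for sid, rep in reports.items()
    ]
    pd.DataFrame(rows).to_csv(str(path), sep="\t", index=False)
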