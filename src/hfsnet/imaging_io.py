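"""Volume I/O and preprocessing for three-phase dynamic CT.

Responsibilities: reading NIfTI volumes and DICOM series, in-plane
resampling to a fixed 256x256 / 1.4 mm-per-pixel grid, soft-tissue intensity
normalization, Z-axis alignment of the non-contrast / arterial /
portal-venous phases by nearest slice coordinate, and stacking aligned
phases into multi-channel images for the 2D networks.

Axis convention: arrays are indexed ``(slice, row, col)`` = (z, y, x),
0-based; ``spacing_mm`` is ``(z, y, x)``.  Diameters are reported in cm
using the in-plane spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

PHASE_NAMES = ("non_contrast", "arterial", "portal_venous")

# preprocessing defaults (recorded in case sidecars so they are auditable)
TARGET_SIZE = 256
TARGET_SPACING_MM = 1.4
HU_CLIP = (-50.0, 150.0)  # narrow soft-tissue window (W200/C50) for liver CT


class AlignmentError(RuntimeError):
    """Raised when the three phases share no usable Z range."""


@dataclass
class SinglePhaseVolume:
    """One phase: a 3D intensity array plus its geometry."""

    data: np.ndarray            # (slices, rows, cols)
    spacing_mm: tuple           # (z, y, x)
    z_coords: np.ndarray | None = None
    case_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3D (slice, row, col)")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.z_coords is None:
            self.z_coords = np.arange(self.data.shape[0]) * self.spacing_mm[0]
        self.z_coords = np.asarray(self.z_coords, dtype=np.float64)
        if len(self.z_coords) != self.data.shape[0]:
            raise ValueError("one z coordinate per slice required")
        if len(self.z_coords) > 1 and not np.all(np.diff(self.z_coords) > 0):
            raise ValueError("z coordinates must be strictly increasing")


@dataclass
class DynamicCTVolume:
    """Z-aligned three-phase volume; the pipeline's raw input."""

    non_contrast: np.ndarray
    arterial: np.ndarray
    portal_venous: np.ndarray
    spacing_mm: tuple
    z_coords: np.ndarray | None = None
    case_id: str = ""

    def __post_init__(self):
        shapes = {self.non_contrast.shape, self.arterial.shape,
                  self.portal_venous.shape}
        if len(shapes) != 1:
            raise ValueError("all three phases must share one shape after "
                             "alignment")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.z_coords is None:
            self.z_coords = (np.arange(self.non_contrast.shape[0])
                             * self.spacing_mm[0])
        self.z_coords = np.asarray(self.z_coords, dtype=np.float64)

    @property
    def phases(self) -> tuple:
        return (self.non_contrast, self.arterial, self.portal_venous)

    @property
    def shape(self) -> tuple:
        return self.non_contrast.shape

    def phase(self, name: str) -> np.ndarray:
        if name not in PHASE_NAMES:
            raise KeyError(f"unknown phase {name!r}")
        return getattr(self, name)


@dataclass
class LabelVolume:
    """Integer instance labels: 0 background, positive ids = instances."""

    labels: np.ndarray
    role: str = "tumor"  # "liver" | "tumor"
    spacing_mm: tuple = (2.5, 1.4, 1.4)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer typed")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if self.role not in ("liver", "tumor"):
            raise ValueError("role must be 'liver' or 'tumor'")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def instance_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


# -- reading -----------------------------------------------------------------

def load_volume(path, format: str | None = None,
                case_id: str = "") -> SinglePhaseVolume:
    """Load one phase from a NIfTI file or a DICOM series directory.

    Orientation is normalized to closest-canonical (RAS) and arrays are
    returned in (slice, row, col) order with increasing z.
    """
    path = Path(path)
    if format is None:
        format = "dicom" if path.is_dir() else "nifti"
    if format == "nifti":
        return _load_nifti(path, case_id)
    if format == "dicom":
        return _load_dicom_series(path, case_id)
    raise ValueError(f"unknown format {format!r}")


def _load_nifti(path: Path, case_id: str) -> SinglePhaseVolume:
    img = nib.as_closest_canonical(nib.load(str(path)))
    arr = np.asanyarray(img.dataobj)  # (x, y, z)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {arr.ndim}D")
    data = np.transpose(arr, (2, 1, 0))  # -> (z, y, x)
    zooms = img.header.get_zooms()[:3]   # (x, y, z)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    nz = data.shape[0]
    vox = np.zeros((nz, 3))
    vox[:, 2] = np.arange(nz)
    z_coords = nib.affines.apply_affine(img.affine, vox)[:, 2]
    return SinglePhaseVolume(data, spacing, z_coords, case_id or path.stem)


def _load_dicom_series(path: Path, case_id: str) -> SinglePhaseVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FileNotFoundError(f"no .dcm files in {path}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    dz = np.diff(zs)
    if len(dz) and (dz.max() - dz.min()) > 0.1 * np.median(dz):
        i = int(np.argmax(dz))
        raise ValueError(
            f"inconsistent slice spacing in {path}: Z gap of {dz[i]:.2f} mm "
            f"between z={zs[i]:.2f} and z={zs[i + 1]:.2f} "
            f"(median {np.median(dz):.2f} mm)")
    ref = slices[0]
    py, px = (float(v) for v in ref.PixelSpacing)
    data = np.stack([
        ds.pixel_array.astype(np.float64) * float(getattr(ds, "RescaleSlope", 1))
        + float(getattr(ds, "RescaleIntercept", 0)) for ds in slices
    ])
    spacing = (float(np.median(dz)) if len(dz) else 1.0, py, px)
    return SinglePhaseVolume(data, spacing, zs,
                             case_id or getattr(ref, "PatientID", path.name))


# -- writing -----------------------------------------------------------------

def save_nifti(data: np.ndarray, spacing_mm: tuple, path,
               z_origin: float = 0.0) -> None:
    """Write a (slice, row, col) array as NIfTI with the package's axis
    convention (inverse of :func:`load_volume`)."""
    arr = np.transpose(np.asarray(data), (2, 1, 0))  # (x, y, z)
    sz, sy, sx = spacing_mm
    affine = np.diag([sx, sy, sz, 1.0]).astype(np.float64)
    affine[2, 3] = z_origin
    nib.save(nib.Nifti1Image(arr, affine), str(path))


# -- preprocessing -----------------------------------------------------------

def resample_inplane(vol: SinglePhaseVolume,
                     target_spacing: float = TARGET_SPACING_MM,
                     is_label: bool = False,
                     anisotropy_tol: float = 0.01) -> SinglePhaseVolume:
    """Rescale rows/cols so one pixel equals ``target_spacing`` mm.

    Linear interpolation for intensities, nearest for labels; physical
    in-plane extent is preserved to within one voxel.
    """
    sz, sy, sx = vol.spacing_mm
    if abs(sy - sx) > anisotropy_tol * max(sy, sx):
        raise ValueError(f"anisotropic in-plane spacing ({sy} vs {sx} mm) "
                         "beyond tolerance")
    factors = (1.0, sy / target_spacing, sx / target_spacing)
    if np.allclose(factors, 1.0):
        return SinglePhaseVolume(vol.data.copy(), (sz, target_spacing,
                                                   target_spacing),
                                 vol.z_coords, vol.case_id)
    order = 0 if is_label else 1
    out = ndimage.zoom(vol.data, factors, order=order, mode="nearest",
                       grid_mode=True)
    return SinglePhaseVolume(out, (sz, target_spacing, target_spacing),
                             vol.z_coords, vol.case_id)


def _crop_or_pad(data: np.ndarray, target: int, fill: float) -> np.ndarray:
    out = data
    for ax in (1, 2):
        size = out.shape[ax]
        if size > target:
            lo = (size - target) // 2
            sl = [slice(None)] * 3
            sl[ax] = slice(lo, lo + target)
            out = out[tuple(sl)]
        elif size < target:
            before = (target - size) // 2
            pad = [(0, 0)] * 3
            pad[ax] = (before, target - size - before)
            out = np.pad(out, pad, constant_values=fill)
    return out


def normalize_intensity(data: np.ndarray, clip=HU_CLIP) -> np.ndarray:
    """Clip to the soft-tissue window and scale that fixed window to [0, 1].

    The window is fixed (not per-volume min-max) because CT intensities are
    calibrated in HU; a data-dependent rescale would map the same tissue to
    different values depending on what else is in the volume — e.g. a
    lesion-free liver would be stretched to lesion-like brightness in the
    arterial phase.
    """
    lo, hi = clip
    out = np.clip(np.asarray(data, dtype=np.float64), lo, hi)
    return (out - lo) / (hi - lo)


def preprocess(vol: SinglePhaseVolume,
               target_size: int = TARGET_SIZE,
               target_spacing: float = TARGET_SPACING_MM,
               normalize: bool = True,
               clip=HU_CLIP,
               is_label: bool = False) -> SinglePhaseVolume:
    """Standardize one phase: resample in-plane to ``target_spacing`` mm/px,
    center crop/pad to ``target_size``², then (for intensities) clip to the
    soft-tissue window and min-max normalize to [0, 1]."""
    res = resample_inplane(vol, target_spacing, is_label=is_label)
    fill = 0.0 if is_label else float(np.min(res.data))
    data = _crop_or_pad(res.data, target_size, fill)
    if normalize and not is_label:
        data = normalize_intensity(data, clip)
    elif is_label:
        data = np.rint(data).astype(np.int32)
    return SinglePhaseVolume(data, res.spacing_mm, res.z_coords, res.case_id)


# -- Z alignment -------------------------------------------------------------

def align_phases(nc: SinglePhaseVolume, art: SinglePhaseVolume,
                 pv: SinglePhaseVolume, tol: float | None = None,
                 case_id: str = "") -> DynamicCTVolume:
    """Match the three phases slice-by-slice on physical Z coordinates.

    The portal-venous grid restricted to the common Z range is the
    reference; each phase contributes its nearest slice (within ``tol``,
    default half the reference slice spacing).  Raises
    :class:`AlignmentError` when the ranges do not overlap or a reference
    slice has no counterpart.
    """
    phases = {"non_contrast": nc, "arterial": art, "portal_venous": pv}
    zlo = max(v.z_coords.min() for v in phases.values())
    zhi = min(v.z_coords.max() for v in phases.values())
    if zlo > zhi:
        raise AlignmentError("phases share no Z range; cannot align")
    ref = pv.z_coords[(pv.z_coords >= zlo - 1e-9) & (pv.z_coords <= zhi + 1e-9)]
    if ref.size == 0:
        raise AlignmentError("no portal-venous slice inside the common Z range")
    if tol is None:
        dz = np.diff(pv.z_coords)
        tol = float(np.median(dz)) / 2.0 if dz.size else np.inf

    aligned = {}
    for name, vol in phases.items():
        idx = np.abs(vol.z_coords[None, :] - ref[:, None]).argmin(axis=1)
        dist = np.abs(vol.z_coords[idx] - ref)
        if np.any(dist > tol + 1e-9):
            k = int(np.argmax(dist))
            raise AlignmentError(
                f"phase {name}: no slice within {tol:.2f} mm of z={ref[k]:.2f}")
        aligned[name] = vol.data[idx]

    return DynamicCTVolume(aligned["non_contrast"], aligned["arterial"],
                           aligned["portal_venous"], pv.spacing_mm, ref,
                           case_id or pv.case_id)


def stack_dynamic(volume: DynamicCTVolume, slice_index: int,
                  phases: tuple = PHASE_NAMES) -> np.ndarray:
    """Extract one slice as a multi-channel image, channels ordered as
    requested (default: non-contrast, arterial, portal-venous)."""
    n = volume.shape[0]
    if not -n <= slice_index < n:
        raise IndexError(f"slice {slice_index} out of range for {n} slices")
    return np.stack([volume.phase(p)[slice_index] for p in phases])


# -- per-case persistence ----------------------------------------------------

def write_case(case_dir, volume: DynamicCTVolume,
               liver: LabelVolume | None = None,
               tumor: LabelVolume | None = None) -> None:
    """Write phases and masks as .nii.gz plus a JSON sidecar."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    z0 = float(volume.z_coords[0])
    for name in PHASE_NAMES:
        save_nifti(volume.phase(name), volume.spacing_mm,
                   case_dir / f"{name}.nii.gz", z0)
    if liver is not None:
        save_nifti(liver.labels.astype(np.int16), volume.spacing_mm,
                   case_dir / "liver.nii.gz", z0)
    if tumor is not None:
        save_nifti(tumor.labels.astype(np.int16), volume.spacing_mm,
                   case_dir / "tumor.nii.gz", z0)
    meta = {"case_id": volume.case_id,
            "spacing_mm": list(volume.spacing_mm),
            "z_coords": [float(z) for z in volume.z_coords],
            "provenance": "hfsnet"}
    (case_dir / "case.json").write_text(json.dumps(meta, indent=1))


def read_case(case_dir) -> tuple:
    """Inverse of :func:`write_case`; returns (volume, liver, tumor) with
    ``None`` for absent masks."""
    case_dir = Path(case_dir)
    meta = json.loads((case_dir / "case.json").read_text())
    vols = {}
    for name in PHASE_NAMES:
        vols[name] = load_volume(case_dir / f"{name}.nii.gz").data
    spacing = tuple(meta["spacing_mm"])
    volume = DynamicCTVolume(vols["non_contrast"], vols["arterial"],
                             vols["portal_venous"], spacing,
                             np.asarray(meta["z_coords"]), meta["case_id"])
    liver = tumor = None
    if (case_dir / "liver.nii.gz").exists():
        liver = LabelVolume(load_volume(case_dir / "liver.nii.gz")
                            .data.astype(np.int32), "liver", spacing)
    if (case_dir / "tumor.nii.gz").exists():
        tumor = LabelVolume(load_volume(case_dir / "tumor.nii.gz")
                            .data.astype(np.int32), "tumor", spacing)
    return volume, liver, tumor
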