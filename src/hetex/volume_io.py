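"""Image volume and VOI input/output.

Reads single-frame DICOM series and DICOM-RT structure sets, converts
activity concentration to standardized uptake values (SUV), loads binary
mask volumes from NIfTI, and writes feature tables as CSV spreadsheets.

Coordinate convention: arrays are indexed (z, y, x), 0-based; the world
position of a voxel center is ``origin + index * spacing`` (axis-aligned
axial geometry; oblique orientations are not supported).
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pydicom
from pydicom.errors import InvalidDicomError

__all__ = [
    "ImageVolume",
    "VoiMask",
    "PatientContext",
    "load_dicom_series",
    "to_suv",
    "rtstruct_to_mask",
    "load_mask_volume",
    "load_nifti_volume",
    "save_nifti_volume",
    "write_feature_table",
    "read_feature_table",
]


@dataclasses.dataclass
class ImageVolume:
    """A 3D scalar grid with geometry and intensity units.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Scalar intensities, axis order (z, y, x).
    spacing_mm : tuple of float
        Voxel spacing (dz, dy, dx) in millimetres; all positive.
    origin_mm : tuple of float
        World position of voxel (0, 0, 0), millimetres, (z, y, x) order.
    intensity_units : str
        One of ``"raw"``, ``"Bq/mL"``, ``"SUV"``.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_units: str = "raw"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a non-empty 3D array (z, y, x)")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be three positive values")
        self.origin_mm = tuple(float(s) for s in self.origin_mm)
        if self.intensity_units not in ("raw", "Bq/mL", "SUV"):
            raise ValueError(f"unknown intensity units {self.intensity_units!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        dz, dy, dx = self.spacing_mm
        return dz * dy * dx / 1000.0


@dataclasses.dataclass
class VoiMask:
    """Binary volume of interest aligned voxel-for-voxel with an ImageVolume."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def check_aligned(self, vol: ImageVolume) -> None:
        if self.mask.shape != vol.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match volume {vol.shape}"
            )


@dataclasses.dataclass
class PatientContext:
    """Patient-level quantities needed for SUV conversion.

    decay_correction_factor is the fraction of the injected dose remaining
    at the reference time of the scan (1.0 when the scanner already
    decay-corrects to injection time).
    """

    body_weight_kg: float
    injected_dose_MBq: float
    decay_correction_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("body_weight_kg", "injected_dose_MBq", "decay_correction_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _read_dicom_files(directory: os.PathLike | str) -> list[pydicom.Dataset]:
    directory = Path(directory)
    datasets = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(path))
        except (InvalidDicomError, IsADirectoryError):
            continue
        if not hasattr(ds, "PixelData"):
            continue
        datasets.append(ds)
    if not datasets:
        raise ValueError(f"no DICOM image files found in {directory}")
    return datasets


def load_dicom_series(directory: os.PathLike | str) -> ImageVolume:
    """Load a single-frame DICOM image series into an ImageVolume.

    Slices are sorted by spatial position along the slice normal; rescale
    slope/intercept are applied; units become ``"Bq/mL"`` when the DICOM
    Units attribute says BQML, else ``"raw"``.

    Raises
    ------
    ValueError
        ``"multiple series"`` if files belong to more than one series;
        ``"non-uniform slice spacing"`` if inter-slice distances deviate
        by more than 1% from their mean.
    """
    datasets = _read_dicom_files(directory)

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"multiple series in directory ({len(uids)} series UIDs)")

    # Sort along the slice normal (cross product of the in-plane axes).
    first = datasets[0]
    try:
        iop = np.asarray(first.ImageOrientationPatient, dtype=float)
        normal = np.cross(iop[:3], iop[3:])
        positions = [float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal))
                     for ds in datasets]
    except AttributeError:
        positions = [float(getattr(ds, "InstanceNumber", i))
                     for i, ds in enumerate(datasets)]
    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    positions = [positions[i] for i in order]

    if len(datasets) > 1:
        steps = np.diff(positions)
        mean_step = float(np.mean(steps))
        if mean_step <= 0 or np.any(np.abs(steps - mean_step) > 0.01 * abs(mean_step)):
            raise ValueError("non-uniform slice spacing")
        dz = abs(mean_step)
    else:
        dz = float(getattr(first, "SliceThickness", 1.0) or 1.0)

    ps = [float(v) for v in first.PixelSpacing]  # (row, col) = (dy, dx)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        slices.append(arr * slope + intercept)
    voxels = np.stack(slices, axis=0)

    units = "Bq/mL" if str(getattr(first, "Units", "")).upper() == "BQML" else "raw"
    try:
        ipp = np.asarray(datasets[0].ImagePositionPatient, dtype=float)
        origin = (float(ipp[2]), float(ipp[1]), float(ipp[0]))
    except AttributeError:
        origin = (0.0, 0.0, 0.0)
    return ImageVolume(voxels, (dz, ps[0], ps[1]), origin, units)


def to_suv(vol: ImageVolume, ctx: PatientContext) -> ImageVolume:
    """Convert activity concentration (Bq/mL) to body-weight SUV.

    SUV(v) = concentration(v) / (decay-corrected dose [Bq] / body weight [g]),
    with 1 mL of tissue taken as 1 g.
    """
    if vol.intensity_units != "Bq/mL":
        raise ValueError(f"cannot convert from {vol.intensity_units!r} (need Bq/mL)")
    dose_bq = ctx.injected_dose_MBq * 1e6 * ctx.decay_correction_factor
    weight_g = ctx.body_weight_kg * 1000.0
    suv = vol.voxels / (dose_bq / weight_g)
    return ImageVolume(suv, vol.spacing_mm, vol.origin_mm, "SUV")


# ---------------------------------------------------------------------------
# RT-STRUCT contours -> mask
# ---------------------------------------------------------------------------

def points_in_polygon(px: np.ndarray, py: np.ndarray,
                      poly: np.ndarray) -> np.ndarray:
    """Even-odd (ray casting) point-in-polygon test, vectorized over points.

    A point on a horizontal ray through an edge is counted once per crossing;
    points exactly on vertices follow the half-open edge convention.
    """
    px = np.asarray(px, float)
    py = np.asarray(py, float)
    poly = np.asarray(poly, float)
    inside = np.zeros(px.shape, dtype=bool)
    x1, y1 = poly[-1]
    for x2, y2 in poly:
        crosses = (y1 > py) != (y2 > py)
        if np.any(crosses):
            with np.errstate(divide="ignore", invalid="ignore"):
                xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (px < xint)
        x1, y1 = x2, y2
    return inside


def rtstruct_to_mask(rtstruct: os.PathLike | str, vol: ImageVolume,
                     roi_name: str) -> VoiMask:
    """Rasterize the named ROI of a DICOM-RT structure set onto ``vol``.

    Each planar contour polygon is rasterized on its slice; a voxel belongs
    to the ROI iff its center lies inside the polygon (even-odd rule).
    Multiple polygons on one slice are unioned.

    Raises
    ------
    KeyError
        If ``roi_name`` is absent; the message lists the available names.
    """
    ds = pydicom.dcmread(str(rtstruct))
    names = {}
    for item in getattr(ds, "StructureSetROISequence", []):
        names[int(item.ROINumber)] = str(item.ROIName)
    wanted = [num for num, name in names.items() if name == roi_name]
    if not wanted:
        raise KeyError(
            f"ROI {roi_name!r} not found; available: {sorted(names.values())}"
        )
    roi_number = wanted[0]

    mask = np.zeros(vol.shape, dtype=bool)
    oz, oy, ox = vol.origin_mm
    dz, dy, dx = vol.spacing_mm
    ny, nx = vol.shape[1], vol.shape[2]
    xs = ox + np.arange(nx) * dx
    ys = oy + np.arange(ny) * dy
    gx, gy = np.meshgrid(xs, ys)  # (ny, nx)

    for roi_contour in getattr(ds, "ROIContourSequence", []):
        if int(roi_contour.ReferencedROINumber) != roi_number:
            continue
        for contour in getattr(roi_contour, "ContourSequence", []):
            data = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            if len(data) < 3:
                continue
            k = int(round((data[0, 2] - oz) / dz))
            if not (0 <= k < vol.shape[0]):
                continue
            inside = points_in_polygon(gx, gy, data[:, :2])
            mask[k] |= inside
    return VoiMask(mask)


# ---------------------------------------------------------------------------
# NIfTI volumes (masks, parametric maps)
# ---------------------------------------------------------------------------

def load_nifti_volume(path: os.PathLike | str,
                      intensity_units: str = "raw") -> ImageVolume:
    """Load a NIfTI file as an ImageVolume (data reordered to (z, y, x))."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected a 3D NIfTI volume")
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    voxels = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return ImageVolume(voxels, spacing, (0.0, 0.0, 0.0), intensity_units)


def load_mask_volume(path: os.PathLike | str, vol: ImageVolume | None = None) -> VoiMask:
    """Load a binary mask volume (NIfTI); optionally check alignment."""
    mvol = load_nifti_volume(path)
    mask = VoiMask(mvol.voxels > 0.5)
    if vol is not None:
        mask.check_aligned(vol)
    return mask


def save_nifti_volume(vol: ImageVolume | np.ndarray,
                      path: os.PathLike | str,
                      spacing_mm: Sequence[float] | None = None) -> None:
    """Write a volume to NIfTI (data reordered back to (x, y, z))."""
    import nibabel as nib

    if isinstance(vol, ImageVolume):
        data, spacing = vol.voxels, vol.spacing_mm
    else:
        data = np.asarray(vol, float)
        spacing = tuple(spacing_mm) if spacing_mm is not None else (1.0, 1.0, 1.0)
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_feature_table(rows, out: os.PathLike | str,
                        feature_names: Sequence[str] | None = None) -> None:
    """Write (subject_id, FeatureVector) rows as a CSV spreadsheet.

    All rows must share the same ordered feature-name set. Values round-trip
    at 12 significant digits.
    """
    rows = list(rows)
    if rows:
        keysets = [tuple(fv.keys()) for _, fv in rows]
        if any(ks != keysets[0] for ks in keysets[1:]):
            raise ValueError("heterogeneous feature sets")
        names = list(keysets[0])
    elif feature_names is not None:
        names = list(feature_names)
    else:
        from .features import canonical_feature_names
        names = canonical_feature_names()

    df = pd.DataFrame(
        [[sid] + [float(fv[k]) for k in names] for sid, fv in rows],
        columns=["subject_id"] + names,
    )
    df.to_csv(out, index=False, float_format="%.12g")


def read_feature_table(path: os.PathLike | str) -> pd.DataFrame:
    """Read a feature CSV written by :func:`write_feature_table`."""
    return pd.read_csv(path)
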