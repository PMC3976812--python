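"""Synthetic phantoms and cohorts.

Everything the pipeline consumes can be generated here: SUV-like volumes
with spherical lesions (uniform or fragmented into Voronoi zones), matched
two-group cohorts for discrimination studies, and tiny DICOM series /
RT-STRUCT fixtures for exercising the I/O layer. No external data is
required anywhere in the package.

The default geometry mirrors a clinical whole-body FDG-PET reconstruction:
4.7 mm transverse and 3.3 mm axial voxel spacing, background uptake near
SUV 1 and lesion uptake near SUV 5. Noise is additive Gaussian; an optional
Gaussian point-spread blur emulates finite scanner resolution. These
phantoms reproduce the *spatial* structure the texture indices respond to,
not the physics of PET acquisition (no sinograms or reconstruction), so
conclusions drawn from them concern the computation, not scanner behavior.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from .volume_io import ImageVolume, VoiMask

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "make_phantom",
    "make_cohort",
    "write_fixture_dicom_series",
    "write_fixture_rtstruct",
]

DEFAULT_SPACING = (3.3, 4.7, 4.7)


@dataclasses.dataclass
class LesionSpec:
    """A spherical lesion.

    ``zones = 1`` gives uniform uptake ``value``; ``zones = k > 1``
    partitions the sphere into k Voronoi cells around random interior sites,
    each offset from ``value`` by a uniform draw in +-``level_spread`` and
    re-centered so the lesion's voxel-mean uptake equals ``value`` exactly.
    """

    center: tuple[int, int, int]          # voxel indices (z, y, x)
    radius_mm: float
    value: float
    zones: int = 1
    level_spread: float = 0.0


@dataclasses.dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (26, 24, 24)
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING
    background: float = 1.0
    lesions: Sequence[LesionSpec] = ()
    noise_sd: float = 0.0
    psf_sigma_mm: float = 0.0
    seed: int = 0


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, VoiMask, dict]:
    """Render a phantom volume, the union lesion mask, and ground truth.

    Deterministic given ``spec.seed``. Ground truth holds, per lesion, the
    exact member voxel coordinates and (for fragmented lesions) the Voronoi
    zone assignment and per-zone values.

    Raises
    ------
    ValueError
        If any lesion extends outside the grid.
    """
    if spec.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    sp = np.asarray(spec.spacing_mm, dtype=float)
    vol = np.full(shape, float(spec.background))
    mask = np.zeros(shape, dtype=bool)
    truth: dict = {"lesions": []}

    zz, yy, xx = np.indices(shape)
    for lesion in spec.lesions:
        center = np.asarray(lesion.center, dtype=float)
        r_vox = lesion.radius_mm / sp
        if np.any(center - r_vox < -0.5) or np.any(center + r_vox > np.asarray(shape) - 0.5):
            raise ValueError(f"lesion at {lesion.center} extends outside the grid")
        d2 = (((zz - center[0]) * sp[0]) ** 2 + ((yy - center[1]) * sp[1]) ** 2
              + ((xx - center[2]) * sp[2]) ** 2)
        member = d2 <= lesion.radius_mm ** 2
        coords = np.argwhere(member)
        if len(coords) == 0:
            raise ValueError(f"lesion at {lesion.center} covers no voxel")
        record = {"coords": coords, "value": lesion.value, "zones": lesion.zones}
        if lesion.zones <= 1 or lesion.level_spread == 0.0:
            vol[member] = lesion.value
            record["zone_of_voxel"] = np.zeros(len(coords), dtype=int)
            record["zone_values"] = np.array([lesion.value])
        else:
            k = min(lesion.zones, len(coords))
            sites = coords[rng.choice(len(coords), size=k, replace=False)]
            dist = (((coords[:, None, :] - sites[None, :, :]) * sp) ** 2).sum(axis=2)
            assign = np.argmin(dist, axis=1)
            offsets = rng.uniform(-lesion.level_spread, lesion.level_spread, size=k)
            offsets = offsets - offsets[assign].mean()  # voxel-mean uptake == value
            values = lesion.value + offsets
            vol[coords[:, 0], coords[:, 1], coords[:, 2]] = values[assign]
            record["zone_of_voxel"] = assign
            record["zone_values"] = values
        mask |= member
        truth["lesions"].append(record)

    if spec.psf_sigma_mm > 0:
        from scipy import ndimage
        vol = ndimage.gaussian_filter(vol, sigma=spec.psf_sigma_mm / sp)
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=shape)

    image = ImageVolume(vol, tuple(sp), intensity_units="SUV")
    return image, VoiMask(mask), truth


# ---------------------------------------------------------------------------
# Matched-mean two-group cohort
# ---------------------------------------------------------------------------

def make_cohort(n_per_group: int = 9, effect: float = 1.0, seed: int = 0,
                shape: tuple[int, int, int] = (26, 24, 24),
                radius_mm: float = 18.0, zones: int = 12,
                noise_sd: float = 0.01):
    """Generate a two-group cohort in which mean uptake is uninformative.

    Group 0 subjects carry uniform lesions; group 1 subjects carry
    fragmented lesions whose Voronoi-zone uptake spread scales with
    ``effect`` (zone offsets uniform in +-2*effect SUV, re-centered per
    lesion). The per-subject base uptake values (Normal, mean 5, SD 0.5) are
    drawn once and assigned to *both* groups (a paired design), so the
    SUV_mean distributions are identical across groups by construction and
    mean uptake cannot discriminate, while texture families can. ``effect =
    0`` makes the groups fully exchangeable.

    Returns
    -------
    list of (subject_id, ImageVolume, VoiMask), ndarray of labels
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    base_values = rng.normal(5.0, 0.5, size=n_per_group)
    center = tuple(s // 2 for s in shape)
    subjects = []
    labels = []
    for group in (0, 1):
        for i in range(n_per_group):
            lesion = LesionSpec(
                center=center, radius_mm=radius_mm, value=float(base_values[i]),
                zones=1 if group == 0 else zones,
                level_spread=0.0 if group == 0 else 2.0 * effect)
            spec = PhantomSpec(
                shape=shape, lesions=[lesion], noise_sd=noise_sd,
                seed=int(rng.integers(0, 2 ** 31 - 1)))
            vol, mask, _ = make_phantom(spec)
            subjects.append((f"g{group}_s{i:02d}", vol, mask))
            labels.append(group)
    return subjects, np.asarray(labels, dtype=int)


# ---------------------------------------------------------------------------
# DICOM fixtures (for exercising the I/O layer; written at run time only)
# ---------------------------------------------------------------------------

def write_fixture_dicom_series(directory, volume: np.ndarray | None = None,
                               spacing_mm: tuple[float, float, float] = DEFAULT_SPACING,
                               units: str = "BQML",
                               rescale_slope: float = 1.0,
                               series_uid: str | None = None,
                               file_prefix: str = "slice",
                               origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)):
    """Write a minimal single-frame PT DICOM series (synthetic fixture).

    ``volume`` is (z, y, x); defaults to a 4-slice 8x8 ramp. Pixel data is
    stored as uint16 with the given rescale slope. Returns the list of file
    paths, in slice order.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if volume is None:
        volume = np.tile(np.arange(64, dtype=float).reshape(8, 8), (4, 1, 1))
    volume = np.asarray(volume, dtype=float)
    dz, dy, dx = spacing_mm
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    paths = []
    for k in range(volume.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.UID(
            "1.2.840.10008.5.1.4.1.1.128")  # PET Image Storage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "PT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [origin_mm[2], origin_mm[1],
                                   origin_mm[0] + k * dz]
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = dz
        ds.Units = units
        ds.Rows, ds.Columns = volume.shape[1:]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = rescale_slope
        ds.RescaleIntercept = 0.0
        pixels = np.round(volume[k] / rescale_slope).astype(np.uint16)
        ds.PixelData = pixels.tobytes()
        path = directory / f"{file_prefix}_{k:03d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


def write_fixture_rtstruct(path, rois: dict,
                           frame_uid: str | None = None):
    """Write a minimal DICOM-RT structure set (synthetic fixture).

    ``rois`` maps ROI name -> list of contours, each contour a tuple
    ``(z_mm, [(x_mm, y_mm), ...])``.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.sequence import Sequence as DSequence
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID(
        "1.2.840.10008.5.1.4.1.1.481.3")  # RT Structure Set Storage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "fixture"
    ds.FrameOfReferenceUID = frame_uid or generate_uid()

    ds.StructureSetROISequence = DSequence()
    ds.ROIContourSequence = DSequence()
    for number, (name, contours) in enumerate(rois.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = ds.FrameOfReferenceUID
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = DSequence()
        for z_mm, points in contours:
            contour = Dataset()
            contour.ContourGeometricType = "CLOSED_PLANAR"
            contour.NumberOfContourPoints = len(points)
            data = []
            for x_mm, y_mm in points:
                data.extend([float(x_mm), float(y_mm), float(z_mm)])
            contour.ContourData = data
            rc.ContourSequence.append(contour)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)
    return Path(path)
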