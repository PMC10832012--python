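"""Plan ingest and export.

Two routes into the internal containers:

* a portable JSON bundle (versioned header, base64-packed arrays) that
  round-trips :class:`DoseGrid` + structure sets losslessly — the format
  phantoms and scripted pipelines exchange;
* DICOM RT Dose + RT Structure Set: dose is converted to Gy through the
  dose-grid scaling attribute and contours are rasterised slice-wise onto
  the dose grid with even-odd polygon fill, so every downstream metric
  sees a single shared geometry.

Coordinate convention: physical patient coordinates in cm, voxel indices
0-based, axis order (x, y, z); DICOM millimetres are converted at the
boundary and never leak inward.
"""

from __future__ import annotations

import base64
import datetime
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import DoseGrid, GridGeometry, StructureMask, StructureRole

BUNDLE_FORMAT = "kbpdose-bundle/1"


class BundleFormatError(ValueError):
    """A portable bundle file is unreadable or has the wrong version."""


@dataclass
class PlanBundle:
    """One plan: dose grid, structure set and ingest provenance."""

    plan_id: str
    dose: DoseGrid
    structures: dict[str, StructureMask]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mask in self.structures.values():
            if mask.geometry != self.dose.geometry:
                raise ValueError(
                    f"structure {mask.name!r} is not on the dose grid; "
                    "resample at ingest"
                )


def _encode_array(a: np.ndarray) -> str:
    return base64.b64encode(np.ascontiguousarray(a).tobytes()).decode("ascii")


def write_bundle(bundle: PlanBundle, path) -> None:
    """Serialize a plan bundle to the portable JSON container."""
    geom = bundle.dose.geometry
    payload = {
        "format": BUNDLE_FORMAT,
        "plan_id": bundle.plan_id,
        "prescription_dose": bundle.dose.prescription_dose,
        "geometry": {
            "origin": list(geom.origin),
            "spacing": list(geom.spacing),
            "shape": list(geom.shape),
        },
        "dose_b64_f64le": _encode_array(bundle.dose.dose.astype("<f8")),
        "structures": [
            {
                "name": m.name,
                "role": m.role.value,
                "packed_b64": _encode_array(np.packbits(m.occupancy.ravel())),
            }
            for m in bundle.structures.values()
        ],
        "provenance": bundle.provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def read_bundle(path) -> PlanBundle:
    """Read a portable bundle; wrong or truncated files raise
    :class:`BundleFormatError`."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise BundleFormatError(f"cannot parse bundle file {path}: {exc}") from exc
    if payload.get("format") != BUNDLE_FORMAT:
        raise BundleFormatError(
            f"unsupported bundle format {payload.get('format')!r}; "
            f"expected {BUNDLE_FORMAT!r}"
        )
    g = payload["geometry"]
    geom = GridGeometry(tuple(g["origin"]), tuple(g["spacing"]), tuple(g["shape"]))
    n_vox = int(np.prod(geom.shape))
    dose_arr = np.frombuffer(
        base64.b64decode(payload["dose_b64_f64le"]), dtype="<f8"
    ).reshape(geom.shape)
    dose = DoseGrid(geom, dose_arr.copy(), payload["prescription_dose"])
    structures = {}
    for s in payload["structures"]:
        bits = np.unpackbits(
            np.frombuffer(base64.b64decode(s["packed_b64"]), dtype=np.uint8),
            count=n_vox,
        )
        structures[s["name"]] = StructureMask(
            name=s["name"],
            role=StructureRole(s["role"]),
            occupancy=bits.astype(bool).reshape(geom.shape),
            geometry=geom,
        )
    return PlanBundle(
        plan_id=payload["plan_id"],
        dose=dose,
        structures=structures,
        provenance=payload.get("provenance", {}),
    )


def resample_dose(dose: DoseGrid, geometry: GridGeometry) -> DoseGrid:
    """Trilinear resampling of a dose grid onto a new geometry.

    Used before summing plan series computed on different grids; values
    outside the source extent are taken as zero.
    """
    import itertools

    coords = np.meshgrid(
        *[geometry.axis_coordinates(i) for i in range(3)], indexing="ij"
    )
    idx = [
        (coords[i] - dose.geometry.origin[i]) / dose.geometry.spacing[i]
        for i in range(3)
    ]
    out = ndimage.map_coordinates(dose.dose, idx, order=1, mode="constant", cval=0.0)
    return DoseGrid(geometry, out, dose.prescription_dose)


# ---------------------------------------------------------------------------
# DICOM RT
# ---------------------------------------------------------------------------

_RTDOSE_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
_RTSTRUCT_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"


def _dose_geometry(ds) -> GridGeometry:
    ipp = [float(v) for v in ds.ImagePositionPatient]  # mm
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)  # mm: (y, x)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz, dz[0]):
        raise ValueError("non-uniform GridFrameOffsetVector is not supported")
    z_spacing = float(dz[0]) if offsets.size > 1 else 1.0
    origin = (ipp[0] / 10.0, ipp[1] / 10.0, (ipp[2] + offsets[0]) / 10.0)
    spacing = (col_spacing / 10.0, row_spacing / 10.0, abs(z_spacing) / 10.0)
    shape = (int(ds.Columns), int(ds.Rows), int(ds.NumberOfFrames))
    return GridGeometry(origin, spacing, shape)


def _frame_of_reference(ds) -> str | None:
    if "FrameOfReferenceUID" in ds:
        return str(ds.FrameOfReferenceUID)
    seq = getattr(ds, "ReferencedFrameOfReferenceSequence", None)
    if seq:
        return str(seq[0].FrameOfReferenceUID)
    return None


def _rasterize_contours(contours_mm: list[np.ndarray], geom: GridGeometry) -> np.ndarray:
    """Even-odd rasterisation of closed planar contours onto the grid.

    Each contour is an (N, 3) array of mm coordinates on one axial plane;
    contours on the same slice toggle (XOR), so holes and islands follow
    the even-odd rule.
    """
    from skimage.draw import polygon2mask

    occ = np.zeros(geom.shape, dtype=bool)
    for pts in contours_mm:
        cm = np.asarray(pts, dtype=float) / 10.0
        k = int(round((cm[:, 2].mean() - geom.origin[2]) / geom.spacing[2]))
        if not 0 <= k < geom.shape[2]:
            continue
        poly = np.column_stack(
            [
                (cm[:, 0] - geom.origin[0]) / geom.spacing[0],
                (cm[:, 1] - geom.origin[1]) / geom.spacing[1],
            ]
        )
        plane = polygon2mask((geom.shape[0], geom.shape[1]), poly)
        occ[:, :, k] ^= plane
    return occ


def _infer_role(name: str) -> StructureRole:
    return StructureRole.TARGET if name.upper().startswith(("PTV", "CTV", "GTV")) else StructureRole.OAR


def read_dicom_rt(dose_path, struct_path, prescription_dose: float = 76.0) -> PlanBundle:
    """Ingest a DICOM RT Dose + RT Structure Set pair into one bundle.

    The two files must reference the same frame of reference; dose must be
    stored in GY (converted through ``DoseGridScaling``).  Structures with
    no contours are excluded with a warning.
    """
    import pydicom

    dose_ds = pydicom.dcmread(dose_path)
    struct_ds = pydicom.dcmread(struct_path)

    for_dose = _frame_of_reference(dose_ds)
    for_struct = _frame_of_reference(struct_ds)
    if for_dose and for_struct and for_dose != for_struct:
        raise ValueError(
            "RT Dose and RT Structure Set reference different frames of "
            f"reference ({for_dose} vs {for_struct})"
        )
    units = str(getattr(dose_ds, "DoseUnits", "")).upper()
    if units != "GY":
        raise ValueError(f"unsupported DoseUnits {units!r}; only GY is handled")

    geom = _dose_geometry(dose_ds)
    scaling = float(dose_ds.DoseGridScaling)
    # stored as (frame=z, row=y, col=x) -> internal (x, y, z)
    dose_arr = dose_ds.pixel_array.astype(np.float64).transpose(2, 1, 0) * scaling
    dose = DoseGrid(geom, dose_arr, prescription_dose=prescription_dose)

    roi_names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in struct_ds.StructureSetROISequence
    }
    structures: dict[str, StructureMask] = {}
    for roi_contour in getattr(struct_ds, "ROIContourSequence", []):
        name = roi_names.get(int(roi_contour.ReferencedROINumber), "unknown")
        contour_seq = getattr(roi_contour, "ContourSequence", None)
        if not contour_seq:
            warnings.warn(f"structure {name!r} has no contours; excluded", stacklevel=2)
            continue
        contours = [
            np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            for c in contour_seq
        ]
        occ = _rasterize_contours(contours, geom)
        if not occ.any():
            warnings.warn(
                f"structure {name!r} rasterises to an empty mask; excluded",
                stacklevel=2,
            )
            continue
        structures[name] = StructureMask(
            name=name, role=_infer_role(name), occupancy=occ, geometry=geom
        )

    return PlanBundle(
        plan_id=str(getattr(dose_ds, "SOPInstanceUID", "dicom-plan")),
        dose=dose,
        structures=structures,
        provenance={
            "source": "dicom-rt",
            "dose_file": str(dose_path),
            "struct_file": str(struct_path),
            "dose_grid_scaling": scaling,
            "resampling": "contours rasterised onto the dose grid (even-odd fill)",
        },
    )


def _base_dataset(sop_class: str, frame_of_reference: str):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientName = "phantom"
    ds.PatientID = "phantom"
    ds.Modality = "RTDOSE" if sop_class == _RTDOSE_CLASS else "RTSTRUCT"
    ds.FrameOfReferenceUID = frame_of_reference
    now = datetime.datetime(2000, 1, 1)
    ds.ContentDate = now.strftime("%Y%m%d")
    ds.ContentTime = now.strftime("%H%M%S")
    return ds


def write_dicom_rt(bundle: PlanBundle, dose_path, struct_path) -> None:
    """Export a bundle as a DICOM RT Dose + RT Structure Set pair.

    Dose is quantised to 32-bit integers through ``DoseGridScaling``;
    masks are written as closed planar contours traced at the 0.5 iso-level
    of each axial slice, so a re-ingest reproduces each mask up to one
    voxel layer at the boundary.
    """
    import pydicom
    from pydicom.sequence import Sequence
    from pydicom.uid import generate_uid
    from skimage import measure

    geom = bundle.dose.geometry
    frame = generate_uid()

    dose_ds = _base_dataset(_RTDOSE_CLASS, frame)
    dose_ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    dose_ds.ImagePositionPatient = [
        geom.origin[0] * 10.0,
        geom.origin[1] * 10.0,
        geom.origin[2] * 10.0,
    ]
    dose_ds.PixelSpacing = [geom.spacing[1] * 10.0, geom.spacing[0] * 10.0]  # (row=y, col=x)
    dose_ds.GridFrameOffsetVector = [geom.spacing[2] * 10.0 * k for k in range(geom.shape[2])]
    dose_ds.Columns = geom.shape[0]
    dose_ds.Rows = geom.shape[1]
    dose_ds.NumberOfFrames = geom.shape[2]
    dose_ds.DoseUnits = "GY"
    dose_ds.DoseType = "PHYSICAL"
    dose_ds.DoseSummationType = "PLAN"
    dmax = float(bundle.dose.dose.max())
    scaling = dmax / (2**32 - 2) if dmax > 0 else 1.0
    stored = np.round(bundle.dose.dose / scaling).astype("<u4")
    dose_ds.DoseGridScaling = scaling
    dose_ds.BitsAllocated = 32
    dose_ds.BitsStored = 32
    dose_ds.HighBit = 31
    dose_ds.PixelRepresentation = 0
    dose_ds.SamplesPerPixel = 1
    dose_ds.PhotometricInterpretation = "MONOCHROME2"
    dose_ds.PixelData = stored.transpose(2, 1, 0).tobytes()  # (z, y, x) storage
    dose_ds.save_as(dose_path, enforce_file_format=True)

    struct_ds = _base_dataset(_RTSTRUCT_CLASS, frame)
    struct_ds.StructureSetLabel = bundle.plan_id[:16]
    ref_frame = pydicom.dataset.Dataset()
    ref_frame.FrameOfReferenceUID = frame
    struct_ds.ReferencedFrameOfReferenceSequence = Sequence([ref_frame])
    roi_seq, contour_seq = Sequence(), Sequence()
    for number, mask in enumerate(bundle.structures.values(), start=1):
        roi = pydicom.dataset.Dataset()
        roi.ROINumber = number
        roi.ROIName = mask.name
        roi.ReferencedFrameOfReferenceUID = frame
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)

        rc = pydicom.dataset.Dataset()
        rc.ReferencedROINumber = number
        contours = Sequence()
        for k in range(geom.shape[2]):
            plane = mask.occupancy[:, :, k].astype(float)
            if not plane.any():
                continue
            z_mm = (geom.origin[2] + k * geom.spacing[2]) * 10.0
            padded = np.pad(plane, 1)  # close contours that touch the grid edge
            for trace in measure.find_contours(padded, 0.5):
                trace = trace - 1.0  # undo padding offset
                c = pydicom.dataset.Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                pts = np.column_stack(
                    [
                        (geom.origin[0] + trace[:, 0] * geom.spacing[0]) * 10.0,
                        (geom.origin[1] + trace[:, 1] * geom.spacing[1]) * 10.0,
                        np.full(len(trace), z_mm),
                    ]
                )
                c.NumberOfContourPoints = len(pts)
                c.ContourData = [f"{v:.4f}" for v in pts.ravel()]
                contours.append(c)
        rc.ContourSequence = contours
        contour_seq.append(rc)
    struct_ds.StructureSetROISequence = roi_seq
    struct_ds.ROIContourSequence = contour_seq
    struct_ds.save_as(struct_path, enforce_file_format=True)
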