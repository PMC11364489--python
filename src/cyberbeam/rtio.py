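"""DICOM-RT and internal case-bundle I/O.

Owns every file format and coordinate convention in the package:

* CT image series (read/write), RTSTRUCT (read/write), RTDOSE
  (read/write) and RTPLAN (read/write) through pydicom;
* the ``.ckplan`` plain-text sidecar plan format (one beam per line:
  source xyz, aim xyz, cone mm, MU), because CyberKnife RTPLAN private
  tags vary by vendor version;
* the internal on-disk case bundle: one directory per case with
  compressed arrays plus a JSON geometry manifest.

All geometry is DICOM patient LPS in millimetres with the voxel-center
convention; arrays are indexed ``(x, y, z)`` (column, row, slice).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pydicom
from matplotlib.path import Path as MplPath
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage import measure

from .beams import Beam, Plan
from .grid import BACKGROUND_HU, StructureRole, StructureSet, VolumeGrid, resample_to

__all__ = [
    "CaseBundle",
    "read_ct_series",
    "write_ct_series",
    "read_structures",
    "write_structures",
    "read_dose",
    "write_dose",
    "read_plan",
    "write_plan",
    "read_ckplan",
    "write_ckplan",
    "save_case_bundle",
    "load_case_bundle",
    "export_dicom",
    "harmonize_bundle",
    "resample_to",
]

_CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
_RTSTRUCT_STORAGE = "1.2.840.10008.5.1.4.1.1.481.3"
_RTDOSE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.2"
_RTPLAN_STORAGE = "1.2.840.10008.5.1.4.1.1.481.5"
_PRIVATE_CREATOR = "CYBERBEAM"

#: Default name-pattern table assigning clinical roles to ROI names.
DEFAULT_ROLE_PATTERNS: Tuple[Tuple[str, StructureRole], ...] = (
    ("ptv", StructureRole.TARGET_PTV),
    ("gtv", StructureRole.TARGET_GTV),
    ("ring", StructureRole.RING),
    ("body", StructureRole.BODY),
    ("external", StructureRole.BODY),
    ("skin", StructureRole.BODY),
)


@dataclass
class CaseBundle:
    """One co-registered case: CT, structures, plan, optional dose."""

    ct: VolumeGrid
    structures: StructureSet
    plan: Optional[Plan] = None
    dose: Optional[VolumeGrid] = None

    def __post_init__(self) -> None:
        if not self.structures.grid.same_geometry(self.ct):
            raise ValueError("structures are not co-registered with the CT")
        if self.dose is not None:
            if not self.dose.same_geometry(self.ct):
                raise ValueError("dose is not co-registered with the CT")
            if np.any(self.dose.values < 0):
                raise ValueError("dose must be nonnegative")


# ---------------------------------------------------------------------------
# Common DICOM helpers
# ---------------------------------------------------------------------------


def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _base_dataset(sop_class: str, modality: str, uids: Dict[str, str]) -> Dataset:
    ds = Dataset()
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = generate_uid()
    ds.file_meta = _file_meta(sop_class, ds.SOPInstanceUID)
    ds.Modality = modality
    ds.PatientName = "Synthetic^Phantom"
    ds.PatientID = "CYBERBEAM"
    ds.StudyInstanceUID = uids["study"]
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = uids["frame"]
    return ds


def _grid_orientation(grid: VolumeGrid) -> List[float]:
    return [float(x) for x in np.concatenate([grid.axes[:, 0], grid.axes[:, 1]])]


# ---------------------------------------------------------------------------
# CT series
# ---------------------------------------------------------------------------


def write_ct_series(grid: VolumeGrid, directory, uids: Optional[Dict[str, str]] = None) -> Dict[str, str]:
    """Write an HU volume as an axial CT series (one file per slice)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    uids = uids or {"study": generate_uid(), "frame": generate_uid()}
    series_uid = generate_uid()
    nx, ny, nz = grid.shape
    for k in range(nz):
        ds = _base_dataset(_CT_STORAGE, "CT", uids)
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [
            float(v) for v in grid.indices_to_world(np.array([0.0, 0.0, float(k)]))
        ]
        ds.ImageOrientationPatient = _grid_orientation(grid)
        ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]
        ds.SliceThickness = float(grid.spacing[2])
        ds.Rows, ds.Columns = ny, nx
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed: HU stored directly
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = (
            np.round(grid.values[:, :, k]).astype(np.int16).T.tobytes()
        )
        ds.save_as(directory / f"ct_{k:04d}.dcm", enforce_file_format=True)
    uids["ct_series"] = series_uid
    return uids


def read_ct_series(directory) -> VolumeGrid:
    """Read one coherent axial CT series from a directory of DICOM files.

    Slices are sorted by the projection of their position onto the slice
    normal.  Mixed series UIDs, duplicate positions and gaps in the
    slice spacing are hard errors naming the offending instance.
    """
    directory = Path(directory)
    slices = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except Exception:
            continue
        if getattr(ds, "SOPClassUID", "") == _CT_STORAGE:
            slices.append((path, ds))
    if not slices:
        raise FileNotFoundError(f"no CT slices found in {directory}")
    series = {ds.SeriesInstanceUID for _, ds in slices}
    if len(series) > 1:
        raise ValueError(f"mixed CT series UIDs in {directory}: {sorted(series)}")

    ds0 = slices[0][1]
    iop = np.array(ds0.ImageOrientationPatient, dtype=float)
    x_dir, y_dir = iop[:3], iop[3:]
    normal = np.cross(x_dir, y_dir)
    keyed = sorted(
        ((float(np.dot(np.array(ds.ImagePositionPatient, dtype=float), normal)), path, ds)
         for path, ds in slices),
        key=lambda t: t[0],
    )
    positions = np.array([t[0] for t in keyed])
    diffs = np.diff(positions)
    if len(diffs):
        if np.any(diffs < 1e-6):
            bad = keyed[int(np.argmin(diffs)) + 1][1]
            raise ValueError(f"duplicate slice position in {bad}")
        dz = float(np.median(diffs))
        gaps = np.nonzero(np.abs(diffs - dz) > 1e-3 * max(dz, 1.0))[0]
        if gaps.size:
            g = int(gaps[0])
            raise ValueError(
                f"non-uniform slice spacing between {keyed[g][1].name} and "
                f"{keyed[g + 1][1].name} (positions {positions[g]:.3f} / "
                f"{positions[g + 1]:.3f} mm, expected step {dz:.3f} mm)"
            )
    else:
        dz = float(getattr(ds0, "SliceThickness", 1.0))

    rows, cols = int(ds0.Rows), int(ds0.Columns)
    nz = len(keyed)
    values = np.empty((cols, rows, nz), dtype=np.float32)
    for k, (_, _, ds) in enumerate(keyed):
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        values[:, :, k] = (arr * slope + inter).T
    spacing = np.array(
        [float(ds0.PixelSpacing[1]), float(ds0.PixelSpacing[0]), dz]
    )
    origin = np.array(keyed[0][2].ImagePositionPatient, dtype=float)
    axes = np.stack([x_dir, y_dir, normal], axis=1)
    grid = VolumeGrid(values, origin, spacing, axes)
    grid.frame_of_reference = getattr(ds0, "FrameOfReferenceUID", None)  # type: ignore[attr-defined]
    return grid


# ---------------------------------------------------------------------------
# RTSTRUCT
# ---------------------------------------------------------------------------

_ROLE_TO_DICOM = {
    StructureRole.TARGET_PTV: "PTV",
    StructureRole.TARGET_GTV: "GTV",
    StructureRole.OAR: "ORGAN",
    StructureRole.RING: "AVOIDANCE",
    StructureRole.BODY: "EXTERNAL",
}
_DICOM_TO_ROLE = {v: k for k, v in _ROLE_TO_DICOM.items()}


def role_from_name(name: str, patterns=DEFAULT_ROLE_PATTERNS) -> StructureRole:
    low = name.lower()
    for pat, role in patterns:
        if pat in low:
            return role
    return StructureRole.OAR


def _mask_to_contours(mask: np.ndarray, grid: VolumeGrid) -> List[np.ndarray]:
    """Closed planar contours (world mm) from an axial mask, per slice."""
    contours = []
    for k in range(mask.shape[2]):
        sl = mask[:, :, k]
        if not sl.any():
            continue
        for poly in measure.find_contours(sl.astype(float), 0.5):
            ijk = np.column_stack([poly, np.full(len(poly), float(k))])
            contours.append(grid.indices_to_world(ijk))
    return contours


def write_structures(structures: StructureSet, path, uids: Optional[Dict[str, str]] = None) -> None:
    """Write a StructureSet as a DICOM RTSTRUCT (contours from masks)."""
    uids = uids or {"study": generate_uid(), "frame": generate_uid()}
    ds = _base_dataset(_RTSTRUCT_STORAGE, "RTSTRUCT", uids)
    ds.StructureSetLabel = "cyberbeam"
    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = uids["frame"]
    ds.ReferencedFrameOfReferenceSequence = [ref_frame]

    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    ds.RTROIObservationsSequence = []
    for num, (name, mask) in enumerate(structures.masks.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = uids["frame"]
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for poly in _mask_to_contours(mask, structures.grid):
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(poly)
            c.ContourData = [float(v) for v in poly.ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)

        obs = Dataset()
        obs.ObservationNumber = num
        obs.ReferencedROINumber = num
        obs.ROIObservationLabel = name
        obs.RTROIInterpretedType = _ROLE_TO_DICOM[structures.roles[name]]
        ds.RTROIObservationsSequence.append(obs)
    ds.save_as(path, enforce_file_format=True)


def rasterize_polygon(poly_xy: np.ndarray, shape_xy: Tuple[int, int]) -> np.ndarray:
    """Center-in-polygon rasterization of one in-plane contour.

    A voxel belongs to the structure iff its center lies inside the
    contour polygon (vertices in continuous index coordinates).
    """
    path = MplPath(poly_xy)
    ii, jj = np.meshgrid(np.arange(shape_xy[0]), np.arange(shape_xy[1]), indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel()])
    return path.contains_points(pts, radius=1e-9).reshape(shape_xy)


def read_structures(path, grid: VolumeGrid, patterns=DEFAULT_ROLE_PATTERNS) -> StructureSet:
    """Rasterize an RTSTRUCT onto ``grid``.

    ROI names are preserved verbatim; roles come from the RTSTRUCT
    interpreted type when present, else from the name-pattern table.
    Each planar contour is assigned to the nearest slice within half the
    slice spacing and rasterized with the center-in-polygon rule.
    """
    ds = pydicom.dcmread(path)
    grid_for = getattr(grid, "frame_of_reference", None)
    if grid_for is not None:
        for ref in getattr(ds, "ReferencedFrameOfReferenceSequence", []):
            if ref.FrameOfReferenceUID != grid_for:
                raise ValueError(
                    "RTSTRUCT frame of reference does not match the CT frame"
                )
    names = {int(r.ROINumber): str(r.ROIName) for r in getattr(ds, "StructureSetROISequence", [])}
    interp: Dict[int, str] = {}
    for obs in getattr(ds, "RTROIObservationsSequence", []):
        interp[int(obs.ReferencedROINumber)] = str(getattr(obs, "RTROIInterpretedType", ""))

    out = StructureSet(grid=grid)
    for rc in getattr(ds, "ROIContourSequence", []):
        num = int(rc.ReferencedROINumber)
        name = names.get(num, f"ROI_{num}")
        mask = np.zeros(grid.shape, dtype=bool)
        contour_seq = getattr(rc, "ContourSequence", [])
        if not contour_seq:
            warnings.warn(f"ROI {name!r} has no contours; empty mask", stacklevel=2)
        for c in contour_seq:
            pts = np.array(c.ContourData, dtype=float).reshape(-1, 3)
            ijk = grid.world_to_indices(pts)
            k = float(np.mean(ijk[:, 2]))
            k_near = int(np.round(k))
            if abs(k - k_near) > 0.5 + 1e-6 or not 0 <= k_near < grid.shape[2]:
                continue
            mask[:, :, k_near] |= rasterize_polygon(ijk[:, :2], grid.shape[:2])
        role = _DICOM_TO_ROLE.get(interp.get(num, ""), None) or role_from_name(name, patterns)
        out.add(name, mask, role)
    return out


# ---------------------------------------------------------------------------
# RTDOSE
# ---------------------------------------------------------------------------


def write_dose(dose: VolumeGrid, path, uids: Optional[Dict[str, str]] = None) -> None:
    """Write a Gy volume as a multi-frame RTDOSE.

    Stored as uint32 with ``DoseGridScaling = max / (2^32 - 1)``, so the
    quantization error is far below 0.01 % of the maximum dose.
    """
    if np.any(dose.values < 0):
        raise ValueError("cannot write negative dose")
    uids = uids or {"study": generate_uid(), "frame": generate_uid()}
    ds = _base_dataset(_RTDOSE_STORAGE, "RTDOSE", uids)
    nx, ny, nz = dose.shape
    maxdose = float(dose.values.max())
    scaling = maxdose / (2**32 - 1) if maxdose > 0 else 1.0
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.Rows, ds.Columns = ny, nx
    ds.NumberOfFrames = nz
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.GridFrameOffsetVector = [float(k * dose.spacing[2]) for k in range(nz)]
    ds.ImagePositionPatient = [float(v) for v in dose.origin]
    ds.ImageOrientationPatient = _grid_orientation(dose)
    ds.PixelSpacing = [float(dose.spacing[1]), float(dose.spacing[0])]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    quant = np.round(dose.values.astype(np.float64) / scaling).astype(np.uint32)
    ds.PixelData = np.transpose(quant, (2, 1, 0)).tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_dose(path) -> VolumeGrid:
    """Read a multi-frame RTDOSE into a Gy volume."""
    ds = pydicom.dcmread(path)
    frames = ds.pixel_array.astype(np.float64)  # (nz, ny, nx)
    if frames.ndim == 2:
        frames = frames[None]
    values = np.transpose(frames, (2, 1, 0)) * float(ds.DoseGridScaling)
    offsets = np.array(ds.GridFrameOffsetVector, dtype=float)
    dz = float(np.median(np.diff(offsets))) if len(offsets) > 1 else 1.0
    iop = np.array(ds.ImageOrientationPatient, dtype=float)
    axes = np.stack([iop[:3], iop[3:], np.cross(iop[:3], iop[3:])], axis=1)
    spacing = np.array([float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), dz])
    origin = np.array(ds.ImagePositionPatient, dtype=float)
    return VolumeGrid(values, origin, spacing, axes)


# ---------------------------------------------------------------------------
# Plans: .ckplan sidecar and RTPLAN
# ---------------------------------------------------------------------------

_CKPLAN_HEADER = "source_x\tsource_y\tsource_z\taim_x\taim_y\taim_z\tcone_mm\tmu"


def write_ckplan(plan: Plan, path) -> None:
    """Write the plain-text sidecar plan: one beam per line, TSV, mm/MU."""
    lines = [
        "# cyberbeam plan sidecar v1 (units: mm, MU)",
        f"# prescription_gy={plan.prescription_dose}",
        f"# fractions={plan.fractions}",
        f"# l_source_mm={plan.beams[0].l_source}",
        _CKPLAN_HEADER,
    ]
    for b in plan.beams:
        vals = [*b.source, *b.aim, b.cone, b.mu]
        lines.append("\t".join(f"{v:.6g}" for v in vals))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ckplan(path) -> Plan:
    """Read the ``.ckplan`` sidecar format."""
    meta = {"prescription_gy": 1.0, "fractions": 1, "l_source_mm": 400.0}
    beams: List[Beam] = []
    rows = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    for ln in rows:
        if ln.startswith("#"):
            for key in meta:
                if f"{key}=" in ln:
                    meta[key] = float(ln.split(f"{key}=")[1].split()[0])
            continue
        if ln.startswith("source_x"):
            continue
        parts = ln.split("\t")
        if len(parts) != 8:
            raise ValueError(
                f"beam {len(beams)}: expected 8 fields (source xyz, aim xyz, cone, MU), got {len(parts)}"
            )
        v = [float(p) for p in parts]
        beams.append(Beam(source=v[0:3], aim=v[3:6], cone=v[6], mu=v[7], l_source=meta["l_source_mm"]))
    if not beams:
        raise ValueError(f"no beams found in {path}")
    return Plan(beams=beams, prescription_dose=meta["prescription_gy"], fractions=int(meta["fractions"]))


def write_plan(plan: Plan, path, uids: Optional[Dict[str, str]] = None) -> None:
    """Write a DICOM RTPLAN (this package's documented profile).

    Standard tags carry aim point (IsocenterPosition), cone diameter
    (ApplicatorSequence) and MU (BeamMeterset); the robot source position
    has no standard tag and is stored in the ``CYBERBEAM`` private block.
    """
    uids = uids or {"study": generate_uid(), "frame": generate_uid()}
    ds = _base_dataset(_RTPLAN_STORAGE, "RTPLAN", uids)
    ds.RTPlanLabel = "cyberbeam"
    ds.RTPlanGeometry = "PATIENT"
    dr = Dataset()
    dr.DoseReferenceNumber = 1
    dr.DoseReferenceStructureType = "SITE"
    dr.DoseReferenceType = "TARGET"
    dr.TargetPrescriptionDose = float(plan.prescription_dose)
    ds.DoseReferenceSequence = [dr]

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = int(plan.fractions)
    fg.NumberOfBeams = plan.n_beams
    fg.ReferencedBeamSequence = []
    ds.BeamSequence = []
    for num, b in enumerate(plan.beams, start=1):
        bm = Dataset()
        bm.BeamNumber = num
        bm.BeamName = f"beam_{num:03d}"
        bm.RadiationType = "PHOTON"
        bm.TreatmentDeliveryType = "TREATMENT"
        bm.SourceAxisDistance = float(b.l_source)
        app = Dataset()
        app.ApplicatorID = f"{b.cone:g}"
        app.ApplicatorType = "STEREOTACTIC"
        bm.ApplicatorSequence = [app]
        cp = Dataset()
        cp.ControlPointIndex = 0
        cp.IsocenterPosition = [float(v) for v in b.aim]
        bm.ControlPointSequence = [cp]
        block = bm.private_block(0x3261, _PRIVATE_CREATOR, create=True)
        block.add_new(0x01, "DS", [f"{v:.6f}" for v in b.source])
        ds.BeamSequence.append(bm)

        rb = Dataset()
        rb.ReferencedBeamNumber = num
        rb.BeamMeterset = float(b.mu)
        fg.ReferencedBeamSequence.append(rb)
    ds.FractionGroupSequence = [fg]
    ds.save_as(path, enforce_file_format=True)


def read_plan(path) -> Plan:
    """Read a plan: ``.ckplan`` sidecar or this package's RTPLAN profile.

    Beams with MU = 0 are retained (they carry no encoding weight).
    Missing cone size or MU is a hard error naming the beam index.
    """
    path = Path(path)
    if path.suffix.lower() in (".ckplan", ".tsv", ".txt"):
        return read_ckplan(path)
    ds = pydicom.dcmread(path)
    mus: Dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            mus[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)
    fractions = 1
    if getattr(ds, "FractionGroupSequence", None):
        fractions = int(ds.FractionGroupSequence[0].NumberOfFractionsPlanned)
    rx = 1.0
    if getattr(ds, "DoseReferenceSequence", None):
        rx = float(ds.DoseReferenceSequence[0].TargetPrescriptionDose)

    beams: List[Beam] = []
    for i, bm in enumerate(getattr(ds, "BeamSequence", [])):
        num = int(bm.BeamNumber)
        if num not in mus:
            raise ValueError(f"beam index {i}: missing MU (BeamMeterset)")
        apps = getattr(bm, "ApplicatorSequence", [])
        if not apps:
            raise ValueError(f"beam index {i}: missing cone size (ApplicatorSequence)")
        cone = float(apps[0].ApplicatorID)
        aim = np.array(bm.ControlPointSequence[0].IsocenterPosition, dtype=float)
        block = bm.private_block(0x3261, _PRIVATE_CREATOR)
        source = np.array([float(v) for v in block[0x01].value], dtype=float)
        beams.append(
            Beam(source=source, aim=aim, cone=cone, mu=mus[num],
                 l_source=float(getattr(bm, "SourceAxisDistance", 400.0)))
        )
    if not beams:
        raise ValueError(f"no beams found in {path}")
    return Plan(beams=beams, prescription_dose=rx, fractions=fractions)


# ---------------------------------------------------------------------------
# Internal case bundle
# ---------------------------------------------------------------------------


def save_case_bundle(bundle: CaseBundle, directory, beam_matrix=None) -> None:
    """Write a case as compressed arrays + JSON geometry manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    g = bundle.ct
    geometry = {
        "origin": g.origin.tolist(),
        "spacing": g.spacing.tolist(),
        "axes": g.axes.tolist(),
        "shape": list(g.shape),
    }
    (directory / "geometry.json").write_text(json.dumps(geometry, indent=2))
    volumes = {"ct": g.values.astype(np.float32)}
    if bundle.dose is not None:
        volumes["dose"] = bundle.dose.values.astype(np.float32)
    if beam_matrix is not None:
        volumes["beam"] = beam_matrix.values.astype(np.float32)
    np.savez_compressed(directory / "volumes.npz", **volumes)
    np.savez_compressed(directory / "masks.npz", **bundle.structures.masks)
    roles = {n: r.value for n, r in bundle.structures.roles.items()}
    (directory / "roles.json").write_text(json.dumps(roles, indent=2))
    if bundle.plan is not None:
        write_ckplan(bundle.plan, directory / "plan.ckplan")


def load_case_bundle(directory) -> Tuple[CaseBundle, Optional[VolumeGrid]]:
    """Read a case bundle; returns ``(bundle, beam_matrix_or_None)``."""
    directory = Path(directory)
    geometry = json.loads((directory / "geometry.json").read_text())
    volumes = np.load(directory / "volumes.npz")
    ct = VolumeGrid(
        volumes["ct"],
        np.array(geometry["origin"]),
        np.array(geometry["spacing"]),
        np.array(geometry["axes"]),
    )
    masks = np.load(directory / "masks.npz")
    roles = json.loads((directory / "roles.json").read_text())
    structures = StructureSet(grid=ct)
    for name in masks.files:
        structures.add(name, masks[name].astype(bool), StructureRole(roles[name]))
    plan = None
    if (directory / "plan.ckplan").exists():
        plan = read_ckplan(directory / "plan.ckplan")
    dose = ct.with_values(volumes["dose"]) if "dose" in volumes else None
    beam = ct.with_values(volumes["beam"]) if "beam" in volumes else None
    bundle = CaseBundle(ct=ct, structures=structures, plan=plan, dose=dose)
    return bundle, beam


def export_dicom(bundle: CaseBundle, directory) -> None:
    """Emit the full DICOM view of a case: CT series, RTSTRUCT, RTDOSE, RTPLAN."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    uids = {"study": generate_uid(), "frame": generate_uid()}
    write_ct_series(bundle.ct, directory / "ct", uids)
    write_structures(bundle.structures, directory / "rtstruct.dcm", uids)
    if bundle.dose is not None:
        write_dose(bundle.dose, directory / "rtdose.dcm", uids)
    if bundle.plan is not None:
        write_plan(bundle.plan, directory / "rtplan.dcm", uids)
        write_ckplan(bundle.plan, directory / "plan.ckplan")


def harmonize_bundle(
    ct: VolumeGrid,
    structures: StructureSet,
    dose: Optional[VolumeGrid] = None,
    plan: Optional[Plan] = None,
    inplane: Optional[int] = None,
) -> CaseBundle:
    """Co-register everything onto the CT grid (the training grid).

    Structures are resampled nearest-neighbour and dose trilinearly onto
    the CT geometry; optionally the axial in-plane size is padded/cropped
    symmetrically to ``inplane`` x ``inplane`` voxels (clinical pipelines
    use 512).  Background fills: -1000 HU, 0 Gy, 0 mask.
    """
    ref = ct
    if inplane is not None:
        nx, ny, nz = ct.shape
        new_shape = (inplane, inplane, nz)
        offset = np.array([(inplane - nx) // 2, (inplane - ny) // 2, 0])
        new_origin = ct.indices_to_world(-offset.astype(float))
        ref = VolumeGrid(
            np.zeros(new_shape, dtype=np.float32), new_origin, ct.spacing, ct.axes
        )
        ct = resample_to(ct, ref, mode="linear", background=BACKGROUND_HU)
    new_structures = StructureSet(grid=ct)
    for name, mask in structures.masks.items():
        res = resample_to(structures.grid.with_values(mask), ct, mode="nearest", background=0.0)
        new_structures.add(name, res.values.astype(bool), structures.roles[name])
    new_dose = None
    if dose is not None:
        new_dose = resample_to(dose, ct, mode="linear", background=0.0)
        new_dose.values[new_dose.values < 0] = 0.0
    return CaseBundle(ct=ct, structures=new_structures, plan=plan, dose=new_dose)
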