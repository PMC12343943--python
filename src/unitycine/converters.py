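"""Serialization of geo-referenced cine frames to MHA and DICOM.

MHA files are written as NDims=3 single-slice MetaImages (a 2D MetaImage
cannot express an off-axis 3D origin/orientation fully); DICOM files are
written as derived MR Image Storage objects, the SOP class with the widest
viewer compatibility, carrying geometry in ImagePositionPatient /
ImageOrientationPatient / PixelSpacing and millisecond acquisition times in
AcquisitionTime.  ``convert_session`` runs the whole pipeline:
decode -> classify -> centering shift -> geometry assignment -> write.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from . import image_model, unity_format
from .image_model import (
    CENTERING_SHIFT_PX,
    GeoFrame,
    PlaneLabel,
    TemplateStore,
    apply_centering_shift,
    assign_geometry,
    classify_plane,
    plane_from_cosines,
)
from .unity_format import SessionLayout, parse_examcard, parse_target_centroid

logger = logging.getLogger(__name__)

MR_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.4"
FRAMES_INDEX_FILENAME = "frames_index.json"
REPORT_FILENAME = "report.json"
QUARANTINE_FILENAME = "quarantine.json"


class ConversionError(Exception):
    """The session layout is invalid or a frame cannot be written."""


def deterministic_uid(*parts, root: str = "2.25") -> str:
    """A DICOM UID derived deterministically from its parts (seedable)."""
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return f"{root}.{int.from_bytes(digest[:12], 'big')}"


@dataclass(frozen=True)
class SeriesContext:
    """Identifier bundle for one converted session: one frame of reference
    per session, one series per plane.  Demographics are synthetic
    placeholders by default (real demographics are out of scope)."""

    session_uid: str
    study_uid: str
    frame_of_reference_uid: str
    series_uids: dict[PlaneLabel, str]
    patient_id: str = "PHANTOM-000"
    patient_name: str = "QA^Phantom"

    @classmethod
    def create(cls, session_uid: str, salt: int = 0) -> "SeriesContext":
        return cls(
            session_uid=session_uid,
            study_uid=deterministic_uid(session_uid, "study", salt),
            frame_of_reference_uid=deterministic_uid(session_uid, "for", salt),
            series_uids={
                plane: deterministic_uid(session_uid, "series", plane.value, salt)
                for plane in image_model.CARDINAL_PLANES
            },
        )


@dataclass
class ConversionReport:
    """Outcome of one session conversion; converted + quarantined = input."""

    fraction_id: str
    session_uid: str
    n_input: int
    counts: dict[str, int]
    quarantined: int
    outputs: dict[str, list[str]] = field(default_factory=dict)
    out_dir: str = ""

    @property
    def converted(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {
            "fraction_id": self.fraction_id,
            "session_uid": self.session_uid,
            "n_input": self.n_input,
            "counts": self.counts,
            "converted": self.converted,
            "quarantined": self.quarantined,
            "outputs": self.outputs,
            "out_dir": self.out_dir,
        }


def _direction_matrix(frame: GeoFrame) -> tuple[float, ...]:
    # ITK direction: column j is the physical direction of image axis j
    # (axis 0 = columns, 1 = rows, 2 = slice normal).
    m = np.column_stack([frame.row_cosines, frame.col_cosines, frame.normal])
    return tuple(m.ravel())


def write_mha(frame: GeoFrame, path) -> Path:
    """Write a GeoFrame as a single-slice NDims=3 MetaImage (uncompressed)."""
    path = Path(path)
    img = sitk.GetImageFromArray(frame.pixels.astype(np.uint16)[np.newaxis, :, :])
    dr, dc = frame.spacing_mm
    img.SetSpacing((dc, dr, 1.0))
    img.SetOrigin(tuple(frame.origin_mm))
    img.SetDirection(_direction_matrix(frame))
    sitk.WriteImage(img, str(path), useCompression=False)
    return path


def read_geoframe(path, timestamp_ms: int | None = None) -> GeoFrame:
    """Load a converted frame (MHA or DICOM) back into a GeoFrame.

    For DICOM input the acquisition time (ms within the day) is recovered
    from the dataset; for MHA — which carries no timing — the caller supplies
    the timestamp (e.g. from the conversion frame index).
    """
    path = Path(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim == 3:
        arr = arr[0]
    direction = np.array(img.GetDirection()).reshape(3, 3)
    row_cos, col_cos = direction[:, 0], direction[:, 1]
    spacing = img.GetSpacing()
    ts = timestamp_ms
    if ts is None and path.suffix.lower() == ".dcm":
        ds = pydicom.dcmread(str(path), stop_before_pixels=True)
        ts = _acquisition_time_to_ms(str(ds.AcquisitionTime))
    return GeoFrame(
        pixels=np.ascontiguousarray(arr, dtype=np.uint16),
        plane=plane_from_cosines(row_cos, col_cos),
        spacing_mm=(float(spacing[1]), float(spacing[0])),
        origin_mm=np.array(img.GetOrigin()),
        row_cosines=row_cos,
        col_cosines=col_cos,
        timestamp_ms=int(ts) if ts is not None else 0,
    )


def _ms_to_da_tm(timestamp_ms: int) -> tuple[str, str]:
    t = _dt.datetime.fromtimestamp(timestamp_ms / 1000.0, tz=_dt.timezone.utc)
    return t.strftime("%Y%m%d"), t.strftime("%H%M%S") + f".{timestamp_ms % 1000:03d}000"


def _acquisition_time_to_ms(tm: str) -> int:
    hh, mm, ss = int(tm[0:2]), int(tm[2:4]), int(tm[4:6])
    frac = float("0" + tm[6:]) if len(tm) > 6 else 0.0
    return round(((hh * 60 + mm) * 60 + ss) * 1000 + frac * 1000)


def _ds_str(value: float) -> str:
    # DS values are limited to 16 bytes; 10 significant digits keep
    # round-trips well inside 1e-6 mm for any plausible coordinate.
    return f"{value:.10g}"


def write_dicom(frame: GeoFrame, ctx: SeriesContext, path, instance_number: int = 1) -> Path:
    """Write a GeoFrame as a derived MR Image Storage DICOM object."""
    path = Path(path)
    sop_uid = frame.frame_uid or deterministic_uid(ctx.session_uid, "sop", instance_number)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = MR_IMAGE_STORAGE
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = MR_IMAGE_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "MR"
    ds.ImageType = ["DERIVED", "SECONDARY"]
    ds.PatientID = ctx.patient_id
    ds.PatientName = ctx.patient_name
    ds.StudyInstanceUID = ctx.study_uid
    ds.SeriesInstanceUID = ctx.series_uids.get(
        frame.plane, deterministic_uid(ctx.session_uid, "series", frame.plane.value)
    )
    ds.FrameOfReferenceUID = ctx.frame_of_reference_uid
    ds.SeriesNumber = 1 + list(image_model.CARDINAL_PLANES).index(frame.plane)
    ds.InstanceNumber = instance_number
    ds.SeriesDescription = f"cine {frame.plane.value}"

    date, time = _ms_to_da_tm(frame.timestamp_ms)
    ds.AcquisitionDate = date
    ds.AcquisitionTime = time
    ds.ContentDate = date
    ds.ContentTime = time
    ds.StudyDate = date
    ds.StudyTime = time

    rows, cols = frame.pixels.shape
    dr, dc = frame.spacing_mm
    ds.Rows = rows
    ds.Columns = cols
    ds.PixelSpacing = [_ds_str(dr), _ds_str(dc)]
    ds.SliceThickness = _ds_str(1.0)
    ds.ImagePositionPatient = [_ds_str(v) for v in frame.origin_mm]
    ds.ImageOrientationPatient = [
        _ds_str(v) for v in (*frame.row_cosines, *frame.col_cosines)
    ]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = np.ascontiguousarray(frame.pixels, dtype="<u2").tobytes()

    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
    return path


def convert_session(
    layout: SessionLayout,
    out_dir,
    fmt: str = "mha",
    salt: int = 0,
    templates: TemplateStore | None = None,
    confidence_threshold: float = image_model.DEFAULT_CONFIDENCE_THRESHOLD,
    shift_px: int = CENTERING_SHIFT_PX,
) -> ConversionReport:
    """Convert one discovered session end to end.

    Per-frame failures (unclassifiable plane) are quarantined, never abort
    the session; the report conserves counts (converted + quarantined =
    input).  Outputs are deterministic for a fixed input and salt.
    """
    if fmt not in ("mha", "dicom", "both"):
        raise ValueError(f"unknown output format {fmt!r}")
    if not layout.valid:
        raise ConversionError(
            f"invalid session {layout.fraction_id}: {layout.invalid_reason}"
        )
    out_dir = Path(out_dir)
    fraction_out = out_dir / layout.fraction_id
    fraction_out.mkdir(parents=True, exist_ok=True)

    with open(layout.examcard_path) as fh:
        geometry = parse_examcard(json.load(fh))
    with open(layout.binarymasks_path) as fh:
        centroid = parse_target_centroid(json.load(fh))

    records = unity_format.order_frames(layout.frame_files, geometry)
    ctx = SeriesContext.create(layout.session_uid, salt)
    spacing = (geometry.pixel_spacing_row_mm, geometry.pixel_spacing_col_mm)

    counts = {p.value: 0 for p in image_model.CARDINAL_PLANES}
    outputs: dict[str, list[str]] = {p.value: [] for p in image_model.CARDINAL_PLANES}
    quarantine: list[dict] = []
    index: list[dict] = []

    for record in records:
        label, score = classify_plane(
            record.pixels, templates=templates, threshold=confidence_threshold
        )
        if label is PlaneLabel.UNKNOWN:
            quarantine.append(
                {
                    "file": str(record.source.path),
                    "sequence_index": record.sequence_index,
                    "score": score,
                }
            )
            logger.warning("frame %s quarantined (score %.3f)", record.source.path, score)
            continue
        shifted = apply_centering_shift(record.pixels, shift_px=shift_px)
        frame = assign_geometry(
            shifted,
            label,
            spacing,
            centroid,
            timestamp_ms=record.source.timestamp_ms,
            frame_uid=deterministic_uid(
                layout.session_uid, "sop", record.sequence_index, salt
            ),
        )
        plane_dir = fraction_out / label.value
        plane_dir.mkdir(exist_ok=True)
        stem = f"frame_{record.sequence_index:05d}"
        written: list[str] = []
        if fmt in ("mha", "both"):
            written.append(str(write_mha(frame, plane_dir / f"{stem}.mha")))
        if fmt in ("dicom", "both"):
            written.append(
                str(
                    write_dicom(
                        frame,
                        ctx,
                        plane_dir / f"{stem}.dcm",
                        instance_number=counts[label.value] + 1,
                    )
                )
            )
        counts[label.value] += 1
        outputs[label.value].extend(written)
        index.append(
            {
                "source": str(record.source.path),
                "sequence_index": record.sequence_index,
                "plane": label.value,
                "timestamp_ms": record.source.timestamp_ms,
                "outputs": written,
            }
        )

    report = ConversionReport(
        fraction_id=layout.fraction_id,
        session_uid=layout.session_uid,
        n_input=len(records),
        counts=counts,
        quarantined=len(quarantine),
        outputs=outputs,
        out_dir=str(fraction_out),
    )
    assert report.converted + report.quarantined == report.n_input
    (fraction_out / FRAMES_INDEX_FILENAME).write_text(
        json.dumps(index, indent=1, sort_keys=True)
    )
    (fraction_out / QUARANTINE_FILENAME).write_text(
        json.dumps(quarantine, indent=1, sort_keys=True)
    )
    (fraction_out / REPORT_FILENAME).write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True)
    )
    return report


def load_converted_frames(
    fraction_out, plane: PlaneLabel | None = None
) -> list[GeoFrame]:
    """Load converted frames of one fraction, in acquisition order, using the
    frame index written by :func:`convert_session` for timestamps."""
    fraction_out = Path(fraction_out)
    index = json.loads((fraction_out / FRAMES_INDEX_FILENAME).read_text())
    frames = []
    for entry in sorted(index, key=lambda e: e["sequence_index"]):
        if plane is not None and entry["plane"] != plane.value:
            continue
        frames.append(
            read_geoframe(entry["outputs"][0], timestamp_ms=entry["timestamp_ms"])
        )
    return frames
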