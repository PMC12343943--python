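"""Reading Unity-style 2D cine monitoring sessions from disk.

The on-disk dialect handled here (documented in full in ``docs/format.md``)
is a per-fraction directory containing

* headered binary frame files: an opaque 4,084-byte header followed by a
  row-major, little-endian, unsigned 16-bit pixel payload of
  ``rows x columns`` values;
* ``ExamCards/MotionMonitoring2DImages.ExamCardInfo.json`` carrying the image
  matrix size (``"Rows"``, ``"Columns"``) and the physical field of view
  (``"SliceDimensionXInmm"``, ``"SliceDimensionYInmm"``), from which pixel
  spacing is derived;
* a ``BinaryMasks`` folder with a JSON sidecar holding the target structure's
  centroid in patient (LPS) coordinates, in mm;
* per-frame millisecond timestamps, either from a ``manifest.json`` written
  next to the frames (the reproducible default) or from filesystem metadata.

The frame header is treated as opaque: only its length matters.  Axis
convention: ``SliceDimensionXInmm`` spans the columns (horizontal axis) and
``SliceDimensionYInmm`` the rows, consistent with the ``Rows``/``Columns``
naming of the matrix size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Byte length of the opaque header preceding every frame payload.
HEADER_LENGTH = 4084

#: Pixel payload element type: little-endian unsigned 16-bit.
PIXEL_DTYPE = np.dtype("<u2")

EXAMCARD_SUBDIR = "ExamCards"
EXAMCARD_FILENAME = "MotionMonitoring2DImages.ExamCardInfo.json"
BINARYMASKS_SUBDIR = "BinaryMasks"
MANIFEST_FILENAME = "manifest.json"
FRAME_SUFFIX = ".bin"

EXAMCARD_KEYS = ("Rows", "Columns", "SliceDimensionXInmm", "SliceDimensionYInmm")


class UnityFormatError(Exception):
    """Base class for session-layout and frame-dialect errors."""


class TruncatedFrameError(UnityFormatError):
    """Frame file too short for the header plus the expected payload."""


class SchemaError(UnityFormatError):
    """A JSON sidecar is missing a required key or holds an invalid value."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Image matrix size and physical field of view for one session.

    Pixel spacing is derived, not stored: columns span
    ``slice_dim_x_mm`` and rows span ``slice_dim_y_mm``.
    """

    rows: int
    columns: int
    slice_dim_x_mm: float
    slice_dim_y_mm: float

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.columns <= 0:
            raise SchemaError(
                f"matrix size must be positive, got {self.rows}x{self.columns}"
            )
        if self.slice_dim_x_mm <= 0 or self.slice_dim_y_mm <= 0:
            raise SchemaError(
                "slice dimensions must be positive, got "
                f"{self.slice_dim_x_mm} x {self.slice_dim_y_mm} mm"
            )

    @property
    def pixel_spacing_col_mm(self) -> float:
        """Spacing between column centers (mm/pixel, horizontal)."""
        return self.slice_dim_x_mm / self.columns

    @property
    def pixel_spacing_row_mm(self) -> float:
        """Spacing between row centers (mm/pixel, vertical)."""
        return self.slice_dim_y_mm / self.rows

    @property
    def frame_payload_bytes(self) -> int:
        return 2 * self.rows * self.columns


@dataclass(frozen=True)
class TargetCentroid:
    """Target-structure centroid in patient space (DICOM LPS, mm)."""

    x_mm: float
    y_mm: float
    z_mm: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.x_mm, self.y_mm, self.z_mm])):
            raise SchemaError("centroid coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x_mm, self.y_mm, self.z_mm], dtype=float)


@dataclass(frozen=True)
class RawFrameFile:
    """One on-disk binary cine frame: opaque header plus pixel payload."""

    path: Path
    byte_length: int
    timestamp_ms: int


@dataclass
class SessionLayout:
    """Discovered layout of one treatment-fraction cine session."""

    root: Path
    fraction_id: str
    examcard_path: Path | None
    binarymasks_path: Path | None
    frame_files: list[RawFrameFile] = field(default_factory=list)
    session_uid: str = ""
    valid: bool = True
    invalid_reason: str | None = None


@dataclass
class FrameRecord:
    """A decoded frame placed in acquisition order."""

    pixels: np.ndarray
    source: RawFrameFile
    sequence_index: int


def read_frame_pixels(path, geometry: AcquisitionGeometry) -> np.ndarray:
    """Decode one binary frame file into a ``rows x columns`` uint16 matrix.

    Skips exactly :data:`HEADER_LENGTH` bytes, then reads exactly
    ``2 * rows * columns`` payload bytes as little-endian unsigned 16-bit
    integers in row-major order.  Decoding is lossless:
    :func:`encode_frame_payload` on the result reproduces the payload bytes.
    """
    path = Path(path)
    expected = HEADER_LENGTH + geometry.frame_payload_bytes
    actual = path.stat().st_size
    if actual < expected:
        raise TruncatedFrameError(
            f"{path}: expected at least {expected} bytes "
            f"({HEADER_LENGTH} header + {geometry.frame_payload_bytes} payload "
            f"for {geometry.rows}x{geometry.columns}), got {actual}"
        )
    with open(path, "rb") as fh:
        fh.seek(HEADER_LENGTH)
        payload = fh.read(geometry.frame_payload_bytes)
    pixels = np.frombuffer(payload, dtype=PIXEL_DTYPE)
    return pixels.reshape(geometry.rows, geometry.columns)


def encode_frame_payload(pixels: np.ndarray) -> bytes:
    """Encode a pixel matrix as the on-disk payload (LE uint16, row-major)."""
    return np.ascontiguousarray(pixels, dtype=PIXEL_DTYPE).tobytes()


def parse_examcard(document: dict) -> AcquisitionGeometry:
    """Build the session geometry from a parsed ExamCard JSON document."""
    for key in EXAMCARD_KEYS:
        if key not in document:
            raise SchemaError(f"ExamCard document missing required key {key!r}")
    return AcquisitionGeometry(
        rows=int(document["Rows"]),
        columns=int(document["Columns"]),
        slice_dim_x_mm=float(document["SliceDimensionXInmm"]),
        slice_dim_y_mm=float(document["SliceDimensionYInmm"]),
    )


def parse_target_centroid(document: dict) -> TargetCentroid:
    """Extract the target-structure centroid from a BinaryMasks JSON document.

    Expected schema (fixture-normative; the vendor key names are not public):
    ``{"structure": <name>, "centroid_lps_mm": [x, y, z]}``.
    """
    try:
        triple = document["centroid_lps_mm"]
    except (KeyError, TypeError) as exc:
        raise SchemaError(
            "BinaryMasks document missing required key 'centroid_lps_mm'"
        ) from exc
    if not isinstance(triple, (list, tuple)) or len(triple) != 3:
        raise SchemaError(f"centroid must be a 3-vector, got {triple!r}")
    return TargetCentroid(float(triple[0]), float(triple[1]), float(triple[2]))


def _load_manifest(fraction_dir: Path) -> dict | None:
    manifest_path = fraction_dir / MANIFEST_FILENAME
    if not manifest_path.is_file():
        return None
    with open(manifest_path) as fh:
        return json.load(fh)


def _discover_fraction(fraction_dir: Path, timestamp_source: str) -> SessionLayout:
    layout = SessionLayout(
        root=fraction_dir,
        fraction_id=fraction_dir.name,
        examcard_path=None,
        binarymasks_path=None,
        session_uid=fraction_dir.name,
    )

    examcard = fraction_dir / EXAMCARD_SUBDIR / EXAMCARD_FILENAME
    if examcard.is_file():
        layout.examcard_path = examcard
    else:
        layout.valid = False
        layout.invalid_reason = "missing ExamCard"
        return layout

    masks_dir = fraction_dir / BINARYMASKS_SUBDIR
    mask_jsons = sorted(masks_dir.glob("*.json")) if masks_dir.is_dir() else []
    if mask_jsons:
        layout.binarymasks_path = mask_jsons[0]
    else:
        layout.valid = False
        layout.invalid_reason = "missing centroid"
        return layout

    manifest = _load_manifest(fraction_dir)
    if manifest and manifest.get("session_uid"):
        layout.session_uid = str(manifest["session_uid"])

    if timestamp_source == "manifest":
        if manifest is None:
            layout.valid = False
            layout.invalid_reason = "missing manifest"
            return layout
        stamps = {e["file"]: int(e["timestamp_ms"]) for e in manifest["frames"]}
    elif timestamp_source == "filesystem":
        stamps = None
    else:
        raise ValueError(f"unknown timestamp source {timestamp_source!r}")

    for frame_path in sorted(fraction_dir.glob(f"*{FRAME_SUFFIX}")):
        if stamps is not None:
            if frame_path.name not in stamps:
                logger.warning("%s not listed in manifest; skipped", frame_path)
                continue
            ts = stamps[frame_path.name]
        else:
            ts = frame_path.stat().st_mtime_ns // 1_000_000
        layout.frame_files.append(
            RawFrameFile(
                path=frame_path,
                byte_length=frame_path.stat().st_size,
                timestamp_ms=ts,
            )
        )

    if not layout.frame_files:
        layout.valid = False
        layout.invalid_reason = "no frame files"
    return layout


def discover_session(root, timestamp_source: str = "manifest") -> list[SessionLayout]:
    """Discover per-fraction session layouts under ``root``.

    Every immediate subdirectory is treated as one treatment fraction.
    Fractions with a missing ExamCard, centroid JSON, manifest or frame files
    are returned flagged invalid with a reason rather than silently dropped.
    An empty or frame-less root yields an empty list, not an error.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"session root {root} does not exist")
    layouts = [
        _discover_fraction(sub, timestamp_source)
        for sub in sorted(p for p in root.iterdir() if p.is_dir())
    ]
    for layout in layouts:
        if not layout.valid:
            logger.warning(
                "fraction %s flagged invalid: %s",
                layout.fraction_id,
                layout.invalid_reason,
            )
    return layouts


def order_frames(
    files: list[RawFrameFile], geometry: AcquisitionGeometry
) -> list[FrameRecord]:
    """Decode frames and place them in acquisition order.

    Sorting is by millisecond timestamp; ties (true simultaneity is impossible
    at ~5 frames/s) break deterministically by filename, with a warning.  The
    result is invariant to the input (filesystem enumeration) order.
    """
    ordered = sorted(files, key=lambda f: (f.timestamp_ms, f.path.name))
    seen: set[int] = set()
    for f in ordered:
        if f.timestamp_ms in seen:
            logger.warning(
                "duplicate timestamp %d ms; tie broken by filename (%s)",
                f.timestamp_ms,
                f.path.name,
            )
        seen.add(f.timestamp_ms)
    return [
        FrameRecord(pixels=read_frame_pixels(f.path, geometry), source=f, sequence_index=i)
        for i, f in enumerate(ordered)
    ]
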