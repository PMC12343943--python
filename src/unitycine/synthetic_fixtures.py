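"""Byte-exact synthetic Unity-style cine sessions.

No real Unity cine data is publicly available (the vendor format cannot be
read even by the vendor's own software after treatment), so this generator
is the *normative* counterpart of the reader: it writes the exact binary
dialect documented in ``docs/format.md`` — 4,084-byte sentinel header,
little-endian uint16 row-major payload, ExamCard and BinaryMasks JSON
sidecars, a millisecond-timestamp manifest — around an anti-aliased
rendering of a motion-management QA phantom (a ZEUS-like body with a
cylindrical rod insert, a movable target and a spine-mimicking block) with
programmed periodic motion or whole-phantom translations.

Every session ships with a machine-readable ground-truth JSON (true plane,
displacement and timestamp per frame), so no test needs manual annotation.
Fixed (spec, program, seed) inputs produce byte-identical session trees.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import unity_format
from .image_model import (
    CENTERING_SHIFT_PX,
    DEFAULT_PATCH_SIZE,
    PlaneLabel,
    glyph_pattern,
)
from .unity_format import (
    AcquisitionGeometry,
    SessionLayout,
    TargetCentroid,
    discover_session,
)

#: Opaque header written before every payload: a fixed, non-repeating-period
#: byte pattern so any off-by-one header/payload misalignment shifts
#: recognizable bytes into the payload and fails loudly in tests.
HEADER_SENTINEL = bytes((i * 73 + 41) % 256 for i in range(unity_format.HEADER_LENGTH))

#: Fixed epoch for manifest timestamps: 2025-01-01T00:00:00Z, in ms.
DEFAULT_BASE_TIME_MS = 1_735_689_600_000


class RenderError(Exception):
    """The phantom does not fit in the requested field of view."""


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth geometry and intensity levels of the QA phantom.

    Dimensions are mm.  The rod is a cylindrical sleeve along the
    superior-inferior axis holding a movable bright target insert; the body
    is the outer fluid-filled shell; the spine block is a stack of
    vertebra-like slabs used for translation registration.
    """

    rod_inner_diameter_mm: float = 58.5
    body_inner_length_mm: float = 150.1
    body_inner_width_mm: float = 160.0
    rod_length_mm: float = 100.0
    target_diameter_mm: float = 25.0
    n_vertebrae: int = 4
    vertebra_height_mm: float = 25.0
    vertebra_width_mm: float = 30.0
    vertebra_gap_mm: float = 8.0
    spine_offset_mm: float = 45.0
    background_intensity: float = 1000.0
    body_intensity: float = 8000.0
    rod_intensity: float = 16000.0
    target_intensity: float = 26000.0
    spine_intensity: float = 24000.0
    glyph_intensity: float = 30000.0

    def __post_init__(self) -> None:
        dims = (
            self.rod_inner_diameter_mm,
            self.body_inner_length_mm,
            self.body_inner_width_mm,
            self.rod_length_mm,
            self.target_diameter_mm,
        )
        if any(d <= 0 for d in dims):
            raise ValueError("phantom dimensions must be positive")
        if self.rod_inner_diameter_mm >= self.body_inner_width_mm:
            raise ValueError("rod must fit inside the phantom body")
        if self.target_diameter_mm > self.rod_inner_diameter_mm:
            raise ValueError("target must fit inside the rod")

    @property
    def contrast(self) -> float:
        return self.target_intensity - self.background_intensity


@dataclass(frozen=True)
class MotionProgram:
    """Programmed phantom motion for one session.

    ``periodic`` moves the target insert along the in-plane vertical axis
    with the given waveform; ``shifted`` translates the whole phantom by a
    constant offset (couch-shift scenario); ``static`` does neither.
    Amplitude is the peak displacement from rest, matching how motion
    amplitudes are programmed on the physical phantom.
    """

    kind: str = "static"  # static | periodic | shifted
    amplitude_mm: float = 0.0
    period_s: float = 4.0
    shift_mm: float = 0.0
    frame_interval_s: float = 0.2
    n_frames: int = 50
    waveform: str = "sine"  # sine | triangle
    noise_sd: float = 0.0  # additive Gaussian, as a fraction of contrast
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("static", "periodic", "shifted"):
            raise ValueError(f"unknown program kind {self.kind!r}")
        if self.waveform not in ("sine", "triangle"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")
        if self.amplitude_mm < 0 or self.period_s <= 0:
            raise ValueError("amplitude must be >= 0 and period > 0")

    def displacement_at(self, t_s: float) -> tuple[float, float]:
        """(du, dv) in-plane displacement (mm) at elapsed time ``t_s``."""
        if self.kind == "static":
            return (0.0, 0.0)
        if self.kind == "shifted":
            return (0.0, float(self.shift_mm))
        phase = (t_s / self.period_s) % 1.0
        if self.waveform == "sine":
            w = np.sin(2.0 * np.pi * phase)
        else:
            if phase < 0.25:
                w = 4.0 * phase
            elif phase < 0.75:
                w = 2.0 - 4.0 * phase
            else:
                w = 4.0 * phase - 4.0
        return (0.0, float(self.amplitude_mm * w))


def _rect_alpha(u, v, cu, cv, width, height, du_px, dv_px):
    """Exact area coverage of an axis-aligned rectangle per pixel."""
    au = np.clip((width / 2.0 - np.abs(u - cu)) / du_px + 0.5, 0.0, 1.0)
    av = np.clip((height / 2.0 - np.abs(v - cv)) / dv_px + 0.5, 0.0, 1.0)
    return au * av


def _disc_alpha(u, v, cu, cv, diameter, edge):
    """Approximate area coverage of a disc: linear ramp over one pixel."""
    r = np.hypot(u - cu, v - cv)
    return np.clip(0.5 + (diameter / 2.0 - r) / edge, 0.0, 1.0)


def _paint(img, alpha, value):
    img *= 1.0 - alpha
    img += value * alpha


def render_phantom_frame(
    spec: PhantomSpec,
    plane: PlaneLabel,
    displacement_mm: tuple[float, float],
    geometry: AcquisitionGeometry,
    intensity_scale: float = 1.0,
    pre_shift_px: int = CENTERING_SHIFT_PX,
    move_whole: bool = False,
    stamp_glyph: bool = True,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one anti-aliased cine frame of the phantom.

    In-plane coordinates: u along image columns, v along image rows, origin
    at the phantom center.  The phantom center is drawn ``pre_shift_px``
    columns to the *right* of the image center, the inverse of the fixed
    centering shift, so the converter's shift lands the phantom exactly
    centered.  ``displacement_mm`` moves the target insert only, unless
    ``move_whole`` is set (couch-shift scenario).  The plane's corner glyph
    is stamped over a cleared top-right patch.
    """
    rows, cols = geometry.rows, geometry.columns
    du_px = geometry.pixel_spacing_col_mm
    dv_px = geometry.pixel_spacing_row_mm
    r_idx, c_idx = np.indices((rows, cols), dtype=float)
    u = (c_idx - (cols - 1) / 2.0 - pre_shift_px) * du_px
    v = (r_idx - (rows - 1) / 2.0) * dv_px

    du, dv = displacement_mm
    whole = np.array([du, dv]) if move_whole else np.zeros(2)
    moving = np.array([du, dv])

    half_u = spec.body_inner_width_mm / 2.0 + abs(whole[0])
    half_v = spec.body_inner_length_mm / 2.0 + abs(whole[1])
    if (
        half_u + pre_shift_px * du_px > geometry.slice_dim_x_mm / 2.0
        or half_v > geometry.slice_dim_y_mm / 2.0
    ):
        raise RenderError("phantom exceeds the field of view")

    img = np.full((rows, cols), float(spec.background_intensity))
    edge = max(du_px, dv_px)

    if plane is PlaneLabel.AXIAL:
        # cross-section perpendicular to the body axis: body and rod circles
        _paint(img, _disc_alpha(u, v, *whole, spec.body_inner_width_mm, edge), spec.body_intensity)
        _paint(img, _disc_alpha(u, v, *whole, spec.rod_inner_diameter_mm, edge), spec.rod_intensity)
    else:
        _paint(
            img,
            _rect_alpha(u, v, *whole, spec.body_inner_width_mm, spec.body_inner_length_mm, du_px, dv_px),
            spec.body_intensity,
        )
        _paint(
            img,
            _rect_alpha(u, v, *whole, spec.rod_inner_diameter_mm, spec.rod_length_mm, du_px, dv_px),
            spec.rod_intensity,
        )
        if plane is PlaneLabel.SAGITTAL:
            pitch = spec.vertebra_height_mm + spec.vertebra_gap_mm
            v0 = -(spec.n_vertebrae - 1) / 2.0 * pitch
            for k in range(spec.n_vertebrae):
                _paint(
                    img,
                    _rect_alpha(
                        u,
                        v,
                        spec.spine_offset_mm + whole[0],
                        v0 + k * pitch + whole[1],
                        spec.vertebra_width_mm,
                        spec.vertebra_height_mm,
                        du_px,
                        dv_px,
                    ),
                    spec.spine_intensity,
                )
        target_center = whole if move_whole else moving
        _paint(
            img,
            _disc_alpha(u, v, target_center[0], target_center[1], spec.target_diameter_mm, edge),
            spec.target_intensity,
        )

    if stamp_glyph:
        ps = DEFAULT_PATCH_SIZE
        patch = img[:ps, cols - ps :]
        patch[:] = 0.0
        patch[glyph_pattern(plane, ps)] = spec.glyph_intensity

    img *= intensity_scale
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_sd * spec.contrast * intensity_scale, img.shape)
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def generate_session(
    out_root,
    geometry: AcquisitionGeometry,
    spec: PhantomSpec | None = None,
    program: MotionProgram | None = None,
    planes: tuple[PlaneLabel, ...] = (PlaneLabel.CORONAL,),
    centroid: TargetCentroid = TargetCentroid(0.0, 0.0, 0.0),
    seed: int | None = None,
    intensity_scale: float = 1.0,
    fraction_id: str = "fraction_001",
    session_uid: str | None = None,
    base_time_ms: int = DEFAULT_BASE_TIME_MS,
) -> SessionLayout:
    """Write one complete synthetic session tree and return its layout.

    The fraction directory receives binary frames (interleaved across the
    requested planes at the program's frame interval), the ExamCard and
    BinaryMasks sidecars, a timestamp manifest and a ground-truth JSON.
    """
    spec = spec or PhantomSpec()
    program = program or MotionProgram()
    rng = np.random.default_rng(program.seed if seed is None else seed)

    out_root = Path(out_root)
    fraction_dir = out_root / fraction_id
    fraction_dir.mkdir(parents=True, exist_ok=True)
    session_uid = session_uid or f"1.2.826.0.1.{abs(hash(fraction_id)) % 10**8}"

    examcard_dir = fraction_dir / unity_format.EXAMCARD_SUBDIR
    examcard_dir.mkdir(exist_ok=True)
    (examcard_dir / unity_format.EXAMCARD_FILENAME).write_text(
        json.dumps(
            {
                "Rows": geometry.rows,
                "Columns": geometry.columns,
                "SliceDimensionXInmm": geometry.slice_dim_x_mm,
                "SliceDimensionYInmm": geometry.slice_dim_y_mm,
            },
            indent=1,
            sort_keys=True,
        )
    )
    masks_dir = fraction_dir / unity_format.BINARYMASKS_SUBDIR
    masks_dir.mkdir(exist_ok=True)
    (masks_dir / "target_structure.json").write_text(
        json.dumps(
            {
                "structure": "TARGET",
                "centroid_lps_mm": [centroid.x_mm, centroid.y_mm, centroid.z_mm],
            },
            indent=1,
            sort_keys=True,
        )
    )

    interval_ms = round(program.frame_interval_s * 1000.0)
    manifest_frames = []
    truth_frames = []
    for i in range(program.n_frames):
        plane = planes[i % len(planes)]
        ts_ms = base_time_ms + i * interval_ms
        t_s = i * program.frame_interval_s
        displacement = program.displacement_at(t_s)
        pixels = render_phantom_frame(
            spec,
            plane,
            displacement,
            geometry,
            intensity_scale=intensity_scale,
            move_whole=(program.kind == "shifted"),
            noise_sd=program.noise_sd,
            rng=rng,
        )
        name = f"cine_{ts_ms:013d}_{i:05d}{unity_format.FRAME_SUFFIX}"
        with open(fraction_dir / name, "wb") as fh:
            fh.write(HEADER_SENTINEL)
            fh.write(unity_format.encode_frame_payload(pixels))
        manifest_frames.append({"file": name, "timestamp_ms": ts_ms})
        truth_frames.append(
            {
                "file": name,
                "plane": plane.value,
                "displacement_mm": [displacement[0], displacement[1]],
                "timestamp_ms": ts_ms,
            }
        )

    (fraction_dir / unity_format.MANIFEST_FILENAME).write_text(
        json.dumps(
            {"session_uid": session_uid, "frames": manifest_frames},
            indent=1,
            sort_keys=True,
        )
    )
    (fraction_dir / "ground_truth.json").write_text(
        json.dumps(
            {
                "program": asdict(program),
                "phantom": asdict(spec),
                "intensity_scale": intensity_scale,
                "centroid_lps_mm": [centroid.x_mm, centroid.y_mm, centroid.z_mm],
                "frames": truth_frames,
            },
            indent=1,
            sort_keys=True,
        )
    )

    (layout,) = [
        l for l in discover_session(out_root) if l.fraction_id == fraction_id
    ]
    return layout


def load_ground_truth(fraction_dir) -> dict:
    return json.loads((Path(fraction_dir) / "ground_truth.json").read_text())
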