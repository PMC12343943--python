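"""End-to-end phantom verification experiments.

These helpers re-run, on synthetic sessions, the two verification studies
used to validate the conversion pipeline: recovery of programmed periodic
target motion (amplitudes 5/10/15/20 mm, 4 s period, 0.2 s frame interval)
from tracked centroids, and recovery of programmed whole-phantom
translations (0.5/1/2/3/5 mm) by 2D-2D translation registration, plus the
static dimension measurements (rod inner diameter 58.5 mm, body inner
length 150.1 mm).  Every experiment generates sessions with the fixture
generator, converts them with the full pipeline, and analyzes the converted
frames — nothing is read back from ground truth except for scoring.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .converters import convert_session, load_converted_frames
from .image_model import PlaneLabel
from .motion_qa import (
    estimate_amplitude,
    measure_distance,
    register_translation,
    track_centroid,
)
from .synthetic_fixtures import MotionProgram, PhantomSpec, generate_session
from .unity_format import AcquisitionGeometry

#: 256 x 256 matrix over a 256 mm field of view: 1 mm isotropic pixels.
DEFAULT_GEOMETRY = AcquisitionGeometry(
    rows=256, columns=256, slice_dim_x_mm=256.0, slice_dim_y_mm=256.0
)

DEFAULT_AMPLITUDES_MM = (5.0, 10.0, 15.0, 20.0)
DEFAULT_SHIFTS_MM = (0.5, 1.0, 2.0, 3.0, 5.0)


def _convert_and_load(work_dir, name, geometry, plane, **session_kwargs):
    session_root = Path(work_dir) / name
    layout = generate_session(session_root, geometry, planes=(plane,), **session_kwargs)
    report = convert_session(layout, session_root / "converted", fmt="mha")
    frames = load_converted_frames(Path(report.out_dir), plane=plane)
    return frames


def _tracking_roi(geometry, spec, amplitude_mm):
    """Pixel ROI around the target's full motion range, kept inside the rod
    sleeve so the ROI holds exactly two intensity classes."""
    rows, cols = geometry.rows, geometry.columns
    dr, dc = geometry.pixel_spacing_row_mm, geometry.pixel_spacing_col_mm
    half_v_mm = min(amplitude_mm + spec.target_diameter_mm / 2.0 + 8.0,
                    spec.rod_length_mm / 2.0 - 4.0)
    half_u_mm = min(spec.target_diameter_mm / 2.0 + 8.0,
                    spec.rod_inner_diameter_mm / 2.0 - 4.0)
    rc, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    return (
        int(np.floor(rc - half_v_mm / dr)),
        int(np.ceil(rc + half_v_mm / dr)) + 1,
        int(np.floor(cc - half_u_mm / dc)),
        int(np.ceil(cc + half_u_mm / dc)) + 1,
    )


def run_motion_experiment(
    work_dir,
    amplitudes_mm=DEFAULT_AMPLITUDES_MM,
    seed: int = 42,
    n_frames: int = 101,
    n_reference_frames: int = 11,
    geometry: AcquisitionGeometry = DEFAULT_GEOMETRY,
    spec: PhantomSpec | None = None,
) -> dict:
    """Amplitude-recovery experiment on coronal cine sequences.

    For each programmed amplitude: generate a stationary reference session
    and a periodic-motion session, convert both, track the target centroid
    in the coronal frames against the stationary reference position, and
    estimate the per-cycle amplitude.  Returns per-amplitude estimates and
    signed errors plus their mean and the maximum absolute error.
    """
    spec = spec or PhantomSpec()
    estimates, sds, errors = [], [], []
    for k, amplitude in enumerate(amplitudes_mm):
        static = MotionProgram(kind="static", n_frames=n_reference_frames, seed=seed + 2 * k)
        moving = MotionProgram(
            kind="periodic", amplitude_mm=amplitude, n_frames=n_frames, seed=seed + 2 * k + 1
        )
        ref_frames = _convert_and_load(
            work_dir, f"ref_a{amplitude:g}", geometry, PlaneLabel.CORONAL,
            spec=spec, program=static,
        )
        mov_frames = _convert_and_load(
            work_dir, f"mov_a{amplitude:g}", geometry, PlaneLabel.CORONAL,
            spec=spec, program=moving,
        )
        roi = _tracking_roi(geometry, spec, amplitude)
        trace = track_centroid(mov_frames, roi, reference_frames=ref_frames)
        est = estimate_amplitude(trace)
        estimates.append(est.mean_mm)
        sds.append(est.sd_mm)
        errors.append(est.mean_mm - amplitude)
    errors = np.asarray(errors)
    return {
        "amplitudes_mm": list(amplitudes_mm),
        "estimates_mm": estimates,
        "sds_mm": sds,
        "errors_mm": errors.tolist(),
        "mean_signed_error_mm": float(errors.mean()),
        "max_abs_error_mm": float(np.abs(errors).max()),
        "n_frames": n_frames,
    }


def _spine_roi(geometry, spec):
    rows, cols = geometry.rows, geometry.columns
    dr, dc = geometry.pixel_spacing_row_mm, geometry.pixel_spacing_col_mm
    rc, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    half_v_mm = (spec.n_vertebrae * (spec.vertebra_height_mm + spec.vertebra_gap_mm)) / 2.0 + 12.0
    half_u_mm = spec.vertebra_width_mm / 2.0 + 12.0
    cu = spec.spine_offset_mm / dc
    return (
        int(rc - half_v_mm / dr),
        int(rc + half_v_mm / dr) + 1,
        int(cc + cu - half_u_mm / dc),
        int(cc + cu + half_u_mm / dc) + 1,
    )


def run_shift_experiment(
    work_dir,
    shifts_mm=DEFAULT_SHIFTS_MM,
    seed: int = 42,
    n_frames: int = 3,
    geometry: AcquisitionGeometry = DEFAULT_GEOMETRY,
    spec: PhantomSpec | None = None,
) -> dict:
    """Translation-recovery experiment on sagittal cine frames.

    Generates a reference session and one session per programmed
    whole-phantom shift (subpixel rendering), converts them, and registers
    each shifted frame to the reference with translation-only normalized
    cross-correlation inside an ROI around the vertebral bodies.
    """
    spec = spec or PhantomSpec()
    roi = _spine_roi(geometry, spec)
    ref_frames = _convert_and_load(
        work_dir, "shift_ref", geometry, PlaneLabel.SAGITTAL,
        spec=spec, program=MotionProgram(kind="static", n_frames=n_frames, seed=seed),
    )
    recovered, errors = [], []
    for k, shift in enumerate(shifts_mm):
        frames = _convert_and_load(
            work_dir, f"shift_{shift:g}", geometry, PlaneLabel.SAGITTAL,
            spec=spec,
            program=MotionProgram(
                kind="shifted", shift_mm=shift, n_frames=n_frames, seed=seed + k + 1
            ),
        )
        offset = register_translation(ref_frames[0], frames[0], roi=roi)
        recovered.append(float(offset.shift_mm[1]))
        errors.append(float(offset.shift_mm[1] - shift))
    return {
        "shifts_mm": list(shifts_mm),
        "recovered_mm": recovered,
        "errors_mm": errors,
        "max_abs_error_mm": float(np.max(np.abs(errors))),
        "n_frames": n_frames,
    }


def run_dimension_measurements(
    work_dir,
    seed: int = 42,
    geometry: AcquisitionGeometry = DEFAULT_GEOMETRY,
    spec: PhantomSpec | None = None,
) -> dict:
    """Static dimension measurements on converted phantom frames.

    Measures the rod inner diameter on the axial and coronal frames and the
    body inner length on the coronal and sagittal frames, each with the
    half-maximum edge-profile routine.  Profile placement avoids the target
    insert and the spine block so each profile crosses exactly the intended
    pair of edges.
    """
    spec = spec or PhantomSpec()
    session_root = Path(work_dir) / "static_dims"
    layout = generate_session(
        session_root,
        geometry,
        spec=spec,
        program=MotionProgram(kind="static", n_frames=3, seed=seed),
        planes=(PlaneLabel.AXIAL, PlaneLabel.CORONAL, PlaneLabel.SAGITTAL),
    )
    report = convert_session(layout, session_root / "converted", fmt="mha")
    frames = {
        plane: load_converted_frames(Path(report.out_dir), plane=plane)[0]
        for plane in (PlaneLabel.AXIAL, PlaneLabel.CORONAL, PlaneLabel.SAGITTAL)
    }

    def point(frame, u_mm, v_mm):
        center = frame.center_world()
        return center + u_mm * frame.row_cosines + v_mm * frame.col_cosines

    reach_u = spec.body_inner_width_mm / 2.0 - 10.0
    reach_v = spec.body_inner_length_mm / 2.0 + 10.0
    lateral = spec.rod_inner_diameter_mm / 2.0 + 25.0  # outside the rod

    ax = frames[PlaneLabel.AXIAL]
    rod_axial = measure_distance(ax, point(ax, -reach_u, 0.0), point(ax, reach_u, 0.0))
    cor = frames[PlaneLabel.CORONAL]
    v_off = spec.target_diameter_mm / 2.0 + 10.0  # below the target insert
    rod_coronal = measure_distance(
        cor, point(cor, -reach_u, v_off), point(cor, reach_u, v_off)
    )
    length_coronal = measure_distance(
        cor, point(cor, -lateral, -reach_v), point(cor, -lateral, reach_v)
    )
    sag = frames[PlaneLabel.SAGITTAL]
    length_sagittal = measure_distance(
        sag, point(sag, -lateral, -reach_v), point(sag, -lateral, reach_v)
    )
    return {
        "rod_inner_diameter_mm": {
            "measured": [rod_axial, rod_coronal],
            "mean": float(np.mean([rod_axial, rod_coronal])),
            "ground_truth": spec.rod_inner_diameter_mm,
        },
        "body_inner_length_mm": {
            "measured": [length_coronal, length_sagittal],
            "mean": float(np.mean([length_coronal, length_sagittal])),
            "ground_truth": spec.body_inner_length_mm,
        },
        "n_pixels": geometry.rows * geometry.columns,
    }
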