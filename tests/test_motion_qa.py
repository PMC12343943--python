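import numpy as np
import pytest
from skimage.registration import phase_cross_correlation

from unitycine.image_model import PlaneLabel, assign_geometry
from unitycine.motion_qa import (
    InsufficientCyclesError,
    MotionTrace,
    NoEdgeError,
    NoStructureError,
    NoTargetError,
    estimate_amplitude,
    measure_distance,
    register_translation,
    segment_target,
    track_centroid,
)
from unitycine.unity_format import AcquisitionGeometry

from conftest import GEOMETRY_1MM, ORIGIN_CENTROID

GEOMETRY_HALF_MM = AcquisitionGeometry(512, 512, 256.0, 256.0)

TARGET_ROI = (88, 169, 103, 154)  # around the target's motion range, 1 mm pixels


def profile_points(frame, u0, v0, u1, v1):
    center = frame.center_world()
    return (center + u0 * frame.row_cosines + v0 * frame.col_cosines,
            center + u1 * frame.row_cosines + v1 * frame.col_cosines)


class TestSegmentTarget:
    def test_noise_free_disc_centroid_within_tenth_pixel(self, geoframe_factory):
        frame = geoframe_factory(displacement=(0.0, 3.3))
        _, world = segment_target(frame, TARGET_ROI)
        v = world @ frame.col_cosines
        u = world @ frame.row_cosines
        assert abs(v - 3.3) < 0.1
        assert abs(u - 0.0) < 0.1

    def test_uniform_roi_raises_no_target(self, geoframe_factory):
        frame = geoframe_factory()
        frame.pixels[88:169, 103:154] = 1234
        with pytest.raises(NoTargetError):
            segment_target(frame, TARGET_ROI)

    def test_noisy_disc_centroid_within_half_pixel(self, geoframe_factory, rng):
        frame = geoframe_factory(displacement=(0.0, -6.1), noise_sd=0.05, rng=rng)
        _, world = segment_target(frame, TARGET_ROI)
        assert abs(world @ frame.col_cosines - (-6.1)) < 0.5

    def test_mask_is_the_bright_component(self, geoframe_factory):
        frame = geoframe_factory()
        mask, _ = segment_target(frame, TARGET_ROI)
        assert frame.pixels[mask].mean() > frame.pixels[~mask].mean()


def make_sequence(geoframe_factory, displacements, interval_ms=200, **kwargs):
    return [
        geoframe_factory(displacement=(0.0, dv), timestamp_ms=i * interval_ms, **kwargs)
        for i, dv in enumerate(displacements)
    ]


class TestTrackCentroid:
    def test_stationary_sequence_stays_at_reference(self, geoframe_factory):
        frames = make_sequence(geoframe_factory, [0.0] * 5)
        trace = track_centroid(frames, TARGET_ROI, reference_mm=(0.0, 0.0))
        assert np.nanmax(np.abs(trace.displacements())) < 0.5

    def test_period_of_programmed_motion_recovered(self, geoframe_factory):
        t = np.arange(81) * 0.2
        frames = make_sequence(geoframe_factory, 10.0 * np.sin(2 * np.pi * t / 4.0))
        trace = track_centroid(frames, TARGET_ROI, reference_mm=(0.0, 0.0))
        v = trace.displacements()[:, 1]
        freqs = np.fft.rfftfreq(len(v), d=0.2)
        peak = freqs[1 + np.argmax(np.abs(np.fft.rfft(v - v.mean()))[1:])]
        assert abs(1.0 / peak - 4.0) <= 0.2

    def test_corrupted_frame_becomes_gap_length_preserved(self, geoframe_factory):
        frames = make_sequence(geoframe_factory, [0.0, 1.0, 2.0, 3.0])
        r0, r1, c0, c1 = TARGET_ROI
        frames[2].pixels[r0:r1, c0:c1] = 500
        trace = track_centroid(frames, TARGET_ROI, reference_mm=(0.0, 0.0))
        assert len(trace.positions_mm) == 4
        assert np.isnan(trace.positions_mm[2]).all()
        assert trace.valid_mask().tolist() == [True, True, False, True]

    def test_trace_times_must_strictly_increase(self):
        with pytest.raises(ValueError):
            MotionTrace(times_s=[0.0, 0.0], positions_mm=[[0, 0], [0, 0]],
                        reference_mm=[0, 0])


class TestEstimateAmplitude:
    def _triangular_trace(self, amplitude, period=4.0, dt=0.2, n=81, quantize=1.0):
        t = np.arange(n) * dt
        phase = (t / period) % 1.0
        w = np.where(phase < 0.25, 4 * phase,
                     np.where(phase < 0.75, 2 - 4 * phase, 4 * phase - 4))
        v = amplitude * w
        if quantize:
            v = np.round(v / quantize) * quantize  # pixel quantization
        return MotionTrace(times_s=t, positions_mm=np.column_stack([np.zeros(n), v]),
                           reference_mm=np.zeros(2))

    def test_triangular_motion_amplitude_recovered(self):
        est = estimate_amplitude(self._triangular_trace(10.0))
        assert abs(est.mean_mm - 10.0) <= 0.5
        assert est.sd_mm <= 0.3
        assert est.n_cycles >= 2

    def test_peak_to_peak_mode_doubles_symmetric_motion(self):
        trace = self._triangular_trace(10.0, quantize=0.0)
        est = estimate_amplitude(trace, mode="peak_to_peak")
        assert abs(est.mean_mm - 20.0) <= 0.5

    def test_constant_trace_has_insufficient_cycles(self):
        trace = MotionTrace(times_s=np.arange(10.0),
                            positions_mm=np.ones((10, 2)),
                            reference_mm=np.ones(2))
        with pytest.raises(InsufficientCyclesError):
            estimate_amplitude(trace)

    def test_single_cycle_rejected(self):
        trace = self._triangular_trace(5.0, n=25)
        with pytest.raises(InsufficientCyclesError):
            estimate_amplitude(trace)


SPINE_ROI = (53, 203, 148, 210)  # vertebra column, 1 mm sagittal frames


class TestRegisterTranslation:
    def test_identical_images_give_zero_shift_and_unit_score(self, geoframe_factory):
        frame = geoframe_factory(plane=PlaneLabel.SAGITTAL)
        offset = register_translation(frame, frame, roi=SPINE_ROI)
        assert np.allclose(offset.shift_mm, 0.0, atol=1e-9)
        assert offset.score == pytest.approx(1.0, abs=1e-6)

    def test_integer_pixel_shift_recovered_exactly(self, geoframe_factory):
        fixed = geoframe_factory(plane=PlaneLabel.SAGITTAL)
        moving = assign_geometry(np.roll(fixed.pixels, 3, axis=0),
                                 fixed.plane, fixed.spacing_mm, ORIGIN_CENTROID)
        offset = register_translation(fixed, moving, roi=SPINE_ROI)
        assert abs(np.linalg.norm(offset.shift_mm) - 3.0) < 0.05

    def test_agrees_with_phase_correlation_oracle(self, geoframe_factory):
        fixed = geoframe_factory(plane=PlaneLabel.SAGITTAL)
        moving = geoframe_factory(plane=PlaneLabel.SAGITTAL,
                                  displacement=(0.0, 2.3), move_whole=True)
        offset = register_translation(fixed, moving, roi=SPINE_ROI)
        r0, r1, c0, c1 = SPINE_ROI
        oracle, _, _ = phase_cross_correlation(
            fixed.pixels[r0:r1, c0:c1].astype(float),
            moving.pixels[r0:r1, c0:c1].astype(float),
            upsample_factor=50,
        )
        # oracle reports the shift applied to moving to match fixed (negated);
        # the two estimators agree to within their combined subpixel bias
        assert abs(offset.shift_mm[1] - (-oracle[0])) < 0.25
        assert abs(offset.shift_mm[1] - 2.3) < 0.2

    def test_antisymmetry_within_0_05_mm(self, geoframe_factory):
        a = geoframe_factory(plane=PlaneLabel.SAGITTAL)
        b = geoframe_factory(plane=PlaneLabel.SAGITTAL,
                             displacement=(0.0, 1.7), move_whole=True)
        ab = register_translation(a, b, roi=SPINE_ROI)
        ba = register_translation(b, a, roi=SPINE_ROI)
        assert np.all(np.abs(ab.shift_mm + ba.shift_mm) < 0.05)

    def test_constant_images_raise_no_structure(self, geoframe_factory):
        frame = geoframe_factory(plane=PlaneLabel.SAGITTAL)
        flat = assign_geometry(np.full_like(frame.pixels, 7),
                               frame.plane, frame.spacing_mm, ORIGIN_CENTROID)
        with pytest.raises(NoStructureError):
            register_translation(flat, flat, roi=SPINE_ROI)

    def test_halving_pixel_spacing_does_not_worsen_recovery(self, geoframe_factory):
        shift = 1.3
        errors = {}
        for geom in (GEOMETRY_1MM, GEOMETRY_HALF_MM):
            scale = GEOMETRY_1MM.rows / geom.rows
            fixed = geoframe_factory(plane=PlaneLabel.SAGITTAL, geometry=geom)
            moving = geoframe_factory(plane=PlaneLabel.SAGITTAL, geometry=geom,
                                      displacement=(0.0, shift), move_whole=True)
            r0, r1, c0, c1 = [int(v / scale) for v in SPINE_ROI]
            offset = register_translation(fixed, moving, roi=(r0, r1, c0, c1),
                                          max_shift_px=int(12 / scale))
            errors[geom.rows] = abs(offset.shift_mm[1] - shift)
        # both errors sit at the ~0.01 mm level; allow that much as the
        # noise floor of the comparison
        assert errors[512] <= errors[256] + 0.02


class TestMeasureDistance:
    def test_rod_inner_diameter_on_axial_render(self, geoframe_factory, phantom_spec):
        frame = geoframe_factory(plane=PlaneLabel.AXIAL)
        p0, p1 = profile_points(frame, -70, 0, 70, 0)
        measured = measure_distance(frame, p0, p1)
        assert abs(measured - phantom_spec.rod_inner_diameter_mm) <= 1.0

    def test_body_inner_length_on_coronal_render(self, geoframe_factory, phantom_spec):
        frame = geoframe_factory(plane=PlaneLabel.CORONAL)
        p0, p1 = profile_points(frame, -55, -85, -55, 85)
        measured = measure_distance(frame, p0, p1)
        assert abs(measured - phantom_spec.body_inner_length_mm) <= 1.0

    def test_uniform_profile_raises_no_edge(self, geoframe_factory):
        frame = geoframe_factory(plane=PlaneLabel.AXIAL)
        p0, p1 = profile_points(frame, -10, 0, 10, 0)  # inside the rod plateau
        with pytest.raises(NoEdgeError):
            measure_distance(frame, p0, p1)

    def test_out_of_frame_profile_rejected(self, geoframe_factory):
        frame = geoframe_factory(plane=PlaneLabel.AXIAL)
        p0, p1 = profile_points(frame, -300, 0, 300, 0)
        with pytest.raises(ValueError):
            measure_distance(frame, p0, p1)

    def test_halving_pixel_spacing_does_not_worsen_measurement(
        self, geoframe_factory, phantom_spec
    ):
        errors = {}
        for geom in (GEOMETRY_1MM, GEOMETRY_HALF_MM):
            frame = geoframe_factory(plane=PlaneLabel.AXIAL, geometry=geom)
            p0, p1 = profile_points(frame, -70, 0, 70, 0)
            errors[geom.rows] = abs(
                measure_distance(frame, p0, p1) - phantom_spec.rod_inner_diameter_mm
            )
        assert errors[512] <= errors[256] + 0.01
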