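import numpy as np
import pytest

from unitycine.image_model import PlaneLabel, assign_geometry
from unitycine.synthetic_fixtures import PhantomSpec, render_phantom_frame
from unitycine.unity_format import AcquisitionGeometry, TargetCentroid

#: 1 mm isotropic pixels, the spacing used for the verification experiments.
GEOMETRY_1MM = AcquisitionGeometry(rows=256, columns=256,
                                   slice_dim_x_mm=256.0, slice_dim_y_mm=256.0)

#: 2 mm pixels on a small matrix: cheap frames for bulk/classification tests.
GEOMETRY_2MM = AcquisitionGeometry(rows=128, columns=128,
                                   slice_dim_x_mm=256.0, slice_dim_y_mm=256.0)

ORIGIN_CENTROID = TargetCentroid(0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture
def geoframe_factory(phantom_spec):
    """Build a GeoFrame directly from a rendered phantom frame (no disk),
    with the centering pre-offset disabled so the phantom is centered."""

    def build(plane=PlaneLabel.CORONAL, displacement=(0.0, 0.0),
              geometry=GEOMETRY_1MM, timestamp_ms=0, **render_kwargs):
        pixels = render_phantom_frame(
            phantom_spec, plane, displacement, geometry,
            pre_shift_px=0, **render_kwargs,
        )
        return assign_geometry(
            pixels, plane,
            (geometry.pixel_spacing_row_mm, geometry.pixel_spacing_col_mm),
            ORIGIN_CENTROID, timestamp_ms=timestamp_ms,
        )

    return build


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
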