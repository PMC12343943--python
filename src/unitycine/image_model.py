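"""Plane classification, centering shift and patient-space geometry.

Each converted cine frame carries a plane-specific intensity pattern in its
top-right corner.  The absolute intensities of that pattern vary from
monitoring session to monitoring session, but the *shape* is stable per
plane, so classification binarizes a fixed corner patch (Otsu threshold) and
correlates it against per-plane reference templates — invariant to any
positive session-wide intensity scaling.

Frames are then shifted by a fixed 22 pixels so the anatomy is centered, and
given 3D patient-space (DICOM LPS) geometry such that the continuous image
center coincides with the target-structure centroid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu

from .unity_format import TargetCentroid


class PlaneLabel(str, Enum):
    CORONAL = "coronal"
    SAGITTAL = "sagittal"
    AXIAL = "axial"
    UNKNOWN = "unknown"


#: The three cardinal acquisition planes, in fixture interleaving order.
CARDINAL_PLANES = (PlaneLabel.CORONAL, PlaneLabel.SAGITTAL, PlaneLabel.AXIAL)

#: Fixed number of pixels of the centering shift applied to every frame.
CENTERING_SHIFT_PX = 22

DEFAULT_PATCH_SIZE = 32
DEFAULT_CONFIDENCE_THRESHOLD = 0.8

#: Per-plane direction cosines in LPS, keyed by plane.  ``row_cosines`` is the
#: direction of increasing *column* index (along an image row) and
#: ``col_cosines`` of increasing *row* index — the DICOM
#: ImageOrientationPatient convention, first and second triplet respectively.
PLANE_ORIENTATIONS: dict[PlaneLabel, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    PlaneLabel.AXIAL: ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
    PlaneLabel.CORONAL: ((1.0, 0.0, 0.0), (0.0, 0.0, -1.0)),
    PlaneLabel.SAGITTAL: ((0.0, 1.0, 0.0), (0.0, 0.0, -1.0)),
}


class GeometryError(Exception):
    """Frame too small for the requested corner patch or shift."""


class PlaneAssignmentError(Exception):
    """Patient-space geometry cannot be assigned (plane unknown)."""


def glyph_pattern(plane: PlaneLabel, size: int = DEFAULT_PATCH_SIZE) -> np.ndarray:
    """Reference binary corner pattern for a plane.

    The three patterns are mutually uncorrelated by construction: horizontal
    bars (coronal), vertical bars (sagittal) and a checkerboard (axial), each
    with a bar/cell pitch of ``size // 8`` pixels.
    """
    band = max(size // 8, 1)
    r, c = np.indices((size, size))
    if plane is PlaneLabel.CORONAL:
        return (r // band) % 2 == 0
    if plane is PlaneLabel.SAGITTAL:
        return (c // band) % 2 == 0
    if plane is PlaneLabel.AXIAL:
        return ((r // band) + (c // band)) % 2 == 0
    raise ValueError(f"no glyph for plane {plane!r}")


@dataclass
class CornerSignature:
    """Top-right corner patch and its scale-invariant binarized form."""

    patch: np.ndarray
    normalized_pattern: np.ndarray | None  # None when the patch is flat


def extract_corner_signature(
    pixels: np.ndarray, patch_size: int = DEFAULT_PATCH_SIZE
) -> CornerSignature:
    rows, cols = pixels.shape
    if rows < patch_size or cols < patch_size:
        raise GeometryError(
            f"frame {rows}x{cols} smaller than the {patch_size}x{patch_size} corner patch"
        )
    patch = np.asarray(pixels[:patch_size, cols - patch_size :], dtype=float)
    if np.ptp(patch) == 0:
        return CornerSignature(patch=patch, normalized_pattern=None)
    return CornerSignature(patch=patch, normalized_pattern=patch > threshold_otsu(patch))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


class TemplateStore:
    """Per-plane normalized reference signatures.

    The default templates are the package's corner glyphs; for real sessions
    a store can be re-learned from a labeled sample (:meth:`learn`) and
    persisted as a JSON index (:meth:`save` / :meth:`load`).
    """

    def __init__(self, templates: dict[PlaneLabel, np.ndarray], patch_size: int):
        self.templates = templates
        self.patch_size = patch_size

    @classmethod
    def default(cls, patch_size: int = DEFAULT_PATCH_SIZE) -> "TemplateStore":
        return cls(
            {p: glyph_pattern(p, patch_size) for p in CARDINAL_PLANES}, patch_size
        )

    @classmethod
    def learn(
        cls,
        samples: list[tuple[np.ndarray, PlaneLabel]],
        patch_size: int = DEFAULT_PATCH_SIZE,
    ) -> "TemplateStore":
        """Learn templates as the majority-vote binarized patch per plane."""
        votes: dict[PlaneLabel, list[np.ndarray]] = {}
        for pixels, label in samples:
            sig = extract_corner_signature(pixels, patch_size)
            if sig.normalized_pattern is not None:
                votes.setdefault(label, []).append(sig.normalized_pattern)
        templates = {
            label: np.mean(patterns, axis=0) > 0.5 for label, patterns in votes.items()
        }
        return cls(templates, patch_size)

    def save(self, path) -> None:
        doc = {
            "patch_size": self.patch_size,
            "templates": {
                label.value: np.asarray(tmpl, dtype=int).tolist()
                for label, tmpl in self.templates.items()
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "TemplateStore":
        doc = json.loads(Path(path).read_text())
        templates = {
            PlaneLabel(label): np.asarray(tmpl, dtype=bool)
            for label, tmpl in doc["templates"].items()
        }
        return cls(templates, int(doc["patch_size"]))


def classify_plane(
    pixels: np.ndarray,
    templates: TemplateStore | None = None,
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> tuple[PlaneLabel, float]:
    """Classify a frame's imaging plane from its corner signature.

    Returns the plane whose template best correlates with the binarized
    corner patch, and a confidence score in [0, 1] (negative correlations
    clip to 0).  Below-threshold confidence yields ``UNKNOWN`` rather than a
    guessed label, so silent misclassification cannot corrupt downstream
    geometry.
    """
    store = templates or TemplateStore.default()
    signature = extract_corner_signature(pixels, store.patch_size)
    if signature.normalized_pattern is None:
        return PlaneLabel.UNKNOWN, 0.0
    best_label, best_score = PlaneLabel.UNKNOWN, -np.inf
    for label, template in store.templates.items():
        score = _pearson(signature.normalized_pattern, template)
        if score > best_score:
            best_label, best_score = label, score
    confidence = float(np.clip(best_score, 0.0, 1.0))
    if confidence < threshold:
        return PlaneLabel.UNKNOWN, confidence
    return best_label, confidence


def apply_centering_shift(
    pixels: np.ndarray,
    shift_px: int = CENTERING_SHIFT_PX,
    axis: int = 1,
    direction: int = -1,
) -> np.ndarray:
    """Translate a frame by a fixed pixel count along one axis.

    Default: 22 pixels toward negative columns (content moves left); vacated
    pixels are filled with 0 and the matrix shape is unchanged.  The inverse
    shift is obtained by negating ``direction``.
    """
    if axis not in (0, 1):
        raise ValueError("axis must be 0 (rows) or 1 (columns)")
    n = pixels.shape[axis]
    if n < shift_px + 1:
        raise GeometryError(
            f"axis {axis} has {n} pixels; need at least {shift_px + 1} for the shift"
        )
    out = np.zeros_like(pixels)
    src = np.moveaxis(pixels, axis, 0)
    dst = np.moveaxis(out, axis, 0)
    if direction < 0:
        dst[: n - shift_px] = src[shift_px:]
    else:
        dst[shift_px:] = src[: n - shift_px]
    return out


@dataclass
class GeoFrame:
    """A 2D cine frame placed in 3D patient space.

    ``origin_mm`` is the world coordinate of the *center* of pixel (0, 0);
    ``row_cosines``/``col_cosines`` follow the DICOM ImageOrientationPatient
    convention (directions of increasing column and row index respectively).
    ``spacing_mm`` is (row spacing, column spacing).
    """

    pixels: np.ndarray
    plane: PlaneLabel
    spacing_mm: tuple[float, float]
    origin_mm: np.ndarray
    row_cosines: np.ndarray
    col_cosines: np.ndarray
    timestamp_ms: int = 0
    frame_uid: str | None = None

    def __post_init__(self) -> None:
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.row_cosines = np.asarray(self.row_cosines, dtype=float)
        self.col_cosines = np.asarray(self.col_cosines, dtype=float)
        for v in (self.row_cosines, self.col_cosines):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise PlaneAssignmentError("orientation vectors must be unit length")
        if abs(self.row_cosines @ self.col_cosines) > 1e-9:
            raise PlaneAssignmentError("orientation vectors must be orthogonal")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.row_cosines, self.col_cosines)

    def world_from_index(self, row: float, col: float) -> np.ndarray:
        """World coordinate (mm) of a continuous pixel-center index."""
        dr, dc = self.spacing_mm
        return self.origin_mm + col * dc * self.row_cosines + row * dr * self.col_cosines

    def center_world(self) -> np.ndarray:
        rows, cols = self.pixels.shape
        return self.world_from_index((rows - 1) / 2.0, (cols - 1) / 2.0)


def assign_geometry(
    pixels: np.ndarray,
    plane: PlaneLabel,
    spacing_mm: tuple[float, float],
    centroid: TargetCentroid,
    timestamp_ms: int = 0,
    frame_uid: str | None = None,
) -> GeoFrame:
    """Place a classified frame in patient space.

    The origin is computed so the continuous image center — pixel-center
    index ((rows-1)/2, (cols-1)/2), exact for odd and even matrix sizes —
    maps onto the target centroid, matching how the scanner acquires the
    cine planes through the center of the target structure.
    """
    if plane not in PLANE_ORIENTATIONS:
        raise PlaneAssignmentError(
            f"cannot assign geometry for plane {plane.value!r}"
        )
    row_cos, col_cos = (np.array(v, dtype=float) for v in PLANE_ORIENTATIONS[plane])
    rows, cols = pixels.shape
    dr, dc = spacing_mm
    if dr <= 0 or dc <= 0:
        raise PlaneAssignmentError(f"spacing must be positive, got {spacing_mm}")
    origin = (
        centroid.as_array()
        - ((cols - 1) / 2.0) * dc * row_cos
        - ((rows - 1) / 2.0) * dr * col_cos
    )
    return GeoFrame(
        pixels=pixels,
        plane=plane,
        spacing_mm=(float(dr), float(dc)),
        origin_mm=origin,
        row_cosines=row_cos,
        col_cosines=col_cos,
        timestamp_ms=int(timestamp_ms),
        frame_uid=frame_uid,
    )


def plane_from_cosines(row_cosines, col_cosines) -> PlaneLabel:
    """Recover the plane label from direction cosines (UNKNOWN if off-axis)."""
    for plane, (rc, cc) in PLANE_ORIENTATIONS.items():
        if np.allclose(row_cosines, rc, atol=1e-6) and np.allclose(
            col_cosines, cc, atol=1e-6
        ):
            return plane
    return PlaneLabel.UNKNOWN
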