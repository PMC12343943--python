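# Methods

## Problem

During MR-guided radiotherapy on a 1.5 T MR-linac, 2D cine MR frames
(balanced FFE, ~5 frames/s, 0.2 s per frame, interleaved coronal / sagittal
/ axial planes) are recorded for intrafraction motion monitoring — but they
are stored in a proprietary headered binary layout that no standard imaging
software can open. This package converts those frames into MetaImage (MHA)
and DICOM with full 3D patient-space geometry, and verifies the conversion
against a synthetic motion-management QA phantom with known geometry and
programmed motion.

## Conversion pipeline

1. **Decode** — skip the 4,084-byte opaque header, read `rows × columns`
   little-endian unsigned 16-bit pixels. Matrix size and pixel spacing come
   from the session's ExamCard JSON (`spacing = slice dimension / pixel
   count` per axis; X spans columns). Frames are ordered by millisecond
   timestamps (manifest or filesystem source; ties break by filename).
2. **Classify the plane** — the top-right 32×32 corner patch carries a
   plane-specific pattern whose absolute intensity varies per session but
   whose shape is stable. The patch is binarized at the Otsu threshold and
   compared to per-plane templates by Pearson correlation; the best match
   wins if its score reaches the confidence threshold (default 0.8),
   otherwise the frame is quarantined as `unknown` rather than guessed —
   a silent wrong label would corrupt all downstream geometry.
   Classification runs on the raw decoded frame, before the centering
   shift, because that is where the corner pattern sits.
3. **Center** — every frame is translated by exactly 22 pixels toward
   negative columns (axis and direction configurable; vacated pixels are
   zero-filled). The magnitude is a fixed property of the acquisition
   chain; its true axis/direction on vendor data is undocumented, so the
   default is a package convention mirrored by the fixture generator.
4. **Assign geometry** — the cine planes are acquired through the center of
   the target structure, so the continuous image center (pixel-center index
   `((rows−1)/2, (cols−1)/2)`, exact for odd and even matrices) is mapped
   onto the target centroid read from the BinaryMasks sidecar (LPS, mm).
   Orientation per plane (DICOM row/column cosines): axial (1,0,0)/(0,1,0);
   coronal (1,0,0)/(0,0,−1); sagittal (0,1,0)/(0,0,−1).
5. **Write** — MHA as NDims=3 single-slice MetaImage (offset, transform
   matrix, element spacing; a 2D MetaImage cannot carry the full 3D
   placement); DICOM as derived MR Image Storage with deterministic UIDs
   (SHA-256 of session uid, role and index under a `2.25` root) so re-runs
   are byte-identical and fixtures reproducible. AcquisitionTime carries
   fractional seconds. Per-frame failures quarantine; the conversion
   report conserves counts (converted + quarantined = input).

## QA analyses

* **Dimension measurement** — intensity profile sampled along a world-space
  segment (bilinear interpolation, 0.05 mm steps); the distance between the
  first and last crossings of 50% of the profile's min–max range
  (full-width-half-maximum convention). On the synthetic phantom at 1 mm
  pixels this carries a small systematic bias (≈0.17 mm short for the rod)
  from the one-pixel linear edge ramp of the renderer — well inside the
  one-pixel acceptance band.
* **Target tracking** — within a fixed ROI, Otsu threshold, keep the
  brightest connected component, and take the intensity-above-background
  weighted center of mass (the anti-aliased boundary then contributes its
  true partial coverage, giving subpixel centroids). Replaces the manual
  contouring of the original workflow; justified by the target's high
  boundary contrast. Failures record NaN gaps, never fabricated positions.
* **Amplitude estimation** — displacements relative to a stationary
  reference position are projected on their principal axis; cycles are
  delimited by rising zero-crossings; the per-cycle amplitude is the peak
  displacement magnitude from the reference (default) or peak-to-peak
  (option — the programmed phantom amplitudes are peak displacements from
  rest, hence the default). At least two complete cycles are required.
* **Translation registration** — normalized cross-correlation (Pearson over
  the overlap) evaluated exhaustively for integer shifts within ±12 px,
  then quadratic interpolation of the correlation peak per axis for the
  subpixel fraction. Both images are pre-smoothed with a 1 px Gaussian so
  the peak is locally parabolic. An ROI (e.g. around the vertebral bodies)
  restricts the similarity, which also excludes the identical corner
  glyphs that would otherwise bias the optimum toward zero.

## Synthetic phantom and study conditions

The generator renders a ZEUS-like QA phantom: body shell of inner length
150.1 mm and width 160 mm, a cylindrical rod sleeve of inner diameter
58.5 mm, a bright 25 mm target insert, and (sagittal) a four-vertebra spine
block (25×30 mm slabs, 8 mm gaps, 45 mm lateral offset). Rendering is
anti-aliased: exact area coverage for rectangles, a one-pixel linear ramp
for discs, then uint16 quantization. Intensity levels (background 1,000;
body 8,000; rod 16,000; target 26,000; spine 24,000; glyph 30,000) are
arbitrary but ordered as in the real bFFE contrast (fluid bright); a
session-wide intensity scale emulates the inter-session variation of the
corner patterns. Additive Gaussian noise (fraction of target–background
contrast) is available and off by default: exactness tests run noise-free,
robustness tests seed it explicitly.

Motion programs mirror the physical experiments: periodic target motion at
amplitudes 5/10/15/20 mm with a 4 s period sampled at 0.2 s (sine default;
the programmed waveform is unspecified, triangle available), and constant
whole-phantom shifts of 0.5/1/2/3/5 mm for the couch-translation scenario.
Two rendering simplifications are deliberate: the rod sleeve stays static
while the target insert moves (keeps the tracking ROI two-class, and the
tracked ground truth is the target displacement either way), and the axial
scene omits the target insert so a central profile measures the rod's own
edges. The generator pre-offsets the phantom by +22 columns — the exact
inverse of the centering shift — so converted frames are centered.

What the fixtures do **not** emulate: MR physics (no bFFE contrast model,
no noise correlation, no bias field), dark-band artifacts at plane
intersections, breathing irregularity, and any real vendor header
semantics. Passing tests therefore demonstrate the correctness of the
decoding, geometry, timing and analysis chain under the documented dialect
— not robustness to vendor-side format drift, which is flagged as a
compatibility risk in `docs/format.md`.

## Numerical choices and problem sizes

* Verification experiments run at 256×256 / 1 mm pixels; bulk
  classification tests at 128×128 / 2 mm (1,050 frames across five
  intensity scales). The motion experiment uses 101 frames per amplitude
  (5 sine cycles) in the acceptance script and 61 in the test suite;
  reference positions come from an 11-frame (7 in tests) stationary
  acquisition. These sizes keep the full verification under a few seconds
  while leaving ≥4 (≥2) complete cycles per estimate.
* Geometry round-trips are asserted to 1e-6 mm; DICOM decimal strings use
  10 significant digits.
* Degenerate inputs are first-class: flat corner patch → unknown plane;
  uniform ROI → no-target; constant registration input → no-structure;
  profile without two half-maximum crossings → no-edge; fewer than two
  motion cycles → insufficient-cycles.

## Known limitations

* The BinaryMasks schema, payload byte/element order, and the 22-pixel
  shift direction are package conventions where the vendor format is
  undocumented; real-data use may require template re-learning
  (`TemplateStore.learn`) and configuration of the shift axis.
* Registration is translation-only in-plane; no deformable or 3D–3D
  registration, no dark-band compensation, no gating logic.
* The reference dimension measurement pairs shipped in
  `motion_qa.REFERENCE_DIMENSION_MEASUREMENTS` summarize a manual QA
  session on real converted images; they contextualize the synthetic
  measurements but are not recomputed by this package.
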