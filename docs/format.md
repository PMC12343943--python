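# Session format specification

This document is the single normative description of the on-disk dialect
shared by the reader (`unitycine.unity_format`) and the fixture generator
(`unitycine.synthetic_fixtures`). No public sample of the real vendor data
exists — the vendor's own software cannot re-read it after treatment — so
the generator is the format's reference implementation: every change here
must land in both modules.

## Directory layout

```
<session root>/
  <fraction id>/                       # one directory per treatment fraction
    cine_<timestamp_ms>_<index>.bin    # binary frame files
    ExamCards/
      MotionMonitoring2DImages.ExamCardInfo.json
    BinaryMasks/
      <structure>.json                 # target centroid sidecar
    manifest.json                      # per-frame millisecond timestamps
    ground_truth.json                  # fixture sessions only
```

## Binary frame files

| field   | size                  | content                                          |
|---------|-----------------------|--------------------------------------------------|
| header  | exactly 4,084 bytes   | opaque; only the length matters                  |
| payload | 2 × rows × columns B  | little-endian unsigned 16-bit, row-major         |

A file shorter than `4084 + 2·rows·columns` bytes is rejected as truncated;
trailing bytes beyond the payload are ignored. The fixture generator fills
the header with the fixed sentinel byte pattern `(73·i + 41) mod 256` so any
off-by-one header/payload misalignment moves recognizable bytes into the
payload and fails loudly in tests.

Open compatibility risks for real vendor data (assumed, not verifiable):
payload byte order (little-endian assumed) and element order (row-major
assumed).

## ExamCard JSON

`MotionMonitoring2DImages.ExamCardInfo.json` must carry four keys:
`"Rows"`, `"Columns"`, `"SliceDimensionXInmm"`, `"SliceDimensionYInmm"`.
Pixel spacing is derived as

```
pixel_spacing_col = SliceDimensionXInmm / Columns     # horizontal
pixel_spacing_row = SliceDimensionYInmm / Rows        # vertical
```

i.e. the X dimension spans the columns. This axis mapping is a convention of
this package (the vendor naming does not state it) and is relied on by both
reader and generator.

## BinaryMasks JSON

The vendor key structure is not public; the schema below is
fixture-normative and is a compatibility risk for real sessions:

```json
{"structure": "<name>", "centroid_lps_mm": [x, y, z]}
```

The centroid is in DICOM LPS patient coordinates, mm, one per monitoring
session. The converted frames are placed so their continuous image center
coincides with this point.

## Timestamp manifest

The real acquisition encodes frame times only in Windows file-creation
metadata, which does not survive copying across filesystems. The portable
default is a `manifest.json`:

```json
{"session_uid": "<uid>", "frames": [{"file": "<name>", "timestamp_ms": 1735689600000}, ...]}
```

Timestamps are integer milliseconds since the Unix epoch (millisecond
resolution is required: acquisition runs at ~5 frames/s). A best-effort
`filesystem` timestamp source (file mtime) is available for trees where a
manifest cannot be produced. Ties are broken by lexicographic filename,
with a logged warning.

## Corner plane signatures

Each frame carries a plane-specific pattern in its top-right 32×32-pixel
patch. The fixture glyphs (pitch 4 px) are: horizontal bars = coronal,
vertical bars = sagittal, checkerboard = axial, stamped over a cleared
patch at the session's glyph intensity. Classification binarizes the patch
(Otsu) and correlates against per-plane templates, so any positive
session-wide intensity scaling leaves labels unchanged.

## Ground-truth JSON (fixture sessions)

```json
{
  "program": { ... MotionProgram fields ... },
  "phantom": { ... PhantomSpec fields ... },
  "intensity_scale": 1.0,
  "centroid_lps_mm": [0, 0, 0],
  "frames": [{"file": "...", "plane": "coronal",
              "displacement_mm": [du, dv], "timestamp_ms": 0}, ...]
}
```

`displacement_mm` is the true in-plane offset (u along columns, v along
rows) of the moving content for that frame, so no test needs manual
annotation.
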