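# Methods

This note documents the models, parameter choices, and numerical decisions
behind `dentnum`, and what the synthetic benchmarks do and do not show.

## Image normalization

Radiographs arrive as PNG/JPEG or single-frame DICOM in widely varying
sizes, often with black collar regions around the exposed film area.
Normalization standardizes them for a fixed-input detector without
distorting anatomy:

1. **Grayscale.** RGB inputs collapse to luma
   `0.299 R + 0.587 G + 0.114 B`, rounded half-away-from-zero and clamped
   to [0, 255]. DICOM pixel data is first windowed to 8 bit by min–max
   scaling of the stored range (MONOCHROME1 is inverted); rescale
   slope/intercept is deliberately not applied, since min–max windowing is
   invariant to affine rescaling of the stored values.
2. **Border crop.** A full row/column is border when more than
   `fraction_threshold` (default 0.99) of its pixels are at or below
   `intensity_threshold` (default 10 of 255). Rows/columns are stripped
   from each edge inward until the rule fails. The 0.99 fraction tolerates
   stray bright artifacts (labels, collimator edges) inside an otherwise
   black collar. An entirely dark frame falls back to the full frame with
   a warning rather than producing an empty crop.
3. **Resize.** One uniform scale factor `640 / max(H, W)` for both axes —
   never anisotropic. Area averaging (Pillow `BOX`) for downscaling,
   bilinear for upscaling; standard anti-aliasing practice.
4. **Letterbox pad.** The short side is padded with black (fill 0,
   matching the film background) to 640 × 640, content centered, the odd
   pixel going to the bottom/right.

The crop/scale/pad chain is recorded in a `GeometryTransform` whose
forward/inverse maps are exact affine maps; the only irreversible step is
the integer rounding of the resized short side, which keeps the content
aspect ratio within 1/320 of the post-crop input for radiograph-like
aspect ratios (roughly 3:4 intraoral through 2.6:1 panoramic — thinner
strips would need a larger short side for that bound to hold).
Round-trip error is below one pixel by construction.

## Enhancement

Sharpening subtracts the discrete Laplacian: `out = clamp(f − s·∇²f)` with
the canonical 4-neighbor kernel `[[0,1,0],[1,−4,1],[0,1,0]]` (equivalently
convolution with `[[0,−1,0],[−1,5,−1],[0,−1,0]]` at strength `s = 1`).
Default strength 1.0. A median filter (default 3 × 3 window) runs **after**
sharpening, removing the impulse noise sharpening amplifies while
preserving contours; the two orders are not equivalent and the order is
fixed. Both operators use edge replication at the borders, avoiding the
dark halos zero padding would create at the frame edge. Both agree exactly
with naive double-loop reference implementations on random images.
Enhancement applies to all modalities by default and can be skipped per
modality; its motivation is strongest for panoramic images, where
interproximal gaps are small.

## FDI numbering (panoramic)

**Inputs.** A set of boxes (corners, class permanent/deciduous,
confidence) in one image frame. Boxes may be detector output or
annotations; the algorithm uses geometry and class only.

**Occlusal center.** The occlusal line `y_mid` is the midpoint of the
largest gap in sorted box y-centers, which on a panoramic image falls
between the jaws; a largest gap smaller than the median box height means
only one jaw is present and is a hard error (naming the jaw found). The
midline `x_mid` is estimated by bilateral mirror symmetry: over candidate
midlines, minimize the sum of capped distances between each permanent box
center and the nearest center of the mirrored set (coarse 1 px grid over
the interquartile range, refined over exact pair midpoints, then polished
by the median of matched mirror-pair midpoints). A plain median of
x-centers is also available but is biased by one-sided missing teeth —
deleting a single tooth shifts the median onto the opposite central
incisor — which the symmetry estimator tolerates. Deciduous boxes are
excluded from midline estimation because retained deciduous teeth are
frequently one-sided.

**Quadrants.** A box belongs to the quadrant of its center: upper-left 1,
upper-right 2, lower-right 3, lower-left 4 in image coordinates (clockwise
from the patient's upper right); deciduous classes add 4. Ties on the
midline go left, ties on the occlusal line go up — arbitrary but fixed for
determinism. Since a quadrant anatomically holds at most 8 permanent
teeth, a quadrant that receives more while its same-jaw neighbour has room
returns its midline-nearest boxes across — this repairs midline
mis-splits of a central incisor under heavy jitter.

**Positions and gaps.** Within a quadrant, boxes are ordered by ascending
`|cx − x_mid|` (ties by cx). Walking outward, each span — midline to the
first box's inner edge, then inner edge to the previous box's outer
edge — is compared with the expected tooth width `w*`:

* `median_of_quadrant` (default): `w*` is the median detected box width in
  the jaw; a span `g` skips `round(g / w*)` positions when
  `g > (1 − gap_tolerance) · w*` (default tolerance 0.5, i.e. half a
  tooth).
* `per_position_prior`: per-position expected widths (incisors narrower
  than molars) are supplied and the skip count is the one whose cumulative
  prior widths best explain the span. This resolves multi-tooth gaps whose
  total width is not close to an integer multiple of the median width
  (e.g. two adjacent molars), which the median model can mis-count by one.

Skipped positions are reported missing. Positions that would exceed 8 mean
some inferred gap is spurious; the gaps with the least empty space per
skipped slot are discarded until the quadrant fits (a quadrant holding
more than 8 boxes is a genuine overflow error). Absence *distal* to the
last detected tooth (typically third molars) is not observable from box
coordinates alone: those positions are 0 in the presence table but only
enter the missing list when `include_third_molars_in_gaps` is set.

**Deciduous teeth.** The quadrant comes from the deciduous box's own side
of the midline and jaw (not from the nearest permanent tooth, which near
the midline may sit on the other side). The position is that of the
nearest same-jaw permanent tooth along x, clamped to 5, then de-duplicated
so that outward boxes take larger positions within 1..5. The rule is
well-posed when the deciduous tooth's permanent successor is detected (the
usual mixed-dentition presentation in the supported scenario, and the one
realized by the worked fixture); with the successor absent the nearest
anchor is ambiguous by about half a tooth width and the assigned digit can
be off by one. With no permanent teeth in a jaw, positions fall back to
geometric order from the midline, with a warning.

**Output.** Box↔code assignments (never a duplicate code), the inferred
missing codes, the arch center, a 52-slot presence table (quadrants 1–8 in
FDI order), and any boxes left unassigned by capacity repair.

**PA/BW.** Periapical layouts are numbered 1..n left to right; bitewing
layouts are split into upper/lower rows by the same largest-y-gap
estimator (only when that gap reaches the median box height — otherwise a
single row is assumed) and numbered upper row first, each row left to
right. Sequential indices are not translated into FDI codes: a PA/BW crop
does not carry enough context to anchor the midline.

## Synthetic data

`ArchSpec` describes a panoramic-like frame (default 1200 × 700 px) with
two arches at 250/450 of a 700 px frame height, a parabolic occlusal
curvature of 60/700 of the height across each arch, and per-position tooth
widths (28, 26, 30, 32, 32, 46, 44, 42 px at 1200 px width — ordinal
realism, incisors narrower than molars, is what the gap model needs; the
absolute values are arbitrary and config-exposed). Permanent teeth abut
outward from the midline, mirrored about the arch center; absent codes
leave true gaps; deciduous boxes sit on their successor's slot at 85%
width, shifted toward the occlusal line. Gaussian center jitter is
configurable as absolute pixels (`jitter_sd`) and/or a fraction of each
tooth's own width (`jitter_frac`); widths jitter only behind a flag, so
the ordering/gap logic is what the jitter stresses. All generation is
deterministic per seed. Phantom radiographs render the boxes as bright
ellipses on mid-gray with an exact all-zero border and optional seeded
salt-and-pepper noise, giving ground truth for crop detection and
enhancement.

What the generator does **not** emulate: real radiographic texture,
rotated or overlapping crowded teeth, detector confidence miscalibration,
supernumerary teeth, and PA/BW field-of-view cropping. Passing the
synthetic benchmarks therefore demonstrates the geometric logic under the
stated perturbation model, not clinical-grade performance.

## Benchmarks and problem sizes

* Mixed-dentition fixture (permanent positions 1–7 in all quadrants,
  deciduous 53, 55, 63, 65, 74, 75, 85): numbering must reproduce the
  reference presence table on all 52 slots with an empty missing report.
* Exact recovery: 200 zero-jitter layouts with up to three teeth removed
  per quadrant (interior and terminal positions) and random deciduous
  overlays over present successors; every code and the exact interior
  missing set must be recovered (using per-position width priors — the
  generator's width table — as the anatomical width model).
* Robustness: 200 replicates per jitter level of the full-arch benchmark;
  recovery is exactly 1.0 at zero jitter and stays above 95% at center
  jitter of 25% of the local tooth width (measured ≈ 98%). This is a
  regression threshold of this package, not a clinical claim.
* Filter oracles (100 random ≤ 32 × 32 images), normalization invariants
  (100 random bordered geometries), and hand-computed metric cases.

These sizes keep the full suite under ten seconds on one CPU while the
recovery estimates remain stable to well under a percentage point across
seeds.

## Known limitations

* The midline is unidentifiable from x-coordinates alone when symmetry is
  heavily broken (e.g. most of one side missing); the estimator degrades
  gracefully but quadrant splits near the midline can then be wrong.
* Missing-tooth inference sees only gaps between detected boxes; it
  cannot distinguish a distal gap from a short arch, and false detector
  boxes translate directly into numbering shifts.
* The deciduous position rule inherits the nearest-anchor ambiguity
  described above.
* Dataset splitting operates on identifiers with optional group
  stratification; patient-level grouping is the caller's responsibility.
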