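# Methods

## The measurement model

An osseointegrated implant images as two near-vertical, slightly curved
bright edges (the screw flanks) capped by an even brighter prosthesis
(crown). Marginal bone loss removes the crestal bone along a coronal
section of each flank, replacing the intermediate-intensity bone with
darker soft tissue. The measurement therefore reduces to geometry on
each flank: find the curve of the flank, find where the dark section
begins (bone-defect onset, the apical critical point) and where the
crown begins (the coronal critical point), and take the arc length
between them relative to the flank length.

The pipeline assumes only that detector boxes roughly localize crowns
and screws (no precise segmentation), that the metallic parts are the
brightest structures in their neighbourhood, and that edges are oriented
toward the vertical (within ~60° of it) after the standard acquisition
technique.

## Stages and the parameters that matter

**Gating.** Jaw side comes from the mean box-center *y* per class
(crowns above screws ⇒ lower jaw). A screw is accepted only when
extending its box along *y* to a crown's far edge overlaps more than
`overlap_min = 0.3` of the crown box; ties between candidate crowns go
to the largest overlap, then the nearest center. Contrast quality is the
population σ of intensities inside the paired boxes divided by
`sigma_max = 98` (the value observed at full contrast on 8-bit
radiographs), thresholded at `contrast_threshold = 0.4` inclusive.

**Edge extraction.** A gamma adjustment (`gamma = 1.5`) is always
applied before Canny: it darkens mid-gray tissue relative to the bright
metal. Low-contrast images additionally get the linear stretch of
[m−σ, m+σ] onto [0, 255] first. Canny hysteresis thresholds are
data-driven: high = the `canny_high_pct = 97` percentile of the
Gaussian-smoothed (σ = 1.6) gradient magnitude, low = `0.5·high`.
The percentile is deliberately high because most of a radiograph is
textured bone whose gradients must stay below both thresholds;
measurements on the phantom place texture gradients a factor ~4 below
the structural edges, and 97/0.5 puts both thresholds in that gap. Edges
are then clipped to the screw boxes expanded by `roi_expand = 0.10`
(half per side; floor/ceil rounding so the expansion always contains the
original box) and dilated 3×3 to bridge pixel-level breaks.

**Edge description.** The Hough accumulator uses 1 px × 1° bins,
θ ∈ [0°, 180°), with ρ = x·cosθ + y·sinθ rounded to the nearest bin.
Peaks are bins ≥ all 8 neighbours with at least `hough_min_votes = 15`
votes, at most `hough_n_peaks = 16`, ordered by votes (ties: ρ, then θ)
— the vote floor keeps images with few implants from admitting noise
lines. Lines within 30° of the horizontal are discarded
(`slope_min_deg`). Edge pixels within `line_band = 2` px of a retained
line are kept; along-line runs are split at gaps > `max_gap = 3` px and
runs shorter than `min_seg_len = 10` px dropped. The kept pixels are
dilated with a 1×5 horizontal element **before** connected-component
labeling, so collinear chains separated by small lateral offsets merge
into one group — the point of the dilation is exactly to close such
gaps. Each labeled region is intersected with the ROI edge map to
recover the full pixel alignment; groups need `min_group_px = 30` pixels
and a vertical extent of at least `min_seg_len` (they describe
near-vertical edges). Each group gets a least-squares straight line
(defining the scan direction) and the curve x = a + b·y + c·y². x is
always modeled as a function of y: for near-vertical edges that is the
well-posed orientation.

**Degree selection.** For evaluation, ground-truth point sets are fitted
with degrees 1–3 and the minimum-MSE fit wins. Because nested least
squares always lowers the raw MSE, "minimum" carries a tie band: a
higher degree must improve the MSE by at least 5% relatively
(`DEGREE_REL_TOL`), otherwise the lower degree stands. The measurement
pipeline itself always uses degree 2; the evaluation census on phantoms
confirms degree 2 dominates whenever the edges carry real curvature.

**Critical points.** The curve is traversed in unit y-steps from the
apical end (y_max in the lower jaw, y_min in the upper). At each step,
`scan_extent = 10` pixels (≈ 2.5% of the 410-px image width) are
averaged per flank along the unit normal of the straight-line fit,
starting `scan_start_offset = 3` px away from the curve so the bright
edge itself is skipped; off-grid samples are bilinear, border-clamped.
The accumulated profile takes the darker flank (`Cum = L if L−R < 0
else R`, which equals min(L, R) in every sign case).

*First point:* the first traversal index opening `scan_persist = 3`
consecutive samples at least `scan_min_drop = 20` intensity levels below
the profile mean, provided the remaining profile from that index onward
stays depressed on average (mean at least `scan_min_drop/2` below the
overall mean). The two conditions operationalize "abrupt, sustained": a
resorption-free profile is flat but noisy and crosses its own mean
constantly, so a bare below-mean rule would detect bone loss on healthy
edges, and a deep but local texture dip passes the drop test while
leaving the rest of the profile at its normal level — the tail-mean
check rejects it, and the search continues at the next candidate.
20 levels sits between profile noise (σ ≈ 5 per averaged sample) and
the bone/soft-tissue gap (≈ 40–60 levels on 8-bit radiographs);
setting `scan_min_drop = 0` recovers the bare below-mean rule.

*Reference level:* r_av averages the five samples just past the first
point on the **opposite** flank — the implant/crown side, identified as
the flank the min rule selected less often up to the first point. These
are the "R values" of the traversal: the screw-interior brightness next
to the defect.

*Second point:* continuing past the first point on that same implant
flank, the crown is entered at the first `scan_run_len = 5` consecutive
samples all above `run_factor × r_av`, and the second critical point
takes the y of the first sample of the run. `run_factor = 1.15` encodes
"reaches high intensity values": with a strict > r_av rule the threshold
equals the local screw-side mean, so noise alone produces 5-sample
runs above it (~3% per window); a 15% margin separates crown from screw
brightness (crown/screw intensity ratios on metal prostheses are
comfortably above it) while remaining far below the crown step.
Optionally (`verify_crown`) the second point must fall inside a crown
box, else the pair downgrades to `first_only`.

Critical-point scanning always reads the **original** intensity image,
even when the linear enhancement fed Canny: the stretch saturates screw
and crown to 255 on low-contrast images and would erase exactly the
contrast the crown-entry rule needs.

**Resorption.** Arc length is the unit-step sum Σ√(1 + (dx/dy)²)·Δy
with the derivative at step midpoints (exactly additive at integer
breakpoints). The percentage denominator is the arc over the fitted
span [y_min, y_max] by default; when the physical implant length is
known it can be supplied in mm (`--implant-length-mm`) and is converted
at `calibration_mm_per_px = 0.063` — useful when the apical tip is
occluded. Severity bands are closed at the explicit ends: normal ≤ 10,
early (10, 25], moderate (25, 50), severe ≥ 50.

**Evaluation.** ms_e divides by Y_M − Y_m exactly as defined although
the sum has one more term; rms_e = √ms_e is reported alongside because
summary deviations are quoted in pixels. The per-edge *t* test is the
standard one-sample test of zero mean deviation with df = L_e − 1; the
summary reports mean p across edges and the share of edges whose
deviation is *not* rejected at α = 0.05. Percentage errors E = A − G
(pairs with undetected points excluded) are split into 10 contiguous
batches; m_b is the batch-averaged mean |E| and σ_b the batch-averaged
std of E — with near-zero-mean signed errors the mean of E itself would
say nothing about the error scale.

## What the phantom generator emulates

Each phantom renders, per implant: two smooth flank polynomials with a
shear given by the rotation angle (±10° range) and a gentle taper
(|c| = 3·10⁻⁴ px⁻¹, narrowing apically); a sinusoidal thread
perturbation (amplitude 2 px, period 8 px) on the rendered edges, with
matching intensity bands that fade exponentially (7 px scale) from the
flanks toward the axis — projected threads band the flank region while
the central abutment channel stays uniform; a crown connected through a
12-px neck continuing the flank curves, flaring 14 px per side above; a
textured bone background (low-pass-filtered Gaussian noise, σ = 8);
a darker defect band (26 px wide) along each flank whose vertical extent
encodes the resorption fraction; and i.i.d. Gaussian sensor noise
(σ = 5). Default intensities 245/200/120/60 (crown/screw/bone/defect)
follow the ordering metal > bone > soft tissue. Truth stores the smooth
polynomials, both critical points and the arc-ratio resorption
percentage; detector boxes are the rendered bounding boxes with uniform
corner jitter (default 2 px) and random scores.

The `low_contrast` difficulty compresses the levels to 225/185/150/118
so the box σ falls below the 0.4 threshold and the linear-enhancement
path engages. Upper-jaw phantoms are rendered lower-jaw and mirrored,
truth included.

What the phantom does **not** model: 3D-projection effects (the gradual
intensity transitions that are a known error source on real
radiographs), overlapping natural teeth and restorations near the
implant, detector misses/false boxes beyond jitter, and non-sinusoidal
thread profiles. Passing the recovery suite therefore demonstrates the
pipeline's correctness under the stated image model — clean two-level
defect transitions and isolated implants — not clinical performance.

## Problem sizes and numerical choices

The recovery experiments use 100 phantoms (400 edges) for the accuracy
suite and 20 resorption-free phantoms (80 edges) for specificity, sizes
at which the run completes in seconds while the binomial error on a 95%
specificity bound stays below ~3 points. The acceptance script uses 80 +
20 phantoms and 10 error batches, mirroring the batched-evaluation
design. Bilinear interpolation handles all off-grid profile samples;
rounding is floor(x + 0.5) (round-half-up) wherever an 8-bit value is
produced, so results do not depend on banker's rounding. Degenerate
inputs fail loudly: constant images cannot be linearly enhanced, empty
edge maps and unpaired detections raise gating/description errors with
distinct CLI exit codes (2/3/4), and a fitted curve leaving the image
for more than half its steps aborts the scan.

## Known limitations

* The percentage denominator is the *visible fitted span*, which on a
  connected crown includes the short neck above the junction; this
  biases percentages low by roughly span/(span + neck) (≈ 2 points at
  20% resorption) unless the physical implant length is supplied.
* Gradual (non-abrupt) defect transitions — the 3D-projection failure
  mode — are not corrected; the first point lands where the profile
  first drops 20 levels below its mean, which may be displaced on such
  images.
* A crown no brighter than `run_factor ×` the screw-interior level near
  the defect cannot trigger the crown-entry rule; those edges report
  `first_only` and no percentage.
* One screw pairs with at most one crown; bridged multi-unit prostheses
  are outside the model.
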