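# Methods

## The counting chain

The pipeline assumes a *fixed* camera: the scene background is stable enough
that a single fish-free reference frame represents it, and anything that
differs from the reference is a candidate animal. Subtraction is done in
signed arithmetic and the absolute value taken, so dark fish on a bright
background and bright fish on a dark background are treated symmetrically.
The stretch to [0, 255] uses one min/max pair for the whole image (a
per-channel mode exists but is off by default): the stretch exists to
normalise contrast between frames taken under different lighting, and a
joint stretch preserves the relative channel balance.

Edge detection uses the standard 3 × 3 Sobel pair with gradient magnitude
`sqrt(gx^2 + gy^2)` and edge-replicated borders — a formulation simple
enough to verify against a literal convolution loop. The binarisation
threshold is the genuinely open choice in this design: we default to Otsu's
threshold computed per channel on the gradient magnitude, because it adapts
to the markedly different illumination of frames taken at different hours,
and we provide a fixed-threshold override for controlled comparisons.
Whether one global or three per-channel thresholds is "right" cannot be
settled from first principles; per-channel is the more conservative choice
(a contour visible in any channel survives the OR).

The OR combination and hole filling convert the three edge maps into solid
silhouettes. Hole filling is defined as: every background region not
connected to the raster border becomes foreground. With 8-connected
foreground the enclosed background is flooded 4-connectedly (and vice
versa); 8-connectivity is the default because fish contours run diagonally.
Filling precedes the size filter, so the filter sees silhouette areas, not
contour areas.

The size window [10, 5000] px is inclusive on both ends ("within the
interval" read as closed). At the nominal 480 × 360 geometry, 10 px rejects
isolated edge noise and 5000 px rejects near-field occlusions and merged
schools — which is also why dense schools are systematically *under*counted:
overlapping silhouettes merge into components that either count as one
object or exceed the upper bound and are eliminated outright.

Degenerate inputs: a constant difference image (frame identical to
reference) stretches to all zeros by convention — division by zero is
guarded and a featureless frame must yield zero detections. A gradient-free
channel yields an empty edge mask rather than an Otsu failure.

## Error typology

Categories are assigned first-match in this order: `Correct0`,
`Img0-ClassN`, `Img>20-Class<10`, `Img<10-Class>20`, `ImgN-Class0`,
`CorrectN`, `ImgN-ClassM`. Two orderings deserve comment:

* The school-confusion rule outranks `ImgN-Class0`. A school frame in which
  the automatic chain found nothing (N > 20, M = 0) is a school failure —
  the distinctive, diagnosable failure mode — not a generic zero-detection.
  This is also the only ordering under which the category tallies, the
  frames-with-fish counts and the derived percentages of the reference
  evaluation are mutually consistent.
* The `Img<10-Class>20` predicate is implemented in its mirror-symmetric
  form (N < 10 and M > 20), with the asymmetric variant (N < 20 and M > 10)
  available via `school_rule="prose"`. The class is empty in the reference
  evaluation either way.

The per-class "mean" for the generic miscount class is reported as the mean
absolute discrepancy |M − N| within each subcase (M > N and M < N), with the
raw mean M and mean N also exposed, since a single "mean objects" figure is
ambiguous between the two readings.

Thresholds: school = manual count > 20; low = 10. Both are parameters.

## Habitat time series

Hourly bins are [t, t+1h), labelled at the start, in UTC (the instrument
streams carry no timezone; UTC makes runs reproducible anywhere). A bin is
declared missing when it holds fewer than `coverage_min` (default 0.5) of
the nominally expected samples — 360 for a 10-s CTD, 6 for 10-min ADCP
products. Missing bins are never interpolated; gaps must stay visible to
downstream analyses. Hourly means weight the samples in a bin equally, so
for ADCP products the hourly value is the plain mean of up to six 10-min
values. Current direction is averaged as the angle of the mean unit vector;
all other variables are linear means. Burst reduction (1-min at 1 Hz every
10 min) is the mean of each cadence window's samples stamped at the burst
start; empty windows are skipped with a warning.

The watchdog alarms emulate an observatory's received-data and trend checks,
whose exact production definitions are not published; our rule is a stated
stand-in: one `no_data` alarm per maximal run of missing bins, and a
`trend_deviation` alarm for any bin departing from the centred 24-h rolling
median by more than 5 × MAD, with the MAD floored (default 1e-4, in practice
the instrument resolution) so a perfectly constant stretch cannot produce a
zero denominator.

Coupling aligns hourly fish counts with habitat variables on the hourly grid
over the overlapping span, propagating missing values (a daylight-only
camera leaves night count bins empty) and never resampling habitat values —
every non-missing output value is bit-identical to its input.

Waves are accepted only as already-derived hourly products; spectral
processing of raw 2-Hz bursts is vendor-side and out of scope, as are
salinity/depth/sound-speed derivations internal to the CTD.

## Synthetic data: what it does and does not emulate

Scenes are fusiform ellipses (aspect ratio 2–4, random orientation) at a
fixed intensity offset (default ±80 around a background level of 120) over
a uniform or speckled background, with optional linear illumination drift
and additive Gaussian noise clipped to [0, 255]. The local species are
similar in outline, so shape realism beyond "fusiform blob" adds little for
a counting (not classifying) pipeline. Separated mode enforces a minimum
clearance of 6 px between outlines (largest-first rejection sampling; an
infeasible packing raises rather than silently overlapping). School mode
draws centres inside a disc whose radius scales with the square root of the
total fish area, so member overlap — the mechanism behind school
undercounting — is controllable. The reference and the scene share the same
seed-bound background realisation and differ only in their noise draw,
mirroring two exposures of one fixed scene.

Default stream conditions follow the instrument table: CTD cadence 10 s;
ADCP-style products at 10 min from 1-min 1-Hz bursts; diel (24 h) plus
principal semidiurnal tidal (12.42 h) sinusoids with Gaussian noise and
declared outage gaps.

What passing tests on these scenes shows: the chain's arithmetic is exact,
its count recovery is perfect when objects are separated, in-range and
above threshold, and its school failure mode has the right sign. What it
does not show: performance under fouling, turbidity, fish at the frame
border, partial occlusion by the mooring, or backgrounds that drift between
reference and frame — real-deployment effects the generator deliberately
omits.

## Problem sizes and determinism

The standard verification run uses 50 separated-fish scenes (1–20 fish
each), 20 school scenes of 30 fish, the 500-pair evaluation set, and 100
random instances per brute-force oracle — sizes at which every check runs
in seconds on one core while still exercising each code path. Every
stochastic component takes an explicit seed (children derived via
`numpy.random.SeedSequence`); equal seeds reproduce scenes, pair sets and
streams bit-exactly. CSV writers use fixed column order and 6-significant-
digit floats, so identical inputs give byte-identical files.

## Known limitations

* A single fixed reference frame is assumed for a whole sequence; slow
  background drift (fouling, seasonal light) would need reference refresh,
  which is not modelled.
* Otsu's threshold assumes a bimodal gradient histogram; frames that are
  nearly all edge or all flat can threshold poorly. The fixed override
  exists for such regimes.
* The automatic-prevalence percentage of an evaluation set generated from
  category tallies alone is stochastic (it depends on how many school
  frames drew M = 0), with expectation within 0.05 points of the reference
  figure.
* Counts are per frame; no tracking across frames, no species distinction,
  no animal sizing.
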