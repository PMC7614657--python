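# Methods

This note documents the models, defaults, and design choices behind
`rtqibc`, in the order data flows through the pipeline, and what the
synthetic benchmarks do and do not establish about real microscopy.

## Coordinate and unit conventions

Pixel coordinates are 0-based `(y, x)` with y increasing downward;
centroids are floats. All times are minutes from the start of the live
movie; per-phase durations and kinetic half-times are minutes.
Intensities are arbitrary units (camera counts after correction). The
default live pixel size is 0.65 µm (10x); fixed plates may be imaged at
higher magnification, expressed as an integer or real magnification
ratio relative to the live movie.

## Synthetic data generator

The generator emulates an asynchronously proliferating MCF10A-like
epithelial monolayer imaged every 3 min for 120 frames, 50 nuclei
initially in a 400×400 px field.

**Cell cycle.** G1, S, and G2M durations are lognormal with medians
300, 480, and 240 min and CVs 0.25, 0.15, and 0.20 (a ~17 h cycle,
right-skewed like measured cycle-phase distributions). Initial cells
get a uniform random age within their own cycle, so the population is
asynchronous. At the end of G2M a cell divides into two daughters
placed adjacent to it (centers ±1.1 radii along a random axis,
emulating post-cytokinesis separation), each daughter receiving a
fraction 0.5 ± 0.02 of the parent's integrated H2B intensity.

**Motion.** A per-frame isotropic Gaussian random walk (σ = 1.5
px/frame) with reflection at the field border, plus a soft-core
exclusion: after each step, pairs of nuclei whose center distance falls
below 75% of the sum of their radii are pushed apart symmetrically.
This was a genuinely open design point: a pure random walk is simpler,
but over a two-hour movie it lets nuclei diffuse fully on top of one
another — a configuration real (non-overlapping) nuclei cannot reach
and no segmentation can resolve. The soft core keeps nuclei touchable
(the concavity splitter is still exercised constantly) but never
interpenetrating, matching monolayer geometry. Initial placement
likewise enforces a ≥ 2.2-radius separation where space allows. A
config-level density bound rejects settings whose expected end-of-movie
population would put > 20% of nuclei in contact.

**Reporter kinetics.** The functional forms are a modelling choice —
the underlying biology specifies only "accumulates" and "is degraded":

* CRL4^Cdt2 reporter: linear rise from anaphase to a plateau over 240
  min; exponential decay from S entry with a 6 min half-time.
* APC/C^Cdh1 reporter: 2% basal level until APC/C inactivation, then a
  linear rise over 180 min. Inactivation is drawn N(6, 5²) min before
  S entry (occasionally after, as observed in real cells), truncated to
  fall after anaphase.
* CDT1-like immunofluorescence: constant through G1, exponential decay
  from S entry with half-time 9 min. The "fully degraded" gate is 10%
  of the G1 level, so the gate is crossed 9·log2(10) ≈ 29.9 min after
  S entry — reproducing a ~30 min window in which fired origins coexist
  with undegraded CDT1.
* PCNA foci area: zero outside S phase, ramping to an 80 px plateau
  within 6 min of S entry.
* EdU: cells in S phase at fixation get the Hill-model prediction at
  their ND-CDT1 expression (log-uniform over 0.5–40 a.u.) times
  lognormal noise with CV 0.3; all other cells are ~0. The value
  represents the short-pulse average incorporation rate; pulse kinetics
  are absorbed into the noise term rather than modelled.

**Rendering.** Nuclei are isotropic Gaussian blobs truncated at 2.5 σ
(σ = radius / 2.5), normalized so the integrated blob intensity equals
the trace value — integrated H2B is conserved across frames and splits
with the division fractions. PCNA foci are fixed per-cell spot patterns
(σ = 1 px, amplitude 100 counts, ~7 px footprint per spot at the
working top-hat threshold) within 70% of the nuclear radius; the number
of active spots tracks the foci-area trace. Fixed-plate channels (DNA,
CDT1-IF, geminin-IF, EdU, ND-CDT1-IF) are rendered at the final movie
time at `ratio × live + offset` coordinates; immunofluorescence scales
analyte levels by 400 counts/a.u.

**Camera.** Raw frames are `offset + gain × signal + noise`: offset 100
counts; a Gaussian vignette gain field (amplitude 0.15, normalized to
mean 1, strictly positive); Gaussian read noise (σ = 2 counts) plus
shot-like noise with variance 0.05 × signal; optional linear
bleedthrough between channels applied in the signal domain, so that
with noise disabled flat-field plus bleedthrough correction inverts the
model exactly.

**What the generator does not emulate:** photobleaching, focus drift,
3-D optics, autofluorescent background structure, pre-extraction
physics, segmentation-relevant texture inside nuclei, or drug
pharmacology (treatments are represented only as parameter changes).
Passing benchmarks on this data demonstrates the correctness of the
algorithms under their stated assumptions, not robustness to every
failure mode of real microscopy.

## Image correction

The illumination profile is estimated from background autofluorescence
in cell-free areas aggregated over ≥ 10 sites (per-pixel median of
pixels outside dilated nuclear masks, requiring ≥ 3 observations for at
least half the pixels; uncovered pixels filled from the nearest covered
pixel), or from blank wells. Whether to summarize by mean or median and
how to smooth were open choices; we use the median for robustness and a
Gaussian low-pass with σ = 5% of the image width, since illumination
varies at field scale, then normalize to mean 1. Correction is
`(raw − offset) / profile` clipped at 0; clipping keeps downstream
percentile statistics on non-negative values. Confocal acquisitions can
skip flat-field correction via a per-channel flag. Bleedthrough
correction subtracts `coefficient × source` on corrected images,
clipped at 0.

## Segmentation

**Live (H2B).** Seeds come from a multiscale LoG blob detector over the
configured diameter range. Object extent is obtained by local
thresholding around each seed — 5% of the local background-subtracted
peak, floored at 3× the image noise (MAD-based) — followed by a seeded
watershed on the smoothed image; overlapping detections are suppressed
keeping the stronger response. An optional region-based morphological
active contour (fixed 50-iteration budget) refines the foreground for
low-contrast movies. Because adjacent nuclei can collapse into a single
LoG maximum, objects larger than 1.3× the median area are passed to the
concavity splitter.

**Fixed (DNA stain).** The global threshold is taken from the
log-intensity histogram: after smoothing, the maximum curvature of the
log-count histogram on the descending shoulder between the background
mode and the middle of the inter-class valley — the elbow where the
background peak's parabolic arm meets the valley floor. Binning in the
log domain over the data range makes the threshold scale-covariant
(doubling intensities doubles the threshold). Components are filled,
small objects removed, and objects above the median component area
split.

**Splitting touching nuclei.** Perimeter curvature is estimated on a
σ = 2 px smoothed closed contour as the derivative of the tangent
angle. Candidate split points are local maxima of concavity below
−0.15 rad/px; the pair maximizing (along-perimeter distance) /
(Euclidean distance) defines the splitting chord, recursing on
fragments. Two extensions cover real geometries: partners down to half
the concavity threshold are allowed when only one strong concavity
exists, and for one-sided necks (the far side convex) any contour point
may serve as partner — the ratio rule still selects the opposite side
of the neck. Chord pixels are reassigned to the nearest fragment so
splitting never changes the total foreground pixel count.

## Quantification

Background is the 25th percentile of pixels outside the nuclear mask
dilated by 7.8 µm (nuclear signals) or 15.6 µm (signals with
cytoplasmic components). Per nucleus we record total, mean, and median
background-subtracted intensity; cytoplasmic signals add the median of
a ring 0.65–3.25 µm outside the nuclear edge, excluding pixels within
any nucleus's inner dilation and assigning contested pixels to the
nearest nucleus (no ring pixel is shared); the cyclin E/A-CDK activity
readout is ring median / nuclear median. Puncta area is the count of
top-hat-filtered pixels (radius 2 px wide-field, 3 px confocal) above a
configurable threshold series inside each nucleus; the pipeline
additionally erodes the nuclear interior by 2 px for puncta counting to
suppress spillover from a touching neighbour's foci. Chromatin-bound
channels flagged "no background subtraction" pass background 0 and are
baselined later via the G1 mode. Staining-round utilities remove
incompletely pre-extracted cells above a soluble-reporter gate,
subtract residual first-round signal with an empirical scale factor,
and normalize by a co-expressed marker.

## Tracking

Mutual nearest neighbours within a gate of max(3× motion σ, 10 px);
ties resolved by distance, then |signal change|, then label id. Links
whose integrated H2B changes by more than 25% are severed and flagged.
A flagged merge (one object carrying the summed signal of two lost
tracks) is repaired by locally re-splitting the object and re-linking;
a spurious split (a pair summing to one track's signal that fuses again
within 2 frames, with the original track resuming) is stitched back
with intensity-weighted centroids. Divisions are recorded when a track
ends and two tracks begin the next frame within 4 nucleus radii with
summed signal within 30% of the parent's; daughters then carry the
parent's track id as lineage. There is no gap closing — a nucleus
missing from one frame ends its track — because linking is strictly
frame-to-frame. The numeric tolerances have no published values and
were calibrated on the synthetic benchmark.

## Event annotation

Traces are normalized per cell to their peak after the search start so
thresholds are expression-independent; integrated (total) nuclear
intensity is used for the CRL4 and APC/C reporters. The drop detector
requires, over a fixed 3-frame look-ahead window, a fitted slope ≤
−0.03/frame, a second central difference ≥ 0.01/frame², and a ≥ 10%
drop. The fixed window keeps detection latency independent of how long
before fixation the drop occurred, avoiding bias against recent
S-entries. The rise detector requires a forward slope ≥ 0.01/frame from
a level ≤ 0.1 with a persistent rise to ≥ 0.25 (transient blips are
rejected), then advances to the last flat frame so slow ramps are not
called early. S entry from PCNA foci uses the dual-threshold rule: the
first frame above 50 px that also exceeds the previous 4 frames,
backtracked to the last frame below 3 px. When foci never cross the
high threshold the S entry is treated as unidentifiable rather than
estimated from the rise detector, whose window-leading bias would
systematically pre-date late-movie entries; the rise-based alternative
remains available as an option. All thresholds are configuration,
calibrated on the synthetic benchmark.

## Live-to-fixed matching

Registration computes the circular FFT cross-correlation of the
zero-mean DNA (fixed) and H2B (live, final frame) images after bringing
them to a common scale — bicubic upsampling of the live image or
mean-value binning of the fixed one — and returns the integer-pixel
peak in fixed-frame coordinates, rejecting peaks with normalized
correlation below 0.1. Matching transforms fixed centroids into live
coordinates (`(c − offset) / ratio`) and assigns greedily by ascending
distance, one fixed cell per track at most (a track that divided near
movie end cannot receive two fixed cells), default gate one nucleus
radius. Multi-round (4i-style) stains register every round's DNA image
to round 1 and quantify all rounds under the round-1 primary mask;
rounds that fail to register yield null channels. Acquisition-time
offsets are `position / total × frame interval` in the site acquisition
order; derived times are `(movie end + site offset + fixation delay) −
event time`, fixation delay defaulting to 0, and cells with unannotated
events keep their measurements with null times.

## Statistics

Gates are percentiles (99th, or 95th where stated) of a reference
population of known phase, ≥ 50 cells. The Hill fit is unweighted
least squares via Levenberg–Marquardt with the stated initialization
(EdU_min: 5th percentile of EdU; IC50: median expression; n: 1) and a
restart grid (IC50 × {0.3, 1, 3}, n × {0.5, 1, 2}) used only on
non-convergence; EdU_max is always fixed by the caller. In the recovery
benchmarks EdU_max comes from cells with expression ≤ 0.7 a.u.; because
the simulated expression floor (0.5 a.u.) leaves no true
zero-expressers, a one-step correction adds the fitted curve's
predicted deficit of those cells back onto EdU_max and refits — without
it the fitted Hill coefficient of shallow curves is biased up by ~5%.
Geminin-stratified analysis fits per equal-count bin (≥ 660 cells) and
regresses IC50 on the bin-median stratification level by OLS. The
robust zero-intercept line is IRLS with Tukey bisquare weights (tuning
constant 2, MAD scale re-estimated per iteration, convergence 1e-8 or
100 iterations); it is cross-checked against an independent robust-fit
implementation in the tests. Bootstrap CIs use ≥ 1000 with-replacement
resamples and the percentile method. Binned summaries (default 3 min
bins, ≥ 36 cells per bin) report median/mean/fraction-below-gate with
bootstrap CIs. Outlier trimming removes the top 1% (or both tails);
subsampling equalizes group sizes without replacement; t-tests are
two-sided (two-sample, paired, or one-sample). No multiple-testing
correction is applied; p-values are reported raw.

## Colocalization

Pearson r over nuclear-mask pixels; significance against a
randomization null obtained by shifting the channels 40 px in each of
the four cardinal directions, recomputing r over in-bounds mask pixels,
and averaging. Out-of-bounds pairs are dropped rather than wrapped —
wrap-around would manufacture artificial structure. The 40 px default
corresponds to ~1 µm at the super-resolution pixel scale the analysis
targets and is configurable. Overlay masks (top-hat radius 10 px,
Gaussian σ 1 px, uniform threshold) are for display only.

## Benchmark problem sizes and known limitations

The validation suite uses desk-scale problems chosen to exercise every
code path at high statistical power: Hill recovery uses the published
cell counts (12,039 / 4,573 / 5,000) over 20 seeds; the synthetic plate
is 4 sites × 50 initial cells × 120 frames; the tracking benchmark
pools ≥ 20 divisions over two seeds. At plate scale only ~15–20 matched
cells land in the informative 0–45 min window after S entry, so the
reconstructed CDT1 decay half-time carries ~10% sampling error; it is
estimated from per-cell nuclear medians (robust to boundary spillover
from touching, CDT1-bright G1 neighbours) after subtracting a true-zero
baseline taken from cells fixed long after degradation, mirroring the
G1-baseline normalization used for linear-scale stain quantification.
Known limitations: segmentation assumes roughly isotropic nuclei;
tracking has no gap closing, so a single dropped frame fragments a
track; event detection requires the event to be observable within the
movie (entries in the last ~2 frames are unidentifiable by design); and
the camera model's noise is Gaussian, not a full sCMOS read-noise map.
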