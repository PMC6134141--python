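# Methods

## The analysis model

One *run unit* is a single 315 s trial imaged in one plane at 5.81 Hz
while a whole-field grating alternates 10 s of caudal-to-rostral motion
with 5 s of static presentation (first motion onset at t = 5 s; a
trailing partial motion period is truncated at the trial end).  Tail
kinematics are recorded at 250 Hz.  The pipeline assumes motion-corrected
movies and takes ROI footprints/traces from any source-extraction method;
a naive footprint-averaging extractor is included as plumbing.

### Tail kinematics

The bend angle is the signed angle between the resting body axis and the
vector from the swim-bladder end (tracked point 0) to the tail tip
(point 8); positive = leftward deflection viewed from below.  The body
axis defaults to the median bladder-to-tip vector over the trial, which
is robust because the tail is straight between bouts.  Deflection
extrema are local maxima/minima with |angle| ≥ 5° separated by ≥ 10 ms
(the smaller of two same-sign extrema inside that window is dropped);
extrema closer than 100 ms are grouped into one bout, padded by 20 ms and
clipped to the trace.  Bouts overlapping tracking gaps (> 20% NaN) or
with peak |angle| > 100° (struggles/escapes) are flagged and excluded
from event sets but retained in the bout table.  These thresholds are
design choices — typical larval beat frequency is 20–40 Hz and interbout
intervals are ≫ 100 ms — and are all exposed in the configuration.
Missing frames are carried as NaN and never interpolated.

### Event windows

Swim windows run 2 s before to 5 s after a bout onset and require a
> 0.5 s gap measured from the previous bout's *end* to the candidate's
*start*.  Stimulus windows run 5 s before a motion onset to the end of
the 10 s motion period (the window ends at motion offset; post-motion
static seconds are not included).  Event times live on the 250 Hz
behaviour clock and are snapped to the nearest imaging frame; sub-frame
jitter up to half a frame period (~86 ms) is accepted, consistent with
the temporal resolution of 5.81 Hz imaging.  Windows that would leave the
trial are dropped, not padded — padding would bias the averages.

### Classification

The consistency score of a trace with an event class is the mean over
events of the Pearson correlation between each window and the class
average (Spearman available by configuration).  With fewer than two
events the score is undefined and the trace is unclassified; a
zero-variance window (or average) contributes a correlation of 0 and is
logged.  The 0.6 rule uses strict inequalities; ties go to unclassified.
The two scores are not independent — bouts occur preferentially during
motion — and no decorrelation is attempted; traces above threshold for
both classes are ambiguous and excluded from clustering.

### Clustering

Triggered averages of each driven category are clustered independently:
waveforms are z-scored (correlation is scale-invariant, so this only
fixes the geometry; centroids are reported as raw-waveform means with
per-timepoint SEM), a cluster is seeded with the most-correlated
remaining pair above the threshold (ties broken by lowest index), grown
by sweeping in every waveform with r ≥ 0.75 against the running centroid
until membership stabilizes, removed from the pool, and the process
repeats; clusters below the minimum size are discarded and their members
left unassigned.  The minimum size is 50 at full experimental scale
(hundreds of ROIs across larvae); analyses of single synthetic scenes
scale it to half the per-archetype ROI count.  The procedure is
deterministic given the input order, and on well-separated data the
partition is order-independent (label names aside).

### Pixel maps

Movies are 2×2 uniform mean filtered per frame (window anchored
top-left; "2 pixel mean filter" is ambiguous between 2×2 and radius 2,
and the 2×2 kernel is the implemented default) with nearest-replication
edges.  For each cluster and each of its events, every pixel's intensity
time series within the event window is Pearson-correlated with the
cluster centroid; per-event maps are averaged, ignoring undefined pixels
(zero variance within a window), and a pixel is undefined in the final
map only if undefined in every event.  Correlations use raw filtered
intensities: Pearson correlation is invariant to the affine ΔF/F
transform, so correlating intensities and ΔF/F is equivalent.  Maps from
several larvae, registered to a common space by external tooling, are
combined as a per-pixel weighted mean with weights proportional to event
counts (configurable).

### Preprocessing

ΔF/F is (F − F0)/F0 with F0 the 10th percentile over a sliding 30 s
window by default (robust in activity-dense trials; a global percentile
or an explicit F0 can be configured).  F0 ≤ 0 raises an error rather than
producing unbounded values.  Red→green bleed-through is the Theil–Sen
slope of green vs red time-averaged pixel values over pixels above the
red channel's 90th percentile — the reproducible analogue of reading the
slope off the two-channel scatter plot — and correction subtracts
`factor × red` per pixel, clipped at zero (fluorescence is
non-negative).

## The synthetic study conditions

The generator emulates the recording setup so every stage is testable
against planted ground truth.  Defaults are fixed once and act as the
study conditions for all tests:

* **Stimulus**: 315 s trial, 10 s motion / 5 s static, 21 presentations.
* **Bouts**: an inhomogeneous Poisson process at 0.15 bouts/s during
  motion and 0.02 bouts/s during static (an optional onset-boost factor
  exists but defaults to 0), with a 0.2 s refractory gap.  No numeric
  bout statistics are published for this assay; these values are
  realistic for restrained optomotor swimming at 5–6 dpf and — important
  for interpretation — sparse enough that a 7 s triggered window is
  dominated by its own bout.  At several-fold higher rates the
  event-consistency score degrades for *every* method, because windows
  overlap neighbouring transients; that regime measures bout-process
  overlap, not classifier quality.  Each bout is a 20 Hz sinusoid with a
  ~40 ms Tukey amplitude ramp, lognormal duration around 0.25 s (clipped
  to 0.15–0.5 s) and amplitude ~30 ± 5°, on 1° Gaussian baseline noise.
* **Calcium kernel**: `(1 − e^{−t/0.05}) e^{−t/1.0}`, unit peak — the
  order of GCaMP5 kinetics; both constants configurable.  Sustained
  drives are convolved with steady-state initial history to avoid a
  trial-start turn-on transient.
* **Archetypes**: swim-locked (unit-peak transient per bout, ΔF/F
  amplitude 1.0), stimulus-sustained (boxcar, plateau 0.8), mixed
  (0.1-weight swim transients plus a stimulus drive that adapts with
  τ = 1 s during each motion period), stimulus-suppressed (0.8 baseline
  shut off during motion), silent.  The mixed archetype adapts because a
  non-adapting sum is unidentifiable: after stimulus-triggered averaging
  the bout train smooths into the same static-low/motion-high profile as
  the boxcar response (measured Pearson 0.99–1.0 across seeds), so no
  correlation threshold could separate the two archetypes.  Adaptation
  reproduces the intermediate phasic/tonic profile that makes the mixed
  group a genuinely distinct cluster, which is the structure the analysis
  is designed to detect.  Per-ROI gain jitter (±10%) emulates expression
  variability; it does not affect correlations.
* **Scene geometry**: Gaussian footprints (σ = 1.5 px, truncated at 2σ)
  on randomly chosen cells of a grid that guarantees ≥ 2 px gaps between
  supports — placement always succeeds, footprints never overlap, and
  the 2×2 filter cannot mix two ROIs.  Default frame 128×64 px for
  desk-scale runtime; the experimental 512×249 geometry is available as
  a preset.
* **Noise**: Poisson shot noise on photon-scaled intensities (scale 1.0,
  baseline F0 = 100) plus Gaussian read noise (σ = 2), both optional.
  Trace-level simulation (`simulate_traces`) adds ΔF/F noise of σ = 0.05,
  matched to the SNR of footprint-averaged traces from rendered movies.
* **Red channel**: static anatomy — background 20 plus ~30 blobs of
  intensity 50–150 placed away from green footprints (so red-dominated
  pixels are informative for the bleed fit); bleed factor default 0.1
  (0.2 in the evaluation scenes).

### What the generator does not emulate

Optics/PSF blur, motion artifacts (motion correction is out of scope),
overlapping or demixed sources, neuropil contamination, slow drift and
bleaching, multi-plane volumetric timing, and behavioural idiosyncrasies
(turn/struggle kinematics beyond an amplitude threshold).  Passing tests
therefore demonstrate correctness of the analysis given its stated
assumptions — well-isolated sources, corrected motion, event-dominated
windows — not robustness to those artifacts in real recordings.

## Numerical choices

* Event-to-frame snapping uses `round(t × rate)`; windows are half-open
  in samples, `[onset − pre, onset + post)`.
* Correlation degeneracies: zero-variance windows/pixels are scored 0
  (classification) or flagged undefined and excluded (maps); a constant
  clustering waveform can never be assigned.
* The clustering sweep is capped at 200 iterations per cluster (never
  observed to need more than a handful); seeding ties resolve to the
  lowest waveform index, making results reproducible bit-for-bit.
* Theil–Sen estimation thins the pixel set deterministically (evenly
  spaced over the red intensity range) above 20 000 pixels.
* Bleed-correction and dF/F guards: negative corrected intensities clip
  to 0; F0 ≤ 0 is an error, not a warning.

## Problem sizes used in validation

The evaluation module scores the pipeline on 20 seeded scenes of 20 ROIs
per archetype (classification, cluster recovery, bout detection) and on
rendered 64×48 px movies with 3 ROIs per archetype (pixel maps,
bleed-through), all at full 315 s trial length.  These sizes were chosen
as the smallest at which the statistics are stable; the map machinery is
resolution-independent.  The zero-noise map-exactness check uses a
deterministic periodic bout train (one bout per stimulus cycle, 1 s
after motion onset) so that all event windows are identical and the
measured correlation isolates the map machinery from bout-process
variability, which otherwise dominates (noise-free swim maps under the
stochastic process sit near 0.8 because neighbouring bouts enter the
7 s windows).

## Known limitations

* The swim/stimulus scores are correlated by design of the assay; the
  ambiguous category absorbs strongly mixed responses rather than
  decomposing them.
* Single-event traces cannot be scored and are reported unclassified.
* Cross-larva map combination assumes externally registered maps; no
  registration is performed here.
* The correlation-threshold clustering has no model of cluster count; a
  threshold of 0.75 on z-scored triggered averages implicitly sets the
  granularity.
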