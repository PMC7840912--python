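# Methods

This note documents the models, estimators and numerical choices
behind `granuletrack`, and what the synthetic benchmarks do and do not
establish about real microscopy data.

## Coordinate and unit conventions

Frames are 0-based; positions are micrometres in the image frame with
the origin at the centre of the top-left pixel, x along columns and y
along rows (image convention, y increasing downward).  Defaults follow
the standard recording setup: 0.077 µm pixels, 20 s frame intervals
(3 frames/min), movies of roughly 270–365 frames.  All CSV columns
carry explicit units (`_um`, `_s`, `_um_per_min`).

## The granule life-cycle model (simulator)

The simulator generates ground-truthed movies of the phenomenology
the pipeline is built to measure:

- **Geometry.** The cell is a disc of radius `cell_radius`; granules
  live in an annular zone of width `zone_width` (default 10 µm) at the
  cell margin.  Nucleation is a Poisson process in time
  (`nucleation_rate` per minute) with positions uniform by area in the
  *outer two thirds* of the zone.
- **Fluorescence.** Each granule samples a lifetime from
  N(`mean_lifetime`, `lifetime_sd`) (defaults 26 ± 6 min, floored at
  two frames).  Fluorescence follows a logistic curve from 5% to 95%
  of `plateau_fluo` over `growth_fraction` (default 0.75) of the
  lifetime — slow start, exponential middle, levelling off — then
  decays linearly to zero over the remainder (fast, near-linear
  dissolution).
- **Motion.** During growth the granule drifts radially inward at
  `drift_speed0 · (F/F_birth)^(−size_speed_exponent)` — nascent
  granules are fastest, large granules slow down — plus isotropic
  Brownian jitter with per-step squared displacement 4·D·Δt.  Inward
  drift halts at a terminus radius placed mid-way into the inner third
  of the zone.  During dissolution the drift is zero, leaving only
  jitter (erratic terminal motion).
- **Dissolution onset is position-gated.** Decay begins once *both*
  the growth period has elapsed *and* the granule has reached the
  drift terminus.  A purely time-based rule would let short-lived
  granules born at the outer edge die mid-zone; the gate encodes the
  observed topology — birth restricted to the peripheral two thirds of
  the zone, death to the inner third ("transition zone") — as a
  structural property of the model rather than a statistical tendency.
  With the default drift the gate rarely extends a lifetime by more
  than a frame or two.
- **Fusion.** Whenever two granules come closer than `fusion_radius`,
  the pair fuses: the smaller partner's fluorescence is added to the
  larger's (total fluorescence conserved at the event) and the
  smaller's record ends with `merged_into` set.  Pairs are resolved
  greedily by ascending distance within a frame.
- **Rendering.** Each granule contributes a unit-integral 2-D Gaussian
  (σ = `psf_sigma`, default 0.1 µm ≈ the confocal PSF at these
  wavelengths) scaled by `photon_scale · F`, on a constant background;
  the expected image receives Poisson shot noise and additive Gaussian
  read noise and is clipped to the 16-bit range.
- **Reproducibility.** A single `numpy` generator seeded by
  `rng_seed` drives every draw in a fixed order (per-granule
  propagation, births, fusion resolution, rendering noise), so runs
  are bit-identical for identical configs.

Free parameters without a reported counterpart (nucleation rate,
plateau fluorescence, photon scale, drift speed, size–speed exponent,
diffusion coefficient, fusion radius) are defaults chosen to yield
realistic densities and speeds (tens of granules per cell, local
speeds of a few tenths of µm/min, a handful of fusions per movie);
they are knobs of the simulator, not claims about cells.

What the simulator does **not** emulate: photobleaching and focus
drift, non-circular cell outlines and cell movement, granule shape
(everything is a PSF-limited point), intensity-dependent detector
gain, the dim short-lived cytoplasmic specks seen throughout real
cells, and any second channel (actin/myosin).  Passing the recovery
tests therefore demonstrates correctness of the estimators under the
model, not robustness to every real-data artefact.

## Detection

The detector computes the scale-normalized Laplacian-of-Gaussian
response −σ²·∇²(G_σ∗I) with σ_px = (diameter/2)/(√2·pixel_size), the
blob-optimal scale for the configured diameter (default 1 µm), signed
so bright blobs give positive quality.  Local maxima at or above the
quality threshold (default 33, detector-internal units; recordings
with different intensity scaling need a different value, e.g. 1) are
kept after non-maximum suppression within one blob radius (higher
quality wins).  Sub-pixel positions come from per-axis 3×3 parabolic
interpolation of the response peak, clamped to ±0.5 px.  Fluorescence
is the pixel sum inside the blob radius minus the median of an annulus
1–2 radii out times the disk area — a robust local background chosen
because no specific measurement definition is prescribed for it.
The "auto" quality threshold is Otsu's method on a 256-bin histogram
of qualities; a constant input returns that constant.  On a flat
bimodal gap Otsu may place the cut anywhere in the gap — tests assert
class separation, not a particular cut position.

## Tracking

Frame-to-frame linking solves, per consecutive frame pair, an exact
min-cost assignment (Hungarian algorithm) with squared-distance costs
gated at 1 µm; unassigned detections open or close segments.
Non-assignment is modelled with dummy rows/columns priced at 1.05× the
gate cost, so any admissible link beats dropping both endpoints and
the solution is exactly optimal; cost ties break toward lower spot
indices via an infinitesimal perturbation.

A second, single global assignment joins segment ends to (a) later
segment starts within 1 µm and ≤ 2 frames (gap edges) and (b)
mid-track spots of other segments in the immediately following frame
within 1 µm (merge edges) — one joint matrix, so gap closing and
merging compete on cost.  Splitting is never introduced.  Gap-closed
positions are not interpolated: kinematics treat a gap as one longer
step over its longer duration.

Tracks below 10 spots, or below the (auto or explicit) mean-quality
threshold, are removed and group membership recomputed.  A fusion in
the final movie frame cannot produce a merge edge (there is no next
frame to merge into); recovery tests count only observable fusions.
At high granule density a track that ends within 1 µm of an unrelated
passing track can produce a spurious merge — an inherent property of
gate-based merging, which is why exact merge-count recovery is claimed
(and tested) only under a verified well-separated condition.

## Track taxonomy

Groups are weakly-connected components of the track graph.  The main
track of a merging family is the member with the longest duration
(start to end in seconds); ties break by larger total fluorescence,
then lower track id (determinism; duration was chosen over spot count
as the "longest" criterion).  A track is *complete* when both its
first and last detection lie strictly inside the recording
(`start ≥ 1` and `end ≤ n_frames − 2`), i.e. birth and death were both
observed.  Lifetime is (end − start)·Δt.

## Kinematics

Local speeds use a gliding window of 8 consecutive spots (t−3 … t+4):
track speed = summed step lengths / window duration, advance speed =
net displacement / window duration, both in µm/min with the duration
taken from the actual frame span (140 s for a gap-free window).
Windows are evaluated only where all 8 spots exist — no shrunken edge
windows, so profiles have no values near track ends.  The advance/track
ratio is reported where the track speed is positive.  Both
`mean_local_speed` (average of window speeds) and
`overall_track_speed` (path length / duration) are emitted, since
"mean speed" is ambiguous between them.  Persistence is net
displacement over path length (undefined, NaN, for zero-length paths).
The fluorescence profile normalizes each track to its own maximum and
aligns peaks at 0 min before averaging across tracks; because tracks
leave the average as they die, comparisons of growth versus decay
rates should use the window where all tracks contribute.

## MSD analysis

Per-track MSD uses the overlapping-pair estimator, MSD(nΔt) = mean of
|r(i+n) − r(i)|² over all ordered pairs, for frame lags up to
⌊N/2⌋ (gapped tracks pair existing frames only and record pair counts
per lag).  The exponent fit is ordinary least squares of log MSD on
log lag over the first 50% of available lags (the 50% rule is applied
uniformly to individual fits and the ensemble D fit, limiting
large-lag noise), excluding zero-MSD points; fewer than 5 usable
points yields an undefined, not-accepted fit, and fits with R² < 0.8
are flagged not accepted.

Per-axis exponents rotate each track so its start→end vector lies
along +x; x then captures back-and-forth motion along the transport
axis and y the perpendicular component.  Because the axis is defined
from the data, the transverse component is conditioned on a small net
displacement and its mean exponent sits slightly below 1 even for
isotropic Brownian input (≈ 0.85 in the test conditions); tests assert
accordingly.  The sliding local exponent uses the same 8-frame window
as the kinematics (no window length is otherwise prescribed), fitting
all lags 1…7 within the window — the 50% rule would leave too few
points — without the R² gate (R² is reported alongside), attached to
the window's central time point.

The ensemble MSD weights each curve's contribution per lag by its pair
count (weighted mean and weighted SD); the diffusion coefficient comes
from a through-origin fit of MSD = 4Dt (2-D) over the first 50% of the
mean curve's lags, clamped at zero.

## Cohort statistics

Before/after experiments split each cell's tracks at the boundary
frame (default 30, i.e. 10 min of control recording); spanning tracks
are truncated at the boundary and each part kept only if it still has
≥ 10 spots (truncation rather than exclusion, flagged in the run
manifest).  The pairing unit is the cell: one mean per condition per
cell over solo tracks (overall speed, persistence, accepted α,
accepted perpendicular-axis α), compared with the two-sided Wilcoxon
matched-pairs signed-rank test.  Zero differences are dropped (the
common convention; some software handles them differently).  For ≤ 25
nonzero pairs the exact null distribution of W⁺ is enumerated by
dynamic programming on doubled (hence integer, tie-averaged) ranks;
beyond that a normal approximation with tie correction and no
continuity correction is used.  The p-value is invariant under
positive affine transforms of both members of every pair (signs and
rank order of |differences| are preserved); general monotone
transforms can reorder difference magnitudes and change it.
Significance labels apply the inclusive thresholds: p ≤ 0.001 `***`,
p ≤ 0.01 `**`, p ≤ 0.05 `*`, else `ns`.  Summaries report mean ± SD
(sample SD, ddof 1) and whisker-box quantiles per metric.

## Benchmark problem sizes

The motion-class benchmarks use 200 tracks per regime of 60 frames
(120 for the confined regime) at Δt = 20 s — free diffusion at
D = 0.01 µm²/min, drift 0.4 µm/min over D = 0.002 µm²/min, and
diffusion in a reflecting 0.5 × 0.5 µm box — and report the mean
exponent over accepted fits; ensemble-D recovery uses 300 tracks.
Detection and tracking recovery run on simulated movies of 50–60
frames with cells of 15–18 µm radius.  These sizes give stable
statistics (mean exponents vary by ~0.02 across seeds) while keeping
the full suite fast.

## Known limitations

- The tracker has no motion model (no Kalman prediction); very fast
  or dense granules beyond the 1 µm gates fragment or swap.
- Merging is gate-based; density, not identity, decides fusions.
- Quality units are detector-internal; thresholds do not transfer
  across differently scaled recordings.
- Per-track exponent estimates from short tracks are noisy and
  slightly biased low; the R² gate trims but does not remove this.
- The simulator's truth is a point-particle model; it cannot validate
  segmentation-dependent quantities (granule area, shape).
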