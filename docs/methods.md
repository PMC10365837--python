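# Methods

This note documents the models behind each stage, the parameters that
matter, the numerical choices, and what the synthetic-data validation does
and does not establish.

## Synthetic data generators

The generators define the study conditions under which every stage is
validated; each emits a `TruthRecord` with exactly one entry per simulated
entity.

**Axonal transport.** Vesicles move along a straight 100 µm axon window
imaged every 200 ms for 1 min (300 frames). Each motile vesicle follows a
three-state Markov process (anterograde / retrograde / paused) with
per-second switching hazards (defaults: 0.05 moving→pause, 0.02 direction
reversal, 0.10 pause→moving each way); segment speeds are drawn per segment
from N(1.2, 0.3) µm/s anterograde and N(1.0, 0.3) µm/s retrograde, clipped
at 0.05 µm/s. A fraction (default 0.2) of vesicles is strictly static. The
axial convention is that position increases toward the presynapse, so
anterograde displacement is positive. Reaching a window edge flips the
motion state (reflection); truth stores the realized per-frame velocity, so
integrating truth velocities reproduces truth positions to machine
precision by construction. Rendering: Gaussian spots of σ = 1.3 px on a
100-photon background at 0.1 µm/px (a 63× objective scale; the pixel size
is configurable), with Poisson noise by default (Gaussian and noise-free
modes exist for analytic checks). Spot SNR is defined shot-noise limited as
`amplitude / sqrt(background)`.

Not emulated: axon curvature (curved paths are exercised only in kymograph
extraction tests), photobleaching, camera gain, out-of-focus motion.
Passing recovery tests therefore shows the tracking and metrics are correct
for in-focus, straight-axon traffic at the stated density and SNR — not
that the detector is robust to every real-microscope artifact.

**pHluorin exocytosis.** Per field, one pre-stimulation and three
post-stimulation movies (300 frames each at 200 ms). Events per ROI are
Poisson in time (defaults 2/min before, 6/min after stimulation — a
several-fold activity increase typical of pharmacological stimulation);
each event is a uniform step of ΔF = 50 over a disc ROI (radius 4 px on a
100-photon baseline) decaying exponentially with τ = 2 s. Trace SNR is
`amplitude / σ` of the ROI-mean trace.

**EM synapses.** The default terminal is an 800 × 500 nm bouton (flat
PSD-facing base, elliptical cap); the active zone is the base edge.
Vesicle centroids are placed uniformly within the requested distance band
from the active-zone polyline, clipped to the terminal, under a hard-core
constraint of 2 × vesicle radius (40 nm) — synaptic vesicles do not
interpenetrate. Band counts follow the requested mix by largest remainder,
so they sum exactly to `n_vesicles`. Over-packed bands raise rather than
silently under-fill.

**Two-channel puncta.** A controlled fraction of punctum centers is shared
between channels (jitter ≤ 1 px); the rest are independent. A crowding
index above 0.3 triggers a warning because object counting becomes
unreliable when spots overlap.

**Paired EPSCs.** Each sweep is the sum of two inward biexponential
currents (τ_rise = 1 ms, τ_decay = 10 ms) at t₁ and t₁ + ISI with peak
amplitudes A1 and A1·PPR plus white Gaussian noise, sampled at 10 kHz. The
kernel is normalized by its maximum on the sample grid, so the rendered
peak equals the requested amplitude exactly at the sampled resolution.
ISIs shorter than ~5× the rise-to-peak time are flagged as overlapping.

## Kymographs and tracking

The kymograph (time × arc length, maximum intensity across the path width,
one bin per pixel) is retained as the visualization/QC artifact; metrics
are computed from per-frame detections projected to arc length, which are
directly testable against truth.

Detection is difference-of-Gaussians (σ ratio 1.6) maxima with
background-subtracted intensity above threshold and intensity-weighted
centroid refinement; detections are projected onto the axon polyline
(arc length measured from the declared soma end).

Linking was the hard design problem: thirty vesicles on 100 µm of 1-D axon
cross constantly, and naive nearest-neighbor linking produces chimera
tracks that scramble direction classes. Three mechanisms keep identities:

1. **Static-first claiming.** A position occupied in ≥ 70% of all frames
   and spanning ≥ 90% of the recording is a static site; its detections are
   claimed before any linking, which makes static tracks immune to being
   dragged away by passing vesicles. A motile vesicle's pause never
   qualifies (it does not span the recording).
2. **Velocity-predicted assignment with ambiguity rejection.** Remaining
   detections are linked per frame by Hungarian assignment on the distance
   to each track's velocity-extrapolated position, gated at
   `0.4 µm + 1.5|v|Δt` per elapsed frame. A link whose cost advantage over
   the nearest competitor is below 0.12 µm is refused outright: merged
   frames during a crossing become a short gap (bridged up to 4 frames)
   instead of a coin-flip identity swap.
3. **Velocity-consistent stitching.** Fragments are re-joined when one
   starts on the extrapolated path of another with agreeing local
   velocities; opposite-direction movers fail the velocity check, which is
   what separates a genuine occlusion from a chimera.

Segmentation labels per-step velocities (averaged over ±2 steps against a
0.1 µm/s pause threshold), merges runs shorter than 3 steps into their
longer neighbor, then refines each boundary against the raw per-step labels
(exact for clean data) and re-merges stubs. Segment speed is |net
displacement| / duration; edge steps that do not move with the run are
trimmed first, because boundary smear into a pause otherwise biases speeds
downward. A segment whose net displacement is below 0.4 µm — the
localization-confidence distance, also used as the static threshold — is
relabelled a pause: sub-resolution excursions are not evidence of directed
transport.

Classification: static if the maximal excursion from the start stays below
0.4 µm; otherwise the direction with the larger cumulative unsigned
displacement, with exact ties going to the later-occurring direction
(logged). In recovery scoring, a track is judged against the class of its
matched truth trajectory over the track's own frame window, computed with
the same classifier — the class of an unobserved part of a recording is
not knowable from the track.

Measured performance at the study conditions (30 vesicles, SNR 8, 20
seeds): ~96–97% per-track classification accuracy and ~4% mean error on the
anterograde segmental speed; truth-fed tracks reproduce truth counts and
flux exactly.

## Exocytosis event detection

Per-ROI mean traces are analysed by matching pursuit with backfitting:

- baseline = trailing (causal) 25-frame rolling median of the
  event-subtracted trace, padded at the start with the trace's global
  median. The trailing window keeps an event's own decay out of its
  baseline, so an isolated step's measured ΔF is unbiased — a centered
  window would overlap the decay and under-report peak ΔF.
- the residual is matched-filtered with the event template (exponential
  decay, template truncated at 3τ, amplitude-preserving normalization), and
  events are added one at a time at the filter maximum above threshold;
- after each addition all amplitudes are refitted jointly (least squares on
  the template matrix, alternated with baseline re-estimation until
  convergence) and events whose refitted amplitude falls below threshold
  are pruned — this keeps dense clusters from proliferating spurious
  events;
- onsets are then re-localized by a short step statistic (the matched
  filter's correlation peak is ~one decay constant wide and localizes
  poorly), and finally sub-separation pairs are resolved by a χ² test: a
  candidate event closer than the separation limit is accepted only if it
  improves the fit by > 16 noise variances, so a genuine double fusion
  splits but a lone event plus noise does not.

Noise-free contracts are exact (truth onsets, ΔF equal to the injected
amplitude); at trace SNR 5 under the default rates the detector reaches
~96% recall and ~99% precision over seeds. Events in the first few frames
of a movie and fusions within ≤ 2 frames of each other on one synapse are
the residual failure modes.

The normalized activity `y_i = ((Δ_i − mean(x)) + 100)/100` is affine in
Δ_i with slope exactly 1/100 and equals 1 when Δ_i matches the reference
mean; `y_post` aggregates the three post-stimulation acquisitions by mean,
keeping pre and post on the same per-acquisition scale. Per-field amplitude
is the mean per-event peak ΔF; the amplitude ratio is post/pre per matched
ROI with NaN (and a warning) for zero/missing denominators.

## EM morphometry

Areas are shoelace areas (shapely), converted nm² → µm². Distance bands are
differences of round-capped buffers of the active-zone polyline
(quad_segs = 64, sub-0.1% arc error) clipped to the terminal; zone areas
are computed on the clipped bands. Vesicles are assigned by centroid
distance with half-open bands [k·40, (k+1)·40) nm, so boundary ties are
deterministic; centroids outside the terminal are excluded and logged, and
counts conserve (zones + beyond + excluded = total). Vesicle radius is
retained in the geometry type for an optional edge-distance mode. Zone
assignment is rigid-motion invariant; clipped areas agree with 10⁶-sample
rejection sampling to < 1%.

## Colocalization

DoG inner sigma is `diameter / (2√(2 ln 2))` (filter pass band matched to
the punctum FWHM) with the classic 1.6 sigma ratio; constant thresholds per
channel; components below 4 px removed. A reference-channel particle is
colocalized if its component overlaps ≥ 1 px of the other channel's mask —
the measure is intentionally asymmetric (swapping the reference changes the
denominator, not the dual count), and the reference channel is an explicit
argument. Chance overlap of unpaired puncta adds a few percent at the
default densities, visible as the small positive offset at low true shared
fractions.

## Paired-pulse analysis

EPSCs are inward; amplitudes are |extremum − baseline| in a 20 ms window
after each stimulus. Baseline 1 is a 5 ms pre-stimulus mean; baseline 2 is
a short (≤ 1 ms) window immediately before stimulus 2, which removes the
residual first-pulse current to first order at short ISIs (at 25 ms ISI
with τ_decay = 10 ms a percent-level bias remains; at 250–500 ms the
noise-free recovery is exact to better than 1e-6). The reported per-cell
statistic is the mean of per-sweep A2/A1 ratios (sweeps measured
individually, then averaged); the ratio of mean amplitudes is also emitted
and the two agree in the noise-free limit. QC: relative variation
(max − min)/first-sweep value of input and series resistance; strictly
above 20% rejects the whole experiment (exactly 20% is accepted).

## Statistical workflow

ROUT is applied per group as the degenerate constant-location case of
robust regression: IRLS location fit with Lorentzian weights
`1/(1 + (r/RSDR)²)`, robust scale RSDR = 68.27th percentile of |residuals|
with the n/(n−K) small-sample correction, residuals converted to t-like
scores with n−1 df, and flags assigned by Benjamini–Hochberg step-up at
rate Q on two-sided tail probabilities. Flags are location/scale
equivariant; on clean Gaussian data the mean flagged fraction is far below
Q, and a 10σ contaminant is always caught. The gate runs Shapiro-Wilk per
group (3 ≤ n ≤ 5000; constant groups are an error) and takes the
parametric branch only when every group passes at α.

Test selection is a pure function of (design, branch): two groups →
Student t-test or Mann-Whitney; more than two → one-way ANOVA with Tukey
or Kruskal-Wallis with Dunn (rank z statistics with tie-corrected standard
errors, Bonferroni-multiplied — the convention of "Dunn's multiple
comparison test"); two-factor designs → two-way ANOVA with Tukey (> 2
groups) or Sidak-adjusted within-level comparisons (2 groups). The
two-factor nonparametric case, which the decision tree does not define, is
run as a two-way ANOVA on ranks with a logged warning. All tests
two-sided. Under the null the full workflow rejects at ~0.03–0.05 — the
slight conservatism is the expected cost of outlier removal before
testing.

## Problem sizes

Validation workloads were sized to make Monte-Carlo error small relative
to the tolerances while keeping the default suite quick: 20 seeded movies
for transport recovery, 10 fields for event recovery, 100 random
geometries (plus one 10⁶-sample area check) for EM, 2000 simulations for
the null-calibration of the statistics workflow, and 1000 for ROUT rates.

## Known limitations

- Tracking assumes one axon per movie and in-focus spots of a single size;
  two truly static vesicles closer than the detection resolution are
  counted as one (no tracker can split a permanently merged spot).
- Event detection assumes the step-rise/exponential-decay template with a
  known decay constant; strongly wrong τ biases amplitudes.
- The EM module consumes annotations (terminal outline, active zone,
  centroids); it does not segment raw micrographs. The optional
  blob-detection helper is for synthetic images only.
- ROUT here follows the published construction; it is validated by its
  statistical properties, not by matching any specific commercial
  implementation's flagged points.
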