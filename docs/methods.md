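# Methods

This note documents the models and procedures forcebind implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the design choices made where the underlying protocol leaves
the behavior open.

## Filament-region quantification (TIRF pipeline)

**Model.** A dual-color TIRF movie provides an actin channel and an ABP
channel, aligned frame-for-frame and pixel-for-pixel (no registration is
performed).  Filament regions — connected components representing one
filament or a small bundle — are detected in the actin channel only;
intensities in both channels are then quantified over each region's pixels
in the *raw* frames.  Preprocessing exists solely to drive segmentation.

**Segmentation.** Each actin frame passes through, in order: unsharp mask
(Gaussian radius `unsharp_radius` = 2 px, weight `unsharp_weight` = 0.6),
median filter (`median_radius` = 1 px, i.e. a 3 × 3 window), and
rolling-ball background subtraction (`rolling_ball_radius` = 25 px), with
the result clipped at zero.  These defaults are standard choices for
~1-px-wide fluorescent filaments: the unsharp mask boosts thin ridges, the
median filter removes single-pixel shot noise, and the rolling ball removes
smooth illumination background (a constant frame maps to exactly zero).
Binarization uses Otsu's threshold by default (parameter-free and
reproducible), with a fixed absolute threshold available via
`threshold_method: absolute`.  Connected components use 8-connectivity so
thin diagonal filaments stay contiguous.  Components below
`min_area` = 10 px are noise-rejected, and components whose centroid lies
fewer than `edge_margin` = 30 px from any image edge are excluded, which
guarantees the 60 × 60 px background window always fits inside the image.
Distance to the edge is the minimum of the centroid's 0-based coordinates
and their complements with respect to the last row/column index.

**Tracking.** Regions are linked frame to frame by shortest Euclidean
centroid distance with a hard gate of `gate_distance` = 24 px.  Candidate
(track, region) pairs within the gate are resolved greedily in ascending
distance order, exact ties broken by lower track id, one region per open
track per frame.  Unmatched regions open new tracks; an open track that
receives no match is closed permanently, so track frames are strictly
consecutive and a region reappearing after a gap becomes a new track.  This
deliberately overcounts filaments rather than guessing identities across
gaps.  Greedy matching (rather than globally optimal assignment) is the
specified behavior; the test suite compares it against a brute-force
optimal-assignment oracle on small frames and confirms the two coincide on
the large majority of random configurations.  Tracks shorter than
`min_track_len` = 10 frames are dropped, which suppresses poorly tethered
filaments that flicker in and out of the evanescent field.

**Quantification.** For each track observation and channel, the local
background is the mean intensity over the 60 × 60 px window centered on the
(rounded) centroid, excluding the pixels of *every* region detected in that
frame.  If no window pixel survives, the frame's ratio is marked missing.
The per-frame ratio is (⟨ABP⟩ − bg_ABP)/(⟨actin⟩ − bg_actin); frames whose
denominator magnitude is at most `epsilon_denominator_scale` (10⁻⁶) times
the movie's intensity range are marked missing to avoid sign flips from
background over-subtraction.  The track average over defined frames is the
reported per-filament ratio, and the mean over track averages is the
per-chamber summary.  Two invariances characterize the estimator: adding
any constant to both channels leaves ratios unchanged (background
subtraction), and scaling the ABP channel by *s* scales every ratio by
exactly *s*.

## Trap force–fluorescence analysis

**Force binning.** The per-frame force is the mean of the two-trap average
(f₁ + f₂)/2 over the 200 Hz samples falling in each confocal frame's
[start, end) interval (the final frame is closed).  An empty interval is an
error naming the frame.

**Rupture detection.** A rupture is a decrease of at least
`drop_threshold` = 1 pN within at most `drop_window` = 5 samples (25 ms at
200 Hz — effectively instantaneous); detected events are separated by at
least `drop_window` samples, and the final breaking force is the force at
the last sample before the final drop.  Gradual declines spread over many
samples are not ruptures.

**Multi-filament exclusion.** Tethers formed by capturing filaments from
solution may contain more than one filament, in three configurations:
several filaments of different lengths attached at both ends (betrayed by
multiple rupture peaks as each shortest filament reaches full extension and
breaks); filaments not all attached at both ends (betrayed by internal
step-like reductions in the actin-intensity line scan where a non-bridging
filament ends); and parallel filaments of essentially equal length (not
directly observable per recording, but enriched at high breaking force —
hence the exclusion of recordings breaking at or above
`breaking_force_cutoff` = 16.5 pN, above the ~6 pN single-filament regime).
Classification priority is multi_peak → dangling_filament → high_force →
single_candidate; only single-candidate recordings are included, and every
recording receives exactly one class.  Line-scan steps compare adjacent
plateaus of `min_plateau` = 5 px: a following plateau at or below
(1 − `step_fraction`) = 70 % of the preceding one is a step; a run of
adjacent flagged positions counts once.  The 30 % default reflects that a
non-bridging end removes at least one filament's worth of a ≥ 2-filament
signal (a ≥ 33 % drop for 2 → 1), with headroom for noise.

**Paired averages.** For recordings with at least
`n_quantifiable_frames` = 10 quantifiable frames before the final rupture,
the high-force average is the mean ratio of the last `window_frames` = 5
pre-rupture frames and the low-force average the mean of the 5 frames
immediately preceding those; the windows are disjoint and adjacent.  Only
the final tether to rupture is used.  Shorter recordings are excluded from
the paired analysis.

**Normalization and threshold detection.** Within each recording, ratios
are divided by the recording maximum (idempotent; output maximum exactly
1).  Pooled (force, normalized ratio) points are standardized per axis to
unit variance and clustered with K-means, k = 2, `kmeans_n_init` = 50
restarts under a caller-supplied seed (ties broken by lowest inertia —
scikit-learn's behavior).  Whether the clustering should use both axes or
force alone is genuinely open; both are exposed (`kmeans_features`), with
both-axes standardized as the default since the fluorescence axis is what
makes the low/high-force split scientifically meaningful.  The threshold
force is the midpoint between the maximum force of the low-force cluster
and the minimum force of the high-force cluster.  With a continuous
response and noise, a few transition-zone points routinely land on the
"wrong" side, making the clusters' force ranges overlap slightly; the
result is then flagged `separating = False` but the midpoint is still
reported, since it remains a consistent boundary estimate for slight
overlaps.  Degenerate inputs (all points identical, or fewer than 4
points) are errors.  Silhouette scores on the clustering coordinates are
reported for k ∈ {2, 3, 4}; only the comparison between them is asserted
(a maximum at k = 2 supports a single threshold).

## Statistics

**Exact Wilcoxon signed-rank.** Zero differences are dropped before ranking
(Wilcoxon's convention; the Pratt variant — rank zeros with the rest, then
discard their ranks — is available behind `zero_method="pratt"`).  Tied
magnitudes receive mid-ranks, and the exact test is conditional on the
realized rank multiset.  The null distribution of the positive-rank sum is
built by a generating-function recursion over the doubled ranks (doubling
makes mid-ranks integral), which is algebraically identical to enumerating
all 2ⁿ sign assignments; the test suite verifies exact agreement with a
literal brute-force enumerator.  The two-sided p doubles the smaller
one-sided tail, capped at 1 — this reproduces the boundary values
2·2⁻⁷ = 0.015625 and 2·2⁻⁶ = 0.03125 attained by unidirectional samples.
Above `exact_cutoff` = 25 effective pairs, a normal approximation with
continuity correction and an Edgeworth kurtosis term is used (the signed
rank sum is symmetric, so the first correction beyond the normal is the
fourth-cumulant term κ₄ = −Σrᵢ⁴/8); at n = 15 this agrees with the exact p
to well within 0.01.

**Kolmogorov–Smirnov.** Two-sample KS via scipy, exact when
n_a · n_b ≤ 10 000 and asymptotic otherwise; the method used is recorded in
every result, and the statistic is invariant under strictly monotone
transforms of both samples.

## Synthetic data

**Movies.** Filaments are rendered as line segments with a Gaussian
cross-section (σ = 1 px), the ABP-channel amplitude equal to
`true_ratio` × the actin amplitude, optional per-frame drift and
birth/death frames.  Backgrounds are constant, linear-ramp or smooth-blob;
noise is Poisson shot noise on signal + background plus additive Gaussian
read noise (sd 2 counts), a standard camera model.  Default amplitude 300
over background 100 gives a signal-to-noise level at which the pipeline
recovers true ratios within 10 % with margin.  Optional exponential
photobleaching is omitted by default because the per-frame ratio cancels
decay shared by both channels.  Generators are pure functions of
(spec, seed).

**Trap recordings.** Force ramps linearly (default 1 pN/s) with small
Gaussian sample noise (0.05 pN); at each breaking force the trace drops
instantaneously, and configuration 1 resumes ramping to the next peak.
The per-frame binding response is logistic,
r(F) = r₀ + Δr/(1 + exp(−(F − F_th)/w)) — the simplest monotone step with a
width parameter, a generator assumption rather than a mechanistic claim.
Two width regimes are used deliberately: within-recording fixtures default
to w = 1 pN (binding rises visibly across the ramp, which is what the
paired low/high-force windows probe), while the pooled-points generator
(`synth_force_response_points`) defaults to w = 0.1 pN, a step-like pooled
scatter suitable for threshold detection; Δr = 0 gives the
force-insensitive control.  Confocal frames default to 0.5 s so a ~6 pN
ramp yields the ≥ 10 quantifiable frames the paired analysis requires.
Line scans are flat plateaus (scaled by filament count), with an internal
50 % step for the dangling-filament configuration.

**What passing tests do and do not show.** The generators emulate the
statistical structure the analyses assume — ratio-preserving rendering,
instantaneous ruptures on linear ramps, a monotone binding response — not
filament mechanics, motor kinetics, trap compliance, focus drift or
bleaching asymmetries.  Ground-truth recovery therefore validates the
estimators and their contracts, not instrument-specific systematics; the
per-recording normalization and paired designs exist precisely because real
recordings carry such systematics.  The dimensionless `true_ratio`
deliberately abstracts over binding stoichiometry (occupancy vs per-site
brightness), which the intensity ratio cannot distinguish.

## Problem sizes and numerical choices

Test fixtures use 192 × 192 px movies of 12–15 frames with 3 filaments, and
trap recordings of a few seconds at 200 Hz — sizes at which every stage's
behavior is exercised and exact statistics remain enumerable.  Threshold
recovery is assessed over 100 seeded replicates of 200 points per
threshold.  K-means uses 50 restarts per fit under a fixed seed, making
stochastic initialization reproducible.  CSV output uses shortest
round-trip decimals (bit-exact re-reads).  Known limitations: no channel
registration, drift correction, filament skeletonization or bundling-state
classification; greedy tracking can differ from the optimal assignment in
crowded scenes; the force threshold is only meaningful when the pooled
scatter actually separates, and the `separating` flag should be inspected
before interpreting it.
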