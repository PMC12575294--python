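# Methods

## The detection model

A putative mossy-fiber synapse is operationalized as a connected set of
pixels that simultaneously exceeds an intensity threshold in the
postsynaptic channel and another in the presynaptic channel. The pipeline
is deliberately simple and literal: fixed global thresholds (no
adaptive/Otsu thresholding), a pixel-wise AND, connected-component
extraction by flood fill, and a hard minimum-size filter. Its assumptions
are that acquisition settings are constant across samples (so one
threshold pair is meaningful for a whole cohort), that colocalized signal
is well above the background noise floor, and that touching synapses need
not be split (no watershed).

Thresholding is strict (`intensity > threshold`); at 16-bit depth a
one-count shift is immaterial, and strictness makes the all-equal edge
case unambiguous. The size filter keeps clusters at exactly the minimum
area (150 px: remove only what is *smaller*). Connectivity defaults to
4-neighbor, the classic flood-fill notion; 8-connectivity is available in
`DetectionParams`, and the oracle-equivalence tests run both.

### Block flood fill

Large panels are processed in 500 × 500-px blocks. Within a block, seed
candidates are every `seed_stride`-th (default 4th) pixel of the block in
row-major linear order; each true, not-yet-visited seed starts a flood
fill over the full image, so fills cross block boundaries. Visited state
is kept per block: a cluster straddling a boundary is discovered
independently by each block that seeds it, exactly the situation that
makes edge duplicates possible, and duplicates are then collapsed by the
cluster's canonical pixel (the member with minimum row-major linear
index) — a key that is independent of discovery order. Consequences,
asserted by the test suite:

- at stride 1 the output is identical to exhaustive connected-component
  labeling (independent oracle: `scipy.ndimage.label`);
- the deduped result is invariant to block size and traversal order, so
  blocks may be processed in parallel or sequentially;
- with stride 4, a cluster is found iff it contains a seed candidate.
  A ≥150-px cluster essentially always does, but every run also reports
  `n_unassigned_px` (mask pixels not reached by any seed) so strided
  misses can be audited rather than assumed away.

The flood fill is a plain stack-based fill over the boolean mask,
authored here rather than delegated, because the block/stride/dedup
semantics *are* the algorithm under test; cost is proportional to the
number of true pixels, which is small for sparse synaptic masks.

## Calibration and quantities

Pixel scale defaults to 350/8000 × 420/10000 μm/px (the tiled-panel
geometry this was designed for), so a 200-px punctum is ~0.37 μm² and the
150-px floor is ~0.27 μm². Puncta per cluster is
`max(1, round(area / 200))` — half rounds away from zero, floored at one
because a retained cluster is at least one punctum. Log-size histograms
default to log₁₀ (the base is recorded in the output; counts are
base-invariant). Per-mouse density sums clusters and neurons across the
mouse's panels before dividing — the ratio of totals, never the mean of
per-panel ratios. The percent reduction between group means is computed
from the means, `100 (1 − m_a/m_b)`; for 4.75 vs 6.31 that is 24.7%.

## Statistics

Pooled cluster sizes: two-sided Mann-Whitney U (exact p by full
enumeration of the permutation distribution when both samples are ≤ 20,
valid under ties; tie-corrected normal approximation with continuity
correction otherwise) and two-sample Kolmogorov-Smirnov (asymptotic p).
Both wrap `scipy.stats`; oracle tests check them against brute-force
enumeration and a direct ECDF sweep. Pooling treats clusters, not mice,
as units; the per-mouse ANOVA is the pseudoreplication-safe complement.

Per-mouse metrics: two-way Group × Sex ANOVA with Type III sums of
squares under sum-to-zero contrasts (statsmodels OLS), the appropriate
choice for unbalanced cells such as 2M/3F vs 3M/4F; with 12 mice in 4
cells the Group term has df (1, 8). If a cell is empty, or one
observation per cell saturates the model, the interaction is dropped with
a warning; a constant response reports F = 0, p = 1 rather than a 0/0
artifact. On balanced designs Type III coincides with sequential SS
(checked in tests).

Behavior: the discrimination ratio is time near the novel condition over
time near the familiar one (1 = no preference); zero familiar time is an
error, not an infinity.

## Colocalization

The colocalization statistic is the peak of the circular normalized 2D
cross-correlation `C(l) = mean(â(x) b̂(x+l)) / (σ_a σ_b)` within a
±`max_lag` window (default 50 px), computed by FFT. Circularity gives
exact identities — autocorrelation peak 1 at lag 0, exact shift recovery,
`C_ab(l) = C_ba(−l)` — and agrees with a direct-sum oracle to 1e-8.

The null randomizes the spatial relationship while preserving each
channel's autocorrelation: toroidal shifts of the second channel, with
both offset components uniform in `[2·max_lag, dim − 2·max_lag)` so null
windows are clear of the observed one. For a toroidal shift by `s` the
shuffled correlogram is exactly the unshifted correlogram displaced by
`s`, so null peaks are read from one full correlogram; a test verifies
this equals literally rolling the image and recomputing. A per-pixel
permutation shuffle (destroying autocorrelation — a more liberal null) is
available as `mode="permute"`. The add-one estimator
`p = (1 + #{null ≥ obs}) / (1 + n)` avoids p = 0; defaults
`n_shuffles = 200`, `max_lag = 50` are desk-scale choices. The overlap
score `|A ∩ B| / min(|A|, |B|)` complements the correlogram for
already-thresholded masks.

## The synthetic generator

`make_scene` emulates the statistical structure the analysis assumes, not
the optics: somata are uniform discs (rendered only in the optional
nuclear channel), puncta are isotropic Gaussian blobs whose sigma is
calibrated per channel so the strictly-above-threshold footprint area
matches a target (default 200 px) after baseline and integer quantization
are accounted for; a cluster's 1 + Poisson(mean − 1) puncta are placed
with mutually overlapping footprints inside a disc (default radius two
punctum diameters) tangent to the soma perimeter, emulating perisomatic
clustering. Distractors appear in one channel only and are kept clear of
clusters and opposite-channel distractors, so by construction they never
colocalize. Noise is additive Gaussian (sd 25) on a baseline (100) —
far below the 515/350 thresholds — with optional Poisson shot noise.
Scenes retain their ground truth, including each cluster's ideal
thresholded AND footprint computed with exactly the renderer's
arithmetic (float32 accumulation, baseline, rounding), so on noiseless
renders detection must reproduce counts *and* areas exactly.

Placement uses rejection sampling with pairwise clearance constraints so
distinct clusters' footprints cannot touch (detection can then be scored
against truth without matching heuristics). A cluster that finds no room
after 200 attempts across all somata is skipped and counted
(`n_skipped_clusters`). In crowded geometries (small images, large somata,
high density) the perimeter "capacity" of a soma ring saturates, and the
realized density falls below the nominal parameter and becomes coupled to
the soma count; at the default geometry (2,000 × 2,000 px panels,
150-px-radius somata, 8–12 somata, densities near 4.75–6.31) the skip
rate is ≲2%, which is why cohort-level tests use that geometry.
`make_cohort` draws panels per mouse (default 2), neuron counts per panel
(uniform 8–12), and alternates sex deterministically (M, F, …) within
each group so Group × Sex cells are never empty.

What the generator does **not** emulate: PSF/Airyscan optics, z-stacks,
stitching seams, photobleaching, spatially varying background,
between-mouse biological overdispersion (per-mouse counts are Poisson
given neuron count), or somata occluding signal. Passing tests therefore
demonstrate algorithmic correctness (thresholding, labeling, dedup,
normalization, statistics) and parameter recovery under the assumed
signal model — not robustness to real-tissue artifacts, which still
requires the visual QC outputs (`write_labeled_mask`) and manual-count
spot checks.

## Problem sizes and numerical choices

Tests run at desk scale: 2,000 × 2,000-px panels (the full 8,000 × 10,000
geometry remains a config option), 512 × 512 oracle masks at densities
0.005–0.05, 25-replicate cohort recovery, 2,000-replicate rank-test
calibration, and 50-replicate shuffle-null calibration. Default group
settings for synthetic cohorts are 4.75 (ET-like) vs 6.31 (CT-like)
clusters/neuron with 5 vs 7 mice; the CT-like group also gets a heavier
puncta-per-cluster tail (1.8 vs 1.5) so size-distribution shifts are
exercised alongside density differences.

Degenerate inputs are rejected loudly rather than coerced: zero-variance
channels for correlation, empty samples for tests, zero neurons for
normalization, zero familiar time for discrimination ratios, baselines at
or above a threshold for generation. Empty masks yield empty tables; an
empty overlap mask yields score 0 with a warning. All randomness flows
from explicit integer seeds (`numpy.random.default_rng`); the pipeline
fans one global seed into per-stage child seeds so stages are
independently rerunnable and whole runs are byte-reproducible.

## Known limitations

- Fixed global thresholds assume constant acquisition settings; no
  illumination-field correction is provided.
- Touching clusters merge (no watershed); the puncta-per-cluster estimate
  is a size ratio, not a segmentation.
- The two depth panels per mouse are summed, not averaged, before
  normalization; alternatives would change per-mouse values slightly.
- The shuffle-null mechanism and lag window for the cross-correlation are
  package choices (the conservative toroidal shift); observed peaks are
  comparable across runs only at fixed `max_lag`.
- Pooled-size tests inherit the pseudoreplication caveat above.
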