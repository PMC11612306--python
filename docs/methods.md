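# Methods

## Model and procedure

tcPALM treats the detection stream of one spatial cluster as a counting
process. During a clustering event of duration T, molecules are
recruited and detected at a roughly constant rate, so the cumulative
count N(t) rises approximately linearly over the ON-window and is flat
outside it; single-molecule photophysics in fixed cells instead spreads
detections over the entire acquisition. The analysis chain is:

localizations → DBSCAN spatial clusters → temporal bursts (blinking
cutoff) → cumulative-trace fit → gate ledger → summaries and rank test.

### Trace model

Each burst's cumulative trace (one point per occupied frame) is fitted
by least squares with

    N(t) = A · Φ((t − t₀)/w) + b · (t − t_first)

where Φ is the standard normal CDF. The correlation time is defined as
the 10–90 % rise time of the sigmoid, τ = 2 Φ⁻¹(0.9) · w = 2.5631 · w.
The trace model is not uniquely identifiable without constraints: on a
linear ramp the background term alone fits perfectly, leaving w
arbitrary. We therefore constrain

* 0 < A ≤ 2 · N_final — the sigmoid carries the majority of detections;
* t₀ ∈ [t_first, t_last] — the half-rise lies inside the observed
  burst, so τ describes the observed rise rather than an extrapolated
  sigmoid;
* 10⁻⁶·span ≤ w ≤ 10·span;
* 0 ≤ b ≤ 0.25 · N_final / span — background is a minority of in-region
  detections (inside a genuine cluster region the uniform background
  contributes a few detections at most; the bound mainly regularizes
  ramp-like fixed-cell traces).

Fits are deterministic: initialization at t₀ = empirical median
detection time, w = (t₉₀ − t₁₀)/2.5631, A = N_final, b = 0, refined by
bounded trust-region least squares; if the optimizer fails to converge
the initialization itself is reported (and its R² will normally fail
the gate). A trace concentrated in a single frame is the exact w → 0
step limit and is returned with τ = 0 and R² = 1. R² is computed as
1 − SS_res/SS_tot on the trace points.

The per-burst table also retains the raw burst span (last − first
detection time) next to τ, since "lifetime" can reasonably be read as
either; all gating and statistics use τ.

### Burst segmentation

Gaps strictly greater than the blinking cutoff split bursts; a gap
exactly equal to the cutoff merges ("maximum tolerated gap" reading).
The default cutoff is 100 frames (1 s): shorter cutoffs fragment
clustering events into bursts too small to fit reliably.

### Gate ledger

Order: R² ≥ 0.98 (inclusive) → subsample to 2500 bursts (seeded,
without replacement; if fewer are available all are kept and a warning
logged) → frequency filter (histogram bins [k·w, (k+1)·w), default
width 2 s; values in bins strictly below 20 % of the modal count are
removed; the modal bin is never removed) → live/fixed rule (live-like
iff τ < 20 s, strict; τ = 20 s is fixed-like). Each gate's drop count
is recorded and drops + retained always equals the input count. The
ledger is idempotent. The frequency filter is applied per condition;
the bin width is a package choice (no canonical value exists).

### Statistics

Because the "±" printed next to a median is ambiguous, summaries always
report both median ± MAD and mean ± SEM, labelled. The condition
comparison is the unpaired two-sided Wilcoxon rank-sum / Mann–Whitney U
test: exact null distribution when n₁+n₂ ≤ 20 with no ties, otherwise
the normal approximation with tie and continuity correction
(scipy.stats.mannwhitneyu supplies both regimes; correctness is checked
in the tests against a full enumeration of rank assignments).

## Synthetic data

The simulator emulates the study conditions directly in localization
space (no camera or PSF rendering): 10,000 frames × 10 ms over a 15-µm
square field, localization error σ = 15 nm.

* **Live preset** — 10 transient clusters, member-position scale
  σ = 60 nm, lifetimes uniform on 4–12 s (the regime in which observed
  small-cluster lifetimes fall), ON-starts uniform over the feasible
  range, centres rejection-sampled to ≥ 2 µm separation, 80 molecules
  per cluster recruited uniformly over the ON-window, 50 Hz uniform
  background. Uniform recruitment gives an approximately linear
  cumulative ramp — the cleanest test signal for the trace fit.
* **Fixed preset** — 200 immobile emitters placed uniformly, blinking
  as an alternating ON/OFF renewal process for the whole acquisition
  (no bleaching truncation, by construction of the control), so traces
  span most of the 100 s and fitted correlation times land well above
  20 s.
* **Blinking** — geometric (memoryless) ON and OFF durations in
  frames; defaults mean ON 1 frame, mean OFF 12 frames, mean 3
  re-activations per molecule before bleaching (live mode only), and a
  per-frame detection probability min(1, rate·Δt) with rate 100 Hz.
  The OFF mean is kept far below the 100-frame cutoff so that a
  persistent emitter yields a single temporal burst; molecule counts
  and duty cycles are not published for this system, so these defaults
  reproduce the qualitative regime (live τ in 5–10 s, fixed τ > 20 s),
  not any quantitative photophysics.

Every simulated detection carries `truth_cluster_id` (−1 for
background); readers tolerate its absence in real files. What passing
tests on these data do **not** show: robustness to drift, z-blur,
chromatic/registration error, heterogeneous backgrounds, overlapping
clusters, or non-uniform recruitment kinetics — none of which the
generator models.

## Numerical and design choices

* **DBSCAN defaults**: linking radius 100 nm, min 10 detections.
  Because each molecule contributes several detections within
  localization error, a 50-nm radius fragments peripheral molecules
  into satellite clusters; 100 nm links them while staying far above
  background density (50 Hz background ≈ 22 detections/µm², ~0.7
  expected neighbours per 100-nm disc). The tree algorithm is pinned
  (ball_tree) for speed on stacked near-coincident points; labels are
  identical to the default.
* **Diameter** = maximum pairwise member distance (convex-hull
  accelerated). This is the strictest "extent" reading and is
  sensitive to single attached outliers; it is recorded per cluster so
  alternative definitions can be compared downstream.
* **Boundary conventions**: diameter exactly 200 nm → large; gap
  exactly equal to the cutoff → merge; R² exactly 0.98 → retained;
  τ exactly 20 s → fixed-like; frequency exactly 20 % of modal →
  retained. Each follows the strict/inclusive wording of the
  corresponding rule.
* **Determinism**: every stochastic step takes an explicit seed;
  per-condition seeds are spawned from the pipeline seed, and re-running
  a pipeline with the same config and seed reproduces `summary.json`
  byte-for-byte (outputs embed the config hash and seed, never wall
  time).
* **Problem sizes** in the tests and acceptance script — 20 simulated
  acquisitions per preset for the live/fixed discrimination, 20
  constant-rate 8-s clusters for the τ-recovery check, 1000 random
  frame lists for the segmentation oracle, 500 null replicates at
  n = 40 vs 45 for rank-test calibration — are the package's default
  study conditions; they complete in a few minutes on one CPU.

## Known limitations

* Cluster selection is algorithmic (DBSCAN), not a reimplementation of
  any particular ROI-picking workflow; results depend on the linking
  radius in the usual DBSCAN ways.
* Fitting is per temporal burst, not per whole-ROI trace; a cluster
  with several well-separated events contributes several lifetimes.
* The 2500-burst normalization subsamples at random; two analyses of
  the same data with different subsample seeds differ (slightly) unless
  the seed is fixed.
* The frequency filter's bin width (2 s) is a convention; very small
  gated sets make the modal-bin criterion coarse.
* Fixed-cell R² values here are high (clean synthetic ramps fit well),
  so the live/fixed separation rests on the 20-s τ rule rather than on
  the R² gate; real fixed-cell data are noisier.
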