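# tcpalm

Time-correlated PALM (tcPALM) analysis of transient RNA polymerase II
clusters, from raw single-molecule localization tables to per-cluster
lifetimes and between-condition statistics.

## The problem

Live-cell PALM of Dendra2-tagged RPB1 records, over a 100-s acquisition
(10,000 frames at 10 ms exposure), one localization per detected
molecule per frame. RNA Pol II forms two kinds of nuclear foci: small
clusters (extent < 200 nm), transient assemblies whose lifetime tracks
transcription initiation, and large (> 200 nm) persistent clusters.
tcPALM extracts the *temporal* signature of a spatial cluster: the
cumulative detection count N(t) inside the cluster region rises
sigmoidally during a clustering event, and the rise time is the
cluster's lifetime. Isolated fluorophores in fixed cells blink for the
whole acquisition and produce slow ramps instead — the two regimes are
separated by the fitted correlation time.

This package is aimed at microscopists and image analysts who have
ThunderSTORM-style localization CSVs (or want a ground-truth synthetic
stand-in) and need a reproducible, scriptable version of that analysis.

## The method

1. **Spatial clusters** — DBSCAN on (x, y) localizations (linking
   radius 100 nm, ≥ 10 detections); cluster diameter = maximum pairwise
   member distance; small iff diameter < 200 nm.
2. **Temporal bursts** — per cluster, detections are merged into
   maximal runs whose inter-detection gaps are ≤ the maximum blinking
   cutoff (100 frames), absorbing Dendra2 dark states.
3. **Cumulative-trace fit** — each burst's N(t) is fitted by

   N(t) = A · Φ((t − t₀)/w) + b · (t − t_first),

   a Gaussian-CDF sigmoid plus a bounded linear background. The
   correlation time is the 10–90 % rise time, τ = 2 · 1.28155 · w.
4. **Gating** — fits with R² < 0.98 are discarded; conditions are
   normalized to a common burst count (2500) by seeded subsampling;
   lifetimes in histogram bins under 20 % of the modal bin frequency
   are removed; live-cell clustering is identified by τ < 20 s (fixed
   cells sit above).
5. **Statistics** — per-condition median ± MAD and mean ± SEM, the
   empirical cumulative distribution, and the unpaired two-sided
   Wilcoxon rank (Mann–Whitney U) test between conditions.

A synthetic-data module generates live-cell tables (transient clusters
with known ON-windows, geometric ON/OFF blinking, localization error,
uniform background) and fixed-cell controls (immobile emitters blinking
for the whole acquisition) with ground-truth sidecars, so the entire
pipeline is testable without any imaging data.

## Worked example

`examples/05_end_to_end.py` simulates two conditions whose true cluster
lifetimes are 6 s and 10 s and runs the whole pipeline:

```text
short: n=16  median tau = 5.26 s (MAD 0.62)
long: n=19  median tau = 9.45 s (MAD 1.65)
short vs long: p = 1.71e-06
```

The medians recover the order of the simulated lifetimes (a
constant-rate ON-window of length T yields a fitted 10–90 % rise time
somewhat below T), and the rank test separates the conditions. The
other example scripts cover each capability in isolation: simulation
(`01`), spatial clustering (`02`, prints the per-cluster diameter/class
table), single-burst fitting (`03`: `tau = 5.67 s` for a known 8-s
ON-window, `R^2 = 0.979`), and gating plus statistics (`04`, prints the
per-gate provenance ledger).

The same stages are scriptable from a shell via the thin `tcpalm` CLI
(`simulate`, `clusters`, `lifetimes`, `compare`, `run`).

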