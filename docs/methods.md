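# Methods

This note records the models, estimators, and numerical choices behind
`fhfquant`, and what the synthetic-data generators do and do not emulate.

## 1. Spectral-count interactome scoring

### Model

Proximity-labeling (BioID) experiments compare streptavidin pull-downs
from a bait-tagged cell line against a cytoplasmic-control line, with
peptide-level spectral counts as the abundance proxy. The quantification
chain is:

1. **Distributed spectral counts (dSpC).** A peptide shared by several
   proteins contributes its count to each protein in proportion to that
   protein's *unique* spectral count in the same replicate:
   `dSpC_k = uSpC_k + sum_shared sSpC * uSpC_k / sum_j uSpC_j`.
   When none of the sharing proteins has unique evidence in a replicate
   the proportional rule is 0/0; the count is then split equally, the
   symmetric choice that conserves totals. Per-replicate totals are
   conserved exactly (checked to 1e-9).
2. **dNSAF.** `dNSAF_i = (dSpC_i / L_i) / sum_j (dSpC_j / L_j)` with
   `L_i` the protein length in amino acids; each replicate's column sums
   to 1 (or is all zero for an empty run). dNSAF is therefore invariant
   to per-replicate rescaling of counts.
3. **Enrichment.** Per protein, fold enrichment is the ratio of bait to
   control average dNSAF, each average taken over replicates with nonzero
   dNSAF. A protein absent from every control replicate but present in
   the bait has infinite fold enrichment; the infinity is preserved in
   memory and in the main tables, capped (default log2 fold = 10) only in
   the exported display column, and written as the sentinel `inf` on disk.
4. **Significance.** A two-sample two-tailed t-test on the per-replicate
   dNSAF values (classic equal-variance Student's t by default; Welch
   optional; optional log2 transform). Degenerate inputs are resolved by
   the limits of the t statistic: zero variance in both groups with equal
   means gives p = 1, with different means p = 0 plus a `degenerate_test`
   flag.
5. **Hit filter.** `is_hit` iff (fold >= 3 OR control-absent) AND
   p < 0.05 AND nonzero dNSAF in >= 3 of 4 bait replicates. No
   multiple-testing correction enters the filter; a Benjamini-Hochberg
   q-value column is emitted for information only.
6. **Intersections and export.** Multi-bait hit sets are partitioned by
   exact membership subset (the counting behind multi-bait interaction
   diagrams), and node/edge tables are written for generic graph viewers;
   the tables round-trip losslessly.

### Zero replicates in the t-test

The default (`zero_policy="nonzero"`) tests only the replicates with
nonzero dNSAF on each side, falling back to the full vectors when either
side has fewer than two nonzero replicates (so an absent protein is still
tested against its zeros). The rationale: a replicate in which a protein
escaped detection carries no abundance measurement, and treating it as a
measured zero inflates the within-group variance enough that a protein
five-fold enriched in three of four replicates fails p < 0.05 — with one
zero among four otherwise-constant bait values the t statistic is bounded
near 2.1 whatever the abundance scale, below the 0.05 critical value at
6 degrees of freedom. This mirrors the nonzero-replicate convention
already used for the averages behind the fold ratio.
`zero_policy="include"` restores the measured-zero interpretation.

### What the generator emulates

`simulate_spectral_counts` draws peptide counts as Poisson with
protein-level rate `baseline_count_mean * L / mean(L)` (counts scale with
protein length at equal molar abundance — the assumption length
normalization exists to undo), multiplied by `enrichment_factor` for
planted interactors in bait replicates. Each protein carries
`max(2, L // 200)` unique peptides; a configurable fraction of peptides
is shared between random protein pairs; planted interactors drop out of
any single replicate (either condition) with probability `dropout_prob`.
Defaults are the 4-versus-4 replicate design with 500 background + 20
planted proteins, 10 expected counts per background protein, fivefold
enrichment, 10% sharing, and 10% dropout.

Not emulated: peptide misidentification, protein inference ambiguity
beyond two-way sharing, correlated replicate effects, the bait protein's
own dominance of the pull-down, and abundance-dependent detectability.
Passing recovery tests therefore demonstrate the correctness of the
scoring chain under idealized count statistics, not robustness to every
failure mode of real MS data.

Under these conditions the recovery ceiling is sharp: the 3-of-4
presence clause alone caps sensitivity at `0.9^4 + 4*0.1*0.9^3 = 0.948`
with 10% dropout, sampling noise at 10-count depth pushes realized fold
ratios below 3 for a few percent of planted interactors (composition
effects make the realized dNSAF ratio ~4.3 for a planted count ratio
of 5), and small-sample t noise removes ~2% more, leaving measured mean
sensitivity at 0.90 (with seed-set-to-seed-set variation of about
±0.015 at 20 simulations).

## 2. Single-molecule motility

### Event taxonomy

Traces are position-versus-time series along a microtubule, one per
landed molecule. With excursions measured from the running positional
extrema:

* **diffusive** — at least one excursion > 0.6 um in *each* direction;
* **processive** — not diffusive, net displacement >= 0.6 um (every
  reversal is then automatically <= 0.6 um);
* **static** — everything else.

Equivalently (and checked against this form by brute force), an upward
excursion > 0.6 um exists iff some ordered sample pair rises by more
than 0.6 um. The 0.6-um scale doubles as the static threshold so the
taxonomy has a single length scale. Whether the two opposite excursions
must be adjacent is ambiguous in the field's verbal definitions;
anywhere-in-trace is implemented. Classification runs on raw positions;
a centered moving-average smoothing window is available but off by
default.

### Segmentation, pauses, velocities

Processive events are split into constant-velocity segments in two
stages. Pauses are found first, directly on positions: maximal windows
of at least 3 frame intervals whose positional range stays below
0.1 um (about twice the default localization noise; both parameters
exposed). Windows split by a single noise excursion are coalesced when
the displacement across the gap is itself below the pause threshold.
The moving stretches between pauses are then segmented by bottom-up
merging of per-frame velocities (merge adjacent segments while their
velocity difference is below 0.2 um/s; absorb segments shorter than 3
intervals into the closer-velocity neighbor). Doing pause detection
before velocity merging prevents short bursts of motion from being
averaged into pauses and vice versa.

Segment velocity is displacement over duration; where a segment abuts a
pause, the slope is estimated after dropping the boundary interval
(which mixes paused and moving time within one frame) whenever at least
one interior interval remains. Velocities are reported as magnitudes,
from non-pause segments of processive events spanning more than five
frames; each segment of a multivelocity event contributes its own entry.
Run length is the summed absolute displacement of non-pause segments.

### Rates

* **Landing rate** = interior processive events (first sample after
  frame 0 and last sample before the final frame) divided by
  (microtubule length x movie time), summed across movies. The interior
  requirement makes the estimate independent of events that touch the
  movie boundaries, at the cost of a censoring loss for events whose
  runs would outlast the movie.
* **Pausing frequency** = pause segments across multivelocity events
  divided by total run length (undefined and flagged at zero run
  length).
* **Colocalized fraction** = fraction of processive events with
  second-channel signal on at least one sample (partial overlap counts).
* Group comparisons: Welch's t and Mann-Whitney (two-sided), via SciPy.

### What the generator emulates

`simulate_traces` lands events as a Poisson process
(`landing_rate_true * mt_length` per second per movie), assigns classes
by the configured fractions, and integrates processive runs as piecewise
linear paths: truncated-normal velocity, exponential run length (mean
4 um, floored at 0.8 um so every planted run exceeds the taxonomy
scale; runs are also truncated at the microtubule end), pauses planted
as a Poisson process along the run (0.2 per um) with durations of
4 frames plus an exponential remainder (mean 2 s) — at least one frame
above the analyzer's 3-frame pause definition, since sub-resolution
pauses are unrecoverable by any method at the given frame interval.
Diffusive events are Gaussian random walks (step SD 0.18 um/frame)
resampled until they satisfy the bidirectional-excursion rule; static
events hold position. Gaussian localization noise (default 0.02 um) is
added per frame and positions are clipped to the microtubule. Defaults
mirror a 3-minute movie at 0.4 s/frame on a 25-um microtubule,
0.8 um/s mean velocity, 50 movies.

For recovery checks the landing-rate ground truth is the generator-
implied *processive* landing rate, computed in closed form by
`expected_processive_landing_rate`: the raw rate times the processive
class fraction, the survival of the 0.6-um microtubule-end truncation,
and the movie-end censoring factor `1 - E[event duration]/T` that the
interior-event counting rule itself imposes. Because a two-standard-
error check on a single Poisson draw fails one seed in twenty by
construction, recovery tests pool three independently seeded datasets
(seeds 0, 1, 2) and test the pooled count.

Not emulated: photobleaching, stage drift, spot-linking errors, motors
passing each other, minus-end-directed runs (positions increase toward
the minus end so all planted runs are positive; reported velocities are
magnitudes anyway), and intensity information beyond a boolean second
channel.

## 3. ROI and tubule quantification

The centrosome-accumulation statistic is
`(I_centrosome / I_cell) / (A_centrosome / A_cell)`: exactly 1 for
uniform fluorescence, >1 for accumulation, invariant to global intensity
rescaling and to the area unit. ROI geometry (circle drawing, sum
projections, membrane masks) is upstream; this module consumes measured
intensities and areas, which is where the arithmetic begins. No
background subtraction is applied by default; a constant per-pixel
offset parameter is available.

A tubule track counts as motile iff it moved from its initial location
and exceeded 1 um in length at some point (strict inequality); per-cell
counts are summarized as the percentage of cells with strictly more than
a threshold (default 5) qualifying tubules. Group comparisons use the
Kruskal-Wallis omnibus test with Dunn's post hoc rank z-tests; Dunn's
test is implemented in-package (no packaged implementation is
available here) with the standard tie-corrected pooled-rank variance and
Bonferroni adjustment over the tested pairs (adjustment method
exposed; the field's common default). The ROI generator draws the
centrosomal intensity fraction as `accumulation_true x area fraction`
with multiplicative Gaussian noise, clipped so the centrosome never
exceeds the whole cell; with zero noise the ratio is recovered exactly.

## 4. Problem sizes and determinism

Every generator consumes a single integer seed through NumPy's
`default_rng`; identical configs give byte-identical tables. The test
suite uses derandomized property-based testing plus fixed seeds; the
spectral-count recovery checks run 20 simulations of 520 proteins
(4+4 replicates), motility recovery pools three 50-movie datasets
(~1,200 events), and the statistical tests are compared against
independent base-R implementations on 100 random datasets at 1e-6
relative tolerance. These sizes keep the full suite under a minute on
one CPU while leaving the stochastic checks adequately powered; the
acceptance script (`scripts/acceptance.py`) re-runs the same chains at
comparable sizes.

## 5. Known limitations

* The dNSAF chain assumes two-way peptide sharing in the generator;
  the distribution rule itself handles arbitrary sharing degrees.
* Pause detection is resolution-limited: pauses shorter than 3 frame
  intervals, or with positional range above the threshold (e.g., under
  localization noise well above 0.05 um), are not detected.
* The landing-rate estimator is negatively biased by design for events
  whose runs outlast the movie; comparisons should use the censoring-
  corrected expectation, as the recovery tests do.
* With strong noise the 600-nm taxonomy applied to raw positions can
  misclassify borderline events; the smoothing window exists for such
  data but changes the effective threshold.
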