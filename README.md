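# fhfquant

Quantitative analysis pipelines for experiments on FHF cargo-adaptor
complexes (FTS–Hook–FHIP, the ternary adaptors that couple cytoplasmic
dynein/dynactin to membrane cargo), with matched synthetic-data
generators so every stage can be validated against known ground truth.

The package covers the three measurement types such studies combine:

1. **BioID interactome scoring** (`fhfquant.proteomics`) — from
   peptide-level spectral counts to hit lists. Shared-peptide counts are
   distributed by unique evidence, length-normalized to the distributed
   Normalized Spectral Abundance Factor
   `dNSAF_i = (dSpC_i / L_i) / Σ_j (dSpC_j / L_j)`, compared to a
   cytoplasmic control as a ratio of nonzero-replicate averages, and
   filtered with the three-part rule: fold enrichment ≥ 3 (or absence
   from the control), Student's two-tailed t-test p < 0.05, and presence
   in ≥ 3 of 4 bait replicates. Multi-bait hit sets are partitioned by
   membership subset, and node/edge tables are exported for graph
   viewers.
2. **Single-molecule motility** (`fhfquant.motility`) — kymograph-derived
   traces are classified with the 600-nm excursion taxonomy (processive /
   diffusive / static), segmented into constant-velocity stretches with
   pause detection, and summarized as segment velocities (events > 5
   frames), run lengths, landing rate (interior events per μm·s),
   pausing frequency (pauses per μm of run), and two-color colocalized
   fraction, with Welch-t / Mann-Whitney comparisons.
3. **ROI and tubule quantification** (`fhfquant.imaging`) — the
   area-normalized centrosome-accumulation ratio
   `(I_cen/I_cell)/(A_cen/A_cell)`, motile-tubule counting (moved from
   origin and > 1 μm), percent-of-cells summaries, and Kruskal–Wallis
   with Dunn's post hoc test.

`fhfquant.simulate` provides seeded generators for all three data kinds
(spectral counts with planted interactors, traces with known velocity /
landing-rate / pause / colocalization parameters, ROI tables with a known
accumulation ratio) that emit ground-truth logs alongside the data.

## Worked example

```python
import numpy as np
from fhfquant.simulate import ProteomeSimConfig, simulate_spectral_counts
from fhfquant.proteomics import interactome_pipeline

sim = simulate_spectral_counts(
    ProteomeSimConfig(n_background_proteins=50, n_true_interactors=5, seed=42)
)
res = interactome_pipeline(sim.bait, sim.control, sim.proteins)
print(res[res.is_hit][["protein_id", "fold_enrichment", "p_value", "n_present_bait"]])
```

```
protein_id  fold_enrichment  p_value  n_present_bait
   INT0000         3.985265 0.003395               4
   INT0001         3.940489 0.000042               3
   INT0003         3.866293 0.000055               4
   INT0002         3.762750 0.002541               4
   INT0004         3.560400 0.000425               3
```

All five planted interactors (and nothing else) pass the filter: their
realized dNSAF fold enrichments sit near 4 (a planted count-level
enrichment of 5, compressed by dNSAF renormalization), each with
p < 0.05 and presence in at least 3 of 4 bait replicates.

The motility chain on ten simulated movies (0.8 μm/s planted velocity,
0.2 pauses/μm, 70% two-channel colocalization):

```python
from fhfquant.simulate import MotilitySimConfig, simulate_traces
from fhfquant.motility import MovieParams, events_from_table, summarize

cfg = MotilitySimConfig(n_movies=10, seed=42)
trace_sim = simulate_traces(cfg)
movie = MovieParams(cfg.frame_interval, cfg.n_frames, cfg.mt_length)
events = [e for _, sub in trace_sim.traces.groupby("movie_id")
          for e in events_from_table(sub, movie)]
s = summarize(events, [movie] * cfg.n_movies)
```

prints (via the fields of `s`):

```
processive=88 diffusive=2 static=23
median velocity 0.768 um/s | landing rate 1.93e-03 /um/s | pausing 0.201 /um | coloc 0.74
```

— the median velocity within 4% of truth, the pausing frequency within
1%, and the colocalized fraction near the planted 0.7.

A `fhfquant` command-line interface wraps the same chains
(`fhfquant simulate`, `interactome`, `motility`, `imaging`); see
`fhfquant --help`.

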