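# nanomon

Real-time monitoring of nanopore metagenome sequencing runs.

Nanopore sequencers deliver reads continuously while a run is in progress,
which makes it possible to follow a microbial community — a bioreactor, a
fermentation, a patient sample — *as it is being sequenced* instead of
after the fact. `nanomon` implements the monitoring core of such a system
for people who run 16S rRNA amplicon or shotgun (WGS) nanopore experiments:

- **Streaming FASTQ QC and filtering** — per-read mean quality via
  error-probability averaging, batch statistics (N50, base counts, quality
  quartiles), and the default length/quality presets
  (16S: keep 1–2 kb reads; WGS: keep ≥ 2 kb; both at mean quality ≥ Q10).
- **Taxonomic profiling with EM refinement** — an in-memory canonical
  k-mer classifier (default k = 15) over a user-supplied reference set,
  with ambiguous reads redistributed by a multinomial-mixture
  expectation–maximization and conservative per-read LCA assignment.
  External profilers can plug in via the compatibility-matrix interface.
- **A time-series sample store** — timestamped samples keyed by
  (project, sample), counts tables per taxonomic rank, sequencing-effort
  normalization, and the dashboard's top-N + "Other" reduction.
- **Dashboard statistics** — Shannon/Simpson alpha diversity, Bray–Curtis
  beta diversity with classical PCoA, Pearson/Kendall/Spearman
  taxonomy–metadata correlations, and horizon-plot deviation series.
- **A polling directory watcher + CLI** — each FASTQ batch the sequencer
  drops into the run directory is processed exactly once
  (filter → classify → store → re-export), surviving restarts via a
  content-digest manifest.
- **A deterministic synthetic-data generator** — references, taxonomies,
  reads, abundance time series with changepoints, and timed fixture runs,
  so the whole pipeline is testable offline.

## The statistics at the core

Raw counts `c_r` are normalized by each sample's aligned bases `b` and a
scaling factor `f` (the mean of `b` across the samples being compared):

    c_n = c_r / b · f

Alpha diversity uses `H = −Σ p_i log2 p_i` and `D = 1 − Σ p_i²`; beta
diversity is the Bray–Curtis dissimilarity
`d(u, v) = Σ|u_i − v_i| / Σ|u_i + v_i|`, embedded by PCoA (Gower
double-centering of `−½ d²` plus eigendecomposition). Correlations are
Pearson `ρ = cov(X, Y)/(σ_X σ_Y)`, Kendall `τ = (C − D)/(C + D)` (tau-b tie
handling by default), and Spearman `r_s = ρ(R(X), R(Y))`. The EM update is
`γ_rt ∝ a_t w_rt` (per-read responsibilities), `a_t = mean_r γ_rt`, with
pruning of taxa below 1e-5 and renormalization. Metagenome-assembled
genomes are retained at `completeness > 80 %, contamination < 10 %`
(pipeline rule) or `≥ 90 % / < 5 %` (MIMAG high-quality).

## Worked example

`examples/02_profile_community.py` simulates 1,000 reads at a 70/30
mixture of two synthetic species, classifies and EM-refines them:

```
true draw: {4: 0.701, 5: 0.299}
  Genus_1 species_1      0.701
  Genus_1 species_2      0.299
unclassified fraction: 0.000
genus-level: {'Genus_1': 1.0}
```

The recovered abundances equal the realized multinomial draw because at
k = 15 the synthetic references share no k-mers, so no read is ambiguous;
the EM's job on real data is exactly the reads that are.

`examples/04_watch_directory.py` stages a 3-batch synthetic run and polls
it in:

```
poll: ingested ['sample_t00_20240101T000000']
poll: ingested ['sample_t01_20240101T010000']
poll: ingested ['sample_t02_20240101T020000']
after restart, rescan ingests: [] (exactly-once)
stored samples: 3
```

The other examples cover filtering/QC, the full dashboard statistics
stack on a time series with a 10× community shift (alpha diversity drops
from ≈2.5 to ≈1.4 bits at the changepoint; PCoA axis 1 separates the two
regimes at 92 % variance explained), and MAG quality filtering.

A `nanomon` console command wraps the same library surface
(`init`, `watch`, `analyze`, `stats`, `export`, `simulate`); run
`nanomon --help`.

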