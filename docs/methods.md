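# Methods

## Scope and model of a run

`nanomon` models a sequencing run as a stream of FASTQ batches landing in a
directory. Each batch becomes one timestamped *sample* of one *project*;
the pipeline per batch is fixed: parse → QC statistics → length/quality
filter → k-mer classification → EM abundance refinement → store → refresh
exports. Everything downstream (tables, diversity, ordination,
correlation, horizon series) is a pure function of the store, so
incremental and batch processing provably converge to the same outputs.

## Read QC and filtering

Per-read quality is the PHRED transform of the mean per-base error
probability, `−10·log10(mean_i 10^(−q_i/10))` — the long-read convention
(Filtlong, NanoPlot), chosen because an arithmetic mean of PHRED scores
overstates reads with low-quality tails. Batch mean quality pools error
probabilities over all bases; quality quartiles are quartiles of the
per-read means. The N50 is the length-weighted median of the read-length
multiset.

Filter presets: 16S amplicon keeps reads in [1000, 2000] bp, WGS keeps
≥ 2000 bp, both at mean quality ≥ Q10. Boundary semantics are strict
removal ("shorter than", "below"), so reads exactly at a threshold pass; a
1e-9 epsilon in the quality comparison absorbs float rounding (a
uniformly-Q10 read evaluates to 9.999999999999998). Removal categories are
assigned by the first failing rule in the order short → long → quality so
the report partitions the input exactly. QC statistics default to the raw
input (pre-filter), since they describe what the sequencer produced; the
functions compose either way.

FASTQ parsing is Biopython's FastqGeneralIterator behind a wrapper that
enforces the strict 4-line Phred+33 dialect, auto-detects gzip from magic
bytes, and converts failures into parse errors naming the record index.

## Classification and EM abundance refinement

The shipped classifier is a didactic in-memory canonical k-mer counter:
every canonical k-mer (lexicographic min of k-mer and reverse complement)
of every reference maps to the set of source taxids, and a read's weight
for taxon t is the count of its canonical k-mers found for t. Default
k = 15 balances specificity (random 15-mer collisions between ~1.6 kb
references occur with probability ~2·10⁻³ per pair, and the synthetic
generator rejection-samples them to zero) against error tolerance (at a 2 %
substitution rate a k-mer survives intact with probability 0.98¹⁵ ≈ 0.74,
leaving hundreds of informative k-mers per kilobase). The classifier is a
stand-in interface, not a competitor to production profilers: any tool that
can emit per-read candidate weights can inject a `CompatibilityMatrix`.

Abundances come from a multinomial mixture: community abundances `a_t` are
mixture weights and the k-mer hit counts `w_rt` are unnormalized
compatibility likelihoods. E-step: `γ_rt = a_t w_rt / Σ_t' a_t' w_rt'`;
M-step: `a_t = mean over classified reads of γ_rt`. Initialization is
uniform over taxa with any nonzero column; convergence is
`max|Δa| < 1e-6` or 100 iterations; taxa ending below 1e-5 are pruned and
the mass renormalized. The log-likelihood `Σ_r log Σ_t a_t w_rt` is
non-decreasing (a property test asserts it per iteration). Reads with no
index hits form the unclassified fraction; profile masses satisfy
`Σ p_i + unclassified_at_rank + unclassified_fraction = 1`.

Per-read assignments are reporting-only: each classified read maps to the
LCA of all taxa within one k-mer of its maximum weight (near-ties are
treated as ties because one k-mer of weight is within noise). Both the EM
posterior (default) and the LCA read-count fractions are exposed, since
profilers differ in which they report.

The aligned-base proxy `b` used for normalization is the total bases of
classified reads; the store labels which flavor of `b` a sample carries so
externally profiled samples can supply profiler-reported aligned bases
instead.

## Store and normalization

Samples are keyed by (project_id, sample_id); upserts are idempotent and
last-write-wins, which makes store state independent of arrival order.
Persistence is a single JSON-lines file — deliberately simple, no server
database. Naive timestamps are treated as UTC.

Counts tables put samples (chronological) in rows and taxa in columns;
counts are profile mass scaled so each row sums to the sample's
classified-read count. Normalization: `c_n = c_r / b · f` with
`f = mean(b)` over the samples in the table — `f` is scoped to the table,
so it depends only on which samples are compared, never on which taxa,
making normalization commute with taxa subsetting. The top-N reduction
ranks taxa by total across samples (ties broken lexicographically for
determinism) and folds the remainder into "Other", preserving row sums.

MAG retention: the pipeline rule is strict (completeness > 80,
contamination < 10); the MIMAG high-quality rule is completeness ≥ 90 and
contamination < 5. The completeness boundary mode is explicit
(`strict`/`inclusive`) because the two rules read their boundaries
differently.

## Dashboard statistics

Diversity is computed on abundances renormalized over classified mass;
unclassified reads are excluded since they carry no taxon identity.
Shannon uses log2 (units: bits). Bray–Curtis, PCoA, and all three
correlation coefficients are implemented natively from their defining
formulas; scipy and scikit-bio implementations serve as independent
cross-checks in the test suite only. PCoA clamps negative eigenvalues
(non-Euclidean distance input) to zero and reports them; variance
explained is relative to the clamped spectrum.

Kendall's tau defaults to tau-b (ties corrected in the denominator,
matching the standard analysis stacks); a "printed" mode computes
`(C − D)/(C + D)` with tied pairs excluded, and the result records which
mode produced it. Spearman uses average ranks. No p-values are produced —
the dashboard reports coefficients.

Horizon series: `vs_mean` (deviation from the series mean; the default, as
used for per-taxon deviation charts) and `vs_previous` (successive
differences, first point 0) are both provided since both conventions are
in circulation. Bands slice `[0, max|dev|]` into `n_bands` (default 4)
equal intervals; a constant series yields all-zero deviations and bands.

## Watcher

Polling, not filesystem events, for portability; default poll interval
5 s. A file is ingested when its size is identical immediately before and
after the read — a still-growing batch is deferred to the next poll.
Exactly-once is enforced by a JSON manifest keyed by path with a SHA-256
content digest: a restart resumes without reprocessing, a re-delivered
identical file is skipped, and new content under an old path (digest
change) is processed as a fresh sample. Malformed FASTQ is quarantined in
the manifest as failed rather than retried forever; unreadable files are
logged and skipped. Sample identity is the filename stem; the timestamp is
parsed from a `_YYYYMMDDTHHMMSS` name suffix when present, else the file
mtime. The reference index is built once per monitor and held in memory.

## Synthetic data

The generator emulates a small full-length 16S amplicon time series:
default 3 genera × 2 species under one phylum, 1.6 kb uniform-random
references (rejection-checked to share no canonical 15-mers), reads of
1200–1600 bp (16S) or 2000–10000 bp (WGS), substitution-only errors at
2 %, and a two-level quality model (90 % of bases Q18, 10 % Q7, mean
≈ Q14.7) so everything passes the Q10 filter the way a healthy run would.
Time series draw a baseline composition from a Dirichlet, multiply
selected taxa by an effect from the changepoint onward, renormalize, and
add per-timepoint Dirichlet noise at concentration 200 (mild compositional
jitter); one metadata variable tracks a chosen taxon's abundance linearly
with optional Gaussian noise. Randomness is a PCG64 generator seeded per
(seed, stream) pair, so outputs are byte-identical across platforms for a
given spec.

What the generator does *not* emulate — indels and homopolymer errors,
quality autocorrelation, chimeras, shared k-mers between related taxa,
databases with thousands of references — bounds what passing tests show:
they validate the algorithms' contracts and statistical behavior, not
classifier accuracy on real nanopore data.

## Problem sizes and numerical choices

Tests and the acceptance script use deliberately small instances — 6-taxon
reference sets, 1000-read recovery runs, 3-batch watcher fixtures,
correlation series of n ≤ 50 — sized so the full suite completes in well
under a minute while still leaving the stochastic checks statistically
meaningful (a 1000-read multinomial at 0.7 has σ ≈ 0.014, against a ±0.03
recovery band). Seeded RNGs make every stochastic assertion reproducible.
Degenerate inputs are defined rather than left to chance: empty FASTQ
batches yield zeroed QC with flagged-missing means, an all-unclassified
matrix yields unclassified_fraction 1 with an empty profile, zero-variance
correlation inputs yield flagged-missing (NaN) coefficients, and
Bray–Curtis on two all-zero vectors is an error.

## Known limitations

The k-mer classifier ignores k-mer multiplicity within a reference and
does not model read error rates in the EM likelihood. EM abundances are
read-fraction, not genome-size-corrected. The store is single-process;
concurrent monitors over one store file are not supported. PCoA is exact
(dense eigendecomposition), fine for hundreds of samples, not tens of
thousands.
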