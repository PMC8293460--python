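# Methods

## Motif scanning and enrichment

A mature miRNA sequence of length L over {A, C, G, U} has L − k + 1 k-mer
windows (k = 4 by default). Every window position is tested independently
against the motif set, so overlapping occurrences are all counted:
`UUGUUU` contributes one occurrence each of UUGU, UGUU and GUUU. Because
the motifs are distinct k-mers of equal length, a single window can match
at most one motif, and the per-sequence total is both the sum of per-motif
counts and the number of motif-bearing windows. This window convention is
the only one consistent with per-miRNA tabulations in which a six-base
G/U run yields three distinct motif counts.

Enrichment treats the 4-mer window as the sampling unit. With N background
windows of which K carry a motif, and n foreground windows of which k
carry one, the reported p-value is the hypergeometric upper tail
P(X ≥ k), X ~ Hypergeom(N, K, n), including the observed point mass. The
tail is evaluated with `scipy.stats.hypergeom.sf`, which works on
log-gamma terms and is stable at N ~ 5 × 10⁴. Two approximations are
inherited from the window formulation and documented rather than patched:
windows within a sequence overlap and are not independent, and the
foreground windows are by default *not* removed from the background (the
comparison is against the entire background set; `subtract_foreground=True`
removes them). A per-sequence formulation (`unit="sequence"`, counting
sequences with at least one motif) is provided as an alternative unit.

## Exosomal miRNA differential abundance

The pipeline is a state machine raw → normalized → log2; each stage
refuses inputs in the wrong state, so double normalization or filtering of
raw counts is impossible.

1. **Normalization.** Each sample's counts are divided by the sample's
   total count, then by the sample's (total-normalized) value of a
   designated stable reference miRNA — miR-26a-5p, an established
   endogenous control for exosomal miRNA. The reference row becomes
   exactly 1.0 everywhere and the result is invariant to per-sample
   library-size rescaling. Algebraically the two steps reduce to dividing
   by the reference count; the explicit two-step form mirrors the
   field-standard workflow and keeps intermediate totals inspectable.
2. **Log transform and abundance filter.** Values become
   log2(x + pseudocount). The default pseudocount is *adaptive*: half the
   smallest positive normalized value. On the reference-ratio scale,
   typical values span roughly 10⁻³–10, so any fixed pseudocount of order
   1 would dominate weakly-expressed miRNAs and shrink every fold change
   toward 1; the adaptive choice admits zeros while perturbing expressed
   features negligibly. A miRNA is retained iff there is at least one
   group in which it strictly exceeds the per-sample 25th-percentile
   threshold in every sample of that group. Thresholds are computed per
   sample across all miRNAs of that sample, on the log scale by default —
   retention is identical on the raw scale (`threshold_scale="raw"`)
   because log2(x + c) is monotone.
3. **Testing and selection.** Per miRNA, a one-sided Welch t-test of
   mean(epileptogenic) > mean(non-epileptogenic) on log2 values
   (pooled-variance optional via `equal_var=True`). Linear fold change is
   2^(difference of group means on the log2 scale). Candidates require
   p ≤ α (0.05) and FC ≥ 1.5; no multiple-testing correction is applied,
   matching the selection rule the pipeline reproduces. Zero-variance
   rows are flagged `degenerate` with p forced to 1 (equal means) or 0/1
   by sign. Output is sorted by fold change descending.

## Expression-panel induction analysis

**Normalization.** Per-sample scale factors equalize the geometric mean of
housekeeping genes (all genes when none are given) across samples,
followed by log2 with a 0.5 pseudocount on the counts scale. This is a
transparent stand-in for proprietary panel-normalization software: it
reproduces the removal of per-sample scale, not any proprietary internals,
and pathway scores built on it are interpreted qualitatively
(direction of dose trends), never numerically against external software.

**Differential expression** is a two-sided Welch t-test per gene on log2
values against the control condition, with significant genes partitioned
into increased/repressed by sign. Designs with only two replicate wells
per dose are accepted but flagged low-power in the run summary: at noise
sd 0.25 log2 and n = 2 + 2 the Welch test has ≈ 2 degrees of freedom and
only ~30% power at a 2-fold effect, so planted-recovery tests compare
detection counts against a noncentral sampling oracle rather than the
planted totals.

**Dose response** reports per-gene condition means in dose order and a
strict-monotone-increase flag; no formal trend test is computed.

**Pathway scores** standardize each gene across samples (sd via ddof = 1;
zero-sd genes score 0) and average z-scores over pathway members present
on the panel; missing members are reported. The score of a union of
disjoint pathways is the size-weighted mean of the parts.

**Gene-set CDF shift.** For a tissue experiment with a reference condition
and two groups, each gene's log2 fold change per group is the difference
of group mean and reference mean (group-mean formulation; per-sample fold
changes are not used). The two per-gene fold-change vectors are compared
with a two-sample, two-sided Kolmogorov–Smirnov test — asymptotic by
default, `ks_method="exact"` for small sets. Note that both vectors share
the reference mean and, in paired designs, possibly per-gene biology, so
null p-values on such data are conservative rather than exactly uniform;
the calibration tests therefore use independently drawn groups and the
exact method (the discrete statistic's exact p-values are conservative by
construction, with tail rates at nominal levels).

Gene symbols are matched case-insensitively (both sides uppercased)
throughout, since panel exports vary in case.

## Network hubs

Edge lists are ingested as undirected simple graphs: endpoint order is
normalized, duplicates collapse, self-loops are dropped with a warning.
Degrees are tabulated per node (networkx), nodes with degree ≥ 1 form the
interconnected set, and hubs are ranked by degree descending with
lexicographic tie-breaks for determinism. Server-side interaction-
enrichment statistics of PPI databases are deliberately not reimplemented
— they depend on the server's background degree model — so the module
consumes exported edge lists (optional third score column with
`--min-score` filtering).

## Synthetic data

Every generator is a pure function of a `SimulationConfig` (seed
mandatory); outputs are byte-reproducible and each generator returns a
manifest of planted truths, so recovery tests are self-contained. Defaults
encode the study conditions the pipeline targets:

- **Sequences**: 2,656 background miRNAs of length 19–24 with ~1.45% of
  windows carrying a TLR7/8 motif; a 37-sequence foreground at ~2.55%
  (matching window frequencies of 718/49,418 and 18/707). Bases are
  uniform over {A, C, G, U}; motif counts per sequence are binomial in the
  window count and planted at non-overlapping positions. In exact-density
  mode the base sequence is rejection-sampled motif-free and planting is
  re-drawn if junction effects create extra motifs, so realized counts
  equal planted counts (density 0 ⇒ exactly zero motifs).
- **miRNA counts**: two groups of 3 samples; log-normal baselines
  (log2 ~ N(8, 2)); 37 planted features with fold changes log-spaced over
  1.5–17.4 applied in the epileptogenic group; within-group noise sd 0.3
  log2; an abundant reference feature with sd 0.05; 100 low-abundance
  features (log2 ~ N(0, 0.3)) exercising the 25th-percentile filter;
  per-sample library sizes varying 2-fold; values rounded to integer
  counts.
- **Panels**: 770 genes. Cells design: control / 20 / 40 µg·mL⁻¹ doses,
  two replicate wells each, 84 genes planted up (+1 log2 at full dose,
  scaled by dose fraction, so they are dose-monotone in expectation) and
  21 down (−1 log2), noise sd 0.25 log2. Tissue design: 3 reference, 5
  non-epileptogenic, 5 epileptogenic samples; an 84-gene set with
  per-gene induction spread 0.5 log2 shared between tuber groups plus a
  0.6 log2 epileptogenic shift.
- **Graphs**: 64 nodes, hubs SQSTM1 (degree 12) and CDKN1A (degree 11)
  attached to distinct non-hub nodes over an Erdős–Rényi remainder with
  mean degree 2. Explicit hub attachment (rather than a full
  configuration model) guarantees the planted degrees without
  multi-edge/self-loop repair, while leaving non-hub degrees small.

What the generators do *not* emulate: sequencing-error and read-level
effects, count overdispersion beyond log-normal noise (a negative-binomial
variant is a possible extension), batch structure, correlated genes, and
the paired biology of real tuber tissue. Passing recovery tests therefore
demonstrate correctness of the implemented procedures at their stated
operating characteristics, not performance claims on patient data —
in particular, counts that depend on undeposited patient samples
(numbers of retained/selected/DE genes) are covered by operating-
characteristic tests, not by numeric reproduction.

## Numerical and interface choices

- Welch rather than pooled t-tests by default (robust to unequal
  variances; pooled available by flag).
- Percentile thresholds use linear interpolation (pandas `quantile`
  default); the retention rule is strict (`>`), so a feature exactly at
  the threshold is excluded.
- Hub and fold-change orderings break ties deterministically
  (lexicographic / stable sort).
- Acceptance-style simulations in the test suite use scaled problem sizes
  (e.g. 120–400-feature matrices, 40–200 replicates per property), chosen
  so each operating characteristic is measured with binomial error well
  inside its asserted bound.
- FASTA I/O uses two-line records; ids are the header token up to the
  first whitespace. DNA-alphabet input is mapped T→U by default
  (`rna_strict` rejects it) because public mature-miRNA FASTA ships U
  while many user exports ship T.
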