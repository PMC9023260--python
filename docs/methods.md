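# Methods

## Scope and data model

The package starts where read processing ends: its inputs are a set of
3′UTR sequences (FASTA, `gene|transcript` headers), a
differential-expression summary table (TSV with `gene_id`, `read_support`,
`log2fc`, `padj`) produced by a standard DE tool, and gene-id lists for
overlap testing. It does not align reads, count features, or fit a DE
model, and it does not extract 3′UTR coordinates from genome annotation.

Sequences are normalised at ingest to uppercase RNA over {A, C, G, U}
(T → U); anything else is rejected with the record and position named.
When a gene has several 3′UTR isoforms the longest is analysed; equal
lengths are resolved by lexicographically smallest transcript id — the
choice is a convention, required only for determinism.

DE categories follow the standard rule: a gene is *excluded* below 10 mean
reads; among detected genes, *up* means log₂FC > 1 with adjusted p < 0.05,
*down* the mirror image, everything else *unchanged*. Genes with missing
log₂FC or adjusted p are *unchanged*, not excluded: DE tools emit NA for
independent-filtering casualties that are nonetheless detected, and the
unchanged set is "detected but not differentially expressed".

## Motif scanning

Motifs are exact k-mers (AUUUA, UAUUUAU, GAAA). Occurrences are counted
**overlapping** by default: class II AREs are blocks of overlapping
pentamers (UUAUUUAUU contains two AUUUA), and non-overlapping counting
would undercount exactly the strongest elements. A non-overlapping mode is
exposed for comparison. Note `n_5mer ≥ n_7mer` always, since every
UAUUUAU contains an AUUUA at offset 1.

Motif deletion removes the leftmost occurrence and rescans until none
remains. Iteration matters: excising an occurrence can join its flanks
into a fresh occurrence, and a single pass would leave it behind. The
result is guaranteed motif-free, with a length decrement that is a
multiple of the motif length — deleting three isolated 7-mers from a
2529-nt sequence gives exactly 2508 nt.

Context windows default to a 12-nt flank per side (31-nt windows around
the 7-mer), clipped at sequence edges. Inter-motif distance is the gap
from one hit's end to the next hit's start, so an immediately adjacent
downstream motif has distance 0 and overlapping hits have negative
distances.

The probe classifier implements the binding rule established by the
gel-shift panel: predict binding iff the probe contains at least one
UAUUUAU. The packaged 17-probe panel stores each probe's reported outcome
and whether that outcome is stated in the source text (9 probes) or
inferred from the single-7-mer binding observation (8 probes); the
classifier is 100% concordant on the stated outcomes.

## ARE scoring

The score combines the three classic ARE features — pentamer count,
pentamer proximity, and local A/U context:

```
S = w_p · n_pentamers + w_c · n_cluster_pairs + w_a · n_AU_flank_sides
```

* every overlapping AUUUA occurrence contributes `w_p` (default 1.0);
* every consecutive pentamer pair whose gap (next start − previous end) is
  ≤ `cluster_max_gap` (default 10 nt) contributes `w_c` (default 1.5)
  once — per pair, not per cluster, which keeps the proximity term exactly
  testable (appending an isolated pentamer adds exactly `w_p`; the score
  is non-increasing in the separation of a pentamer pair; doubling all
  weights doubles every score);
* each pentamer contributes `w_a` (default 0.5) per flank side whose 5-nt
  window has A/U fraction ≥ 0.8; shorter edge flanks are evaluated on the
  available bases and an empty flank never qualifies.

This is an AREScore-*like* function: it re-parameterises the published
algorithm's three features, it does not reproduce that program's numbers
(its constants are not public). All constants live in `AREScoreParams`
and are echoed into every output file. No numeric score from the original
tool is asserted anywhere; the scoring module is validated by its
invariants and by cohort-level rank behaviour (planted-enriched categories
score higher on average).

## Enrichment statistics

**Kolmogorov–Smirnov.** The statistic is the exact sup-gap between the
two ECDFs, evaluated at tie-group boundaries, so heavily tied count data
are handled exactly. The default p-value is asymptotic: the Kolmogorov
distribution at `sqrt(n1·n2/(n1+n2)) · D`. With discrete counts this is
conservative (the continuous null overstates D's spread under ties), so a
permutation mode is provided as the safer choice: when the number of
distinct label splits C(n1+n2, n1) is at most `n_perm` every split is
enumerated and the p-value is exact (the fully separated n=m=2 case gives
exactly 2/6); otherwise `n_perm` seeded random splits give the add-one
estimate (1 + #{D* ≥ D})/(1 + n_perm). The three pairwise category
comparisons (up–unchanged, down–unchanged, up–down) are reported with raw
p-values; no multiple-testing correction is applied, and an empty
category yields a flagged missing comparison rather than an error.

**GAAA binning.** Counts are summarised in five bins {0}, (0,10],
(10,20], (20,30], (30,∞) — left-open right-closed, so a count of exactly
10 falls in (0,10]. Each category summary also carries the fraction of
genes with count > 10 and the fraction with at least one occurrence.

**Overlap testing.** For lists of sizes n and m in a universe of N, the
observed overlap k is compared with its expectation nm/N (fold
enrichment k/(nm/N)). Two tails are reported: the exact hypergeometric
upper tail P(K ≥ k) (scipy) and the continuity-corrected normal
approximation Φ̄((k − ½ − nm/N)/σ). The exact tail is the oracle; the
approximation is accurate to <0.01 once the expected overlap is in the
tens (it converges to the exact tail as N grows at fixed proportions) but
is visibly off (≈0.06) in the Poisson-like regime where the expected
overlap is ~1 — use the exact tail there. Ids outside the universe are
dropped with a logged warning.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes — not
real transcriptomes. Defaults: 549 up / 603 down / 15 684 unchanged
genes; 3′UTR lengths log-normal with median 800 nt and log-sd 0.8
(a realistic mammalian 3′UTR length spread); i.i.d. background with A/U
fraction 0.55 (3′UTRs are AU-biased; A=U and G=C within the two groups);
planted 7-mer rates 1.2/gene in the up category vs 0.3 elsewhere; lone
pentamers at 0.5/gene everywhere; GAAA at 4/gene (up) vs 2 (others),
mirroring the modest co-regulation shift; DE effect |log₂FC| mean 2.5
with adjusted p drawn below 0.05 for DE genes and above for unchanged,
and read support always above the detection threshold so the emitted
table recategorises to exactly the configured sizes.

Planted counts are Poisson by default (enrichment is distributional, as
in real cohorts where many genes lack the motif entirely); a `fixed` mode
plants deterministic counts for exact tests. Motifs are written at
uniform positions without mutual overlap (bounded rejection sampling;
drawn lengths are raised to fit the planted payload when necessary), so
the recomputed census always dominates the planted truth and, with no
planting, the mean occurrence count matches the i.i.d. expectation
(L−k+1)·∏p exactly by linearity. One seeded stream drives every draw, so
cohorts are byte-identical across runs.

What the generator does **not** emulate: positional motif clustering,
secondary structure, composition heterogeneity along the UTR, isoform
structure, and DESeq2's dispersion model. Passing recovery tests
therefore demonstrates that the pipeline's statistics behave correctly
under its own assumptions, not that those assumptions hold for any real
transcriptome.

## Calibration and power checks (problem sizes)

The simulation-backed checks use these sizes, chosen to make each effect
decisive while keeping the default run quick:

* **Power:** 100 cohorts of 500 up vs 15 000 unchanged genes (rates 1.2
  vs 0.3); the up-vs-unchanged KS test on 7-mer counts is significant at
  p < 0.05 in ≥ 99 of 100 cohorts.
* **Null calibration:** 200 cohorts of 400 vs 400 genes (median UTR
  300 nt) with equal planting rates; permutation p-values (999 splits)
  for the GAAA comparison are consistent with U(0,1) by a KS test at
  α = 0.01. The permutation mode is used here deliberately: the
  asymptotic p is conservative under ties by construction, so its null
  distribution is not uniform and would not be a meaningful calibration
  target.
* **Overlap null:** 1000 random 300-vs-300 draws from a 2000-gene
  universe; the mean fold enrichment is within 3 standard errors of 1.
* The asymptotic KS p-value's rejection rate on continuous
  same-distribution pairs (n = 500 per side, 2000 replicates) sits within
  3 standard errors of the nominal 5%.

## Pipeline orchestration

The `aremotif` CLI maps each stage to a subcommand (`scan`, `score`,
`classify-probes`, `enrich`, `overlap`, `windows`, `simulate`, `run`).
`run` executes everything end to end from a plain-text `key = value`
configuration file, overridable by flags. TSV and JSON outputs carry a
provenance header (package version, configuration hash, seed, and every
threshold); FASTA outputs stay header-free because comment lines break
standard FASTA parsers, and a `run_manifest.json` carries the provenance
for the whole bundle instead. The configuration hash covers analysis
parameters only (not the output location), so re-running an identical
configuration reproduces byte-identical non-log outputs. On any stage
failure the partial outputs are removed and the process exits non-zero
(2 for input/schema errors, 3 for generation/statistics errors).

## Known limitations

* Motifs are exact k-mers; degenerate/IUPAC patterns and position weight
  matrices are out of scope, as is RNA secondary structure.
* The ARE score is a documented re-parameterisation, not the published
  program; absolute values are not comparable with that tool's output.
* The asymptotic KS p on count data is conservative; prefer the
  permutation mode when p-values near the threshold matter.
* The normal-approximation overlap p degrades for expected overlaps near
  1; the exact tail is always reported alongside it.
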