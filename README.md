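# aremotif

Motif-level analysis of 3′UTR regulation by the ZFP36 (tristetraprolin)
family of RNA-binding proteins. ZFP36-family proteins destabilise mRNAs
through AU-rich elements (AREs) in their 3′UTRs; gel-shift evidence shows
that ZFP36L2 in particular requires a minimal 7-mer element, **UAUUUAU** —
a lone AUUUA pentamer is not sufficient. Its antagonist ELAVL2 stabilises
transcripts through **GAAA** motifs, so transcripts carrying both motif
types are candidates for co-regulation.

`aremotif` packages the sequence analysis that sits downstream of a
differential-expression (DE) experiment on such a system:

* **Motif census** — overlapping occurrence counts of AUUUA, UAUUUAU, and
  GAAA in the longest annotated 3′UTR per gene, plus window extraction
  (~31 nt context around each 7-mer) and inter-motif spacing.
* **Binding-rule classifier** — predicts `bind`/`no_bind` for an RNA probe
  from the 7-mer rule; the 17-probe EMSA panel used to establish the rule
  ships as a packaged fixture.
* **ARE scoring** — an AREScore-like score
  `S = w_p·n_pentamers + w_c·n_cluster_pairs + w_a·n_AU_flanks`
  combining pentamer count, pentamer proximity (consecutive pairs within a
  gap threshold), and A/U-rich flank context. All constants are explicit
  parameters, serialised into every output.
* **Enrichment statistics** — two-sample Kolmogorov–Smirnov comparisons of
  any census field across DE categories (up / down / unchanged, defined by
  adjusted p < 0.05 and |log₂FC| > 1 on genes with ≥ 10 reads), five-bin
  GAAA summaries ({0}, (0,10], (10,20], (20,30], >30), and a
  hypergeometric gene-list overlap test with fold enrichment
  `k / (n·m/N)`, exact tail, and continuity-corrected normal
  approximation.
* **Synthetic cohorts** — a seeded generator of 3′UTR sets with
  category-dependent planted motif densities and a matching DE table, so
  the whole pipeline is testable without any download.

## Worked example

Simulate a small cohort (60 up / 60 down / 300 unchanged genes, 7-mers
planted at 1.2 per upregulated gene vs 0.3 elsewhere) and run the full
pipeline:

```bash
aremotif simulate --outdir cohort --seed 7 --n-up 60 --n-down 60 \
    --n-unchanged 300 --utr-length-median 400
aremotif run --utr-fasta cohort/utrs.fasta --de-table cohort/de_table.tsv \
    --outdir results --seed 7
```

`results/comparisons.tsv` then contains (provenance header omitted):

```
field     pair               n1   n2    D                    p_value                 method
n_7mer    up_vs_unchanged    60   300   0.48000000000000004  1.9719011151982892e-10  asymptotic
n_7mer    down_vs_unchanged  60   300   0.06333333333333335  0.9880753185990147      asymptotic
n_7mer    up_vs_down         60   60    0.4166666666666667   5.9858956615351225e-05  asymptotic
arescore  up_vs_unchanged    60   300   0.41000000000000003  1.0012436041534026e-07  asymptotic
```

Read: the planted 7-mer enrichment in the upregulated category is
recovered (D = 0.48, p ≈ 2×10⁻¹⁰ against unchanged genes; the ARE score
shows the same separation), while the downregulated category, planted at
background rate, is indistinguishable from unchanged (p ≈ 0.99). The
bundle also contains the per-gene census and score tables, GAAA bin
summaries (`gaaa_bins.json`), and the 7-mer context windows
(`windows.fasta`).

Classifying the packaged probe panel:

```bash
aremotif classify-probes
```

prints one row per probe; every probe with a text-stated gel-shift
outcome is predicted correctly by the 7-mer rule, e.g.

```
name          are_class   predicted  reported_binding  concordant
Mpl           7mer        bind       bind              true
Elavl2 ARE2   5mer_only   no_bind    no_bind           true
Fgf23         5mer_only   no_bind    no_bind           true
Tnf-alpha     7mer        bind       bind              true
```

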