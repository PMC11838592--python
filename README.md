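# modbench

Benchmarking pipeline for nanopore direct-RNA modification callers.

Deep-learning callers such as Dorado and m6Anet assign each candidate base
on each sequenced molecule a **per-read modification probability**.
Evaluating them is subtle: chemical ground truth (GLORI, eTAM-seq) reports
only *positively* modified sites, so false positives cannot be measured
from wild-type (WT) data alone. The standard remedy is a paired **in
vitro transcribed (IVT)** sample built from canonical NTPs: it contains no
modifications, so *every* modification call on IVT reads is a false
positive. `modbench` implements the complete evaluation around this
design, for m6A, pseudouridine, or any modification handled per-read:

- parsing per-read call tables (Modkit-`extract`-style genomic TSV and
  m6Anet-style transcript-coordinate tables, with transcript-to-genome
  lifting over GTF exon models);
- thresholding and per-site aggregation: a read's call is *modified* iff
  its probability exceeds the threshold t (strict `>`), and the per-site
  **modification ratio** is `n_modified / coverage` over all assessed
  reads — no intermediate-probability calls are discarded;
- candidate-site enumeration: exonic DRACH 5-mers (D=A/G/U, R=A/G, H=A/C/U;
  18 concrete motifs) for m6A, exonic U for pseudouridine, strand-aware;
- the four evaluation statistics, per read and per site, swept over a
  threshold grid:
  - **recall** = |predicted ∩ truth| / |truth| (a site is predicted
    when its ratio ≥ 10%, the ground-truth convention);
  - **correlation** = Spearman ρ between predicted ratios and
    ground-truth stoichiometries (at true-positive sites by default);
  - **FPR** = fraction of IVT calls (or sites) labeled modified;
  - **FDR** (IVT-normalized, after Kong et al.) =
    (IVT positives / IVT total) ÷ (WT positives / WT total), a lower
    bound on the true FDR, capped at 1, undefined when positive counts
    are too small to be stable;
- motif-stratified versions of every per-site statistic;
- a **probabilistic blacklist** of sites recurrently called modified
  across independent IVT samples, scored by a Beta–Binomial posterior
  `(α + n_positive) / (α + β + n_observed)` and applied as a post-filter;
- a fully seeded synthetic-data generator (reference + exon models +
  paired WT/IVT call tables + ground truth) with closed-form expected
  statistics, so the entire pipeline is testable without sequencing data.

## Worked example

Generate a synthetic benchmark (2000 exonic DRACH sites, 10% truly
modified, coverage ~30×, well-separated bimodal emissions) and evaluate it:

```sh
$ modbench simulate --seed 7 --outdir demo/bundle --n-ivt-samples 2
$ modbench benchmark --bundle demo/bundle --outdir demo/out \
      --recommended-threshold 0.5
{"fdr_read": 0.044621, "fdr_site": null, "fpr_read": 0.002011, "fpr_site": 0.0, "recall": 0.964103, "spearman": 0.929831}
```

Reading the numbers: at the per-read threshold 0.5 the caller recovers
96.4% of truly modified sites (`recall`), its per-site ratios track the
true stoichiometries with Spearman ρ = 0.93 (`spearman`), and 0.2% of the
modification-free IVT reads are miscalled (`fpr_read`). No IVT *site*
reaches the 10% ratio cutoff here (`fpr_site` = 0.0), so the per-site FDR
is reported as undefined (`null`) rather than 0 — fewer than the minimum
10 positive predictions exist to estimate it. The per-read FDR says that
false calls could account for up to ~4.5% of the WT read-level positives.

The run directory also contains `metric_curve.tsv` (all six statistics at
101 thresholds), `fdr_vs_ratio.tsv`, `motif_metrics.tsv` (every statistic
per DRACH 5-mer), per-sample BED-like site tables, `blacklist.tsv`, and
`summary.json` with record counts at every filter step so each
denominator is auditable.

Real data flows through the same commands via a YAML run configuration
(`modbench benchmark --config run.yaml`) declaring the WT/IVT call
tables with their dialects, the ground-truth table, and the reference
FASTA + GTF. `modbench aggregate`, `modbench blacklist-build` and
`modbench blacklist-apply` expose the individual stages.

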