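# Methods

## Evaluation model

`modbench` evaluates per-read modification callers against two references:
a chemically derived ground truth of per-site stoichiometries, and a
modification-free IVT control. The statistical model is deliberately
minimal. A caller emits, for read *i* at genomic site *s*, a probability
p_is that the base is modified. A **threshold policy** t classifies the
call as modified iff p_is > t — strictly greater, so a probability exactly
at the threshold is unmodified. The **per-site modification ratio** at t
is r_s = n_modified(s, t) / coverage(s): all assessed reads count in the
denominator, unlike Modkit's pileup, which discards intermediate-confidence
calls and thereby entangles the decision threshold with the denominator.
A site is a **positive prediction** when r_s ≥ c (inclusive), with c = 0.10
by default because the ground-truth resources themselves report sites at
the 10% stoichiometry cutoff.

Four statistics follow, each at per-read and/or per-site resolution:

- **Recall** — |predicted ∩ truth| / |truth|, over a truth table
  restricted to the coverage-filtered candidate universe. False negatives
  are split into *assessed-but-below-cutoff* and *never-assessed*
  (`fn_no_prediction`), because callers that require high local coverage
  lose most of their sensitivity through the second channel. True
  negatives are not identifiable against a positives-only truth and are
  reported as 0.
- **Correlation** — Spearman ρ (average ranks on ties) between predicted
  ratios and ground-truth stoichiometries on common sites, restricted by
  default to true-positive sites.
- **FPR** — the fraction of IVT calls (per read) or IVT sites (per site)
  classified modified. Every IVT molecule is unmodified by construction,
  so no truth table is needed.
- **FDR (IVT-normalized)** — (IVT positives / IVT total) ÷
  (WT positives / WT total). Normalizing to fractions makes unequal
  sample sizes cancel; the quantity lower-bounds the true FDR because IVT
  only captures false positives that arise without any modification
  present (signal noise, model bias), not those induced by neighboring
  modifications. The value is capped at 1 on request (default on) and is
  **undefined** — never 0 or 1 — when either sample's positive count is
  at or below `min_positives` (default 10), mirroring the practice of
  dropping unstable high-threshold points. The guard is applied to both
  samples' counts; the figure caption that motivates it does not say
  which count, and guarding both is the conservative reading.

Sweeping t over a grid (101 evenly spaced points plus any recommended
thresholds — shipped defaults 0.033 for m6Anet and 0.61 for
Dorado/Modkit, both overridable since the latter is sample-estimated)
produces the full metric curves; a second sweep varies the ratio cutoff c
at fixed t.

## Coordinates, candidate sites, motifs

Internal coordinates are 0-based half-open; GTF is converted on ingest,
BED conventions are used on output; U is normalized to T. Sites are
strand-specific (modification chemistry is strand-specific), so the same
genomic position on opposite strands yields two distinct sites and no
cross-strand merging occurs. Candidate m6A sites are exonic positions
whose sense-strand 5-mer (reverse-complemented for minus-strand
transcripts) matches DRACH on the DNA alphabet (D∈{A,G,T}, R∈{A,G}, A, C,
H∈{A,C,T}; 18 concrete motifs); pseudouridine candidates are exonic
sense-strand T. Contexts at sequence edges are N-padded and N never
matches DRACH.

Transcript-coordinate calls (m6Anet dialect) are lifted to the genome by
walking exon blocks in transcription order (descending with within-exon
reversal on the minus strand). Predictions from multiple transcripts are
pooled per genomic site; a read assessed at one genomic site through
several transcripts — or through supplementary alignments in the genomic
dialect — is collapsed to its maximum-probability call, keeping one vote
per molecule. The original evaluation pools transcript predictions per
genomic site without stating read-level handling; max-probability
collapse is this package's choice.

## Numerical choices

- Ratios are kept as exact integer pairs. Cutoffs written as decimals are
  interpreted exactly (`Fraction(str(0.1)) = 1/10`), so 3 modified reads
  of 30 sits *at* a 10% cutoff and is called positive; comparing against
  the binary float 0.1 would silently break these ties. Boundary
  semantics throughout: strict `>` for the per-read threshold, inclusive
  `≥` for the ratio cutoff and the coverage filter (default minimum 10
  reads, matching the coverage restriction applied to ground truth).
- Probabilities outside [0, 1] in input tables are skipped and counted,
  not clamped: row counts are conserved as parsed + skipped, and every
  filter (parse, candidate-set, coverage) logs its drop count so each
  statistic's denominator is auditable from the run summary.
- Undefined statistics (empty denominators, fewer than 3 common sites,
  zero variance, the FDR guard) are explicit `None`/`NA`, never coerced.
- Threshold sweeps pre-sort per-site probability arrays once and count
  exceedances by binary search, so a 101-point sweep costs little more
  than a single aggregation.
- Blacklist entries are sorted by descending score with site identity as
  the tie-break; all tables are written with stable ordering and `repr`
  float formatting so reruns are byte-identical.

## The synthetic-data generator

The generator emulates the statistical structure the evaluation relies
on, not nanopore physics. Defaults (one choice, used everywhere):

| parameter | default | rationale |
|---|---|---|
| n_sites | 2000 | desk-scale stand-in for the multi-million-site exonic DRACH universe |
| modified_fraction | 0.10 | a few hundred true sites keeps per-site statistics stable; the genome-wide truth fraction (~2%) would leave too few at this scale |
| stoichiometry | Beta(1.2, 1.8) rescaled to [0.1, 1] | median ≈ 0.44, inside the 39–48% range of ground-truth medians; the floor mirrors the ground-truth convention of reporting only sites with ≥10% stoichiometry, so synthetic truth has the same no-true-negatives structure |
| coverage | NegBin(mean 30, dispersion 8), floor 1 | overdispersed read depth typical of transcript-level sampling |
| emissions (bimodal) | modified Beta(9,1), unmodified Beta(1,9) | well-separated double-peaked probability distribution (Dorado-like) |
| emissions (unimodal) | modified Beta(2,5), unmodified Beta(1,15) | single peak near zero (m6Anet-like) |
| fp_tail_weight / motif_fp_weights | 0 / {} | per-motif mixing of the high-probability component into unmodified emissions, producing recurrent motif-dependent false positives when enabled |
| three_prime_bias | 0 | optional linear inflation of the false-positive tail toward read ends |

Generation: sites are drawn from the enumerated DRACH candidates of a
random multi-exon reference (80 transcripts on alternating strands, one
gene per contig; uniform bases give the analytic DRACH density 18/1024
per exonic base). Each truly modified site gets a stoichiometry θ; WT
read states are Bernoulli(θ), IVT reads are all unmodified; each read's
probability is drawn from the emission matching its state, with
unmodified reads mixing in the modified emission at the (motif-weighted)
tail weight. Everything is deterministic under the seed.

Closed-form expected statistics serve as an independent oracle: a read is
called modified with marginal probability q = θ·π1 + (1−θ)·π0, where π1
and π0 are the upper-tail masses of the two emissions beyond t, so the
per-site positive count is exactly Binomial(c, q); expected recall and
per-site FPR integrate the Binomial tail over the coverage pmf (exact
sum) and the stoichiometry law (Gauss–Legendre quadrature, 96 nodes).
The emission crossing point (densities equal; 0.5 for the default pair)
is the natural operating threshold for separated emissions.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: basecalling and alignment
errors, signal-level correlations between neighboring sites,
modification co-occurrence, transcript-abundance-driven coverage
structure, the confounding of nearby modifications (the component of
FDR the IVT design itself cannot see), or genuine caller biases beyond
the Beta-mixture family.

## Blacklist model

Sites recurrently positive across independent IVT samples are scored by
a Beta–Binomial posterior mean, score = (α + k) / (α + β + n), where n is
the number of IVT samples observing the site (coverage after filtering)
and k the number calling it positive. The uniform prior Beta(1,1) is the
package default: it behaves gracefully with a single sample (one positive
observation scores 2/3, not 1). The posterior mean with n samples is
bounded by (α + n)/(α + β + n), so stringent score cutoffs require either
more samples or a sharper prior — with three samples and a 0.9 cutoff,
for example, a prior like Beta(1, 0.25) is needed for consistently
positive sites to clear the bar. The model is an extension point:
coverage-weighted or sequence-context-aware scores would slot into the
same interface. Score stability as a function of the number of IVT
samples is reported on simulations rather than prescribing a panel size.

## Problem sizes

Tests and the acceptance script run the generator at 300–2000 sites with
coverage means 20–50 (10⁴–10⁵ reads per sample), 50 randomized
brute-force instances of ≤100 sites × ≤50 reads, and 10-seed null
calibrations — sizes chosen so the whole suite completes in well under a
minute per property while leaving Monte-Carlo error small against the
effects being tested.

## Limitations

The pipeline evaluates callers; it does not run them. modBAM MM/ML tags
are out of scope (the extract-style TSV is the interchange format), as
are signal-level simulation, isoform quantification, and positional-bias
analysis beyond the generator knob. The IVT-normalized FDR is a lower
bound, not an estimate, of the true FDR; the per-site FPR denominator
defaults to aggregated (covered) IVT sites, with the full candidate
universe available as an explicit alternative since published figures
differ subtly in this choice.
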