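# Methods

This note records the models, parameter choices and numerical rules the
package implements, and what its synthetic-data tests do and do not
demonstrate about real data.

## Degron motif scanning

Motif patterns are strings over the 20 standard amino-acid letters plus
a lowercase `x` wildcard; the shipped patterns are the KEN-box (`KEN`)
and the minimal D-box (`RxxL`). Scanning is exhaustive: every
occurrence is reported, including overlapping ones, in ascending start
order with 1-based inclusive coordinates (the convention of protein
databases, so a degron "at residues 622–624" is `start=622, end=624`).
Reporting all occurrences is the lossless choice; downstream stages
only need "at least one hit per gene".

Rules for edge cases:

- An `X` in a sequence (unknown residue) matches a wildcard position
  but never a fixed pattern letter — an unknown residue is not evidence
  for a degron.
- Non-amino-acid characters in input FASTA are replaced by `X` with a
  warning; duplicate protein ids and empty files are fatal.
- Isoforms collapse at gene level: a gene is motif-positive if any of
  its protein records has a hit, because the candidate intersection and
  all truth sets are keyed by gene symbol.
- Flank context defaults to w = 10 residues per side, clipped at
  sequence boundaries and never padded.

No structural-accessibility filtering is applied: a motif in a buried
domain counts the same as one in a disordered region. This inflates the
motif-positive set relative to the biologically accessible one and is a
known limitation of sequence-only degron calling.

## Periodicity voting

Each transcriptome study contributes a flat gene list; a study "calls"
a gene periodic iff the gene is on its list. After case-folding and an
optional local alias table (raw → canonical symbol; unmapped symbols
pass through and are reported rather than dropped), a gene's votes are
the number of distinct studies calling it, and the periodic set is
every gene with votes ≥ `min_votes` (default 2 of a 4-study roster).
Duplicate (gene, study) rows collapse with a warning, which makes
voting idempotent and permutation-invariant. Raising `min_votes` can
only shrink the set.

## Candidate substrates and recovery statistics

Candidates are the exact intersection of motif-positive genes and
periodic genes, sorted by symbol, carrying their hits and votes;
curation annotations join by left-join so uncurated candidates survive
with empty fields.

Recovery of a truth set by a candidate set uses the hypergeometric
frame: `q = |candidates ∩ truth|`, `m = |truth|`,
`n = universe − |truth|`, `k = |candidates|`, expectation
`e = (m/(m+n))·k`, fold `q/e`, percentage enrichment bias
`((q − e)/k) × 100`, and significance from the exact upper tail
`P(X ≥ q)`. The upper tail is the default because the question asked is
over-representation; a flag exposes the lower tail for depletion.
`P(X ≥ 0)` is exactly 1; `e = 0` with `q > 0` reports an
infinity-flagged fold rather than dividing by zero.

The universe size matters and is always an explicit parameter: the
default for substrate recovery is the number of distinct genes in the
scanned proteome, but fold enrichment scales linearly with it, so two
analyses are only comparable under the same universe.

## Methylation statistics

- QC: a probe is excluded if its detection p-value exceeds the
  threshold (default 0.05) in any one sample.
- Transform: `M = log2(β′/(1 − β′))` with β clamped to
  `[ε, 1 − ε]`, ε = 1e−6 — β of exactly 0 or 1 is saturated signal and
  would map to ±∞. The inverse transform round-trips to ≤1e−9 inside
  the clamp range.
- Differential testing: per-probe logFC is the mean M difference
  (test − reference). The default p-value engine is a moderated
  two-sample t-test: per-probe pooled variances are modelled as draws
  from a scaled-F prior fitted across the array by method of moments on
  log s², each variance is shrunk toward the prior, and the prior
  degrees of freedom add to the residual ones. At 2–3 replicates per
  group — the typical array design — an unmoderated test has almost no
  power after multiple-testing adjustment, which is why variance
  moderation is the field standard for this design; plain Welch and
  Student engines remain available (`engine="welch"`/`"student"`), and
  any callable mapping two (probes × samples) arrays to p-values plugs
  in. If the log-variances are no more dispersed than chi-square
  sampling noise predicts, the fit degenerates gracefully to complete
  pooling. Probes constant across all samples get p = 1. Adjustment is
  Benjamini–Hochberg across all tested probes; significant probes
  (adjusted p ≤ α, default 0.05) are classified hyper- or
  hypomethylated by the sign of logFC.
- Overlap analysis between two call sets partitions probes into
  common / unique-to-A / unique-to-B; the overlap percentage divides by
  the union by default (configurable to either input set, since
  published overlap percentages often leave the denominator unstated).
- Annotation: probe positions are 1-based single bases converted to
  half-open `[pos−1, pos)` intervals and intersected with BED-like
  features. When intervals conflict, one label is assigned by the
  priority promoter-TSS > TTS > exon > intron > intergenic (ties by
  file order); probes outside every interval are intergenic.
  Replication timing is classified by sign: value > 0 early, < 0 late,
  exactly 0 (or no overlap) unassigned.
- Feature enrichment reuses the q/m/n/k core with `q` = significant
  probes of the chosen direction in the feature, `m` = all array probes
  in the feature, `k` = all significant probes of that direction. When
  features partition the array, the per-feature `q` values sum to `k`.

## Signature scoring

Expression preprocessing is `log2(value + pseudocount)` (pseudocount 1,
since RSEM-style estimates can be 0) followed by per-gene median
centering — the conventional axis for "median centered" expression
matrices. A signature score is the per-sample median over the signature
genes present (missing genes are reported; an entirely absent signature
is an error), so the score is invariant to adding non-signature genes.
The cohort splits at the median score: strictly greater → high, ties at
the median → low (deterministic, so |high| ≤ |low|). A companion score
(CIN70-style) defaults to the mean over its gene set, the common
averaged-signature reading, with median as an option. Two scores are
compared by Pearson r, r², and the two-sided p; zero-variance scores
are an error rather than a NaN.

## Synthetic data: what it emulates, what it does not

Each generator is seeded (`numpy.random.default_rng`, no global state),
regenerates bit-identically from (parameters, seed), and writes a
manifest recording every planted fact, so closed-loop tests can verify
each stage against exact ground truth.

- `gen_proteome`: i.i.d. background residues (uniform frequencies by
  default, 500-residue proteins, 2,000 by default) with motif strings
  overwritten at manifest positions, optional isoform multiplicity.
  Real proteomes have length variation, composition bias and repeats —
  so background motif rates here follow the closed form
  `1 − (1 − p_K p_E p_N)^(L−2)`, not the empirical human rate.
- `gen_periodicity`: each of 4 studies calls true-periodic genes with a
  sensitivity (default 0.8) and others with a false-positive rate
  (default 0.02), independently; real studies are correlated through
  shared biology and platforms, which voting theory here ignores.
- `gen_substrate_benchmark`: gene sets over a 20,263-gene universe with
  exact planted overlaps sized to a published substrate-discovery
  funnel (2,206 motif-positive × 651 periodic → 145 candidates; 26/53
  and 22/33 truth-set captures; 31/53 jointly with an IP/MS set). It is
  a synthetic stand-in for curated substrate tables: it checks the
  pipeline's set algebra and statistics at realistic sizes, not the
  biology of any real list.
- `gen_beta`: one synthetic chromosome tiled with fixed-size feature
  blocks and coarser alternating early/late replication-timing blocks;
  baseline probe M ~ N(0, 2²), per-sample noise N(0, σ²) on the M scale
  (default σ = 0.5), and a +δ M-shift (default 2) in the test group at
  planted probes, drawn either entirely from one feature or with a
  configurable in-feature rate ratio. Default design is 3-vs-3 with 50
  planted among 500 null probes. Probe-chemistry artefacts, batch
  effects and spatial correlation of methylation are not modelled.
- `gen_expression`: one latent factor per sample; signature-B genes
  load on `ρf + √(1−ρ²)h`, so the two signature scores have population
  correlation ρ (default 0.85, the order of magnitude seen for
  proliferation-linked signatures). Values are emitted on the raw scale
  with per-gene baselines so the preprocessing path is exercised.

Passing parameter-recovery tests therefore demonstrates that the
implementation recovers what it planted under its own noise model — it
does not validate motif biology, study concordance, or array chemistry
on real data.

## Problem sizes and tolerances

Test and acceptance runs use desk-scale problems chosen to make the
statistics stable: 1,000 random sequences × 3 patterns for the scanner
oracle; every hypergeometric tuple with universe ≤ 12 against draw
enumeration (≤1e−12 relative); 10,000 probes for the interval-oracle
comparison; 20 seeds of the 3-vs-3 planted-shift design; 100 seeds of
the 3× planted-feature-rate design; 50 seeds of the ρ = 0.85 /
n = 500 latent-factor design (mean recovered r within ±0.05). The
pipeline is deterministic end to end: identical config and seed give
byte-identical outputs.

## Known limitations

- Sequence-only degron calling ignores structural accessibility and
  coactivator context; the D-box pattern alone matches most proteins
  and is useful only in combination.
- The moderated t engine is a standard empirical-Bayes variance
  shrinkage, not a re-implementation of any specific published
  pipeline's exact moderation; probe-level calls on real arrays will
  differ in detail from pipelines using other moderation or
  normalization choices.
- Enrichment folds depend on the chosen universe; the package never
  guesses one silently.
- The alias table is user-supplied; with an empty table, symbol
  normalization is case-folding only.
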