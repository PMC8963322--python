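# Methods

This note describes the models and procedures implemented in `herivome`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## Scientific setting

Insect-specific RNA viruses that are transmitted vertically (through eggs
or ovaries) leave characteristic small-RNA footprints in their hosts:
Dicer-2 processes viral double-stranded RNA into 21-nt siRNAs from both
strands, while the Piwi pathway produces 24–31-nt piRNAs whose 5′-uridine
(U1) and position-10 adenine (A10) biases on opposite strands — the
ping-pong signature — indicate Piwi-mediated amplification. Endogenous
viral elements (EVEs), virus-derived sequences integrated into the host
genome, are transcribed and processed into abundant piRNAs; when an EVE is
~20–25% diverged from its exogenous counterpart, most small RNAs can be
assigned unambiguously to one source, except in short perfectly conserved
stretches. Finally, when host populations are geographically isolated, an
inherited virus codiverges with its host: virus phylogenies mirror host
mitochondrial phylogenies, and an insect COI molecular clock converts
between-population divergence into a persistence timescale.

The package implements each of these inferences as a testable operation,
plus a seeded generator producing data with exactly these signatures.

## Read mapping

Reads of 15–40 nt are aligned gaplessly to reference contigs by an
exhaustive scan: every offset on both strands is scored by position-wise
comparison (vectorized over offsets), and placements whose match fraction
(matches / read length) reaches the configured minimum are kept. Two
thresholds matter in practice: 0.95 ("strict", within-population mapping)
and 0.75 ("relaxed", mapping reads across diverged population strains).
At these read lengths a seed-and-extend heuristic cannot guarantee full
sensitivity once ~25% of positions may mismatch (a single interior
mismatch can destroy every 12-mer of an 18-nt read), so exhaustive
scanning is both the simplest and the only exact choice; its cost is
negligible at small-RNA scale. Properties: the mapper equals a pure-Python
brute-force oracle on random instances; placements are antisymmetric under
reverse-complementing the read set; placement sets shrink monotonically
with the threshold.

Conventions: N never counts as a match on either side; coordinates are
0-based half-open; the default policy reports the single best placement
(most matches, ties broken by lowest contig id, lowest start, sense before
antisense), with an all-placements mode used by the EVE module. Stranded
per-base coverage sums each placement's footprint and is exportable as a
two-track bedgraph.

## Size profiles and the siRNA-enrichment call

Per contig, mapped read lengths are histogrammed over 18–31 nt by strand
(lengths outside the range land in an overflow bin), and
`norm21 = 100 × counts[21] / total_18_31` gives the normalized 21-nt
percentage; a profile with no 18–31-nt reads is flagged `no_data` rather
than given a meaningless zero. The enrichment call is TRUE when all three
of these hold: total mapped reads ≥ `min_reads` (default 50), the 21-nt
count is at least `peak_ratio` (default 2.0) times its larger neighbor
(20 or 22 nt), and norm21 ≥ `min_norm21` (default 20%). No numeric cutoff
for "enrichment" exists in common usage, so the defaults are declared
pipeline policy, configurable, and every call records the three
comparisons that produced it. The `min_reads` gate deliberately returns
FALSE for sparse profiles — a handful of reads should never yield a weak
positive. The normalization denominator is per-contig (each virus's own
18–31-nt reads); a per-sample denominator is a documented alternative.

## piRNA filtering and the ping-pong bias test

Candidates are alignments with read length 24–31 nt. For each strand
group, relative A/C/G/U frequencies are computed at positions 1–24 from
the read 5′ end; reads shorter than a position simply do not contribute
there, so every position is normalized over the reads covering it.
Antisense U1 and sense A10 enrichments are each tested with a one-sided
exact binomial test against a background of 0.25 per base (the minimal
null; a contig-composition background can be substituted), at
`alpha = 0.001` with Bonferroni correction over the number of contigs
tested. Verdicts: `none`, `u1_only`, `a10_only`, or `ping_pong` (both
significant). "Sense" follows the mapping strand against the reference as
supplied; for negative-sense virus genomes supplied in genome orientation,
sense reads correspond to genome-strand-derived RNAs.

## EVE versus exogenous virus

The exogenous segment and the EVE are aligned globally (match +1,
mismatch −1, gap open −5, gap extend −1). Excluded intervals — typically
the inserted copy of a tandem duplication, supplied by the user or by the
generator's ground truth — are excised from the EVE *before* alignment:
a tandem repeat makes the gap placement degenerate (the optimal alignment
can open the gap anywhere within the repeat), so excluding columns after
the fact would cut identity runs at an arbitrary equivalent position.
With the excision, the report's identity percentage and its maximal
identity windows agree exactly with a position-wise census of the
generated pair. A window whose EVE-side interval crosses an excision
junction is reported start-anchored in original EVE coordinates; because
the excised copy is a tandem repeat, an equivalent contiguous EVE window
always exists.

The ambiguity mask is the union of identity windows at least
`min_read_len` (default 18 — the shortest read considered, hence the
conservative choice) long, in each sequence's own coordinates. Read
assignment maps every read against both references in all-placements
mode: a read mapping at threshold to both is `ambiguous` (authoritative),
as is a read whose placements lie wholly inside a mask interval (the fast
path); otherwise it is labeled by its unique target, or `unmapped`.
Per-label size profiles let EVE-derived reads be shown piRNA-sized while
viral reads are siRNA-sized. At ~22% divergence roughly 1–6% of reads
(mostly 21-mers, which tolerate one mismatch at the 0.95 threshold) are
ambiguous by chance dual-mappability; an ambiguous call is an abstention,
not an error, mirroring the practice of excluding unassignable reads.

## Phylogeography

Distances are uncorrected p-distances (proportion of differing sites over
mutually non-gap, non-N columns) — the natural companion of a
percent-per-My clock; no multiple-hit correction is applied. Trees are
built by neighbor joining (scikit-bio's implementation, taxa sorted
lexicographically first so tie-breaking is deterministic); NJ is
consistent on additive matrices, which the tests exploit as an exact
round-trip oracle. Congruence between host and virus trees is reported
as (i) the Robinson–Foulds distance on unrooted topologies, normalized by
2(n−3), via dendropy, and (ii) the Pearson correlation of the two
distance matrices' upper triangles with a taxa-permutation null
(default 9,999 permutations, seeded; add-one p-value). With k taxa the
permutation null has k! distinct relabelings, so resolving p ≤ 0.01
requires ≥ 8 taxa; the codivergence checks use 8 populations for this
reason. Clock dating is `TMRCA = divergence / rate × 10⁶` years, also
reported rounded to the nearest 100,000 years; the continental anchor
(divergence 0.0288, rate 0.0354/My) gives 813,559 ≈ 800,000 years.
Prevalence from a screening table is Σ positives / Σ screened (percent,
one decimal), with per-population Clopper–Pearson 95% intervals (scipy's
exact method).

## Synthetic data generator

One seeded `SimulationConfig` drives everything; identical config + seed
gives byte-identical outputs (each operation draws from its own
deterministic stream, so stages can be regenerated independently).

* **Genomes**: uniform-random contigs, default 3 segments of 2,000 nt
  (a trisegmented bunyavirus-like architecture at reduced length).
* **Small-RNA libraries**: each read is siRNA-class with probability
  `sirna_fraction_21` (default 0.6; germline libraries of inherited
  viruses are strongly 21-dominated), else piRNA-class. siRNAs are exact
  21-mers from uniform positions on either strand (`strand_balance`
  default 0.5 — a modeling choice; real strand ratios are uneven and
  virus-specific). piRNA lengths are drawn from `pirna_length_weights`
  (default unimodal over 24–31, peaking at 27). The ping-pong signature
  is imposed by categorically resampling one position: the 5′ base of an
  antisense piRNA becomes U with probability `u1_prob` (default 0.8) and
  otherwise one of A/C/G uniformly; position 10 of a sense piRNA becomes
  A with probability `a10_prob` likewise. The configured probability is
  therefore exactly the marginal frequency of the biased base —
  `u1_prob = 0.25` is indistinguishable from uniform — which is what the
  recovery tests measure. The resampled base may mismatch the contig
  (≤1 mismatch per read, still mappable at the 0.95 threshold). FASTQ
  qualities are constant; no sequencing error is simulated (inputs model
  pre-trimmed inserts).
* **EVEs**: a copy of a segment substituted at rate `eve_divergence`
  (default 0.22) per site outside the conserved motifs (default three
  motifs of 31/35/39 nt), then the `eve_duplication` interval (default
  500 nt) is inserted in tandem. Substitutions only — indel evolution is
  out of scope — under an independent-sites, equal-rates model, matching
  the use of uncorrected identity percentages. Ground truth (motif and
  duplication coordinates in both coordinate systems, substituted sites)
  is returned alongside, and `eve_identity_truth` provides the
  independent position-wise census used as the alignment oracle.
* **Codiverging loci**: an ultrametric population tree is built from
  pairwise `split_times` (My; validated for three-point consistency), and
  host and virus loci evolve along it by per-branch independent-site
  substitution with probability rate × branch length per site. Expected
  between-population p-distance is ≈ 2 × rate × split time (the small
  second-order multiple-hit deficit, ~0.03 pp at these depths, is below
  sampling noise at the locus lengths used). Defaults: five populations
  with nested splits at 0.407/0.55/0.65/0.8 My, host clock 0.0354/My
  (insect COI), virus rate multiplier 2.0 (a modeling choice standing in
  for faster viral substitution; only relative distances matter to the
  congruence statistics). `random_split_times` generates an independent
  random ultrametric tree for the no-codivergence null.

What the generator does **not** emulate: read-count overdispersion and
hotspot coverage structure, RNA secondary structure, codon/protein
realism, host transposon background, indels, rate heterogeneity across
sites, and explicit 10-nt 5′-overlap bookkeeping for ping-pong pairs
(the positional biases are imposed marginally). Tests passing on these
data therefore demonstrate correctness of the computations under the
stated generative model, not robustness to every property of real
libraries.

## Problem sizes and numerical choices

The test and reproduction runs use deliberately desk-scale sizes chosen
as a balance of statistical resolution and runtime: mapper/oracle
comparisons on 50 instances of 300–800-nt references with 60–110 reads at
thresholds {0.75, 0.95, 1.0}; signature-recovery estimates at 10,000
reads (3-SD binomial bands) with 50–100 seeded replicates for call
rates; EVE checks on a 2,000-nt segment with 4,000 reads; codivergence on
8 populations with 4,000-nt loci and 9,999 permutations; the
two-population clock anchor as the mean p-distance over 10 replicate
10-kb loci (Monte Carlo SE ≈ 0.05 pp). Ties in the
best-placement policy and NJ are broken lexicographically; permutation
and simulation RNGs are all seeded explicitly; probabilities are compared
with exact binomial tails rather than normal approximations throughout.

## Known limitations

* The enrichment call thresholds are policy, not estimated quantities;
  changing them changes calls (they are recorded per call for audit).
* Ambiguity masking uses perfect-identity windows only; near-identical
  windows (e.g. one mismatch in 24 nt) are handled by the dual-mapping
  rule rather than the mask.
* p-distances are uncorrected by design; deep divergences would need a
  substitution-model correction and a different clock treatment.
* NJ with short loci can misplace shallow splits; congruence statistics
  on very short alignments reflect that sampling noise.
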