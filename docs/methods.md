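# Methods

This note records the statistical model, the parameter choices, the
design decisions made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Calling model

All internal coordinates are 0-based half-open; user-facing tables are
1-based. Per sample (tissue × biological replicate × technical run) we
tally, at every covered position, the count of each base on each
alignment strand, keeping only base calls with Phred score strictly
greater than 20. The quality filter is applied symmetrically to edited
and unedited bases, so the edit ratio's denominator is high-quality
coverage; an asymmetric reading (quality-filtering only mismatches)
would make the ratio incoherent across sites with different quality
profiles. Technical runs are summed within each biological replicate
before any calling, reflecting the observation that run effects on edit
ratios are negligible in barcoded multi-run designs.

A candidate site requires, in every biological replicate of a tissue,
the same alternate base with

* edited reads ≥ `min_edited_reads` (default 2), and
* edit ratio strictly > `min_edit_ratio` (default 0.05).

Both inequalities follow the convention "greater than 5%" / "Phred
score > 20"; the edited-read count is a ≥ bound. At multi-allelic
columns the alternate is the non-reference base with the highest pooled
high-quality count, ties broken alphabetically; other mismatching bases
are ignored throughout (they count as neither edited nor unedited in the
bias table). Sites are called per tissue and unioned; a site's record
carries every sample's counts and the list of tissues in which it passed.

Two variant filters follow. Known SNPs (any VCF/BED of positions) are
removed outright. Positions whose edit ratio is 100% in *every* sample
covering them are removed as fixed differences from the reference; a
site covered in only one sample at 100% is removed under the same rule —
the conservative reading, since nothing in such data distinguishes
editing from a private SNP.

## Strand-bias test

The artifact model: systematic sequencer errors occur in specific
sequence contexts and therefore appear on reads of one orientation only,
whereas genuine editing is orientation-blind. For each candidate whose
2×2 table (edited/unedited × forward/reverse, pooled over **all**
samples, "all reads aligned to the editing site") totals at least
`min_reads_bias_test` = 20 reads, we compute a two-sided Fisher exact
p-value by hypergeometric enumeration over one margin, summing the
probabilities of all tables whose point probability does not exceed the
observed one (with the conventional 1 + 1e-7 relative tie gate). Two
sidedness is deliberate: bias toward either strand is an artifact
signal. The Bonferroni family is all tested sites in the current run
(all tissues combined) — the most reproducible reading of a run-level
correction — and sites with corrected p < 0.05 are flagged. Untested
(under-covered) sites carry no p-value and are never flagged, so low
coverage is not treated as evidence of bias.

The test is conservative under the null by discreteness (verified by
simulation in the test suite), and an all-zero table is undefined and
returns p = 1 with a warning.

Context profiling reports per-offset base frequencies over ±`motif_window`
(default 50) bp around flagged sites — on the plus strand by default,
optionally oriented to the strand carrying the majority of a site's
edited reads — and a degenerate-motif scan (default `GGCWGG`, both
strands, footprint overlapping the window) reports the fraction of sites
with a nearby hit.

## Annotation

Orientation assumes transcripts originate from the annotated gene
strand; a site under genes on exactly one strand is complemented
accordingly, genes on both strands leave the site in plus-strand space
flagged ambiguous, and intergenic sites stay plus-strand. Canonical =
{A→G, C→T}; complementary-canonical = {T→C, G→A}; the remaining eight
substitutions are non-canonical.

Feature classes use precedence coding > 3′UTR > 5′UTR > intronic >
intergenic when transcripts disagree — coding-first is the
consequence-conservative choice and keeps "depleted from coding"
well-defined. Exonic positions of non-coding transcripts classify as
intronic: the five-class scheme has no ncRNA-exon class, and transcribed
non-CDS, non-UTR sequence is the closest match. Coding effects translate
the strand-aware spliced codon containing the site with the standard
genetic code (one consensus transcript per site, lowest transcript id on
ties); a CDS whose spliced length is not divisible by 3 is skipped with
a warning.

The per-gene artifact flag generalizes the divergent-paralog failure
mode: among non-canonical sites with no strand bias, any gene holding
more than `max_gene_artifact_fraction` (default 0.25) of them is
flagged, and its sites marked suspect rather than removed — the evidence
is about the gene (reference-genome error, unannotated paralog), not
about any one site.

## Permutation enrichment

Backgrounds are coverage-matched: eligible positions have pooled
coverage ≥ `background_min_coverage` (default 20) in the combined
pileup. Pooling across samples (rather than per-sample eligibility) is
this package's choice; at the benchmark's coverage the two eligible sets
coincide. A 10,000-position background sample is drawn for the
distribution report; enrichment p-values come from `n_permutations` =
1000 redraws of exactly |sites| eligible positions, classified the same
way as the sites. One-sided p-values are reported separately for
enrichment (permuted count ≥ observed) and depletion (≤), with the
plus-one rule p = (k+1)/(N+1), whose floor 1/1001 matches a "<0.001"
reporting convention.

Seed targets are exact Watson–Crick reverse-complement matches of
mature microRNA nucleotides 2–8 (7-mer) in spliced 3′UTR sequence — no
G:U wobble, no flanking requirements (wobble would only enlarge the
target set; exact matching is the stricter and simpler primitive).
Matches are projected to genomic intervals across splice junctions.
Disruption = a 3′UTR site inside ≥ 1 target interval (the site must lie
within the 7-mer itself, not flanking it). Creation = the edited spliced
3′UTR contains a seed match overlapping the edited position that the
unedited sequence lacks at that window, found by brute-force scan of the
≤ 7 overlapping windows.

The disruption permutation redraws |sites| coverage-eligible 3′UTR
positions and counts how many fall in targets. The creation permutation
is base-matched: each observed site's gene-oriented (from, to) pair is
reassigned to a random eligible 3′UTR position whose oriented reference
base equals *from*, and the to-base is applied there. Base matching
makes the null well-defined (an A→G edit cannot be simulated at a C) and
controls for base composition; positions are drawn with replacement
within each from-base pool, and the creation status of every
(position, to-base) pair is precomputed once.

## Synthetic benchmark

The generator emulates the structure of a three-tissue mouse RNA-seq
editing study at desk scale. Defaults (chosen once as the study
conditions; the problem sizes are the package's own choice):

| parameter | default | rationale |
|---|---|---|
| genome | 1 chromosome, 20 genes, ~53 kb | smallest scale with hundreds of sites' capacity |
| gene structure | 5′UTR 120 nt; CDS 900 nt over 2 exons; 3′UTR 600 nt over 2 exons; introns 300/150 nt | spliced UTRs exercise junction-aware projection; CDS divisible by 3 by construction |
| design | 3 tissues × 3 biological replicates × 2 technical runs | the emulated study design |
| reads | 68 bp single-end, per-replicate coverage ~ Poisson(50) | read length echoes the emulated platform; single-end because alignment-time pairing logic is out of scope |
| planted edits | 60; 85% A→G / 15% C→T; ratio 0.3; 80% in 3′UTRs, half of those inside embedded seed targets | A:C ratio mirrors the canonical editing spectrum; ratio 0.3 is a typical intermediate editing level |
| bias errors | 40, error rate 0.5 on one random strand only; 55% given a GGC[A/T]GG context, the rest preceded by GG | fully strand-biased by construction; motif fraction mirrors the reported error context |
| SNP-like sites | 10 at ratio 1.0, half listed in the "known SNPs" VCF | exercises both variant filters |
| paralog | last gene, 8 CDS positions mismatching at 50% on both strands, alt = complement(ref) | unbiased non-canonical cluster confined to one gene |
| qualities | Phred 35, with 5% of bases at Phred 10 | exercises the quality filter without an error model |

Seed-target 7-mers and error-motif contexts are written into the
reference *before* the FASTA is serialized, so on-disk inputs match the
truth table. Each sample draws from its own RNG stream derived from the
master seed, so adding runs never perturbs other samples, and all
outputs are byte-reproducible.

What the generator does **not** model — and hence what passing tests do
not show about real data: alignment and reference-genome errors other
than the single paralog gene; quality-dependent substitution error
matrices (the only error process is the planted strand-biased one); PCR
duplicates and fragment-size effects; intronic read coverage from
pre-mRNA (intronic planted edits are therefore mostly unrecoverable at
these settings, which the recovery scoring reports per category);
expression-level variation between genes beyond length weighting; and
creation events among the planted edits (the creation statistic is
exercised by oracle tests rather than by the benchmark, whose observed
creation count is 0).

## Numerical choices and degenerate inputs

* Fisher p-values: float hypergeometric pmf with the 1 + 1e-7 tie gate;
  agreement with an exact-rational enumerator is within 1e-10 for every
  table with total ≤ 40 (measured: ~6e-16).
* Permutation draws are without replacement within a draw (except the
  base-matched creation pools, with replacement); all RNGs are
  `numpy.random.default_rng` seeded from the run seed plus a fixed
  per-purpose offset.
* Alt-base ties break alphabetically; coding-transcript ties break on
  transcript id; empty site lists make profiling/enrichment raise rather
  than return vacuous results; an empty Fisher table returns 1 with a
  warning; background sampling raises when fewer eligible positions
  exist than requested, stating the eligible count.
* Binomial interval checks in the recovery analysis use the central 95%
  interval of Binomial(n = pooled high-quality coverage, p = true ratio).

## Known limitations

The pipeline consumes aligned reads (SAM) and does not revisit
alignment; mismapped reads present as editing (the paralog flag catches
only the clustered form). Pooling bias tables across all samples maximizes
power but assumes the artifact is shared across samples — a run-specific
artifact would be diluted. Sites under genes on both strands are counted
in plus-strand space and flagged ambiguous rather than resolved. The
creation permutation conditions on the observed substitution spectrum;
it does not model the joint placement of edits within clusters.
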