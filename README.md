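# editscan

Strand-aware discovery and characterization of RNA editing sites from
aligned RNA-seq reads.

## The problem

RNA editing alters transcript sequences co- or post-transcriptionally.
In mammals only two canonical chemistries are known: adenosine
deamination to inosine (read as guanine, so A→G) and cytidine
deamination to uridine (C→T). High-throughput RNA-seq nevertheless
reports all twelve possible base substitutions, and the ten
"non-canonical" types are largely artifacts: systematic sequencer errors
whose tell-tale signature is *strand bias* — the mismatch appears almost
exclusively on reads sequenced in one orientation, while genuine editing
is supported by reads of both orientations. `editscan` implements a
pipeline that calls candidate sites from strand-resolved pileups,
removes genomic variants, filters strand-biased artifacts with a Fisher
exact test, and then asks where the surviving sites fall — in particular
whether they concentrate in 3′UTRs and inside microRNA seed-target
sites, where editing can rewire post-transcriptional regulation.

Because the kind of multi-tissue, multi-replicate data this analysis
needs is rarely redistributable, the package ships a first-class
synthetic-data generator that plants true edits, strand-biased errors,
SNP-like fixed differences, and a divergent-paralog artifact into a
simulated genome, so every stage is testable end to end against known
truth.

## The method

**Candidate calling.** For each sample, bases with Phred score > 20 are
tallied per genomic position and alignment strand; technical runs are
pooled within each biological replicate. A site is a candidate iff in
*every* biological replicate of a tissue the same alternate base is
supported by ≥ 2 high-quality reads at an edit ratio (edited / total
reads) strictly greater than 5%. Known SNPs are removed, as are
positions edited at 100% in every covering sample (fixed differences
from the reference, not editing).

**Strand-bias filter.** For each candidate covered by ≥ 20 reads, a
2×2 table

|          | forward | reverse |
|----------|---------|---------|
| edited   | a       | b       |
| unedited | c       | d       |

is tested with a two-sided Fisher exact test (point-probability
criterion, computed by hypergeometric enumeration). Sites with a
Bonferroni-corrected p < 0.05 (family = all tested sites in the run) are
flagged as artifacts. Sequence context around flagged sites is profiled
(per-offset base frequencies; degenerate-motif scan, default `GGCWGG`,
within ±50 bp).

**Annotation.** Assuming transcripts arise from the annotated gene
strand, sites are oriented (a T→C mismatch under a minus-strand gene is
an A→G edit) and classed canonical (A→G, C→T), complementary-canonical
(T→C, G→A) or non-canonical; features are assigned as
3′UTR / coding / intronic / 5′UTR / intergenic with coding-first
precedence; coding sites get synonymous / non-synonymous calls from
strand-aware spliced codons; genes concentrating unbiased non-canonical
sites (the unannotated-paralog failure mode) are flagged suspect.

**Enrichment.** Feature and microRNA seed-target enrichment are measured
by permutation: N = 1000 redraws of the same number of coverage-matched
positions (coverage ≥ 20), with p = (k+1)/(N+1). A seed target is an
exact reverse-complement match of mature microRNA nucleotides 2–8 in a
3′UTR; edits inside a match disrupt it, and edits whose altered sequence
forms a new match create one.

## Worked example

Run the built-in synthetic benchmark (three tissues × three biological
replicates × two technical runs, 68 bp reads, per-replicate coverage
≈ 50, with 60 planted canonical edits — 80% in 3′UTRs, half of those
inside seed targets — 40 strand-biased error sites, 10 SNP-like fixed
differences, and one divergent-paralog gene):

```yaml
# config.yaml
out_dir: editing_run
params:
  rng_seed: 1
sim:
  rng_seed: 1
```

```bash
editscan run-all --config config.yaml
cat editing_run/report.txt
```

which prints (abridged):

```
n_candidates             111
n_after_snp_filter       106
n_after_fixed_filter     101
n_strand_biased          40
n_retained               61

retained sites by editing class:
  canonical                53
  complementary_canonical  0
  non_canonical            8

feature enrichment (permutation):
  3UTR         observed=48 expected=14.19 p_enrich=0.000999 p_deplete=1
  coding       observed=11 expected=21.01 p_enrich=0.996 p_deplete=0.007992

microRNA seed-target analysis:
  3'UTR sites            48
  in seed targets        24 (p=0.000999)

suspect clustered-artifact genes: gene019

error-motif (GGCWGG) fraction near strand-biased sites: 0.550
```

Reading this: of 111 candidate sites, the SNP and 100%-ratio filters
remove the planted genomic variants, the Fisher filter flags all 40
planted strand-biased errors, and the 61 retained sites are dominated by
canonical edits. The retained sites are strongly enriched in 3′UTRs
(48 observed vs ≈ 14 expected, p = 1/1001, the permutation floor) and
depleted from coding sequence; half of the 3′UTR sites fall inside
microRNA seed targets (p = 1/1001). The eight retained non-canonical
sites cluster in `gene019` — the planted divergent paralog — which the
per-gene artifact check flags rather than silently removing. 55% of
flagged sites have the planted `GGC[A/T]GG` error motif nearby.

`editscan score --config config.yaml` compares the retained table
against the generator's truth; stage-wise subcommands (`simulate`,
`call`, `filter-bias`, `annotate`, `enrich`) run prefixes of the
pipeline on the same config.

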