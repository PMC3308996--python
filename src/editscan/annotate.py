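"""Gene-oriented edit typing, genomic-feature classification, coding
effects, and per-gene artifact clustering.

Because standard RNA-seq libraries lose strand-of-origin information,
sites are oriented by assuming transcripts arise from the annotated gene
strand: a T>C mismatch under a minus-strand gene is an A>G edit. A>G and
C>T are the canonical editing types (A-to-I read as guanine, and C-to-U);
T>C and G>A are their reverse-complement images (antisense transcripts or
double-stranded substrates); the remaining eight substitutions have no
known catalyzing enzyme and are classed non-canonical.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .io import GeneModel, ReferenceGenome, complement
from .pileup import EditingSiteCandidate

logger = logging.getLogger(__name__)

CANONICAL = "canonical"
COMPLEMENTARY = "complementary_canonical"
NON_CANONICAL = "non_canonical"

_CANONICAL_PAIRS = {("A", "G"), ("C", "T")}
_COMPLEMENTARY_PAIRS = {("T", "C"), ("G", "A")}

FEATURE_CLASSES = ["3UTR", "coding", "intronic", "5UTR", "intergenic"]
#: precedence when overlapping transcripts disagree (highest wins)
FEATURE_PRECEDENCE = {"coding": 4, "3UTR": 3, "5UTR": 2, "intronic": 1, "intergenic": 0}
_FEATURE_CODE = {"intergenic": 0, "intronic": 1, "5UTR": 2, "3UTR": 3, "coding": 4}
_CODE_FEATURE = {v: k for k, v in _FEATURE_CODE.items()}

SYNONYMOUS = "synonymous"
NON_SYNONYMOUS = "non_synonymous"
NOT_CODING = "not_coding"


@dataclass(frozen=True)
class EditType:
    """A gene-oriented substitution and its editing class."""

    from_base: str
    to_base: str

    @property
    def edit_class(self) -> str:
        pair = (self.from_base, self.to_base)
        if pair in _CANONICAL_PAIRS:
            return CANONICAL
        if pair in _COMPLEMENTARY_PAIRS:
            return COMPLEMENTARY
        return NON_CANONICAL

    def __str__(self) -> str:
        return f"{self.from_base}>{self.to_base}"


ALL_EDIT_TYPES = [EditType(f, t) for f in "ACGT" for t in "ACGT" if f != t]


class GeneIndex:
    """Position lookups over a set of transcript models.

    Overlap queries use per-chromosome sorted span lists; mass feature
    classification uses a painted per-chromosome class array where the
    highest-precedence class wins (coding > 3UTR > 5UTR > intronic >
    intergenic).
    """

    def __init__(self, models: Sequence[GeneModel], genome: ReferenceGenome):
        self.models = list(models)
        self.genome = genome
        self._by_chrom: dict[str, tuple[list[int], list[tuple[int, int, GeneModel]]]] = {}
        spans: dict[str, list[tuple[int, int, GeneModel]]] = {}
        for m in self.models:
            spans.setdefault(m.chrom, []).append((*m.span, m))
        self._max_span: dict[str, int] = {}
        for chrom, lst in spans.items():
            lst.sort(key=lambda t: t[0])
            self._by_chrom[chrom] = ([t[0] for t in lst], lst)
            self._max_span[chrom] = max(e - s for s, e, _ in lst)
        self._class_arrays: dict[str, np.ndarray] = {}

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, lst = entry
        out = []
        # spans sorted by start: only entries within the longest span can hit
        for i in range(bisect_right(starts, pos) - 1, -1, -1):
            s, e, m = lst[i]
            if pos - s >= self._max_span[chrom]:
                break
            if s <= pos < e:
                out.append(m)
        return out

    def class_array(self, chrom: str) -> np.ndarray:
        """Per-position feature codes (paint order = ascending precedence)."""
        if chrom not in self._class_arrays:
            arr = np.zeros(self.genome.length(chrom), dtype=np.uint8)
            per_class: dict[str, list[tuple[int, int]]] = {
                "intronic": [], "5UTR": [], "3UTR": [], "coding": []}
            for m in self.models:
                if m.chrom != chrom:
                    continue
                per_class["intronic"].append(m.span)
                per_class["5UTR"].extend(m.utr5_intervals())
                per_class["3UTR"].extend(m.utr3_intervals())
                per_class["coding"].extend(m.cds_intervals())
            for cls in ("intronic", "5UTR", "3UTR", "coding"):
                code = _FEATURE_CODE[cls]
                for s, e in per_class[cls]:
                    arr[s:e] = np.maximum(arr[s:e], code)
            self._class_arrays[chrom] = arr
        return self._class_arrays[chrom]

    def classify(self, chrom: str, pos: int) -> str:
        if chrom not in self.genome:
            return "intergenic"
        return _CODE_FEATURE[int(self.class_array(chrom)[pos])]


def _class_for_transcript(pos: int, m: GeneModel) -> str:
    if not m.contains(pos):
        return "intergenic"
    if not m.in_exon(pos):
        return "intronic"
    if not m.is_coding:
        # the 5-class scheme has no ncRNA-exon class; treated as intronic
        return "intronic"
    if m.cds_start <= pos < m.cds_end:
        return "coding"
    downstream = pos >= m.cds_end if m.strand == "+" else pos < m.cds_start
    return "3UTR" if downstream else "5UTR"


def orient_edit_type(site: EditingSiteCandidate, index: GeneIndex) -> EditType:
    """Orient a plus-strand ref/alt pair by the strand of overlapping genes.

    A site under gene(s) on exactly one strand is complemented when that
    strand is minus; genes on both strands leave the site in plus-strand
    space flagged ambiguous; intergenic sites stay plus-strand.
    The result is recorded on the site and returned.
    """
    models = index.overlapping(site.chrom, site.pos)
    strands = {m.strand for m in models}
    if strands == {"-"}:
        et = EditType(complement(site.ref_base), complement(site.alt_base))
        site.strand_context = "-"
    elif strands == {"+"}:
        et = EditType(site.ref_base, site.alt_base)
        site.strand_context = "+"
    elif strands:
        et = EditType(site.ref_base, site.alt_base)
        site.strand_context = "ambiguous"
    else:
        et = EditType(site.ref_base, site.alt_base)
        site.strand_context = "intergenic"
    site.gene_from, site.gene_to = et.from_base, et.to_base
    site.edit_class = et.edit_class
    site.genes = sorted({m.gene_id for m in models})
    return et


def classify_genomic_feature(site: EditingSiteCandidate, index: GeneIndex) -> str:
    """Assign exactly one feature class to a site (precedence on conflict)."""
    models = index.overlapping(site.chrom, site.pos)
    best = "intergenic"
    for m in models:
        cls = _class_for_transcript(site.pos, m)
        if FEATURE_PRECEDENCE[cls] > FEATURE_PRECEDENCE[best]:
            best = cls
    site.feature = best
    return best


def annotate_coding_effect(site: EditingSiteCandidate, index: GeneIndex,
                           genome: ReferenceGenome) -> str:
    """Translate the reference and edited codons at a coding site.

    The spliced, strand-aware codon containing the site is built from the
    transcript whose CDS covers it (lowest transcript_id on ties) and
    translated with the standard genetic code. Non-coding sites return
    ``not_coding``; a CDS whose spliced length is not divisible by 3 is
    skipped with a warning.
    """
    coding_models = [m for m in index.overlapping(site.chrom, site.pos)
                     if _class_for_transcript(site.pos, m) == "coding"]
    if not coding_models:
        site.coding_effect = NOT_CODING
        return NOT_CODING
    m = min(coding_models, key=lambda mm: mm.transcript_id)
    cds_seq = m.cds_sequence(genome)
    if len(cds_seq) % 3 != 0:
        logger.warning("CDS of %s has length %d (not divisible by 3); "
                       "coding effect skipped", m.transcript_id, len(cds_seq))
        site.coding_effect = NOT_CODING
        return NOT_CODING
    cds_pos = m.cds_positions()
    idx = int(np.nonzero(cds_pos == site.pos)[0][0])
    codon_i, within = divmod(idx, 3)
    ref_codon = cds_seq[codon_i * 3:codon_i * 3 + 3]
    alt = site.alt_base if m.strand == "+" else complement(site.alt_base)
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    effect = SYNONYMOUS if ref_aa == alt_aa else NON_SYNONYMOUS
    site.coding_effect = effect
    return effect


def flag_clustered_gene_artifacts(sites: Sequence[EditingSiteCandidate],
                                  max_fraction: float = 0.25) -> list[str]:
    """Flag genes that concentrate the unbiased non-canonical sites.

    A single gene holding a large share of non-canonical sites that show
    no strand bias is the signature of an unannotated divergent paralog or
    reference-genome error (apparent editing at ~50% on both strands).
    Genes holding more than ``max_fraction`` of all such sites are
    flagged, and their sites are marked suspect (not removed).
    Returns the flagged gene ids.
    """
    pool = [s for s in sites
            if s.edit_class == NON_CANONICAL and not s.strand_biased]
    if not pool:
        return []
    per_gene: dict[str, int] = {}
    for s in pool:
        for g in s.genes:
            per_gene[g] = per_gene.get(g, 0) + 1
    flagged = sorted(g for g, n in per_gene.items()
                     if n / len(pool) > max_fraction)
    flagged_set = set(flagged)
    for s in sites:
        if flagged_set & set(s.genes):
            s.artifact_gene_flag = True
    return flagged


def edit_type_counts(sites: Sequence[EditingSiteCandidate]) -> dict[str, int]:
    """Count sites per gene-oriented substitution type (12 keys)."""
    counts = {str(et): 0 for et in ALL_EDIT_TYPES}
    for s in sites:
        if s.gene_from is not None:
            counts[f"{s.gene_from}>{s.gene_to}"] += 1
    return counts
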