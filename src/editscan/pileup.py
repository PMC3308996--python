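"""Strand-resolved pileups and candidate editing-site calling.

A candidate site must be supported, in every biological replicate, by at
least ``min_edited_reads`` high-quality edited reads (Phred strictly above
``min_base_phred``) at an edit ratio strictly greater than
``min_edit_ratio`` for one and the same alternate base. Known SNPs and
positions fixed at a 100% edit ratio in every covering sample are then
removed as genomic variants rather than editing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import (AlignedRead, DNA_BASES, FORWARD, REVERSE, ReferenceGenome,
                 encode_bases)
from .params import PipelineParams

logger = logging.getLogger(__name__)

#: row layout of a pileup count matrix: (base A,C,G,T) x (forward, reverse)
N_ROWS = 8


def _row(base_code: int, reverse: bool) -> int:
    return base_code * 2 + int(reverse)


@dataclass
class PileupColumn:
    """Per-position, per-alignment-strand high-quality base counts."""

    chrom: str
    pos: int
    ref_base: str
    hq_counts: dict[tuple[str, str], int]
    total_coverage: int

    def __post_init__(self) -> None:
        if self.total_coverage != sum(self.hq_counts.values()):
            raise ValueError("total_coverage must equal the sum of hq_counts")
        if any(v < 0 for v in self.hq_counts.values()):
            raise ValueError("counts must be non-negative")

    def base_count(self, base: str) -> int:
        return (self.hq_counts.get((base, FORWARD), 0)
                + self.hq_counts.get((base, REVERSE), 0))


class SamplePileup:
    """Array-backed pileup for one sample: (8, L) counts per chromosome."""

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        self.counts: dict[str, np.ndarray] = {}

    def _matrix(self, chrom: str) -> np.ndarray:
        if chrom not in self.counts:
            self.counts[chrom] = np.zeros((N_ROWS, self.genome.length(chrom)),
                                          dtype=np.int32)
        return self.counts[chrom]

    def add_bases(self, chrom: str, positions: np.ndarray, base_codes: np.ndarray,
                  reverse: bool | np.ndarray) -> None:
        mat = self._matrix(chrom)
        rev = np.broadcast_to(np.asarray(reverse, dtype=np.int64), positions.shape)
        valid = base_codes < 4  # N bases are never counted
        rows = base_codes[valid].astype(np.int64) * 2 + rev[valid]
        np.add.at(mat, (rows, positions[valid]), 1)

    def coverage(self, chrom: str) -> np.ndarray:
        if chrom not in self.counts:
            return np.zeros(self.genome.length(chrom), dtype=np.int64)
        return self.counts[chrom].sum(axis=0)

    def covered_positions(self, chrom: str) -> np.ndarray:
        return np.nonzero(self.coverage(chrom))[0]

    def column(self, chrom: str, pos: int) -> PileupColumn:
        mat = self._matrix(chrom)
        hq = {}
        for code, base in enumerate(DNA_BASES):
            for rev, strand in ((0, FORWARD), (1, REVERSE)):
                c = int(mat[_row(code, bool(rev)), pos])
                if c:
                    hq[(base, strand)] = c
        return PileupColumn(chrom, pos, self.genome[chrom][pos], hq,
                            int(mat[:, pos].sum()))

    def add(self, other: "SamplePileup") -> "SamplePileup":
        for chrom, mat in other.counts.items():
            self._matrix(chrom)
            self.counts[chrom] += mat
        return self

    @staticmethod
    def combine(pileups: Iterable["SamplePileup"], genome: ReferenceGenome
                ) -> "SamplePileup":
        out = SamplePileup(genome)
        for p in pileups:
            out.add(p)
        return out


def build_pileups(reads: Iterable[AlignedRead], genome: ReferenceGenome,
                  params: PipelineParams) -> dict[tuple[str, str, str], SamplePileup]:
    """Count high-quality bases per (tissue, replicate, run) sample.

    Bases with Phred <= ``min_base_phred`` are excluded entirely (the
    quality filter applies symmetrically to edited and unedited bases, so
    the edit-ratio denominator is high-quality coverage).
    """
    buffers: dict[tuple[str, str, str], dict[str, list]] = {}
    for read in reads:
        chrom_len = genome.length(read.chrom) if read.chrom in genome else None
        if chrom_len is None:
            raise ValueError(f"read {read.read_id} aligned to unknown chromosome {read.chrom}")
        key = (read.tissue, read.replicate, read.run)
        buf = buffers.setdefault(key, {})
        per_chrom = buf.setdefault(read.chrom, [[], [], []])
        rev = read.strand == REVERSE
        for seg in read.segments:
            if seg.end > chrom_len:
                raise ValueError(
                    f"read {read.read_id} extends beyond end of {read.chrom} "
                    f"({seg.end} > {chrom_len})")
            keep = np.asarray(seg.quals) > params.min_base_phred
            if not keep.any():
                continue
            pos = np.arange(seg.start, seg.end)[keep]
            codes = encode_bases(seg.bases)[keep]
            per_chrom[0].append(pos)
            per_chrom[1].append(codes)
            per_chrom[2].append(np.full(pos.shape, rev, dtype=np.int64))
    out: dict[tuple[str, str, str], SamplePileup] = {}
    for key, buf in buffers.items():
        pile = SamplePileup(genome)
        for chrom, (pos_l, code_l, rev_l) in buf.items():
            if pos_l:
                pile.add_bases(chrom, np.concatenate(pos_l),
                               np.concatenate(code_l), np.concatenate(rev_l))
            else:
                pile._matrix(chrom)
        out[key] = pile
    return out


def pool_technical_replicates(pileups: Mapping[tuple[str, str, str], SamplePileup],
                              ) -> dict[tuple[str, str], SamplePileup]:
    """Sum counts across technical runs within each biological replicate."""
    pooled: dict[tuple[str, str], SamplePileup] = {}
    for (tissue, replicate, _run), pile in sorted(pileups.items()):
        key = (tissue, replicate)
        if key not in pooled:
            pooled[key] = SamplePileup(pile.genome)
        pooled[key].add(pile)
    return pooled


@dataclass
class EditingSiteCandidate:
    """A candidate editing site with per-replicate support and annotations.

    ``ref_base``/``alt_base`` are in plus-strand space; gene-oriented type
    and classification (``gene_from``/``gene_to``/``edit_class``) are filled
    by the annotation stage, strand-bias statistics by the bias filter, and
    feature / coding-effect / microRNA flags by their stages.
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    tissues: list[str]
    per_replicate: dict[str, tuple[int, int, float]]
    pooled_edited: int
    pooled_total: int
    genes: list[str] = field(default_factory=list)
    gene_from: str | None = None
    gene_to: str | None = None
    edit_class: str | None = None
    strand_context: str | None = None
    bias_p_raw: float | None = None
    bias_p_bonferroni: float | None = None
    strand_biased: bool = False
    feature: str | None = None
    coding_effect: str | None = None
    mirna_disrupted: list[str] = field(default_factory=list)
    mirna_created: list[str] = field(default_factory=list)
    artifact_gene_flag: bool = False

    def __post_init__(self) -> None:
        if self.alt_base == self.ref_base:
            raise ValueError("alt_base must differ from ref_base")
        rep_edit = sum(v[0] for v in self.per_replicate.values())
        rep_tot = sum(v[1] for v in self.per_replicate.values())
        if (rep_edit, rep_tot) != (self.pooled_edited, self.pooled_total):
            raise ValueError("pooled counts must equal replicate sums")
        for edited, total, ratio in self.per_replicate.values():
            if total and not (0 <= ratio <= 1):
                raise ValueError("edit ratio outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt_base)

    @property
    def pooled_ratio(self) -> float:
        return self.pooled_edited / self.pooled_total if self.pooled_total else 0.0


def call_candidate_sites(replicate_pileups: Mapping[str, SamplePileup],
                         genome: ReferenceGenome, params: PipelineParams,
                         tissue: str = "tissue") -> list[EditingSiteCandidate]:
    """Call candidate sites from one tissue's biological-replicate pileups.

    The alternate base at a multi-allelic column is the non-reference base
    with the highest pooled high-quality count (alphabetical tie-break);
    other mismatching bases are ignored. A site is emitted iff, in every
    replicate, that base has >= ``min_edited_reads`` high-quality reads and
    an edit ratio strictly above ``min_edit_ratio``.
    """
    if not replicate_pileups:
        raise ValueError("no biological replicates supplied")
    if len(replicate_pileups) != params.n_replicates:
        raise ValueError(
            f"expected {params.n_replicates} biological replicates, "
            f"got {len(replicate_pileups)}")
    rep_names = sorted(replicate_pileups)
    sites: list[EditingSiteCandidate] = []
    chroms = sorted({c for p in replicate_pileups.values() for c in p.counts})
    for chrom in chroms:
        ref_codes = genome.encoded(chrom)
        mats = [replicate_pileups[r]._matrix(chrom) for r in rep_names]
        # pooled per-base counts (strands summed) to choose the alt base
        pooled = sum(m.reshape(4, 2, -1).sum(axis=1) for m in mats)
        totals_per_rep = [m.sum(axis=0) for m in mats]
        masked = pooled.astype(np.int64).copy()
        valid_ref = ref_codes < 4
        masked[ref_codes[valid_ref], np.nonzero(valid_ref)[0]] = -1
        masked[:, ~valid_ref] = -1  # never call on N reference
        alt_codes = masked.argmax(axis=0)
        alt_pooled = masked[alt_codes, np.arange(masked.shape[1])]
        candidate_pos = np.nonzero(alt_pooled >= params.min_edited_reads)[0]
        if candidate_pos.size == 0:
            continue
        ok = np.ones(candidate_pos.shape, dtype=bool)
        edited_by_rep, total_by_rep = [], []
        for m, tot in zip(mats, totals_per_rep):
            per_base = m.reshape(4, 2, -1).sum(axis=1)
            edited = per_base[alt_codes[candidate_pos], candidate_pos]
            total = tot[candidate_pos]
            edited_by_rep.append(edited)
            total_by_rep.append(total)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(total > 0, edited / np.maximum(total, 1), 0.0)
            ok &= (edited >= params.min_edited_reads) & (ratio > params.min_edit_ratio)
        for idx in np.nonzero(ok)[0]:
            pos = int(candidate_pos[idx])
            per_rep = {}
            for r, edited, total in zip(rep_names, edited_by_rep, total_by_rep):
                e, t = int(edited[idx]), int(total[idx])
                per_rep[f"{tissue}/{r}"] = (e, t, e / t if t else 0.0)
            sites.append(EditingSiteCandidate(
                chrom=chrom, pos=pos,
                ref_base=DNA_BASES[ref_codes[pos]],
                alt_base=DNA_BASES[alt_codes[pos]],
                tissues=[tissue], per_replicate=per_rep,
                pooled_edited=sum(v[0] for v in per_rep.values()),
                pooled_total=sum(v[1] for v in per_rep.values())))
    sites.sort(key=lambda s: s.key)
    return sites


def merge_tissue_calls(per_tissue: Mapping[str, Sequence[EditingSiteCandidate]],
                       ) -> list[EditingSiteCandidate]:
    """Union of per-tissue calls; a site passing in several tissues is merged."""
    merged: dict[tuple[str, int, str], EditingSiteCandidate] = {}
    for tissue in sorted(per_tissue):
        for site in per_tissue[tissue]:
            if site.key in merged:
                m = merged[site.key]
                m.tissues = sorted(set(m.tissues) | set(site.tissues))
                m.per_replicate.update(site.per_replicate)
                m.pooled_edited = sum(v[0] for v in m.per_replicate.values())
                m.pooled_total = sum(v[1] for v in m.per_replicate.values())
            else:
                merged[site.key] = site
    return sorted(merged.values(), key=lambda s: s.key)


def filter_known_snps(sites: Sequence[EditingSiteCandidate],
                      snps: set[tuple[str, int]]) -> list[EditingSiteCandidate]:
    """Drop candidate sites at known SNP positions."""
    kept = [s for s in sites if (s.chrom, s.pos) not in snps]
    logger.info("known-SNP filter removed %d of %d sites",
                len(sites) - len(kept), len(sites))
    return kept


def filter_fixed_sites(sites: Sequence[EditingSiteCandidate],
                       sample_pileups: Mapping[tuple, SamplePileup],
                       ) -> list[EditingSiteCandidate]:
    """Drop sites whose edit ratio is 100% in every sample covering them.

    Such positions are fixed differences from the reference (unannotated
    SNPs or assembly errors), not editing. A site covered in only one
    sample at 100% is likewise removed.
    """
    kept = []
    for site in sites:
        all_fixed = True
        covered_anywhere = False
        for pile in sample_pileups.values():
            if site.chrom not in pile.counts:
                continue
            col = pile.counts[site.chrom][:, site.pos]
            total = int(col.sum())
            if total == 0:
                continue
            covered_anywhere = True
            code = DNA_BASES.index(site.alt_base)
            edited = int(col[code * 2] + col[code * 2 + 1])
            if edited != total:
                all_fixed = False
                break
        if covered_anywhere and all_fixed:
            continue
        kept.append(site)
    logger.info("100%%-ratio filter removed %d of %d sites",
                len(sites) - len(kept), len(sites))
    return kept
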