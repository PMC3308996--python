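"""Domain types and readers/writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open throughout; every user-facing
table prints 1-based positions (the ``chr10:57235791`` convention used to
name editing sites). RNA alphabets are normalized to DNA (U -> T) at
ingestion so the genome, reads, and microRNA seeds share one space;
microRNA sequences are additionally kept as given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

DNA_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(DNA_BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FORWARD = "forward"
REVERSE = "reverse"


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes A=0 C=1 G=2 T=3; anything else -> 4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for b, c in _BASE_CODE.items():
        out[arr == ord(b)] = c
    return out


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

class ReferenceGenome:
    """Mapping chromosome name -> uppercase DNA sequence over {A,C,G,T,N}."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one sequence")
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            seq = seq.upper().replace("U", "T")
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"chromosome {name!r} contains invalid bases {sorted(bad)}")
            self.sequences[name] = seq
        self._encoded: dict[str, np.ndarray] = {}

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def chroms(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence on [start, end), truncated at chromosome bounds."""
        seq = self.sequences[chrom]
        return seq[max(start, 0):min(end, len(seq))]

    def encoded(self, chrom: str) -> np.ndarray:
        if chrom not in self._encoded:
            self._encoded[chrom] = encode_bases(self.sequences[chrom])
        return self._encoded[chrom]


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Parse a FASTA file into a :class:`ReferenceGenome`.

    Sequences are uppercased with U mapped to T. Duplicate or empty headers
    and empty records raise :class:`ParseError` naming the offending line.
    """
    sequences: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 and line[1:].split() else ""
                if not name:
                    raise ParseError(f"{path}: line {lineno}: empty FASTA header")
                if name in sequences:
                    raise ParseError(f"{path}: line {lineno}: duplicate record {name!r}")
                current = name
                sequences[name] = []
            else:
                if current is None:
                    raise ParseError(f"{path}: line {lineno}: sequence before any header")
                sequences[current] = sequences.get(current, [])
                sequences[current].append(line)
    if not sequences:
        raise ParseError(f"{path}: no FASTA records found")
    joined = {name: "".join(parts) for name, parts in sequences.items()}
    for name, seq in joined.items():
        if not seq:
            raise ParseError(f"{path}: record {name!r} has an empty sequence")
    return ReferenceGenome(joined)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models (BED12)
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A transcript: exon structure, strand, and optional CDS bounds.

    ``exons`` are genomic 0-based half-open intervals sorted by start and
    non-overlapping. ``cds_start``/``cds_end`` bound the coding region on
    the genome (None for non-coding transcripts).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: degenerate exon ({s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons unsorted or overlapping")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: half-specified CDS")
        if self.cds_start is not None:
            if not (self.span[0] <= self.cds_start < self.cds_end <= self.span[1]):
                raise ValueError(f"{self.transcript_id}: CDS outside transcript span")

    # -- coordinate helpers -------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def exon_positions(self) -> np.ndarray:
        """Genomic positions of the spliced transcript, ascending."""
        if not hasattr(self, "_exon_pos"):
            self._exon_pos = np.concatenate(
                [np.arange(s, e) for s, e in self.exons])
        return self._exon_pos

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, genome: ReferenceGenome) -> str:
        """mRNA-oriented (5'->3') spliced sequence in DNA alphabet."""
        plus = "".join(genome[self.chrom][s:e] for s, e in self.exons)
        return plus if self.strand == "+" else reverse_complement(plus)

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos < e

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Index of a genomic position in the mRNA-oriented spliced sequence."""
        offset = 0
        for s, e in self.exons:
            if s <= pos < e:
                idx = offset + (pos - s)
                if self.strand == "-":
                    idx = self.spliced_length - 1 - idx
                return idx
            offset += e - s
        return None

    def transcript_to_genomic(self, idx: int) -> int:
        if not (0 <= idx < self.spliced_length):
            raise IndexError(f"transcript index {idx} out of range")
        if self.strand == "-":
            idx = self.spliced_length - 1 - idx
        return int(self.exon_positions[idx])

    # -- UTR / CDS structure -------------------------------------------------

    def _exonic_mask_regions(self, lo: int, hi: int) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons:
            a, b = max(s, lo), min(e, hi)
            if a < b:
                out.append((a, b))
        return out

    def cds_intervals(self) -> list[tuple[int, int]]:
        if not self.is_coding:
            return []
        return self._exonic_mask_regions(self.cds_start, self.cds_end)

    def utr3_intervals(self) -> list[tuple[int, int]]:
        """Genomic intervals of the 3'UTR (exonic, downstream of the CDS)."""
        if not self.is_coding:
            return []
        if self.strand == "+":
            return self._exonic_mask_regions(self.cds_end, self.span[1])
        return self._exonic_mask_regions(self.span[0], self.cds_start)

    def utr5_intervals(self) -> list[tuple[int, int]]:
        if not self.is_coding:
            return []
        if self.strand == "+":
            return self._exonic_mask_regions(self.span[0], self.cds_start)
        return self._exonic_mask_regions(self.cds_end, self.span[1])

    def utr3_positions(self) -> np.ndarray:
        """Genomic positions of the 3'UTR ordered along the mRNA (5'->3')."""
        ivals = self.utr3_intervals()
        if not ivals:
            return np.empty(0, dtype=np.int64)
        pos = np.concatenate([np.arange(s, e) for s, e in ivals])
        return pos[::-1] if self.strand == "-" else pos

    def utr3_sequence(self, genome: ReferenceGenome) -> str:
        plus = "".join(genome[self.chrom][s:e] for s, e in self.utr3_intervals())
        return plus if self.strand == "+" else reverse_complement(plus)

    def cds_positions(self) -> np.ndarray:
        ivals = self.cds_intervals()
        if not ivals:
            return np.empty(0, dtype=np.int64)
        pos = np.concatenate([np.arange(s, e) for s, e in ivals])
        return pos[::-1] if self.strand == "-" else pos

    def cds_sequence(self, genome: ReferenceGenome) -> str:
        plus = "".join(genome[self.chrom][s:e] for s, e in self.cds_intervals())
        return plus if self.strand == "+" else reverse_complement(plus)


def read_gene_models(path: str | Path, dialect: str = "BED12") -> list[GeneModel]:
    """Read transcript models from BED12 (thickStart/thickEnd = CDS bounds)."""
    if dialect != "BED12":
        raise ValueError(f"unsupported gene-model dialect {dialect!r}")
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(f"{path}: line {lineno}: expected 12 BED fields, got {len(parts)}")
            try:
                chrom = parts[0]
                start, end = int(parts[1]), int(parts[2])
                name = parts[3]
                strand = parts[5]
                thick_start, thick_end = int(parts[6]), int(parts[7])
                n_blocks = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}: line {lineno}: blockCount mismatch")
            exons = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
            if exons[0][0] != start or exons[-1][1] != end:
                raise ParseError(f"{path}: line {lineno}: blocks do not span chromStart..chromEnd")
            cds_start = cds_end = None
            if thick_start != thick_end:
                if not (start <= thick_start < thick_end <= end):
                    raise ParseError(f"{path}: line {lineno}: CDS outside transcript")
                cds_start, cds_end = thick_start, thick_end
            gene_id = name.split("|")[0]
            transcript_id = name.split("|")[1] if "|" in name else name
            try:
                models.append(GeneModel(gene_id, transcript_id, chrom, strand,
                                        exons, cds_start, cds_end))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start, end = m.span
            thick = (m.cds_start, m.cds_end) if m.is_coding else (start, start)
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            starts = ",".join(str(s - start) for s, e in m.exons) + ","
            name = m.gene_id if m.gene_id == m.transcript_id else f"{m.gene_id}|{m.transcript_id}"
            fh.write("\t".join(map(str, [
                m.chrom, start, end, name, 0, m.strand,
                thick[0], thick[1], "0,0,0", len(m.exons), sizes, starts])) + "\n")


# ---------------------------------------------------------------------------
# SNP sets (minimal VCF or BED)
# ---------------------------------------------------------------------------

def read_snps(path: str | Path, dialect: str | None = None) -> set[tuple[str, int]]:
    """Read known-SNP positions; VCF POS (1-based) converted to 0-based."""
    path = Path(path)
    if dialect is None:
        dialect = "VCF" if path.suffix.lower() == ".vcf" else "BED"
    snps: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect == "VCF":
                    snps.add((parts[0], int(parts[1]) - 1))
                elif dialect == "BED":
                    snps.add((parts[0], int(parts[1])))
                else:
                    raise ValueError(f"unsupported SNP dialect {dialect!r}")
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return snps


def write_snps_vcf(snps: Iterable[tuple[str, int, str, str]], path: str | Path) -> None:
    """Write (chrom, 0-based pos, ref, alt) records as a minimal VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in sorted(snps):
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# microRNAs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mirna:
    mirna_id: str
    sequence: str  # mature sequence 5'->3', RNA alphabet as given

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 8:
            raise ValueError(f"{self.mirna_id}: mature sequence shorter than 8 nt")
        if set(seq) - set("ACGU"):
            raise ValueError(f"{self.mirna_id}: sequence not over A/C/G/U")

    @property
    def seed(self) -> str:
        """Seed = mature nucleotides 2-8 (7-mer), RNA alphabet."""
        return self.sequence.upper()[1:8]

    @property
    def seed_dna(self) -> str:
        return self.seed.replace("U", "T")


def read_mirnas(path: str | Path) -> list[Mirna]:
    """Read mature microRNAs from a 2-column TSV (id, sequence) or FASTA."""
    path = Path(path)
    mirnas: list[Mirna] = []
    if path.suffix.lower() in {".fa", ".fasta"}:
        name, parts = None, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        mirnas.append(Mirna(name, "".join(parts).upper().replace("T", "U")))
                    name, parts = line[1:].split()[0], []
                elif line:
                    parts.append(line)
        if name is not None:
            mirnas.append(Mirna(name, "".join(parts).upper().replace("T", "U")))
        return mirnas
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected id<TAB>sequence")
            try:
                mirnas.append(Mirna(parts[0], parts[1].upper().replace("T", "U")))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return mirnas


def write_mirnas(mirnas: Sequence[Mirna], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# mirna_id\tsequence\n")
        for m in mirnas:
            fh.write(f"{m.mirna_id}\t{m.sequence}\n")


# ---------------------------------------------------------------------------
# Aligned reads (SAM)
# ---------------------------------------------------------------------------

@dataclass
class ReadSegment:
    """A gap-free aligned stretch: genomic start, bases, per-base Phred scores."""
    start: int
    bases: str
    quals: np.ndarray

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("segment bases and quality scores differ in length")

    @property
    def end(self) -> int:
        return self.start + len(self.bases)


@dataclass
class AlignedRead:
    """One aligned read with sample metadata and splice-aware segments.

    ``strand`` is the alignment orientation on the reference (the sequencing
    direction the strand-bias test contrasts); bases are always stored in
    plus-strand space as in SAM.
    """

    read_id: str
    sample_id: str
    tissue: str
    replicate: str
    run: str
    chrom: str
    start: int
    strand: str  # forward | reverse
    segments: list[ReadSegment]

    def __post_init__(self) -> None:
        prev_end = -1
        for seg in self.segments:
            if seg.start < prev_end:
                raise ValueError(f"{self.read_id}: segments unordered or overlapping")
            prev_end = seg.end


# CIGAR operation codes consuming query and/or reference
_CIG_QUERY = {0, 1, 4, 7, 8}
_CIG_REF = {0, 2, 3, 7, 8}


def _rg_metadata(header) -> dict[str, tuple[str, str, str, str]]:
    """Map read-group ID -> (sample_id, tissue, replicate, run) from @RG lines."""
    meta = {}
    for rg in header.to_dict().get("RG", []):
        rid = rg["ID"]
        sample = rg.get("SM", rid)
        tissue = rg.get("DS", sample)
        replicate = rg.get("LB", "rep1")
        run = rg.get("PU", "run1")
        meta[rid] = (sample, tissue, replicate, run)
    return meta


def read_sample_sheet(path: str | Path) -> dict[str, tuple[str, str, str, str]]:
    """Sidecar TSV: read_group<TAB>sample<TAB>tissue<TAB>replicate<TAB>run."""
    meta = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 columns")
            meta[parts[0]] = tuple(parts[1:5])
    return meta


def read_alignments(path: str | Path,
                    sample_sheet: Mapping[str, tuple[str, str, str, str]] | None = None,
                    ) -> list[AlignedRead]:
    """Read mapped reads from SAM into :class:`AlignedRead` records.

    Soft-clipped bases are excluded; N operations open splice gaps between
    segments; unmapped reads are skipped with a logged count. Sample
    metadata comes from @RG header lines (SM=sample, DS=tissue,
    LB=biological replicate, PU=technical run) or a sidecar sample sheet.
    """
    reads: list[AlignedRead] = []
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        meta = dict(_rg_metadata(sam.header))
        if sample_sheet:
            meta.update(sample_sheet)
        try:
            alignments = list(sam)
        except OSError as exc:  # pysam signals malformed records this way
            raise ParseError(f"{path}: {exc}") from exc
        for aln in alignments:
            if aln.is_unmapped:
                n_unmapped += 1
                continue
            seq = aln.query_sequence
            quals = aln.query_qualities
            if seq is None or quals is None:
                raise ParseError(f"{path}: read {aln.query_name}: missing SEQ or QUAL")
            cigar = aln.cigartuples or []
            consumed_q = sum(ln for op, ln in cigar if op in _CIG_QUERY)
            if consumed_q != len(seq):
                raise ParseError(
                    f"{path}: read {aln.query_name}: CIGAR consumes {consumed_q} bases "
                    f"but SEQ has {len(seq)}")
            quals = np.asarray(quals, dtype=np.int16)
            segments: list[ReadSegment] = []
            gpos = aln.reference_start
            qpos = 0
            seg_start, seg_bases, seg_quals = gpos, [], []
            for op, ln in cigar:
                if op in (0, 7, 8):  # M, =, X
                    seg_bases.append(seq[qpos:qpos + ln])
                    seg_quals.append(quals[qpos:qpos + ln])
                    qpos += ln
                    gpos += ln
                elif op == 1:  # I: query only
                    qpos += ln
                elif op == 4:  # S: clipped, excluded
                    qpos += ln
                elif op in (2, 3):  # D / N: reference gap -> close segment
                    if seg_bases:
                        segments.append(ReadSegment(seg_start, "".join(seg_bases),
                                                    np.concatenate(seg_quals)))
                    gpos += ln
                    seg_start, seg_bases, seg_quals = gpos, [], []
                # 5 (H), 6 (P): consume nothing we track
            if seg_bases:
                segments.append(ReadSegment(seg_start, "".join(seg_bases),
                                            np.concatenate(seg_quals)))
            rg = aln.get_tag("RG") if aln.has_tag("RG") else None
            sample, tissue, replicate, run = meta.get(
                rg, (rg or "sample", rg or "sample", "rep1", "run1"))
            reads.append(AlignedRead(
                read_id=aln.query_name, sample_id=sample, tissue=tissue,
                replicate=replicate, run=run,
                chrom=aln.reference_name, start=aln.reference_start,
                strand=REVERSE if aln.is_reverse else FORWARD,
                segments=segments))
    if n_unmapped:
        logger.info("skipped %d unmapped reads in %s", n_unmapped, path)
    return reads


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------

SITE_TABLE_COLUMNS = [
    "chrom", "position", "ref", "alt", "tissues", "gene_ids",
    "edit_from", "edit_to", "edit_class", "strand_context",
    "pooled_edited", "pooled_total", "pooled_ratio",
    "per_replicate", "bias_p_raw", "bias_p_bonferroni", "strand_biased",
    "feature", "coding_effect", "mirna_disrupted", "mirna_created",
    "artifact_gene_flag",
]


def write_site_table(sites, path: str | Path) -> None:
    """Serialize editing-site candidates as a TSV with 1-based positions."""
    rows = []
    for s in sites:
        per_rep = ";".join(
            f"{k}:{v[0]}/{v[1]}" for k, v in sorted(s.per_replicate.items()))
        rows.append({
            "chrom": s.chrom,
            "position": s.pos + 1,
            "ref": s.ref_base,
            "alt": s.alt_base,
            "tissues": ",".join(s.tissues),
            "gene_ids": ",".join(s.genes),
            "edit_from": s.gene_from if s.gene_from is not None else ".",
            "edit_to": s.gene_to if s.gene_to is not None else ".",
            "edit_class": s.edit_class or ".",
            "strand_context": s.strand_context or ".",
            "pooled_edited": s.pooled_edited,
            "pooled_total": s.pooled_total,
            "pooled_ratio": f"{s.pooled_edited / s.pooled_total:.6g}" if s.pooled_total else "NA",
            "per_replicate": per_rep,
            "bias_p_raw": f"{s.bias_p_raw:.6g}" if s.bias_p_raw is not None else "NA",
            "bias_p_bonferroni": (f"{s.bias_p_bonferroni:.6g}"
                                  if s.bias_p_bonferroni is not None else "NA"),
            "strand_biased": int(s.strand_biased),
            "feature": s.feature or ".",
            "coding_effect": s.coding_effect or ".",
            "mirna_disrupted": ",".join(s.mirna_disrupted) or ".",
            "mirna_created": ",".join(s.mirna_created) or ".",
            "artifact_gene_flag": int(s.artifact_gene_flag),
        })
    df = pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read a written site table back; positions stay 1-based in the frame."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
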