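"""Synthetic RNA-seq benchmark with planted edits and planted artifacts.

The generator emulates the structure of a multi-tissue mouse RNA-seq
editing study at desk scale: a random genome carrying spliced gene models
on both strands, mature microRNAs, and strand-resolved aligned reads per
(tissue, biological replicate, technical run). Into this it plants

* true canonical edits (A>G / C>T in gene orientation) at a configured
  edit ratio, appearing on reads of both orientations, preferentially in
  3'UTRs and optionally inside microRNA seed targets;
* strand-biased error sites, where the mismatch occurs only on reads of
  one alignment orientation, most of them adjacent to a planted
  GGC[A/T]GG context (the remainder preceded by GG);
* SNP-like fixed differences (every read carries the alternate), a
  subset listed in the "known SNPs" file;
* a divergent-paralog gene whose exons mismatch at ~50% on both strands
  (the reference-genome failure mode that mimics unbiased non-canonical
  editing).

Every output is reproducible from the master seed; each sample draws
from its own RNG stream so adding runs never perturbs other samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .annotate import GeneIndex, _FEATURE_CODE
from .io import (DNA_BASES, FORWARD, REVERSE, GeneModel, Mirna,
                 ReferenceGenome, complement, reverse_complement, write_fasta,
                 write_gene_models, write_mirnas, write_snps_vcf)
from .pileup import EditingSiteCandidate

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study-design and generative parameters of the synthetic benchmark.

    Defaults mirror the emulated study: three tissues, three biological
    replicates each, sequenced across two technical runs as 68 bp reads,
    with per-replicate per-base coverage around 50. Planted canonical
    edits default to an edit ratio of 0.3, 85% A>G / 15% C>T, 80% of them
    in 3'UTRs with half of those inside microRNA seed targets; error
    sites are fully strand-biased at rate 0.5 on the designated strand.
    """

    rng_seed: int = 0
    chrom_name: str = "chr1"
    n_genes: int = 20
    gap_len: int = 400
    utr5_len: int = 120
    cds_exon_lens: tuple[int, int] = (450, 450)
    intron_len: int = 300
    utr3_exon_lens: tuple[int, int] = (300, 300)
    utr3_intron_len: int = 150
    n_mirnas: int = 20
    mirna_len: int = 22
    n_edits: int = 60
    edit_feature_weights: dict = field(default_factory=lambda: {
        "3UTR": 0.80, "coding": 0.05, "5UTR": 0.05, "intronic": 0.10})
    edit_in_seed_fraction: float = 0.5
    edit_ratio: float | tuple[float, ...] = 0.3
    edit_ag_fraction: float = 0.85
    coverage_mean: float = 50.0
    read_length: int = 68
    tissues: tuple[str, ...] = ("liver", "adipose", "bone")
    n_replicates: int = 3
    n_runs: int = 2
    n_bias_errors: int = 40
    bias_error_rate: float = 0.5
    bias_motif_fraction: float = 0.55
    n_snps: int = 10
    snp_known_fraction: float = 0.5
    paralog_divergences: int = 8
    paralog_mismatch_rate: float = 0.5
    background_read_fraction: float = 0.10
    low_quality_fraction: float = 0.05
    base_quality: int = 35
    low_quality: int = 10

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "read_length", "n_replicates", "n_runs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        ratios = self.edit_ratios
        if not ratios or any(not (0 < r < 1) for r in ratios):
            raise ValueError("edit ratios must lie in (0, 1)")
        w = sum(self.edit_feature_weights.values())
        if abs(w - 1) > 1e-9:
            raise ValueError(f"edit feature weights must sum to 1, got {w}")

    @property
    def edit_ratios(self) -> tuple[float, ...]:
        r = self.edit_ratio
        return (r,) if isinstance(r, (int, float)) else tuple(r)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation parameter(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("cds_exon_lens", "utr3_exon_lens", "tissues"):
            if key in d:
                d[key] = tuple(d[key])
        if isinstance(d.get("edit_ratio"), list):
            d["edit_ratio"] = tuple(d["edit_ratio"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEdit:
    chrom: str
    pos: int
    ref: str            # plus-strand space
    alt: str
    gene_from: str      # gene-oriented type
    gene_to: str
    ratio: float
    feature: str
    in_seed_target: bool


@dataclass(frozen=True)
class PlantedBiasError:
    chrom: str
    pos: int
    ref: str
    error_base: str
    biased_strand: str  # forward | reverse
    motif_context: str  # "GGCWGG", "GG", or "none"


@dataclass(frozen=True)
class PlantedSnp:
    chrom: str
    pos: int
    ref: str
    alt: str
    known: bool


@dataclass
class SyntheticTruth:
    """Everything planted, for recovery scoring."""

    edits: list[PlantedEdit]
    bias_errors: list[PlantedBiasError]
    snps: list[PlantedSnp]
    paralog_gene: str | None
    paralog_positions: list[tuple[str, int, str, str]]  # chrom,pos,ref,alt

    def __post_init__(self) -> None:
        cats = [
            {(e.chrom, e.pos) for e in self.edits},
            {(e.chrom, e.pos) for e in self.bias_errors},
            {(s.chrom, s.pos) for s in self.snps},
            {(c, p) for c, p, _, _ in self.paralog_positions},
        ]
        seen: set = set()
        for cat in cats:
            if cat & seen:
                raise ValueError("planted categories must be position-disjoint")
            seen |= cat
        for e in self.edits:
            if not (0 < e.ratio < 1):
                raise ValueError("planted edit ratios must lie in (0, 1)")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# category\tchrom\tposition\tref\talt\tdetail1\tdetail2\tdetail3\n")
        for e in truth.edits:
            fh.write(f"edit\t{e.chrom}\t{e.pos + 1}\t{e.ref}\t{e.alt}\t"
                     f"{e.gene_from}>{e.gene_to}:{e.ratio:g}\t{e.feature}\t"
                     f"{int(e.in_seed_target)}\n")
        for b in truth.bias_errors:
            fh.write(f"bias_error\t{b.chrom}\t{b.pos + 1}\t{b.ref}\t{b.error_base}\t"
                     f"{b.biased_strand}\t{b.motif_context}\t.\n")
        for s in truth.snps:
            fh.write(f"snp\t{s.chrom}\t{s.pos + 1}\t{s.ref}\t{s.alt}\t"
                     f"{'known' if s.known else 'novel'}\t.\t.\n")
        for c, p, r, a in truth.paralog_positions:
            fh.write(f"paralog\t{c}\t{p + 1}\t{r}\t{a}\t{truth.paralog_gene}\t.\t.\n")


# ---------------------------------------------------------------------------
# Genome / annotation generation
# ---------------------------------------------------------------------------

def _build_gene(gene_idx: int, g0: int, strand: str, chrom: str,
                cfg: SimConfig) -> GeneModel:
    """Lay one spliced gene onto the genome starting at plus-strand g0."""
    cds1, cds2 = cfg.cds_exon_lens
    u3a, u3b = cfg.utr3_exon_lens
    elems = [("utr5", cfg.utr5_len), ("cds", cds1), ("intron", cfg.intron_len),
             ("cds", cds2), ("intron", cfg.intron_len), ("utr3", u3a),
             ("intron", cfg.utr3_intron_len), ("utr3", u3b)]
    if strand == "-":
        elems = elems[::-1]
    exons: list[tuple[int, int]] = []
    cds_lo, cds_hi = None, None
    pos = g0
    for kind, ln in elems:
        if kind != "intron":
            if exons and exons[-1][1] == pos:
                exons[-1] = (exons[-1][0], pos + ln)
            else:
                exons.append((pos, pos + ln))
            if kind == "cds":
                cds_lo = pos if cds_lo is None else min(cds_lo, pos)
                cds_hi = pos + ln if cds_hi is None else max(cds_hi, pos + ln)
        pos += ln
    return GeneModel(gene_id=f"gene{gene_idx:03d}", transcript_id=f"tx{gene_idx:03d}",
                     chrom=chrom, strand=strand, exons=exons,
                     cds_start=cds_lo, cds_end=cds_hi)


def generate_reference_and_annotation(cfg: SimConfig
                                      ) -> tuple[ReferenceGenome, list[GeneModel],
                                                 list[Mirna]]:
    """Random genome, spliced gene models on both strands, and microRNAs.

    Deterministic under ``cfg.rng_seed``; CDS lengths are divisible by 3
    by construction.
    """
    if sum(cfg.cds_exon_lens) % 3 != 0:
        raise ValueError("total CDS length must be divisible by 3")
    rng = np.random.default_rng([cfg.rng_seed, 11])
    gene_span = (cfg.utr5_len + sum(cfg.cds_exon_lens) + 2 * cfg.intron_len
                 + sum(cfg.utr3_exon_lens) + cfg.utr3_intron_len)
    genome_len = cfg.n_genes * (gene_span + cfg.gap_len) + cfg.gap_len
    seq = "".join(np.array(list(DNA_BASES))[rng.integers(0, 4, genome_len)])
    genome = ReferenceGenome({cfg.chrom_name: seq})
    models = []
    for i in range(cfg.n_genes):
        g0 = cfg.gap_len + i * (gene_span + cfg.gap_len)
        strand = "+" if i % 2 == 0 else "-"
        models.append(_build_gene(i, g0, strand, cfg.chrom_name, cfg))
    mirnas: list[Mirna] = []
    seeds_seen: set[str] = set()
    while len(mirnas) < cfg.n_mirnas:
        mat = "".join(np.array(list("ACGU"))[rng.integers(0, 4, cfg.mirna_len)])
        mir = Mirna(f"syn-miR-{len(mirnas) + 1}", mat)
        if mir.seed in seeds_seen:
            continue
        seeds_seen.add(mir.seed)
        mirnas.append(mir)
    return genome, models, mirnas


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

class _MutableGenome:
    """Plus-strand byte view of the genome, editable during planting."""

    def __init__(self, genome: ReferenceGenome):
        self.arrays = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}

    def get(self, chrom: str, pos: int) -> str:
        return chr(self.arrays[chrom][pos])

    def set(self, chrom: str, pos: int, base: str) -> None:
        self.arrays[chrom][pos] = ord(base)

    def freeze(self) -> ReferenceGenome:
        return ReferenceGenome({c: a.decode("ascii") for c, a in self.arrays.items()})


def _oriented(base: str, strand: str) -> str:
    return base if strand == "+" else complement(base)


def plant_truth(genome: ReferenceGenome, models: Sequence[GeneModel],
                mirnas: Sequence[Mirna], cfg: SimConfig
                ) -> tuple[ReferenceGenome, SyntheticTruth]:
    """Plant edits, strand-biased errors, SNPs, and a paralog region.

    Seed-target 7-mers and error-motif contexts are written into the
    reference, so the returned (new) genome must be the one serialized
    and used for read simulation. Placement is deterministic under the
    seed; infeasible requests (e.g. in-seed edits with no microRNAs)
    raise ``ValueError``.
    """
    rng = np.random.default_rng([cfg.rng_seed, 22])
    mut = _MutableGenome(genome)
    index = GeneIndex(models, genome)
    chrom = cfg.chrom_name
    class_arr = index.class_array(chrom)
    reserved = np.zeros(genome.length(chrom), dtype=bool)

    def reserve(pos: int, pad: int = 8) -> None:
        reserved[max(0, pos - pad):pos + pad + 1] = True

    def free(pos: int, pad: int = 8) -> bool:
        return not reserved[max(0, pos - pad):pos + pad + 1].any()

    def strand_at(pos: int) -> str:
        g = index.overlapping(chrom, pos)
        return g[0].strand if g else "+"

    # --- allocate edit counts per feature class --------------------------
    feat_counts: dict[str, int] = {}
    acc = 0
    items = sorted(cfg.edit_feature_weights.items())
    for i, (feat, w) in enumerate(items):
        n = (cfg.n_edits - acc) if i == len(items) - 1 else round(w * cfg.n_edits)
        feat_counts[feat] = n
        acc += n

    edits: list[PlantedEdit] = []
    n_in_seed = round(feat_counts.get("3UTR", 0) * cfg.edit_in_seed_fraction)
    if n_in_seed and not mirnas:
        raise ValueError("in-seed edits requested but no microRNAs generated")

    coding_models = [m for m in models if m.is_coding and
                     m.utr3_positions().size >= 7]

    def _pick_type() -> tuple[str, str]:
        return ("A", "G") if rng.random() < cfg.edit_ag_fraction else ("C", "T")

    ratios = cfg.edit_ratios

    def _pick_ratio() -> float:
        return float(ratios[rng.integers(len(ratios))])

    # --- in-seed-target 3'UTR edits: embed the target, edit inside it ----
    for _ in range(n_in_seed):
        placed = False
        for _attempt in range(200):
            m = coding_models[rng.integers(len(coding_models))]
            mir = mirnas[rng.integers(len(mirnas))]
            probe = reverse_complement(mir.seed_dna)  # transcript-oriented match
            from_b, to_b = _pick_type()
            offsets = [j for j, b in enumerate(probe) if b == from_b]
            if not offsets:
                continue
            j = offsets[rng.integers(len(offsets))]
            pos_map = m.utr3_positions()
            u = int(rng.integers(0, pos_map.size - 7 + 1))
            gpositions = pos_map[u:u + 7]
            if not all(free(int(g)) for g in gpositions):
                continue
            for k, g in enumerate(gpositions):
                mut.set(chrom, int(g), _oriented(probe[k], m.strand))
            gpos = int(gpositions[j])
            for g in gpositions:
                reserve(int(g), pad=2)
            reserve(gpos)
            edits.append(PlantedEdit(
                chrom=chrom, pos=gpos, ref=_oriented(from_b, m.strand),
                alt=_oriented(to_b, m.strand), gene_from=from_b, gene_to=to_b,
                ratio=_pick_ratio(), feature="3UTR", in_seed_target=True))
            placed = True
            break
        if not placed:
            raise ValueError("could not place an in-seed-target edit; "
                             "genome too crowded")

    # --- remaining edits: positions whose oriented base matches the type --
    feature_pools = {
        feat: np.nonzero(class_arr == code)[0]
        for feat, code in _FEATURE_CODE.items()}
    for feat, want in sorted(feat_counts.items()):
        remaining = want - sum(1 for e in edits if e.feature == feat)
        for _ in range(remaining):
            placed = False
            for _attempt in range(500):
                pool = feature_pools[feat]
                if pool.size == 0:
                    break
                pos = int(pool[rng.integers(pool.size)])
                if not free(pos):
                    continue
                strand = strand_at(pos)
                from_b, to_b = _pick_type()
                if _oriented(mut.get(chrom, pos), strand) != from_b:
                    continue
                reserve(pos)
                edits.append(PlantedEdit(
                    chrom=chrom, pos=pos, ref=_oriented(from_b, strand),
                    alt=_oriented(to_b, strand), gene_from=from_b, gene_to=to_b,
                    ratio=_pick_ratio(), feature=feat, in_seed_target=False))
                placed = True
                break
            if not placed:
                raise ValueError(f"could not place a planted edit in {feat}")

    # --- strand-biased error sites over exonic positions ------------------
    exonic = np.nonzero(np.isin(class_arr,
                                [_FEATURE_CODE[c] for c in ("coding", "3UTR", "5UTR")])
                        )[0]
    bias_errors: list[PlantedBiasError] = []
    n_motif = round(cfg.n_bias_errors * cfg.bias_motif_fraction)
    for i in range(cfg.n_bias_errors):
        placed = False
        for _attempt in range(500):
            pos = int(exonic[rng.integers(exonic.size)])
            if pos < 8 or not free(pos):
                continue
            ref = mut.get(chrom, pos)
            alts = [b for b in DNA_BASES if b != ref]
            err = alts[rng.integers(3)]
            strand = FORWARD if rng.random() < 0.5 else REVERSE
            if i < n_motif:
                motif = "GGC" + ("A" if rng.random() < 0.5 else "T") + "GG"
                for k, b in enumerate(motif):
                    mut.set(chrom, pos - 6 + k, b)
                tag = "GGCWGG"
            else:
                mut.set(chrom, pos - 2, "G")
                mut.set(chrom, pos - 1, "G")
                tag = "GG"
            reserve(pos)
            bias_errors.append(PlantedBiasError(chrom, pos, ref, err, strand, tag))
            placed = True
            break
        if not placed:
            raise ValueError("could not place a strand-biased error site")

    # --- SNP-like fixed differences ---------------------------------------
    snps: list[PlantedSnp] = []
    n_known = round(cfg.n_snps * cfg.snp_known_fraction)
    for i in range(cfg.n_snps):
        for _attempt in range(500):
            pos = int(exonic[rng.integers(exonic.size)])
            if not free(pos):
                continue
            ref = mut.get(chrom, pos)
            alts = [b for b in DNA_BASES if b != ref]
            alt = alts[rng.integers(3)]
            reserve(pos)
            snps.append(PlantedSnp(chrom, pos, ref, alt, known=i < n_known))
            break
        else:
            raise ValueError("could not place a SNP")

    # --- divergent paralog gene -------------------------------------------
    paralog_gene = None
    paralog_positions: list[tuple[str, int, str, str]] = []
    if cfg.paralog_divergences > 0 and models:
        pm = models[-1]
        paralog_gene = pm.gene_id
        cds_pos = pm.cds_positions()
        for _ in range(cfg.paralog_divergences):
            for _attempt in range(500):
                pos = int(cds_pos[rng.integers(cds_pos.size)])
                if not free(pos):
                    continue
                ref = mut.get(chrom, pos)
                reserve(pos)
                paralog_positions.append((chrom, pos, ref, complement(ref)))
                break
            else:
                raise ValueError("could not place a paralog divergence")

    new_genome = mut.freeze()
    truth = SyntheticTruth(edits=edits, bias_errors=bias_errors, snps=snps,
                           paralog_gene=paralog_gene,
                           paralog_positions=paralog_positions)
    return new_genome, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _special_table(truth: SyntheticTruth, genome: ReferenceGenome, cfg: SimConfig
                   ) -> tuple[dict[str, np.ndarray], dict[tuple[str, int], tuple]]:
    mask = {c: np.zeros(genome.length(c), dtype=bool) for c in genome.chroms()}
    table: dict[tuple[str, int], tuple] = {}
    for e in truth.edits:
        table[(e.chrom, e.pos)] = ("edit", e.alt, e.ratio)
        mask[e.chrom][e.pos] = True
    for b in truth.bias_errors:
        table[(b.chrom, b.pos)] = ("bias", b.error_base, b.biased_strand,
                                   cfg.bias_error_rate)
        mask[b.chrom][b.pos] = True
    for s in truth.snps:
        table[(s.chrom, s.pos)] = ("snp", s.alt)
        mask[s.chrom][s.pos] = True
    for c, p, _r, a in truth.paralog_positions:
        table[(c, p)] = ("paralog", a, cfg.paralog_mismatch_rate)
        mask[c][p] = True
    return mask, table


def _segments_from_positions(positions: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) runs of consecutive genomic positions."""
    runs = []
    start = prev = int(positions[0])
    for p in positions[1:]:
        p = int(p)
        if p == prev + 1:
            prev = p
        else:
            runs.append((start, prev - start + 1))
            start = prev = p
    runs.append((start, prev - start + 1))
    return runs


def simulate_reads(genome: ReferenceGenome, models: Sequence[GeneModel],
                   truth: SyntheticTruth, cfg: SimConfig, out_dir: str | Path
                   ) -> list[Path]:
    """Write one SAM per (tissue, replicate, run); returns the paths.

    Reads originate from spliced transcripts (plus a configurable
    fraction of genomic background reads), with random alignment
    orientation; planted positions modify read bases as configured. Base
    qualities are ``base_quality`` except a ``low_quality_fraction`` of
    bases at ``low_quality``.
    """
    if cfg.coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rl = cfg.read_length
    usable = [m for m in models if m.spliced_length >= rl]
    spliced_seqs = ["".join(genome[m.chrom][s:e] for s, e in m.exons)
                    for m in usable]
    splens = np.array([m.spliced_length for m in usable], dtype=np.float64)
    weights = splens / splens.sum()
    total_splen = float(splens.sum())
    mask, table = _special_table(truth, genome, cfg)
    cov_per_run = cfg.coverage_mean / cfg.n_runs
    target_reads = cov_per_run * total_splen / rl
    paths = []
    for t_idx, tissue in enumerate(cfg.tissues):
        for r_idx in range(cfg.n_replicates):
            rep = f"rep{r_idx + 1}"
            for run_idx in range(cfg.n_runs):
                run = f"run{run_idx + 1}"
                rng = np.random.default_rng(
                    [cfg.rng_seed, 33, t_idx, r_idx, run_idx])
                path = out_dir / f"{tissue}.{rep}.{run}.sam"
                _write_sample_sam(path, genome, usable, spliced_seqs, weights,
                                  mask, table, cfg, rng, tissue, rep, run,
                                  int(rng.poisson(target_reads)))
                paths.append(path)
    return paths


def _write_sample_sam(path: Path, genome: ReferenceGenome,
                      models: Sequence[GeneModel], spliced_seqs: Sequence[str],
                      weights: np.ndarray, mask, table, cfg: SimConfig,
                      rng: np.random.Generator, tissue: str, rep: str, run: str,
                      n_reads: int) -> None:
    if n_reads <= 0:
        raise ValueError("zero-coverage configuration: no reads to simulate")
    rl = cfg.read_length
    rg_id = f"{tissue}.{rep}.{run}"
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": genome.length(c)} for c in genome.chroms()],
        "RG": [{"ID": rg_id, "SM": f"{tissue}.{rep}", "DS": tissue,
                "LB": rep, "PU": run}],
    }
    n_bg = int(round(cfg.background_read_fraction * n_reads))
    tx_idx = rng.choice(len(models), size=n_reads, p=weights)
    tx_start = (rng.random(n_reads)
                * (np.array([m.spliced_length for m in models])[tx_idx] - rl + 1)
                ).astype(np.int64)
    rev_flags = rng.random(n_reads + n_bg) < 0.5
    lowq = rng.random((n_reads + n_bg, rl)) < cfg.low_quality_fraction
    chroms = genome.chroms()
    chrom_lens = np.array([genome.length(c) for c in chroms])
    bg_chrom = rng.integers(0, len(chroms), size=n_bg)
    bg_start = (rng.random(n_bg) * (chrom_lens[bg_chrom] - rl + 1)).astype(np.int64)

    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        ref_ids = {c: sam.get_tid(c) for c in chroms}
        for i in range(n_reads + n_bg):
            if i < n_reads:
                m = models[tx_idx[i]]
                chrom = m.chrom
                s = int(tx_start[i])
                positions = m.exon_positions[s:s + rl]
                bases = list(spliced_seqs[tx_idx[i]][s:s + rl])
            else:
                chrom = chroms[bg_chrom[i - n_reads]]
                s = int(bg_start[i - n_reads])
                positions = np.arange(s, s + rl)
                bases = list(genome[chrom][s:s + rl])
            reverse = bool(rev_flags[i])
            if mask[chrom][positions].any():
                for k in np.nonzero(mask[chrom][positions])[0]:
                    spec = table[(chrom, int(positions[k]))]
                    kind = spec[0]
                    if kind == "edit":
                        if rng.random() < spec[2]:
                            bases[k] = spec[1]
                    elif kind == "snp":
                        bases[k] = spec[1]
                    elif kind == "bias":
                        strand_name = REVERSE if reverse else FORWARD
                        if strand_name == spec[2] and rng.random() < spec[3]:
                            bases[k] = spec[1]
                    elif kind == "paralog":
                        if rng.random() < spec[2]:
                            bases[k] = spec[1]
            quals = np.full(rl, cfg.base_quality, dtype=np.uint8)
            quals[lowq[i]] = cfg.low_quality
            a = pysam.AlignedSegment()
            a.query_name = f"{rg_id}.{i}"
            a.query_sequence = "".join(bases)
            a.flag = 16 if reverse else 0
            a.reference_id = ref_ids[chrom]
            a.reference_start = int(positions[0])
            a.mapping_quality = 60
            runs = _segments_from_positions(positions)
            cigar = []
            for j, (rs, ln) in enumerate(runs):
                if j > 0:
                    gap = rs - (runs[j - 1][0] + runs[j - 1][1])
                    cigar.append((3, gap))  # N
                cigar.append((0, ln))  # M
            a.cigartuples = cigar
            a.query_qualities = quals.tolist()
            a.set_tag("RG", rg_id)
            sam.write(a)


# ---------------------------------------------------------------------------
# Orchestration and scoring
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimConfig, out_dir: str | Path) -> dict:
    """Generate, plant, and serialize a complete synthetic dataset.

    Returns a manifest with file paths plus the in-memory genome, models,
    microRNAs, and truth. The FASTA is written after planting so the
    on-disk genome matches the truth table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome0, models, mirnas = generate_reference_and_annotation(cfg)
    genome, truth = plant_truth(genome0, models, mirnas, cfg)
    write_fasta(genome, out_dir / "genome.fa")
    write_gene_models(models, out_dir / "genes.bed")
    write_mirnas(mirnas, out_dir / "mirnas.tsv")
    write_snps_vcf([(s.chrom, s.pos, s.ref, s.alt) for s in truth.snps if s.known],
                   out_dir / "snps_known.vcf")
    write_truth(truth, out_dir / "truth.tsv")
    sam_paths = simulate_reads(genome, models, truth, cfg, out_dir / "reads")
    return {
        "genome": genome, "models": models, "mirnas": mirnas, "truth": truth,
        "genome_fasta": out_dir / "genome.fa",
        "genes_bed": out_dir / "genes.bed",
        "mirnas_tsv": out_dir / "mirnas.tsv",
        "snps_vcf": out_dir / "snps_known.vcf",
        "truth_tsv": out_dir / "truth.tsv",
        "sam_paths": sam_paths,
    }


def score_calls_against_truth(sites: Sequence[EditingSiteCandidate],
                              truth: SyntheticTruth) -> dict:
    """Precision/recall of called sites against each planted category.

    A call matches truth iff it has the same (chrom, pos, alt).
    """
    called = {(s.chrom, s.pos, s.alt_base) for s in sites}
    edit_keys = {(e.chrom, e.pos, e.alt) for e in truth.edits}
    bias_keys = {(b.chrom, b.pos, b.error_base) for b in truth.bias_errors}
    snp_keys = {(s.chrom, s.pos, s.alt) for s in truth.snps}
    paralog_keys = {(c, p, a) for c, p, _r, a in truth.paralog_positions}
    tp = len(called & edit_keys)
    out = {
        "n_called": len(called),
        "edits": {"n_true": len(edit_keys), "n_recovered": tp,
                  "recall": tp / len(edit_keys) if edit_keys else None},
        "bias_errors_surviving": len(called & bias_keys),
        "snps_surviving": len(called & snp_keys),
        "paralog_surviving": len(called & paralog_keys),
        "precision": tp / len(called) if called else None,
    }
    return out
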