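"""Coverage-matched backgrounds, permutation enrichment, and microRNA
seed-target disruption/creation analysis.

Where editing sites fall in the genome is only interpretable against
where they *could* have been seen, so backgrounds are drawn from
positions with adequate read coverage. Enrichment p-values come from
permutation tests that redraw the same number of coverage-eligible
positions and ask how often the permuted statistic is as or more extreme
than observed; with the plus-one rule p = (k+1)/(N+1), so 1000 iterations
bound p below at 1/1001 (reported as p < 0.001 territory).

A microRNA seed target is an exact reverse-complement match of the
mature nucleotides 2-8 (7-mer) in a 3'UTR; an edit inside such a match
disrupts it, and an edit whose altered sequence forms a new match creates
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotate import GeneIndex, _FEATURE_CODE, FEATURE_CLASSES
from .io import (DNA_BASES, GeneModel, Mirna, ReferenceGenome, complement,
                 reverse_complement)
from .params import PipelineParams
from .pileup import EditingSiteCandidate, SamplePileup

SEED_LENGTH = 7


@dataclass
class PermutationResult:
    """Outcome of a one-sided permutation test (plus-one rule)."""

    observed: int
    n_permutations: int
    n_as_or_more_extreme: int
    p_value: float
    rng_seed: int | None = None
    expected_mean: float | None = None

    def __post_init__(self) -> None:
        expect = (self.n_as_or_more_extreme + 1) / (self.n_permutations + 1)
        if abs(self.p_value - expect) > 1e-12 or not (0 < self.p_value <= 1):
            raise ValueError("p_value must equal (k+1)/(N+1) and lie in (0,1]")


def _perm_result(observed: int, extreme: int, n_perm: int, seed,
                 expected_mean: float | None = None) -> PermutationResult:
    return PermutationResult(
        observed=observed, n_permutations=n_perm, n_as_or_more_extreme=extreme,
        p_value=(extreme + 1) / (n_perm + 1), rng_seed=seed,
        expected_mean=expected_mean)


# ---------------------------------------------------------------------------
# Coverage-eligible positions and background sampling
# ---------------------------------------------------------------------------

def eligible_positions(pileup: SamplePileup, min_coverage: int
                       ) -> list[tuple[str, np.ndarray]]:
    """Per-chromosome positions whose pooled coverage is >= ``min_coverage``."""
    out = []
    for chrom in sorted(pileup.counts):
        pos = np.nonzero(pileup.coverage(chrom) >= min_coverage)[0]
        if pos.size:
            out.append((chrom, pos))
    return out


def sample_background_positions(pileup: SamplePileup, n: int, min_coverage: int,
                                seed: int) -> list[tuple[str, int]]:
    """Uniform sample (without replacement) of coverage-eligible positions."""
    eligible = eligible_positions(pileup, min_coverage)
    flat = [(chrom, int(p)) for chrom, pos in eligible for p in pos]
    if len(flat) < n:
        raise ValueError(
            f"requested {n} background positions but only {len(flat)} positions "
            f"have coverage >= {min_coverage}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(flat), size=n, replace=False)
    return [flat[i] for i in idx]


# ---------------------------------------------------------------------------
# Genomic-feature enrichment
# ---------------------------------------------------------------------------

def feature_enrichment(sites: Sequence[EditingSiteCandidate],
                       pileup: SamplePileup, index: GeneIndex,
                       params: PipelineParams, seed: int | None = None,
                       ) -> dict[str, dict[str, PermutationResult]]:
    """Permutation enrichment/depletion of site feature classes.

    The observed per-class counts are compared against ``n_permutations``
    draws of ``len(sites)`` coverage-eligible positions classified the
    same way; one-sided p-values are reported separately for enrichment
    (permuted count >= observed) and depletion (<= observed).
    """
    if seed is None:
        seed = params.rng_seed
    if not sites:
        raise ValueError("feature enrichment of an empty site list is undefined")
    eligible = eligible_positions(pileup, params.background_min_coverage)
    codes_list = [index.class_array(chrom)[pos] for chrom, pos in eligible]
    if not codes_list:
        raise ValueError("no coverage-eligible background positions")
    codes = np.concatenate(codes_list)
    m = len(sites)
    if codes.size < m:
        raise ValueError(
            f"only {codes.size} eligible positions for draws of size {m}")
    observed = np.zeros(5, dtype=np.int64)
    for s in sites:
        observed[_FEATURE_CODE[s.feature]] += 1
    rng = np.random.default_rng(seed)
    n_perm = params.n_permutations
    ge = np.zeros(5, dtype=np.int64)
    le = np.zeros(5, dtype=np.int64)
    sums = np.zeros(5, dtype=np.float64)
    for _ in range(n_perm):
        draw = rng.choice(codes.size, size=m, replace=False)
        counts = np.bincount(codes[draw], minlength=5)
        ge += counts >= observed
        le += counts <= observed
        sums += counts
    out: dict[str, dict[str, PermutationResult]] = {}
    for cls, code in _FEATURE_CODE.items():
        out[cls] = {
            "enrichment": _perm_result(int(observed[code]), int(ge[code]),
                                       n_perm, seed, sums[code] / n_perm),
            "depletion": _perm_result(int(observed[code]), int(le[code]),
                                      n_perm, seed, sums[code] / n_perm),
        }
    return out


# ---------------------------------------------------------------------------
# microRNA seed targets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedTarget:
    """A 7-mer reverse-complement seed match in a transcript's 3'UTR.

    ``utr_offset`` indexes the match start in the mRNA-oriented 3'UTR
    sequence; ``genomic_intervals`` are plus-strand 0-based half-open and
    may split across a splice junction.
    """

    mirna_id: str
    seed: str  # RNA alphabet, mature nt 2-8
    transcript_id: str
    chrom: str
    utr_offset: int
    genomic_intervals: tuple[tuple[int, int], ...]

    @property
    def genomic_positions(self) -> list[int]:
        return [p for s, e in self.genomic_intervals for p in range(s, e)]


def _runs(sorted_positions: np.ndarray) -> tuple[tuple[int, int], ...]:
    ivals = []
    start = prev = int(sorted_positions[0])
    for p in sorted_positions[1:]:
        p = int(p)
        if p == prev + 1:
            prev = p
        else:
            ivals.append((start, prev + 1))
            start = prev = p
    ivals.append((start, prev + 1))
    return tuple(ivals)


def build_seed_targets(models: Sequence[GeneModel], genome: ReferenceGenome,
                       mirnas: Sequence[Mirna]) -> list[SeedTarget]:
    """All exact reverse-complement seed matches in every 3'UTR."""
    targets: list[SeedTarget] = []
    for m in models:
        utr = m.utr3_sequence(genome)
        if len(utr) < SEED_LENGTH:
            continue
        pos_map = m.utr3_positions()
        for mir in mirnas:
            probe = reverse_complement(mir.seed_dna)
            i = utr.find(probe)
            while i != -1:
                gpos = np.sort(pos_map[i:i + SEED_LENGTH])
                targets.append(SeedTarget(
                    mirna_id=mir.mirna_id, seed=mir.seed,
                    transcript_id=m.transcript_id, chrom=m.chrom,
                    utr_offset=i, genomic_intervals=_runs(gpos)))
                i = utr.find(probe, i + 1)
    return targets


def target_position_map(targets: Sequence[SeedTarget]
                        ) -> dict[tuple[str, int], set[str]]:
    """(chrom, pos) -> microRNA ids whose target interval covers it."""
    out: dict[tuple[str, int], set[str]] = {}
    for t in targets:
        for p in t.genomic_positions:
            out.setdefault((t.chrom, p), set()).add(t.mirna_id)
    return out


def detect_seed_disruption(sites: Sequence[EditingSiteCandidate],
                           targets: Sequence[SeedTarget]
                           ) -> list[EditingSiteCandidate]:
    """Flag 3'UTR sites lying inside >=1 seed-target interval."""
    pos_map = target_position_map(targets)
    flagged = []
    for s in sites:
        if s.feature != "3UTR":
            continue
        hits = pos_map.get((s.chrom, s.pos))
        if hits:
            s.mirna_disrupted = sorted(hits)
            flagged.append(s)
    return flagged


def _creating_mirnas(utr: str, li: int, alt_oriented: str,
                     seed_probes: Mapping[str, str]) -> set[str]:
    """microRNAs whose seed match appears at a window over position ``li``
    only after the edit (brute-force scan of all overlapping 7-mers)."""
    edited = utr[:li] + alt_oriented + utr[li + 1:]
    created: set[str] = set()
    for o in range(max(0, li - SEED_LENGTH + 1),
                   min(li, len(utr) - SEED_LENGTH) + 1):
        win_new = edited[o:o + SEED_LENGTH]
        win_old = utr[o:o + SEED_LENGTH]
        for mirna_id, probe in seed_probes.items():
            if win_new == probe and win_old != probe:
                created.add(mirna_id)
    return created


def detect_seed_creation(sites: Sequence[EditingSiteCandidate],
                         index: GeneIndex, genome: ReferenceGenome,
                         mirnas: Sequence[Mirna]
                         ) -> list[EditingSiteCandidate]:
    """Flag 3'UTR sites whose edit creates a new seed match.

    The edit is applied to the spliced 3'UTR sequence (strand-aware); the
    site is flagged iff some seed has a reverse-complement match
    overlapping the edited position in the edited sequence that was
    absent at that window before the edit.
    """
    probes = {m.mirna_id: reverse_complement(m.seed_dna) for m in mirnas}
    flagged = []
    for s in sites:
        if s.feature != "3UTR":
            continue
        created: set[str] = set()
        for m in index.overlapping(s.chrom, s.pos):
            if not m.is_coding:
                continue
            pos_map = m.utr3_positions()
            where = np.nonzero(pos_map == s.pos)[0]
            if where.size == 0:
                continue
            li = int(where[0])
            utr = m.utr3_sequence(genome)
            alt = s.alt_base if m.strand == "+" else complement(s.alt_base)
            created |= _creating_mirnas(utr, li, alt, probes)
        if created:
            s.mirna_created = sorted(created)
            flagged.append(s)
    return flagged


# ---------------------------------------------------------------------------
# Seed-target permutation tests
# ---------------------------------------------------------------------------

@dataclass
class _Utr3Position:
    chrom: str
    pos: int
    model: GeneModel
    local_index: int
    oriented_base: str


def seed_enrichment(sites_3utr: Sequence[EditingSiteCandidate],
                    pileup: SamplePileup, targets: Sequence[SeedTarget],
                    index: GeneIndex, genome: ReferenceGenome,
                    mirnas: Sequence[Mirna], params: PipelineParams,
                    seed: int | None = None) -> dict[str, PermutationResult]:
    """Permutation tests for seed-target disruption and creation.

    Disruption: the observed number of 3'UTR sites inside seed targets is
    compared to draws of the same number of coverage-eligible 3'UTR
    positions. Creation: each observed site's gene-oriented (from, to)
    pair is reassigned to a random eligible position whose oriented base
    matches ``from``, and the number of target-creating edits is
    recomputed per draw.
    """
    if seed is None:
        seed = params.rng_seed
    if not sites_3utr:
        raise ValueError("seed enrichment of an empty site list is undefined")
    records = _collect_utr3_records(pileup, index, genome,
                                    params.background_min_coverage)
    if len(records) < len(sites_3utr):
        raise ValueError(
            f"only {len(records)} eligible 3'UTR positions for draws of size "
            f"{len(sites_3utr)}")
    pos_map = target_position_map(targets)
    in_target = np.array([(r.chrom, r.pos) in pos_map for r in records])
    probes = {m.mirna_id: reverse_complement(m.seed_dna) for m in mirnas}

    rng = np.random.default_rng(seed)
    n_perm = params.n_permutations
    m_sites = len(sites_3utr)

    observed_disrupt = sum(1 for s in sites_3utr if s.mirna_disrupted)
    ge_d = 0
    sum_d = 0.0
    for _ in range(n_perm):
        draw = rng.choice(len(records), size=m_sites, replace=False)
        stat = int(in_target[draw].sum())
        ge_d += stat >= observed_disrupt
        sum_d += stat
    disruption = _perm_result(observed_disrupt, ge_d, n_perm, seed,
                              sum_d / n_perm)

    # creation: base-matched redraw with the observed substitution spectrum
    observed_create = sum(1 for s in sites_3utr if s.mirna_created)
    pairs = [(s.gene_from or s.ref_base, s.gene_to or s.alt_base)
             for s in sites_3utr]
    by_base: dict[str, np.ndarray] = {}
    for b in DNA_BASES:
        by_base[b] = np.nonzero(
            np.array([r.oriented_base == b for r in records]))[0]
    creates_lookup: dict[tuple[int, str], bool] = {}

    def _creates(rec_idx: int, to_base: str) -> bool:
        key = (rec_idx, to_base)
        if key not in creates_lookup:
            r = records[rec_idx]
            utr = r.model.utr3_sequence(genome)
            creates_lookup[key] = bool(
                _creating_mirnas(utr, r.local_index, to_base, probes))
        return creates_lookup[key]

    ge_c = 0
    sum_c = 0.0
    feasible = all(by_base[f].size > 0 for f, _ in pairs)
    if feasible:
        for _ in range(n_perm):
            stat = 0
            for f, t in pairs:
                pool = by_base[f]
                idx = int(pool[rng.integers(pool.size)])
                if _creates(idx, t):
                    stat += 1
            ge_c += stat >= observed_create
            sum_c += stat
        creation = _perm_result(observed_create, ge_c, n_perm, seed,
                                sum_c / n_perm)
    else:
        creation = _perm_result(observed_create, n_perm, n_perm, seed, None)
    return {"disruption": disruption, "creation": creation}


def _collect_utr3_records(pileup: SamplePileup, index: GeneIndex,
                          genome: ReferenceGenome, min_coverage: int
                          ) -> list[_Utr3Position]:
    """Coverage-eligible 3'UTR positions with transcript context and
    gene-oriented reference base."""
    records: list[_Utr3Position] = []
    code_3utr = _FEATURE_CODE["3UTR"]
    # cache each model's 3'UTR position array and a genomic->local lookup
    loc_cache: dict[str, dict[int, int]] = {}
    for chrom, pos_arr in eligible_positions(pileup, min_coverage):
        classes = index.class_array(chrom)[pos_arr]
        for p in pos_arr[classes == code_3utr]:
            p = int(p)
            best: tuple[str, GeneModel, int] | None = None
            for m in index.overlapping(chrom, p):
                if not m.is_coding:
                    continue
                if m.transcript_id not in loc_cache:
                    loc_cache[m.transcript_id] = {
                        int(g): i for i, g in enumerate(m.utr3_positions())}
                li = loc_cache[m.transcript_id].get(p)
                if li is None:
                    continue
                if best is None or m.transcript_id < best[0]:
                    best = (m.transcript_id, m, li)
            if best is None:
                continue
            _, m, li = best
            base = genome[chrom][p]
            if m.strand == "-":
                base = complement(base)
            records.append(_Utr3Position(chrom, p, m, li, base))
    return records
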