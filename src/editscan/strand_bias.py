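"""Fisher-exact strand-bias artifact filter and sequence-context profiling.

Systematic sequencer errors produce apparent edits supported almost
exclusively by reads sequenced in one direction, whereas genuine editing
is seen on reads of both orientations. Each candidate site covered by at
least 20 reads is tested with a two-sided Fisher exact test on the 2x2
table (edited forward, edited reverse / unedited forward, unedited
reverse); sites with a Bonferroni-corrected p < 0.05 are flagged as
strand-biased artifacts. Flagged sites tend to sit in characteristic
sequence contexts (a GGC[A/T]GG motif nearby, an immediately preceding
GG), which the profiling helpers quantify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .io import DNA_BASES, FORWARD, REVERSE, ReferenceGenome, reverse_complement
from .params import PipelineParams
from .pileup import EditingSiteCandidate, SamplePileup

#: relative tie tolerance when comparing hypergeometric point probabilities
_REL_TIE = 1e-7


@dataclass(frozen=True)
class BiasTable:
    """2x2 contingency table of edited/unedited reads by alignment strand."""

    edited_fwd: int
    edited_rev: int
    unedited_fwd: int
    unedited_rev: int

    def __post_init__(self) -> None:
        if min(self.edited_fwd, self.edited_rev,
               self.unedited_fwd, self.unedited_rev) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.edited_fwd + self.edited_rev + self.unedited_fwd + self.unedited_rev


def fisher_exact_2x2(table: BiasTable) -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    hypergeometric point probability does not exceed that of the observed
    table (point-probability two-sided criterion, with the conventional
    ``1 + 1e-7`` relative tie tolerance). An all-zero table is undefined
    and returns 1 with a warning.
    """
    a, b, c, d = (table.edited_fwd, table.edited_rev,
                  table.unedited_fwd, table.unedited_rev)
    n = a + b + c + d
    if n == 0:
        warnings.warn("Fisher test on an empty table; returning p=1", stacklevel=2)
        return 1.0
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + _REL_TIE)].sum())
    return min(p, 1.0)


def bias_table_for_site(site: EditingSiteCandidate,
                        pileup: SamplePileup) -> BiasTable:
    """Contingency table from pooled high-quality counts at a site.

    Edited rows count the caller's alternate base; unedited rows count the
    reference base; other mismatching bases are excluded.
    """
    mat = pileup.counts.get(site.chrom)
    if mat is None:
        return BiasTable(0, 0, 0, 0)
    alt = DNA_BASES.index(site.alt_base)
    ref = DNA_BASES.index(site.ref_base)
    col = mat[:, site.pos]
    return BiasTable(int(col[alt * 2]), int(col[alt * 2 + 1]),
                     int(col[ref * 2]), int(col[ref * 2 + 1]))


def apply_strand_bias_filter(sites: Sequence[EditingSiteCandidate],
                             pooled_pileup: SamplePileup,
                             params: PipelineParams,
                             ) -> list[EditingSiteCandidate]:
    """Annotate sites with strand-bias statistics and set the biased flag.

    Only sites whose contingency table totals at least
    ``min_reads_bias_test`` reads are tested; the Bonferroni multiplier is
    the number of tested sites in this run (all tissues combined). The
    flag is set iff the corrected p is below ``bias_alpha``. Untested
    sites carry no p-values and are never flagged. Sites are annotated in
    place and returned.
    """
    tested: list[tuple[EditingSiteCandidate, float]] = []
    for site in sites:
        table = bias_table_for_site(site, pooled_pileup)
        if table.total >= params.min_reads_bias_test:
            tested.append((site, fisher_exact_2x2(table)))
        else:
            site.bias_p_raw = None
            site.bias_p_bonferroni = None
            site.strand_biased = False
    m = len(tested)
    for site, p in tested:
        site.bias_p_raw = p
        site.bias_p_bonferroni = min(1.0, p * m)
        site.strand_biased = site.bias_p_bonferroni < params.bias_alpha
    return list(sites)


def split_by_bias(sites: Sequence[EditingSiteCandidate],
                  ) -> tuple[list[EditingSiteCandidate], list[EditingSiteCandidate]]:
    """(retained, strand-biased) partition after annotation."""
    kept = [s for s in sites if not s.strand_biased]
    flagged = [s for s in sites if s.strand_biased]
    return kept, flagged


# ---------------------------------------------------------------------------
# Sequence context of strand-biased sites
# ---------------------------------------------------------------------------

@dataclass
class ContextProfile:
    """Per-offset base frequencies around a set of aligned sites.

    ``frequencies`` has shape (2*window+1, 4) over A,C,G,T; offsets run
    from -window to +window with the site at index ``window``. ``counts``
    holds the number of defined (non-N, in-bounds) bases per offset.
    ``motif_hit_fraction`` is filled by :func:`scan_error_motif` callers.
    """

    window: int
    frequencies: np.ndarray
    counts: np.ndarray
    motif_hit_fraction: float | None = None

    def offset(self, k: int) -> np.ndarray:
        return self.frequencies[self.window + k]


def _oriented_context(site: EditingSiteCandidate, genome: ReferenceGenome,
                      window: int, orient: str,
                      pileup: SamplePileup | None) -> str:
    chrom_seq = genome[site.chrom]
    lo, hi = site.pos - window, site.pos + window + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(chrom_seq))
    seq = "N" * left_pad + chrom_seq[max(lo, 0):min(hi, len(chrom_seq))] + "N" * right_pad
    if orient == "edited_majority" and pileup is not None:
        mat = pileup.counts.get(site.chrom)
        if mat is not None:
            alt = DNA_BASES.index(site.alt_base)
            fwd, rev = int(mat[alt * 2, site.pos]), int(mat[alt * 2 + 1, site.pos])
            if rev > fwd:
                seq = reverse_complement(seq)
    return seq


def context_profile(sites: Sequence[EditingSiteCandidate],
                    genome: ReferenceGenome, window: int,
                    orient: str = "plus",
                    pileup: SamplePileup | None = None) -> ContextProfile:
    """Base-frequency profile of the +/-``window`` bp around the sites.

    ``orient='plus'`` reports plus-strand sequence; ``orient='edited_majority'``
    flips each site's window to the strand carrying most of its edited reads.
    """
    if not sites:
        raise ValueError("context profile of an empty site list is undefined")
    if orient not in ("plus", "edited_majority"):
        raise ValueError(f"unknown orientation {orient!r}")
    width = 2 * window + 1
    tallies = np.zeros((width, 4), dtype=np.int64)
    for site in sites:
        seq = _oriented_context(site, genome, window, orient, pileup)
        for i, base in enumerate(seq):
            code = DNA_BASES.find(base)
            if code >= 0:
                tallies[i, code] += 1
    counts = tallies.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = np.where(counts[:, None] > 0, tallies / np.maximum(counts, 1)[:, None],
                         np.nan)
    return ContextProfile(window=window, frequencies=freqs, counts=counts)


_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "W": "AT"}


def _motif_matches(seq: str, motif: str) -> list[int]:
    hits = []
    k = len(motif)
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in _IUPAC[motif[j]] for j in range(k)):
            hits.append(i)
    return hits


def scan_error_motif(sites: Sequence[EditingSiteCandidate],
                     genome: ReferenceGenome, motif: str = "GGCWGG",
                     window: int = 50) -> tuple[float, dict[tuple[str, int], list[int]]]:
    """Fraction of sites with a degenerate motif hit within +/-``window`` bp.

    A hit is an exact degenerate match on either strand whose footprint
    overlaps the window; per-site hit offsets (motif start relative to the
    site, plus-strand space) are returned alongside the fraction.
    """
    motif = motif.upper()
    bad = set(motif) - set(_IUPAC)
    if bad:
        raise ValueError(f"motif contains unsupported character(s) {sorted(bad)}")
    if not sites:
        return 0.0, {}
    rc = reverse_complement(motif)
    offsets: dict[tuple[str, int], list[int]] = {}
    n_hit = 0
    k = len(motif)
    for site in sites:
        chrom_seq = genome[site.chrom]
        lo = max(0, site.pos - window - (k - 1))
        hi = min(len(chrom_seq), site.pos + window + k)
        seq = chrom_seq[lo:hi]
        site_hits = []
        for m in (motif, rc):
            for start in _motif_matches(seq, m):
                gstart = lo + start
                # footprint [gstart, gstart+k) must overlap the window
                if gstart <= site.pos + window and gstart + k > site.pos - window:
                    site_hits.append(gstart - site.pos)
        if site_hits:
            n_hit += 1
            offsets[(site.chrom, site.pos)] = sorted(set(site_hits))
    return n_hit / len(sites), offsets
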