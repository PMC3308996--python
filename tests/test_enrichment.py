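"""Seed targets, disruption/creation, backgrounds, permutation tests."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from conftest import add_counts, balanced
from editscan.annotate import GeneIndex, classify_genomic_feature
from editscan.enrichment import (PermutationResult, SeedTarget,
                                 build_seed_targets, detect_seed_creation,
                                 detect_seed_disruption, feature_enrichment,
                                 sample_background_positions, seed_enrichment,
                                 target_position_map)
from editscan.io import (GeneModel, Mirna, ReferenceGenome,
                         reverse_complement)
from editscan.params import PipelineParams
from editscan.pileup import EditingSiteCandidate, SamplePileup

LET7 = Mirna("let-7", "UGAGGUAGUAGGUUGUAUAGUU")  # seed GAGGUAG -> probe CTACCTC


def make_gene(utr3, strand="+", cds="ATG" + "GGC" * 5 + "TAA", utr5="CCCCC",
              chrom="c", offset=10, split_at=None, intron=20, gene_id="g1"):
    """Genome + model whose mRNA is utr5+cds+utr3, optionally split into
    two exons at plus-orientation offset ``split_at``."""
    mrna = utr5 + cds + utr3
    plus = mrna if strand == "+" else reverse_complement(mrna)
    if strand == "+":
        cds_lo, cds_hi = offset + len(utr5), offset + len(utr5) + len(cds)
    else:
        cds_lo, cds_hi = offset + len(utr3), offset + len(utr3) + len(cds)
    if split_at is None:
        seq = "T" * offset + plus + "T" * 30
        exons = [(offset, offset + len(plus))]
    else:
        seq = ("T" * offset + plus[:split_at] + "A" * intron
               + plus[split_at:] + "T" * 30)
        exons = [(offset, offset + split_at),
                 (offset + split_at + intron, offset + len(plus) + intron)]
        if cds_lo >= offset + split_at:
            cds_lo += intron
        if cds_hi > offset + split_at:
            cds_hi += intron
    genome = ReferenceGenome({chrom: seq})
    model = GeneModel(gene_id, gene_id + ".t", chrom, strand, exons,
                      cds_lo, cds_hi)
    return genome, model


def _site(chrom, pos, ref, alt, feature="3UTR", **kw):
    s = EditingSiteCandidate(
        chrom=chrom, pos=pos, ref_base=ref, alt_base=alt, tissues=["x"],
        per_replicate={"x/r1": (3, 10, 0.3)}, pooled_edited=3, pooled_total=10)
    s.feature = feature
    for k, v in kw.items():
        setattr(s, k, v)
    return s


class TestBuildSeedTargets:
    def test_reverse_complement_match_found(self):
        genome, model = make_gene("AAAA" + "CTACCTC" + "AAAA")
        (t,) = build_seed_targets([model], genome, [LET7])
        assert t.mirna_id == "let-7"
        assert t.utr_offset == 4
        utr_pos = model.utr3_positions()
        expected = tuple(sorted(int(p) for p in utr_pos[4:11]))
        assert tuple(t.genomic_positions) == expected

    def test_empty_mirna_set(self):
        genome, model = make_gene("AAAACTACCTCAAAA")
        assert build_seed_targets([model], genome, []) == []

    def test_minus_strand_target(self):
        genome, model = make_gene("AAAA" + "CTACCTC" + "AAAA", strand="-")
        (t,) = build_seed_targets([model], genome, [LET7])
        # genomic plus-strand sequence at the match is revcomp of the probe
        lo, hi = t.genomic_intervals[0]
        assert genome["c"][lo:hi] == reverse_complement("CTACCTC")

    def test_target_spanning_junction_has_two_intervals(self):
        utr3 = "AAAA" + "CTACCTC" + "AAAA"
        # split inside the probe: mRNA offset of probe start = 5+21+4 = 30
        genome, model = make_gene(utr3, split_at=33)
        (t,) = build_seed_targets([model], genome, [LET7])
        assert len(t.genomic_intervals) == 2
        assert sum(e - s for s, e in t.genomic_intervals) == 7

    def test_matches_brute_force_on_random_utrs(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        mirnas = [Mirna(f"m{i}", "".join(
            np.array(list("ACGU"))[rng.integers(0, 4, 22)])) for i in range(10)]
        probes = {m.mirna_id: reverse_complement(m.seed_dna) for m in mirnas}
        for i in range(30):
            utr = "".join(bases[rng.integers(0, 4, 60)])
            if i % 3 == 0:  # guarantee some hits
                m = mirnas[int(rng.integers(len(mirnas)))]
                j = int(rng.integers(0, 54))
                utr = utr[:j] + probes[m.mirna_id] + utr[j + 7:]
            strand = "+" if i % 2 == 0 else "-"
            genome, model = make_gene(utr, strand=strand)
            got = {(t.mirna_id, t.utr_offset)
                   for t in build_seed_targets([model], genome, mirnas)}
            expected = {(mid, j) for mid, probe in probes.items()
                        for j in range(len(utr) - 6)
                        if utr[j:j + 7] == probe}
            assert got == expected


class TestSeedDisruption:
    def _setup(self):
        genome, model = make_gene("AAAA" + "CTACCTC" + "AAAA")
        targets = build_seed_targets([model], genome, [LET7])
        utr_pos = model.utr3_positions()
        return genome, model, targets, utr_pos

    def test_site_inside_interval_flagged(self):
        genome, model, targets, utr_pos = self._setup()
        s = _site("c", int(utr_pos[6]), "A", "G")
        assert detect_seed_disruption([s], targets) == [s]
        assert s.mirna_disrupted == ["let-7"]

    def test_site_one_base_outside_not_flagged(self):
        genome, model, targets, utr_pos = self._setup()
        s = _site("c", int(utr_pos[11]), "A", "G")  # match spans 4..10
        assert detect_seed_disruption([s], targets) == []

    def test_non_utr3_site_ignored(self):
        genome, model, targets, utr_pos = self._setup()
        s = _site("c", int(utr_pos[6]), "A", "G", feature="coding")
        assert detect_seed_disruption([s], targets) == []

    def test_overlapping_targets_record_both_mirnas(self):
        # two miRNAs whose probes overlap: CTACCTC and TACCTCA
        mir2 = Mirna("m2", "U" + "UGAGGUA" + "ACGUACGUACGUAG")  # seed UGAGGUA
        assert reverse_complement(mir2.seed_dna) == "TACCTCA"
        genome, model = make_gene("AAAA" + "CTACCTCA" + "AAA")
        targets = build_seed_targets([model], genome, [LET7, mir2])
        utr_pos = model.utr3_positions()
        s = _site("c", int(utr_pos[6]), "A", "G")
        detect_seed_disruption([s], targets)
        assert s.mirna_disrupted == ["let-7", "m2"]


class TestSeedCreation:
    def test_edit_creates_new_match(self):
        # CAGGUAG seed -> probe CTACCTG; UTR holds CTACCTA, edit A>G at its end
        mir = Mirna("mC", "ACAGGUAGAAAAAAAAAAAAAA")
        assert reverse_complement(mir.seed_dna) == "CTACCTG"
        genome, model = make_gene("AAAA" + "CTACCTA" + "AAAA")
        index = GeneIndex([model], genome)
        pos = int(model.utr3_positions()[10])  # the final A of CTACCTA
        assert genome["c"][pos] == "A"
        s = _site("c", pos, "A", "G")
        flagged = detect_seed_creation([s], index, genome, [mir])
        assert flagged == [s] and s.mirna_created == ["mC"]

    def test_preexisting_match_is_not_creation(self):
        genome, model = make_gene("AAAA" + "CTACCTC" + "AAAA")
        index = GeneIndex([model], genome)
        pos = int(model.utr3_positions()[8])
        s = _site("c", pos, genome["c"][pos], "G" if genome["c"][pos] != "G" else "T")
        detect_seed_creation([s], index, genome, [LET7])
        assert s.mirna_created == []

    def test_creation_consistency_with_rescan(self):
        """Applying the edit to the genome turns the creation into a plain match."""
        mir = Mirna("mC", "ACAGGUAGAAAAAAAAAAAAAA")
        utr3 = "AAAA" + "CTACCTA" + "AAAA"
        genome, model = make_gene(utr3)
        pos = int(model.utr3_positions()[10])
        edited_seq = genome["c"][:pos] + "G" + genome["c"][pos + 1:]
        edited_genome = ReferenceGenome({"c": edited_seq})
        targets = build_seed_targets([model], edited_genome, [mir])
        assert any(pos in t.genomic_positions for t in targets)

    def test_minus_strand_creation(self):
        mir = Mirna("mC", "ACAGGUAGAAAAAAAAAAAAAA")
        genome, model = make_gene("AAAA" + "CTACCTA" + "AAAA", strand="-")
        index = GeneIndex([model], genome)
        pos = int(model.utr3_positions()[10])
        assert genome["c"][pos] == "T"  # plus-strand image of the mRNA A
        s = _site("c", pos, "T", "C")   # gene-oriented A>G
        detect_seed_creation([s], index, genome, [mir])
        assert s.mirna_created == ["mC"]


class TestBackgroundSampling:
    def _pileup(self, genome, positions, cov=25):
        p = SamplePileup(genome)
        for pos in positions:
            add_counts(p, "c", pos, balanced("A", cov))
        return p

    def test_sample_is_distinct_eligible_and_deterministic(self):
        genome = ReferenceGenome({"c": "A" * 500})
        pile = self._pileup(genome, range(100, 200))
        a = sample_background_positions(pile, 10, 20, seed=3)
        b = sample_background_positions(pile, 10, 20, seed=3)
        assert a == b
        assert len(set(a)) == 10
        assert all(100 <= pos < 200 for _c, pos in a)

    def test_low_coverage_positions_excluded(self):
        genome = ReferenceGenome({"c": "A" * 500})
        pile = self._pileup(genome, range(100, 110), cov=25)
        for pos in range(300, 310):
            add_counts(pile, "c", pos, balanced("A", 19))
        sample = sample_background_positions(pile, 10, 20, seed=0)
        assert all(pos < 200 for _c, pos in sample)

    def test_requesting_more_than_eligible_raises(self):
        genome = ReferenceGenome({"c": "A" * 500})
        pile = self._pileup(genome, range(100, 105))
        with pytest.raises(ValueError, match="5 positions"):
            sample_background_positions(pile, 10, 20, seed=0)


class TestPermutationResult:
    def test_plus_one_rule_enforced(self):
        r = PermutationResult(observed=3, n_permutations=100,
                              n_as_or_more_extreme=4, p_value=5 / 101)
        assert r.p_value == pytest.approx(5 / 101)
        with pytest.raises(ValueError):
            PermutationResult(observed=3, n_permutations=100,
                              n_as_or_more_extreme=4, p_value=0.04)


def _enrichment_toy(n_utr_eligible=6, n_cds_eligible=6, cov=25):
    """A gene plus pileup giving exactly the requested eligible positions."""
    utr3 = "A" * 40
    genome, model = make_gene(utr3)
    index = GeneIndex([model], genome)
    utr_pos = [int(p) for p in model.utr3_positions()[:n_utr_eligible]]
    cds_pos = [int(p) for p in model.cds_positions()[:n_cds_eligible]]
    pile = SamplePileup(genome)
    for pos in utr_pos + cds_pos:
        add_counts(pile, "c", pos, balanced("G", cov))
    return genome, model, index, pile, utr_pos, cds_pos


class TestFeatureEnrichment:
    def test_degenerate_all_3utr_gives_p_one(self):
        genome, model, index, pile, utr_pos, _ = _enrichment_toy(
            n_utr_eligible=8, n_cds_eligible=0)
        sites = [_site("c", p, "A", "G") for p in utr_pos[:3]]
        params = PipelineParams(n_permutations=200)
        res = feature_enrichment(sites, pile, index, params, seed=1)
        assert res["3UTR"]["enrichment"].p_value == 1.0
        assert res["3UTR"]["depletion"].p_value == 1.0

    def test_observed_below_every_permutation(self):
        genome, model, index, pile, utr_pos, _ = _enrichment_toy(
            n_utr_eligible=8, n_cds_eligible=0)
        sites = [_site("c", utr_pos[0], "A", "G"),
                 _site("c", utr_pos[1], "A", "G", feature="coding"),
                 _site("c", utr_pos[2], "A", "G", feature="coding")]
        params = PipelineParams(n_permutations=200)
        res = feature_enrichment(sites, pile, index, params, seed=1)
        n = params.n_permutations
        assert res["3UTR"]["enrichment"].p_value == 1.0  # draws always give 3
        assert res["3UTR"]["depletion"].p_value == 1 / (n + 1)

    def test_matches_exact_enumeration_on_toy(self):
        genome, model, index, pile, utr_pos, cds_pos = _enrichment_toy()
        sites = [_site("c", utr_pos[0], "A", "G"),
                 _site("c", utr_pos[1], "A", "G"),
                 _site("c", cds_pos[0], "A", "G", feature="coding")]
        n_perm = 20_000
        params = PipelineParams(n_permutations=n_perm)
        res = feature_enrichment(sites, pile, index, params, seed=11)
        codes = [1] * 6 + [0] * 6  # 1 = 3UTR
        exact = (sum(1 for combo in itertools.combinations(codes, 3)
                     if sum(combo) >= 2) / math.comb(12, 3))
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert res["3UTR"]["enrichment"].p_value == pytest.approx(
            exact, abs=3 * se + 1 / n_perm)


class TestSeedEnrichment:
    def test_matches_exact_enumeration_on_toy(self):
        genome, model, index, pile, utr_pos, _ = _enrichment_toy(
            n_utr_eligible=12, n_cds_eligible=0)
        # put 5 of the 12 eligible positions inside a synthetic target
        targets = [SeedTarget("mX", "GAGGUAG", model.transcript_id, "c", 0,
                              ((utr_pos[0], utr_pos[0] + 5),))]
        in_target = set(range(utr_pos[0], utr_pos[0] + 5))
        sites = [_site("c", utr_pos[0], "A", "G", mirna_disrupted=["mX"]),
                 _site("c", utr_pos[1], "A", "G", mirna_disrupted=["mX"]),
                 _site("c", utr_pos[8], "A", "G")]
        n_perm = 20_000
        params = PipelineParams(n_permutations=n_perm)
        res = seed_enrichment(sites, pile, targets, index, genome, [LET7],
                              params, seed=13)
        k_in = sum(1 for p in utr_pos if p in in_target)
        exact = (sum(1 for combo in itertools.combinations(
                        [1] * k_in + [0] * (12 - k_in), 3) if sum(combo) >= 2)
                 / math.comb(12, 3))
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert res["disruption"].p_value == pytest.approx(
            exact, abs=3 * se + 1 / n_perm)

    def test_all_positions_in_targets_gives_p_one(self):
        genome, model, index, pile, utr_pos, _ = _enrichment_toy(
            n_utr_eligible=8, n_cds_eligible=0)
        targets = [SeedTarget("mX", "GAGGUAG", model.transcript_id, "c", 0,
                              ((min(utr_pos), max(utr_pos) + 1),))]
        sites = [_site("c", p, "A", "G", mirna_disrupted=["mX"])
                 for p in utr_pos[:3]]
        params = PipelineParams(n_permutations=200)
        res = seed_enrichment(sites, pile, targets, index, genome, [LET7],
                              params, seed=2)
        assert res["disruption"].p_value == 1.0

    def test_reproducible_under_seed(self):
        genome, model, index, pile, utr_pos, _ = _enrichment_toy(
            n_utr_eligible=12, n_cds_eligible=0)
        targets = [SeedTarget("mX", "GAGGUAG", model.transcript_id, "c", 0,
                              ((utr_pos[0], utr_pos[0] + 5),))]
        sites = [_site("c", utr_pos[0], "A", "G", mirna_disrupted=["mX"]),
                 _site("c", utr_pos[5], "A", "G")]
        params = PipelineParams(n_permutations=500)
        r1 = seed_enrichment(sites, pile, targets, index, genome, [LET7],
                             params, seed=9)
        r2 = seed_enrichment(sites, pile, targets, index, genome, [LET7],
                             params, seed=9)
        assert r1["disruption"].p_value == r2["disruption"].p_value
        assert r1["creation"].p_value == r2["creation"].p_value
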