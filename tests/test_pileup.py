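"""Pileup construction, pooling, candidate calling, and variant filters."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import add_counts, balanced, pileup_with
from editscan.io import (AlignedRead, FORWARD, REVERSE, ReadSegment,
                         ReferenceGenome)
from editscan.params import PipelineParams
from editscan.pileup import (SamplePileup, build_pileups, call_candidate_sites,
                             filter_fixed_sites, filter_known_snps,
                             merge_tissue_calls, pool_technical_replicates)
from editscan.simulate import score_calls_against_truth


def _read(read_id, chrom, start, bases, quals, strand=FORWARD,
          tissue="liver", rep="rep1", run="run1"):
    return AlignedRead(
        read_id=read_id, sample_id=f"{tissue}.{rep}", tissue=tissue,
        replicate=rep, run=run, chrom=chrom, start=start, strand=strand,
        segments=[ReadSegment(start, bases, np.array(quals))])


class TestBuildPileups:
    def test_no_reads_gives_empty_mapping(self, flat_genome):
        assert build_pileups([], flat_genome, PipelineParams()) == {}

    def test_counts_by_base_and_strand(self, flat_genome):
        reads = [_read("a", "chr1", 5, "A", [30]),
                 _read("b", "chr1", 5, "A", [30]),
                 _read("c", "chr1", 5, "G", [30], strand=REVERSE)]
        piles = build_pileups(reads, flat_genome, PipelineParams())
        col = piles[("liver", "rep1", "run1")].column("chr1", 5)
        assert col.hq_counts == {("A", FORWARD): 2, ("G", REVERSE): 1}
        assert col.total_coverage == 3
        assert col.ref_base == "A"

    def test_phred_threshold_is_strict(self, flat_genome):
        # Phred exactly 20 is excluded ("Phred score >20"); 21 is kept
        reads = [_read("a", "chr1", 0, "AG", [20, 21])]
        piles = build_pileups(reads, flat_genome, PipelineParams())
        pile = piles[("liver", "rep1", "run1")]
        assert pile.coverage("chr1")[0] == 0
        assert pile.coverage("chr1")[1] == 1

    def test_read_past_chromosome_end_raises(self, flat_genome):
        reads = [_read("a", "chr1", 1998, "AAAA", [30] * 4)]
        with pytest.raises(ValueError, match="a"):
            build_pileups(reads, flat_genome, PipelineParams())


class TestPoolTechnicalReplicates:
    def test_counts_sum_across_runs(self, flat_genome):
        reads = ([_read(f"a{i}", "chr1", 7, "G", [30], run="run1")
                  for i in range(3)] +
                 [_read(f"b{i}", "chr1", 7, "G", [30], run="run2")
                  for i in range(4)])
        piles = build_pileups(reads, flat_genome, PipelineParams())
        pooled = pool_technical_replicates(piles)
        col = pooled[("liver", "rep1")].column("chr1", 7)
        assert col.hq_counts[("G", FORWARD)] == 7

    def test_single_run_is_identity(self, flat_genome):
        reads = [_read("a", "chr1", 3, "ACG", [30] * 3)]
        piles = build_pileups(reads, flat_genome, PipelineParams())
        pooled = pool_technical_replicates(piles)
        np.testing.assert_array_equal(
            pooled[("liver", "rep1")].counts["chr1"],
            piles[("liver", "rep1", "run1")].counts["chr1"])

    def test_pooled_coverage_is_conserved(self, flat_genome):
        rng = np.random.default_rng(0)
        reads = [_read(f"r{i}", "chr1", int(rng.integers(0, 1990)),
                       "ACGTACGTAC", [30] * 10, run=f"run{1 + i % 3}")
                 for i in range(60)]
        piles = build_pileups(reads, flat_genome, PipelineParams())
        pooled = pool_technical_replicates(piles)
        total_runs = sum(p.coverage("chr1") for p in piles.values())
        total_pooled = sum(p.coverage("chr1") for p in pooled.values())
        np.testing.assert_array_equal(total_runs, total_pooled)


def _replicate_pileups(genome, per_rep_counts, pos=100, ref="A", alt="G"):
    """Three replicate pileups with (edited, total) at one position."""
    piles = {}
    for i, (edited, total) in enumerate(per_rep_counts):
        p = SamplePileup(genome)
        add_counts(p, "chr1", pos, balanced(alt, edited))
        add_counts(p, "chr1", pos, balanced(ref, total - edited))
        piles[f"rep{i + 1}"] = p
    return piles


class TestCallCandidateSites:
    @pytest.mark.parametrize("counts, expected", [
        ([(2, 30), (3, 40), (2, 25)], 1),   # 6.7/7.5/8.0% all pass
        ([(1, 10), (5, 50), (5, 50)], 0),   # rep1 below 2 edited reads
        ([(3, 100), (3, 100), (3, 100)], 0),  # 3% <= 5% threshold
        ([(2, 40), (2, 40), (2, 40)], 0),   # 5% exactly: strict > fails
    ])
    def test_replicate_thresholds(self, flat_genome, counts, expected):
        piles = _replicate_pileups(flat_genome, counts)
        sites = call_candidate_sites(piles, flat_genome, PipelineParams())
        assert len(sites) == expected
        if expected:
            s = sites[0]
            assert (s.ref_base, s.alt_base) == ("A", "G")
            assert s.pooled_edited == sum(e for e, _ in counts)
            assert s.pooled_total == sum(t for _, t in counts)

    def test_alt_base_highest_count_alphabetical_ties(self, flat_genome):
        piles = {}
        for r in ("rep1", "rep2", "rep3"):
            p = SamplePileup(flat_genome)
            add_counts(p, "chr1", 50, balanced("T", 5))
            add_counts(p, "chr1", 50, balanced("C", 5))  # tie with T -> C wins
            add_counts(p, "chr1", 50, balanced("A", 20))
            piles[r] = p
        (site,) = call_candidate_sites(piles, flat_genome, PipelineParams())
        assert site.alt_base == "C"

    def test_zero_replicates_is_config_error(self, flat_genome):
        with pytest.raises(ValueError):
            call_candidate_sites({}, flat_genome, PipelineParams())

    def test_replicate_count_mismatch_raises(self, flat_genome):
        piles = _replicate_pileups(flat_genome, [(5, 20), (5, 20)])
        with pytest.raises(ValueError, match="replicates"):
            call_candidate_sites(piles, flat_genome, PipelineParams())

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.tuples(st.integers(0, 15), st.integers(15, 60)),
                    min_size=3, max_size=3),
           st.integers(2, 5), st.sampled_from([0.05, 0.1, 0.2]))
    def test_calling_is_monotone_in_thresholds(self, counts, min_reads, ratio):
        genome = ReferenceGenome({"chr1": "A" * 200})
        piles = _replicate_pileups(genome, counts)
        loose = call_candidate_sites(piles, genome, PipelineParams())
        strict = call_candidate_sites(
            piles, genome,
            PipelineParams(min_edited_reads=min_reads, min_edit_ratio=ratio))
        assert {s.key for s in strict} <= {s.key for s in loose}

    def test_pooled_ratio_within_replicate_ratio_hull(self, flat_genome):
        counts = [(2, 30), (6, 40), (9, 25)]
        piles = _replicate_pileups(flat_genome, counts)
        (site,) = call_candidate_sites(piles, flat_genome, PipelineParams())
        ratios = [e / t for e, t in counts]
        assert min(ratios) <= site.pooled_ratio <= max(ratios)


class TestVariantFilters:
    def _one_site(self, flat_genome):
        piles = _replicate_pileups(flat_genome, [(5, 20), (5, 20), (5, 20)])
        return call_candidate_sites(piles, flat_genome, PipelineParams()), piles

    def test_known_snp_removed_and_disjoint(self, flat_genome):
        sites, _ = self._one_site(flat_genome)
        snps = {("chr1", 100), ("chr1", 500)}
        kept = filter_known_snps(sites, snps)
        assert kept == []
        assert all((s.chrom, s.pos) not in snps for s in kept)

    def test_empty_snpset_is_identity(self, flat_genome):
        sites, _ = self._one_site(flat_genome)
        assert filter_known_snps(sites, set()) == sites

    @pytest.mark.parametrize("ratios, removed", [
        ([1.0, 1.0, 1.0], True),
        ([1.0, 0.9, 1.0], False),
    ])
    def test_fixed_ratio_filter(self, flat_genome, ratios, removed):
        piles = {}
        for i, r in enumerate(ratios):
            total = 20
            edited = int(round(r * total))
            p = SamplePileup(flat_genome)
            add_counts(p, "chr1", 100, balanced("G", edited))
            add_counts(p, "chr1", 100, balanced("A", total - edited))
            piles[("liver", f"rep{i + 1}")] = p
        sites = call_candidate_sites(
            {k[1]: v for k, v in piles.items()}, flat_genome, PipelineParams())
        assert len(sites) == 1
        kept = filter_fixed_sites(sites, piles)
        assert (len(kept) == 0) is removed

    def test_single_covering_sample_at_100_percent_removed(self, flat_genome):
        # covered in only one sample, fully edited there -> conservative removal
        sites, piles = self._one_site(flat_genome)
        only = SamplePileup(flat_genome)
        add_counts(only, "chr1", 100, balanced("G", 30))
        fixed_site = call_candidate_sites(
            {"rep1": only, "rep2": only, "rep3": only},
            flat_genome, PipelineParams())
        kept = filter_fixed_sites(fixed_site, {("liver", "rep1"): only})
        assert kept == []


class TestMergeAndScore:
    def test_merge_tissue_calls_unions_and_tags(self, flat_genome):
        a = _replicate_pileups(flat_genome, [(5, 20), (5, 20), (5, 20)])
        sites_l = call_candidate_sites(a, flat_genome, PipelineParams(),
                                       tissue="liver")
        sites_b = call_candidate_sites(a, flat_genome, PipelineParams(),
                                       tissue="bone")
        merged = merge_tissue_calls({"liver": sites_l, "bone": sites_b})
        assert len(merged) == 1
        assert merged[0].tissues == ["bone", "liver"]
        assert merged[0].pooled_total == 120  # both tissues' replicates

    def test_score_precision_recall_arithmetic(self, flat_genome, small_manifest):
        truth = small_manifest["truth"]
        perfect = [
            type("S", (), {"chrom": e.chrom, "pos": e.pos, "alt_base": e.alt})()
            for e in truth.edits]
        res = score_calls_against_truth(perfect, truth)
        assert res["edits"]["recall"] == 1.0
        assert res["precision"] == 1.0
        res_none = score_calls_against_truth([], truth)
        assert res_none["edits"]["recall"] == 0.0
        assert res_none["precision"] is None


def test_completeness_on_synthetic_truth(small_manifest):
    """Every planted edit meeting the calling rule in all replicates is called."""
    from editscan.io import read_alignments
    from editscan.pileup import build_pileups

    genome = small_manifest["genome"]
    params = PipelineParams()
    run_piles = {}
    for path in small_manifest["sam_paths"]:
        for key, pile in build_pileups(read_alignments(path), genome,
                                       params).items():
            if key in run_piles:
                run_piles[key].add(pile)
            else:
                run_piles[key] = pile
    pooled = pool_technical_replicates(run_piles)
    by_rep = {rep: p for (_t, rep), p in pooled.items()}
    called = {s.key for s in
              call_candidate_sites(by_rep, genome, params, tissue="liver")}
    alt_code = {b: i for i, b in enumerate("ACGT")}
    for e in small_manifest["truth"].edits:
        qualifies = True
        for p in by_rep.values():
            col = p.counts[e.chrom][:, e.pos]
            edited = col[alt_code[e.alt] * 2] + col[alt_code[e.alt] * 2 + 1]
            total = col.sum()
            if not (edited >= 2 and total > 0 and edited / total > 0.05):
                qualifies = False
        if qualifies:
            assert (e.chrom, e.pos, e.alt) in called
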