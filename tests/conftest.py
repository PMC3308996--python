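"""Shared fixtures: hand-built genomes/pileups and a small synthetic run."""

from __future__ import annotations

import numpy as np
import pytest

from editscan.io import DNA_BASES, FORWARD, REVERSE, GeneModel, ReferenceGenome
from editscan.params import PipelineParams
from editscan.pileup import SamplePileup
from editscan.pipeline import run_pipeline
from editscan.simulate import SimConfig, simulate_dataset


def add_counts(pileup: SamplePileup, chrom: str, pos: int,
               counts: dict[tuple[str, str], int]) -> None:
    """Add (base, strand) -> count at one position."""
    for (base, strand), n in counts.items():
        if n:
            pileup.add_bases(chrom, np.full(n, pos, dtype=np.int64),
                             np.full(n, DNA_BASES.index(base), dtype=np.uint8),
                             strand == REVERSE)


def pileup_with(genome: ReferenceGenome,
                spec: dict[tuple[str, int], dict[tuple[str, str], int]]
                ) -> SamplePileup:
    """Build a pileup from {(chrom, pos): {(base, strand): count}}."""
    p = SamplePileup(genome)
    for (chrom, pos), counts in spec.items():
        add_counts(p, chrom, pos, counts)
    return p


def balanced(base: str, n: int) -> dict[tuple[str, str], int]:
    """n reads of one base split evenly across alignment strands."""
    return {(base, FORWARD): n // 2, (base, REVERSE): n - n // 2}


@pytest.fixture(scope="session")
def flat_genome() -> ReferenceGenome:
    """A featureless 2 kb all-A chromosome for pure counting tests."""
    return ReferenceGenome({"chr1": "A" * 2000})


@pytest.fixture(scope="session")
def coding_gene_setup() -> dict:
    """A crafted genome with one plus- and one minus-strand coding gene.

    Plus gene "gplus" on t1: exon [10,190), CDS [40,160) starting
    ATG AAA CTA; minus gene "gminus" on t1: exon [300,480), CDS [330,450)
    whose mRNA likewise starts ATG AAA CTA.
    """
    seq = list("T" * 600)
    cds = "ATGAAACTA" + "GGC" * 37  # 120 nt, 40 codons
    assert len(cds) == 120
    # plus-strand gene: genomic == mRNA
    seq[10:40] = list("C" * 30)          # 5'UTR
    seq[40:160] = list(cds)
    seq[160:190] = list("C" * 30)        # 3'UTR
    # minus-strand gene: mRNA is the reverse complement of genomic
    from editscan.io import reverse_complement
    seq[330:450] = list(reverse_complement(cds))
    seq[300:330] = list("G" * 30)        # 3'UTR (genomic left = mRNA right)
    seq[450:480] = list("G" * 30)        # 5'UTR
    genome = ReferenceGenome({"t1": "".join(seq)})
    gplus = GeneModel("gplus", "gplus.t1", "t1", "+", [(10, 190)], 40, 160)
    gminus = GeneModel("gminus", "gminus.t1", "t1", "-", [(300, 480)], 330, 450)
    return {"genome": genome, "models": [gplus, gminus]}


@pytest.fixture(scope="session")
def default_params() -> PipelineParams:
    return PipelineParams()


SMALL_SIM = dict(rng_seed=5, n_genes=6, n_edits=15, n_bias_errors=8, n_snps=4,
                 paralog_divergences=4, coverage_mean=30.0, tissues=("liver",))


@pytest.fixture(scope="session")
def small_manifest(tmp_path_factory):
    """A small single-tissue synthetic dataset, generated once per session."""
    out = tmp_path_factory.mktemp("small_sim")
    return simulate_dataset(SimConfig(**SMALL_SIM), out)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Full pipeline run over the small synthetic dataset."""
    out = tmp_path_factory.mktemp("small_run")
    config = {
        "out_dir": str(out),
        "params": {"rng_seed": 5, "n_permutations": 300, "n_background": 2000},
        "sim": dict(SMALL_SIM),
    }
    report, retained = run_pipeline(config)
    return {"config": config, "out_dir": out, "report": report,
            "retained": retained}
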