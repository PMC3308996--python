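"""Pipeline-wide thresholds and tuning knobs.

Every default mirrors the published analysis this package reimplements:
candidate sites need >=2 high-quality edited reads at an edit ratio
strictly greater than 5% in every biological replicate; base calls count
only when their Phred score is strictly greater than 20; the strand-bias
Fisher test is applied to sites covered by at least 20 reads and filtered
at a Bonferroni-corrected p < 0.05; enrichment p-values come from
1000-iteration permutation tests against coverage-matched backgrounds of
10,000 sampled positions (coverage >= 20).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class PipelineParams:
    """Thresholds controlling candidate calling, filtering, and enrichment.

    Attributes
    ----------
    min_edited_reads:
        Minimum high-quality edited reads per biological replicate (>=).
    min_edit_ratio:
        Edit-ratio threshold per replicate; strict lower bound (ratio > value).
    min_base_phred:
        Strict lower bound on the Phred score of a counted base (Phred > value).
    min_reads_bias_test:
        Minimum reads (contingency-table total) for the strand-bias test.
    bias_alpha:
        Family-wise alpha for the Bonferroni-corrected strand-bias filter.
    n_permutations:
        Iterations for permutation enrichment tests.
    n_background:
        Size of the coverage-matched background sample used for the
        genomic-distribution report.
    background_min_coverage:
        Minimum pooled coverage for a position to be background-eligible.
    motif_window:
        Half-width (bp) of the sequence-context window around a site.
    n_replicates:
        Number of biological replicates a tissue must provide.
    max_gene_artifact_fraction:
        A gene holding more than this fraction of all unbiased
        non-canonical sites is flagged as a suspect cluster (the
        reference-genome/paralog failure mode).
    error_motif:
        Degenerate DNA motif scanned near strand-biased sites.
    rng_seed:
        Master seed for every stochastic step.
    """

    min_edited_reads: int = 2
    min_edit_ratio: float = 0.05
    min_base_phred: int = 20
    min_reads_bias_test: int = 20
    bias_alpha: float = 0.05
    n_permutations: int = 1000
    n_background: int = 10_000
    background_min_coverage: int = 20
    motif_window: int = 50
    n_replicates: int = 3
    max_gene_artifact_fraction: float = 0.25
    error_motif: str = "GGCWGG"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_edited_reads", "min_base_phred", "min_reads_bias_test",
                     "n_permutations", "n_background", "background_min_coverage",
                     "n_replicates"):
            if getattr(self, name) <= 0 and name != "min_base_phred":
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("min_edit_ratio", "bias_alpha", "max_gene_artifact_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.motif_window < 0:
            raise ValueError("motif_window must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
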