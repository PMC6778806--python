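"""Configuration objects for the simulator, caller, site filters and screens.

Defaults encode the study conditions: a conifer seed-family design with six
unrelated mother trees, per-bp scaled mutation rate theta = 4.2e-3, STAR-like
mapping rules (unique-best placement, mismatch fraction <= 0.025 over 150-bp
reads) and the vcftools-style site filters (depth >= 10, missing <= 0.5,
biallelic SNPs with QUAL > 20).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


def _harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n + 1))


@dataclass
class SimConfig:
    """Parameters of the population / family / sequencing simulator."""

    n_genes: int = 100
    gene_length: int = 1500
    paralog_fraction: float = 0.0
    paralog_divergence: float = 0.02
    theta: float = 0.0042
    n_mothers: int = 6
    n_pool_haplotypes: int = 40
    isoforms_per_gene: int = 1
    expression_logmean: float = 0.0
    expression_logsd: float = 0.5
    mean_depth: float = 30.0
    error_rate: float = 0.001
    map_max_mismatch_frac: float = 0.025
    map_unique_only: bool = True
    read_len: int = 150
    map_window_step: int = 30  # window start spacing; read_len/step windows cover a site
    cluster_identity: float = 0.95
    block_merge_identity: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_mothers < 1:
            raise ValueError("n_mothers must be >= 1")
        if self.gene_length < self.read_len:
            raise ValueError("gene_length must be >= read_len")
        for name in ("paralog_fraction", "paralog_divergence", "error_rate",
                     "map_max_mismatch_frac", "cluster_identity",
                     "block_merge_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.n_pool_haplotypes < 2 * self.n_mothers:
            raise ValueError(
                "n_pool_haplotypes must be >= 2*n_mothers so that unrelated "
                "maternal haplotypes can be drawn without replacement")
        if self.isoforms_per_gene < 1:
            raise ValueError("isoforms_per_gene must be >= 1")
        if not 1 <= self.map_window_step <= self.read_len:
            raise ValueError("map_window_step must be in [1, read_len]")
        if self.segregation_probability() > 1.0:
            raise ValueError(
                f"theta={self.theta} too large: implied per-site segregation "
                f"probability {self.segregation_probability():.3f} exceeds 1")

    def segregation_probability(self) -> float:
        """Per-site probability of segregating in the haplotype pool.

        Calibrated so that the pool's expected all-pairs pairwise diversity
        per bp equals theta: with derived-allele counts i drawn with
        P(i) ~ 1/i (neutral SFS, i = 1..n-1), the expected pairwise difference
        per segregating site is 1/a where a = sum_{i<n} 1/i, hence the
        segregation probability is theta * a.
        """
        return self.theta * _harmonic(self.n_pool_haplotypes - 1)


@dataclass
class CallerParams:
    """Simplified diploid genotype caller.

    An allele is retained at a sample's site iff its read count is >=
    min_allele_count and its frequency among the sample's reads is >=
    min_allele_frac. error_rate is the caller's assumed per-base error used
    in the genotype-likelihood quality score (floored away from zero so the
    likelihood stays proper even for error-free simulations).
    """

    min_allele_count: int = 2
    min_allele_frac: float = 0.2
    error_rate: float = 0.01

    def validate(self) -> None:
        if self.min_allele_count < 1:
            raise ValueError("min_allele_count must be >= 1")
        if not 0.0 <= self.min_allele_frac <= 1.0:
            raise ValueError("min_allele_frac must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class FilterParams:
    """vcftools-style site filters."""

    min_depth: int = 10
    max_missing: float = 0.5
    min_qual: float = 20.0
    biallelic_only: bool = True


@dataclass
class ScreenParams:
    """Thresholds of the transcript screening rules."""

    multi_copy_identity: float = 85.0   # strict > for the multi-copy rule
    edge_trim: int = 10                 # bp trimmed from each alignment edge
    min_coverage: float = 0.5           # single-copy coverage requirement
    organelle_evalue: float = 5e-2
    organelle_identity: float = 80.0
    contaminant_evalue: float = 1e-5
    contaminant_identity: float = 65.0
    tpm_cutoff: float = 10.0
    # internal self-alignment thresholds used for mosaic detection
    selfhit_min_len: int = 60
    selfhit_min_identity: float = 80.0


@dataclass
class PipelineConfig:
    """Full pipeline configuration; serializable and round-trippable."""

    sim: SimConfig = field(default_factory=SimConfig)
    caller: CallerParams = field(default_factory=CallerParams)
    filters: FilterParams = field(default_factory=FilterParams)
    screen: ScreenParams = field(default_factory=ScreenParams)
    strategies: tuple = ("redundant", "clustered", "supertranscript")
    min_callable: int = 100
    outdir: str = "haplopsc_out"

    def validate(self) -> None:
        self.sim.validate()
        self.caller.validate()
        for s in self.strategies:
            if s not in ("redundant", "clustered", "supertranscript"):
                raise ValueError(f"unknown strategy: {s}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        return cls(
            sim=SimConfig(**d["sim"]),
            caller=CallerParams(**d["caller"]),
            filters=FilterParams(**d["filters"]),
            screen=ScreenParams(**d["screen"]),
            strategies=tuple(d["strategies"]),
            min_callable=d["min_callable"],
            outdir=d["outdir"],
        )
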