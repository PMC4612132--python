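"""Pipeline configuration.

Every threshold the pipeline uses lives here with the published default, so a
single config file documents a run completely.  All values can be overridden
from a JSON key/value file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    """Thresholds and parameters shared across pipeline stages.

    Attributes
    ----------
    bsr_threshold_general:
        BLAST-score-ratio cutoff for the genome-wide shared/unique
        partitioning (0.4).
    bsr_threshold_trg:
        Relaxed BSR cutoff used when re-screening toxin-related genes
        against the reference sets (0.2).
    hit_min_query_coverage:
        Minimum fraction of the query covered by the local alignment for a
        hit to be retained (0.5, i.e. at least half the gene length).
    hit_min_similarity:
        Minimum percent similarity (BLAST "positives") for a hit, strict
        inequality (25 means ">25%").
    hit_max_evalue_network:
        E-value ceiling for hits entering the similarity network (1e-5).
    hit_max_evalue_screen:
        Relaxed e-value ceiling for the external homology screen (1e-3).
    network_max_steps:
        Maximum number of cluster-graph steps joining a cluster to a
        TRG-containing cluster (2).
    min_gene_length_bp:
        Genes shorter than this are excluded from SNP-density scoring (150).
    coverage_cap / coverage_floor:
        Pileup depth normalisation bounds (200 / 5).
    min_read_identity:
        Contract on the upstream read mapping feeding the pileups (0.90);
        recorded for provenance, not enforced here.
    min_variant_qual:
        Phred-scaled minimum confidence for a PASS variant (20).
    indel_mask_bp:
        Half-width of the exclusion zone around indel evidence (5).
    n_permutations:
        Label permutations for PERMANOVA (9999).
    normalization_factor:
        Per-genome TRG counts are divided by the gene total and multiplied
        by this factor (1000).
    """

    bsr_threshold_general: float = 0.4
    bsr_threshold_trg: float = 0.2
    hit_min_query_coverage: float = 0.5
    hit_min_similarity: float = 25.0
    hit_max_evalue_network: float = 1e-5
    hit_max_evalue_screen: float = 1e-3
    network_max_steps: int = 2
    min_gene_length_bp: int = 150
    coverage_cap: int = 200
    coverage_floor: int = 5
    min_read_identity: float = 0.90
    min_variant_qual: float = 20.0
    indel_mask_bp: int = 5
    n_permutations: int = 9999
    normalization_factor: float = 1000.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bsr_threshold_trg <= self.bsr_threshold_general <= 1.0:
            raise ValueError("BSR thresholds must satisfy 0 <= trg <= general <= 1")
        if not 0.0 <= self.hit_min_query_coverage <= 1.0:
            raise ValueError("hit_min_query_coverage must be in [0, 1]")
        if not 0.0 <= self.hit_min_similarity <= 100.0:
            raise ValueError("hit_min_similarity must be in [0, 100]")
        if self.coverage_floor > self.coverage_cap:
            raise ValueError("coverage_floor must not exceed coverage_cap")
        for name in ("network_max_steps", "min_gene_length_bp", "indel_mask_bp",
                     "n_permutations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        """Load a config, overriding defaults with keys present in *path*."""
        with open(path) as fh:
            overrides = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**overrides)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
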