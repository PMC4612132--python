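"""Shared domain types.

Coordinates follow the GFF convention externally (1-based, inclusive); any
internal slicing converts explicitly.  Protein alphabets are the 20 standard
amino acids plus X for ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio.Seq import Seq

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
TRANSLATION_TABLE = 11  # bacterial


@dataclass
class ProteinSeq:
    protein_id: str
    genome_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """A protein-coding gene: coordinates plus nucleotide and protein sequence.

    ``start``/``end`` are 1-based inclusive on the forward strand of
    ``contig``; ``nucleotide_seq`` is the coding sequence already
    strand-corrected (i.e. it starts with the start codon).
    """

    gene_id: str
    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    nucleotide_seq: str
    protein_seq: str = ""
    annotation: str = ""
    partial: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.nucleotide_seq and len(self.nucleotide_seq) != self.length_bp:
            raise ValueError(
                f"gene {self.gene_id}: sequence length "
                f"{len(self.nucleotide_seq)} != span {self.length_bp}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def n_bp(self) -> int:
        """Number of unknown (N) bases in the coding sequence."""
        return self.nucleotide_seq.upper().count("N")

    def translate(self) -> str:
        """Translate the coding sequence (table 11), dropping a trailing stop.

        A length not divisible by 3 is truncated to the last full codon and
        the gene flagged partial.
        """
        seq = self.nucleotide_seq
        rem = len(seq) % 3
        if rem:
            seq = seq[:-rem]
            self.partial = True
        prot = str(Seq(seq).translate(table=TRANSLATION_TABLE))
        if prot.endswith("*"):
            prot = prot[:-1]
        # internal stops mark pseudogene-like or mispredicted models
        self.protein_seq = prot.replace("*", "X")
        return self.protein_seq


@dataclass
class GenomeSet:
    """A named collection of genomes with their proteomes and gene models."""

    set_id: str
    genomes: list[str] = field(default_factory=list)
    proteins: list[ProteinSeq] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    partial: bool = False

    def __post_init__(self) -> None:
        members = set(self.genomes)
        for p in self.proteins:
            if p.genome_id not in members:
                raise ValueError(
                    f"protein {p.protein_id}: genome {p.genome_id} "
                    f"not in set {self.set_id}")
        for g in self.genes:
            if g.genome_id not in members:
                raise ValueError(
                    f"gene {g.gene_id}: genome {g.genome_id} "
                    f"not in set {self.set_id}")

    def proteins_of(self, genome_id: str) -> list[ProteinSeq]:
        return [p for p in self.proteins if p.genome_id == genome_id]

    def genes_of(self, genome_id: str) -> list[GeneModel]:
        return [g for g in self.genes if g.genome_id == genome_id]

    @property
    def total_genes(self) -> dict[str, int]:
        counts = {g: 0 for g in self.genomes}
        for gene in self.genes:
            counts[gene.genome_id] += 1
        if not self.genes:  # protein-only set
            for p in self.proteins:
                counts[p.genome_id] += 1
        return counts

    def check_complete(self) -> None:
        """A complete set has one protein per gene in every genome."""
        per_genome_prot: dict[str, int] = {g: 0 for g in self.genomes}
        for p in self.proteins:
            per_genome_prot[p.genome_id] += 1
        per_genome_gene = {g: 0 for g in self.genomes}
        for gene in self.genes:
            per_genome_gene[gene.genome_id] += 1
        mismatch = {g for g in self.genomes
                    if self.genes and per_genome_prot[g] != per_genome_gene[g]}
        self.partial = bool(mismatch)


@dataclass
class AlignmentHit:
    """One local alignment passing (or to be tested against) the hit filter."""

    query_id: str
    subject_id: str
    raw_score: float
    bitscore: float
    evalue: float
    percent_identity: float
    percent_similarity: float
    query_coverage: float
    subject_coverage: float
    query_start: int = 0   # 1-based inclusive aligned interval
    query_end: int = 0
    subject_start: int = 0
    subject_end: int = 0
    length: int = 0        # alignment columns
    mismatch: int = 0
    gapopen: int = 0

    def __post_init__(self) -> None:
        if self.raw_score < 0:
            raise ValueError("raw_score must be >= 0")
        if self.percent_identity > self.percent_similarity + 1e-9:
            raise ValueError("identity cannot exceed similarity")


@dataclass
class BsrRecord:
    """BLAST score ratio of a query against a reference set."""

    query_id: str
    reference_set_id: str
    self_score: float
    best_score: float
    best_subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.self_score <= 0:
            raise ValueError(f"{self.query_id}: self_score must be positive")
        if self.best_score < 0:
            raise ValueError(f"{self.query_id}: best_score must be >= 0")

    @property
    def bsr(self) -> float:
        return self.best_score / self.self_score


@dataclass
class VennPartition:
    """Shared/unique partition of one genome's genes against two reference sets."""

    genome_id: str
    shared_both: list[str]
    shared_a_only: list[str]
    shared_b_only: list[str]
    unique: list[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "shared_both": len(self.shared_both),
            "shared_a_only": len(self.shared_a_only),
            "shared_b_only": len(self.shared_b_only),
            "unique": len(self.unique),
        }

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class RepeatHit:
    protein_id: str
    repeat_class: str          # YD | RTX
    copies: int
    intervals: list[tuple[int, int]]  # 1-based aa, sorted, non-overlapping
    score: float

    def __post_init__(self) -> None:
        if self.copies != len(self.intervals):
            raise ValueError("copies must equal number of intervals")
        for (s1, e1), (s2, e2) in zip(self.intervals, self.intervals[1:]):
            if s2 <= e1:
                raise ValueError("intervals must be sorted and non-overlapping")


@dataclass
class DomainHit:
    protein_id: str
    domain: str                # ACD | RID | CPD | RHS
    profile_score: float
    interval: tuple[int, int]  # 1-based aa


@dataclass
class TrgAnnotation:
    """Final per-protein toxin-related-gene call with its evidence."""

    protein_id: str
    trg_class: str             # YD | RTX | RTX_accessory | MARTX
    evidence: list = field(default_factory=list)
    mobile_adjacent: bool = False
    conflict: str = ""


@dataclass
class VariantCall:
    contig: str
    pos: int                   # 1-based
    ref: str
    alt: str
    qual: float
    filter: str                # PASS | near_indel | low_depth | high_depth | low_qual
    depth: int = 0
    alt_count: int = 0


@dataclass
class GeneVariability:
    gene_id: str
    length_bp: int
    n_bp: int
    snp_count: int

    @property
    def effective_kb(self) -> float:
        return (self.length_bp - self.n_bp) / 1000.0

    @property
    def snps_per_kb(self) -> float:
        return self.snp_count / self.effective_kb


@dataclass
class TestResult:
    """Outcome of one enrichment test."""

    __test__ = False           # not a pytest collection target

    method: str                # kruskal_wallis | mann_whitney | permanova
    statistic: float
    df: Optional[int]
    p_value: float
    p_adjusted: Optional[float]
    grouping: str
    response: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def bonferroni(results: Iterable[TestResult]) -> list[TestResult]:
    """Apply a Bonferroni correction across one family of tests, in place."""
    results = list(results)
    m = len(results)
    for r in results:
        r.p_adjusted = min(1.0, r.p_value * m)
    return results
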