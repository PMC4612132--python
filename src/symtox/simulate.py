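"""Synthetic genome sets, metadata tables, pileups and count tables with
planted truth.

The generator emulates the statistical structure of a focal symbiont clade
compared against two reference clades:

* a shared **core** proteome present in every genome at low divergence;
* **focal-specific** genes present only in the focal genomes (the
  shared/unique partitioning must recover exactly these);
* planted **TRG families** (YD/Rhs, RTX, MARTX) carrying the class's
  repeat or domain signature, mutated at a controlled divergence;
* a fraction of TRGs placed **directly next to mobile-element marker
  genes** (transposases);
* **codon-shifted** (HGT-like) genes whose synonymous codons are sampled
  from a donor profile at a controlled total-variation distance from the
  resident genome profile, with TRGs shifted more often than the rest of
  the proteome;
* **hypervariable** genes whose per-site polymorphism rate is multiplied
  relative to the background, visible in the generated pileups;
* genome **metadata tables** with a planted per-lifestyle enrichment
  effect on normalized TRG counts;
* per-gene **read-count tables** with a planted TRG share of mRNA.

All randomness flows through one seeded generator, so identical configs
and seeds give byte-identical outputs.  Every planted label is recorded in
the truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hgt import CODONS, FAMILIES
from .model import GeneModel, GenomeSet, ProteinSeq
from .profiles import AA, BACKGROUND, load_default_profiles
from . import io as sio

REVCOMP = str.maketrans("ACGT", "TGCA")

YD_UNIT_LEN = 19          # aa per YD-repeat unit (one [YFH]D dipeptide each)
YD_UNIT_COPIES = 22
RTX_UNIT = "GGAGNDNLS"    # canonical calcium-binding nonapeptide
RTX_UNIT_COPIES = 40
MARTX_RTX_UNIT_COPIES = 8


@dataclass
class SimConfig:
    """Study conditions for the synthetic data.

    Defaults mirror the focal study scaled to desk size: two focal genomes
    against two reference sets of two genomes each; 100 core and 50
    focal-specific genes; 30 YD + 8 RTX + 19 MARTX toxin-related genes per
    focal genome at 30% divergence; about a quarter of TRGs adjacent to
    mobile elements; roughly a third of ordinary genes (and two thirds of
    TRGs) codon-shifted; 5% of genes hypervariable at 10x the background
    substitution rate; 50x read coverage.
    """

    n_focal_genomes: int = 2
    n_reference_genomes: int = 4     # split into two reference sets
    n_core_genes: int = 100
    n_specific_genes: int = 50
    trg_plant_spec: list[tuple[str, int, float]] = field(
        default_factory=lambda: [("YD", 30, 0.3), ("RTX", 8, 0.3),
                                 ("MARTX", 19, 0.3)])
    accessory_copies: int = 2
    hgt_fraction: float = 0.33
    trg_hgt_fraction: float = 0.65
    hgt_codon_shift: float = 0.3
    variable_gene_fraction: float = 0.05
    variable_rate_multiplier: float = 10.0
    mobile_adjacent_fraction: float = 0.25
    enrichment_effect: dict[str, float] = field(
        default_factory=lambda: {"extracellular": 2.0})
    n_genomes_per_lifestyle: int = 40
    read_coverage: float = 50.0
    snp_rate: float = 0.003          # background polymorphic sites per bp
    seq_error_rate: float = 0.002    # per-base sequencing error
    indel_rate: float = 2e-4
    mean_protein_len: int = 200
    min_protein_len: int = 60
    core_divergence: float = 0.02
    specific_divergence: float = 0.05
    trg_mrna_share: float = 0.02
    rubisco_mrna_share: float = 0.005
    total_reads: int = 1_000_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for cls, copies, div in self.trg_plant_spec:
            if cls not in ("YD", "RTX", "MARTX"):
                raise ValueError(f"unknown TRG class {cls!r}")
            if copies < 0:
                raise ValueError("TRG copies must be >= 0")
            if not 0.0 <= div <= 0.6:
                raise ValueError(
                    "TRG divergence must be in [0, 0.6]; higher values "
                    "destroy the planted signatures by construction")
        for name in ("hgt_fraction", "trg_hgt_fraction", "hgt_codon_shift",
                     "variable_gene_fraction", "mobile_adjacent_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.read_coverage <= 0:
            raise ValueError("read_coverage must be positive")


# ---------------------------------------------------------------------------
# sequence-level helpers

def _random_protein(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=length, p=BACKGROUND)
    return "".join(AA[i] for i in idx)


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each residue with probability ``rate`` (uniform over the
    other 19 amino acids)."""
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = [a for a in AA if a != out[i]]
        out[i] = choices[rng.integers(19)]
    return "".join(out)


def _protein_length(cfg: SimConfig, rng: np.random.Generator) -> int:
    length = int(rng.normal(cfg.mean_protein_len, cfg.mean_protein_len * 0.3))
    return max(cfg.min_protein_len, min(length, cfg.mean_protein_len * 4))


def _codon_profile(rng: np.random.Generator) -> np.ndarray:
    """A biased resident codon-usage profile (Dirichlet within families)."""
    profile = np.zeros(len(CODONS))
    for idx in FAMILIES.values():
        profile[idx] = rng.dirichlet(np.full(len(idx), 0.6))
        profile[idx] = np.maximum(profile[idx], 1e-3)
        profile[idx] /= profile[idx].sum()
    return profile


def _shift_profile(profile: np.ndarray, shift: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Donor profile at total-variation distance ``shift`` per synonymous
    family.  Mass moves onto the family's rarest codon (maximal headroom),
    clipped only where the family genuinely cannot move that far."""
    donor = profile.copy()
    for idx in FAMILIES.values():
        if len(idx) < 2:
            continue
        p = profile[idx].copy()
        target = int(np.argmin(p))  # codon gaining mass
        gain_room = 1.0 - p[target]
        move = min(shift, gain_room)
        others = np.array([j for j in range(len(idx)) if j != target])
        avail = p[others].sum()
        if avail <= 0:
            continue
        move = min(move, avail * 0.999)
        p[others] -= move * p[others] / avail
        p[target] += move
        donor[idx] = p / p.sum()
    return donor


def _reverse_translate(protein: str, profile: np.ndarray,
                       rng: np.random.Generator) -> str:
    """Sample a coding sequence for a protein from a codon-usage profile.

    Positions are grouped by amino acid so each family is sampled in one
    vectorised draw; a TAA stop is appended.
    """
    codons: list[str] = [""] * len(protein)
    positions: dict[str, list[int]] = {}
    for i, aa in enumerate(protein):
        positions.setdefault(aa, []).append(i)
    for aa in sorted(positions):
        idx = FAMILIES[aa]
        pos = positions[aa]
        p = profile[idx] / profile[idx].sum()
        draws = rng.choice(len(idx), size=len(pos), p=p)
        for i, d in zip(pos, draws):
            codons[i] = CODONS[idx[d]]
    return "".join(codons) + "TAA"


# ---------------------------------------------------------------------------
# TRG templates

def _yd_template(rng: np.random.Generator) -> str:
    """Rhs-like protein: flank + Rhs core + YD-repeat region + flank."""
    profiles = load_default_profiles()
    core = profiles["RHS"].consensus
    units = []
    for _ in range(YD_UNIT_COPIES):
        unit = list(_random_protein(YD_UNIT_LEN, rng))
        offset = 3 + rng.integers(4)
        unit[offset] = "Y"
        unit[offset + 1] = "D"
        units.append("".join(unit))
    return (_random_protein(60, rng) + core + "".join(units)
            + _random_protein(40, rng))


def _rtx_template(rng: np.random.Generator) -> str:
    repeats = RTX_UNIT * RTX_UNIT_COPIES
    return _random_protein(80, rng) + repeats + _random_protein(50, rng)


def _martx_template(rng: np.random.Generator) -> str:
    """MARTX-like protein: effector domains (ACD, RID, CPD) embedded among
    linkers plus a short RTX-repeat region."""
    profiles = load_default_profiles()
    parts = [_random_protein(80, rng), profiles["ACD"].consensus,
             _random_protein(60, rng), profiles["RID"].consensus,
             _random_protein(60, rng), profiles["CPD"].consensus,
             _random_protein(40, rng), RTX_UNIT * MARTX_RTX_UNIT_COPIES,
             _random_protein(40, rng)]
    return "".join(parts)


_TEMPLATE_BUILDERS = {"YD": _yd_template, "RTX": _rtx_template,
                      "MARTX": _martx_template}


# ---------------------------------------------------------------------------
# genome-set generation

TRUTH_COLUMNS = ["gene_id", "genome_id", "category", "trg_class", "hgt_flag",
                 "variable_flag", "mobile_adjacent_flag"]


def generate_genome_set(cfg: SimConfig) -> tuple[GenomeSet, pd.DataFrame]:
    """Generate focal + reference genomes with planted truth.

    Returns the GenomeSet (genomes named F01.., A01.., B01..; reference
    genomes split alternately into sets A and B) and a per-gene truth
    table.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    resident = _codon_profile(rng)
    donor = _shift_profile(resident, cfg.hgt_codon_shift, rng)

    focal_ids = [f"F{i + 1:02d}" for i in range(cfg.n_focal_genomes)]
    ref_ids = []
    for i in range(cfg.n_reference_genomes):
        set_tag = "A" if i % 2 == 0 else "B"
        ref_ids.append(f"{set_tag}{i // 2 + 1:02d}")
    genome_ids = focal_ids + ref_ids

    core_templates = [_random_protein(_protein_length(cfg, rng), rng)
                      for _ in range(cfg.n_core_genes)]
    rubisco_template = _random_protein(470, rng)  # RuBisCO large subunit size
    specific_templates = [_random_protein(_protein_length(cfg, rng), rng)
                          for _ in range(cfg.n_specific_genes)]
    trg_templates: list[tuple[str, float, str]] = []  # (class, divergence, template)
    for cls, copies, div in cfg.trg_plant_spec:
        for _ in range(copies):
            trg_templates.append((cls, div, _TEMPLATE_BUILDERS[cls](rng)))

    genes: list[GeneModel] = []
    proteins: list[ProteinSeq] = []
    truth_rows: list[dict] = []

    for genome_id in genome_ids:
        is_focal = genome_id in focal_ids
        entries: list[dict] = []  # staged genes before layout

        def stage(protein: str, category: str, trg_class: str = "",
                  annotation: str = "hypothetical protein",
                  force_hgt: bool | None = None) -> dict:
            entry = {"protein": protein, "category": category,
                     "trg_class": trg_class, "annotation": annotation,
                     "hgt": False}
            if is_focal:
                if force_hgt is not None:
                    entry["hgt"] = force_hgt
                elif trg_class:
                    entry["hgt"] = bool(rng.random() < cfg.trg_hgt_fraction)
                else:
                    entry["hgt"] = bool(rng.random() < cfg.hgt_fraction)
            entries.append(entry)
            return entry

        for template in core_templates:
            stage(_mutate_protein(template, cfg.core_divergence, rng), "core")
        stage(_mutate_protein(rubisco_template, cfg.core_divergence, rng),
              "rubisco",
              annotation="ribulose bisphosphate carboxylase large subunit "
                         "(RuBisCO)",
              force_hgt=False)
        if is_focal:
            for template in specific_templates:
                stage(_mutate_protein(template, cfg.specific_divergence, rng),
                      "specific")
            for cls, div, template in trg_templates:
                entry = stage(_mutate_protein(template, div, rng), "trg", cls)
                entry["mobile"] = bool(
                    rng.random() < cfg.mobile_adjacent_fraction)
            for i in range(cfg.accessory_copies):
                kind = "transporter" if i % 2 == 0 else "activator"
                stage(_random_protein(_protein_length(cfg, rng), rng),
                      "accessory", "RTX_accessory",
                      annotation=f"RTX toxin {kind}")

        # gene order: shuffle, then insert mobile-element markers next to
        # the TRGs selected for adjacency
        order = rng.permutation(len(entries))
        ordered = [entries[i] for i in order]
        laid_out: list[dict] = []
        for entry in ordered:
            laid_out.append(entry)
            if entry.get("mobile"):
                laid_out.append({
                    "protein": _random_protein(cfg.min_protein_len + 40, rng),
                    "category": "mobile_marker", "trg_class": "",
                    "annotation": "transposase (mobile element)",
                    "hgt": False})

        # hypervariable flags over all genes of the genome
        variable = rng.random(len(laid_out)) < cfg.variable_gene_fraction

        contig = f"{genome_id}_c1"
        pos = 1
        contig_parts: list[str] = []
        for j, entry in enumerate(laid_out):
            gene_id = f"{genome_id}_g{j + 1:04d}"
            profile = donor if entry["hgt"] else resident
            cds = _reverse_translate(entry["protein"], profile, rng)
            spacer_len = int(rng.integers(20, 200))
            spacer = "".join("ACGT"[k] for k in rng.integers(4, size=spacer_len))
            strand = "+" if rng.random() < 0.5 else "-"
            start = pos + spacer_len
            end = start + len(cds) - 1
            placed = cds if strand == "+" else cds.translate(REVCOMP)[::-1]
            contig_parts.append(spacer + placed)
            pos = end + 1
            gene = GeneModel(gene_id=gene_id, genome_id=genome_id,
                             contig=contig, start=start, end=end,
                             strand=strand, nucleotide_seq=cds,
                             annotation=entry["annotation"])
            gene.protein_seq = entry["protein"]
            genes.append(gene)
            proteins.append(ProteinSeq(gene_id, genome_id, entry["protein"]))
            truth_rows.append({
                "gene_id": gene_id, "genome_id": genome_id,
                "category": entry["category"],
                "trg_class": entry["trg_class"],
                "hgt_flag": bool(entry["hgt"]),
                "variable_flag": bool(variable[j]),
                "mobile_adjacent_flag": bool(entry.get("mobile", False)),
            })

    gs = GenomeSet(set_id="synthetic", genomes=genome_ids,
                   proteins=proteins, genes=genes)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return gs, truth


def focal_genomes(gs: GenomeSet) -> list[str]:
    return [g for g in gs.genomes if g.startswith("F")]


def reference_split(gs: GenomeSet) -> tuple[list[str], list[str]]:
    a = [g for g in gs.genomes if g.startswith("A")]
    b = [g for g in gs.genomes if g.startswith("B")]
    return a, b


def contig_sequences(gs: GenomeSet, genome_id: str) -> dict[str, str]:
    """Reconstruct contig sequences from the laid-out gene models."""
    contigs: dict[str, list[tuple[int, int, str]]] = {}
    for g in gs.genes_of(genome_id):
        placed = (g.nucleotide_seq if g.strand == "+"
                  else g.nucleotide_seq.translate(REVCOMP)[::-1])
        contigs.setdefault(g.contig, []).append((g.start, g.end, placed))
    rng = np.random.default_rng(0)  # spacer fill is arbitrary but fixed
    out: dict[str, str] = {}
    for contig, placed_genes in contigs.items():
        placed_genes.sort()
        parts: list[str] = []
        cursor = 1
        for start, end, seq in placed_genes:
            gap = start - cursor
            if gap > 0:
                parts.append("".join("ACGT"[k]
                                     for k in rng.integers(4, size=gap)))
            parts.append(seq)
            cursor = end + 1
        out[contig] = "".join(parts)
    return out


def write_genome_set(gs: GenomeSet, truth: pd.DataFrame,
                     outdir: str | Path) -> dict[str, dict[str, Path]]:
    """Write per-genome contig FASTA, protein FASTA and GFF3, plus truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, dict[str, Path]] = {}
    for genome_id in gs.genomes:
        fna = outdir / f"{genome_id}.fna"
        faa = outdir / f"{genome_id}.faa"
        gff = outdir / f"{genome_id}.gff3"
        sio.write_fasta(sorted(contig_sequences(gs, genome_id).items()), fna)
        sio.write_fasta([(p.protein_id, p.residues)
                         for p in gs.proteins_of(genome_id)], faa)
        sio.write_gff3(gs.genes_of(genome_id), gff)
        paths[genome_id] = {"fna": fna, "faa": faa, "gff3": gff}
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# metadata tables

LIFESTYLES = ("free_living", "extracellular", "intracellular")
BASE_TRG_RATE = {"YD": 1.0, "RTX": 0.8, "MARTX": 0.5}  # per 1000 genes
TAXONOMY_POOL = [
    ("Gammaproteobacteria", f"Order_{o}", f"Family_{o}{f}")
    for o in "ABCD" for f in "12"
]


def generate_metadata_table(cfg: SimConfig
                            ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Genome metadata with planted per-lifestyle TRG-count enrichment.

    TRG counts are Poisson draws whose normalized mean (per 1000 genes) is
    the class base rate plus one third of the lifestyle's planted effect,
    so both the per-class and summed normalized counts shift by the
    configured amount.
    """
    if cfg.n_genomes_per_lifestyle < 2:
        raise ValueError("each lifestyle category needs at least 2 genomes")
    rng = np.random.default_rng(cfg.rng_seed + 1)
    rows = []
    i = 0
    for lifestyle in LIFESTYLES:
        effect = cfg.enrichment_effect.get(lifestyle, 0.0)
        for _ in range(cfg.n_genomes_per_lifestyle):
            i += 1
            total = int(rng.integers(1500, 5000))
            counts = {}
            for cls, rate in BASE_TRG_RATE.items():
                lam = max(rate + effect / 3.0, 0.0) * total / 1000.0
                counts[cls] = int(rng.poisson(lam))
            tax = TAXONOMY_POOL[rng.integers(len(TAXONOMY_POOL))]
            rows.append({
                "genome_id": f"G{i:04d}", "total_genes": total,
                "YD": counts["YD"], "RTX": counts["RTX"],
                "MARTX": counts["MARTX"],
                "lifestyle": lifestyle,
                "pathogen": bool(rng.random() < 0.4),
                "biofilm": bool(rng.random() < 0.5),
                "tax_class": tax[0], "tax_order": tax[1], "tax_family": tax[2],
            })
    truth = {l: cfg.enrichment_effect.get(l, 0.0) for l in LIFESTYLES}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# pileups

def generate_pileups(gs: GenomeSet, cfg: SimConfig, truth: pd.DataFrame,
                     genome_id: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site pileups over a genome's contigs with planted SNP
    heterogeneity.

    Background sites are polymorphic at ``snp_rate`` per bp; genes flagged
    hypervariable in the truth table use ``snp_rate * multiplier``.  At a
    polymorphic site the minor-allele frequency is uniform on [0.15, 0.5];
    sequencing error adds single-base noise at ``seq_error_rate``; depth is
    Poisson(read_coverage); indel evidence occurs at ``indel_rate``.

    Returns the pileup table and the per-gene truth restricted to this
    genome.
    """
    rng = np.random.default_rng(cfg.rng_seed + 2)
    contigs = contig_sequences(gs, genome_id)
    gene_truth = truth[truth["genome_id"] == genome_id]
    variable_genes = set(gene_truth.loc[gene_truth["variable_flag"],
                                        "gene_id"])
    base_index = {b: i for i, b in enumerate("ACGT")}
    rows = []
    for contig in sorted(contigs):
        seq = contigs[contig]
        n = len(seq)
        rate = np.full(n, cfg.snp_rate)
        for g in gs.genes_of(genome_id):
            if g.contig == contig and g.gene_id in variable_genes:
                rate[g.start - 1:g.end] = (cfg.snp_rate
                                           * cfg.variable_rate_multiplier)
        poly = rng.random(n) < rate
        depth = rng.poisson(cfg.read_coverage, size=n)
        indel = rng.random(n) < cfg.indel_rate
        maf = rng.uniform(0.15, 0.5, size=n)
        for pos in range(n):
            ref = seq[pos]
            d = int(depth[pos])
            counts = [0, 0, 0, 0, 0]  # A C G T N
            if ref in base_index and d > 0:
                alt_n = int(rng.binomial(d, maf[pos])) if poly[pos] else 0
                err_n = int(rng.binomial(d - alt_n, cfg.seq_error_rate))
                counts[base_index[ref]] = d - alt_n - err_n
                if alt_n:
                    alt = base_index["ACGT"[(base_index[ref] + 1
                                             + rng.integers(3)) % 4]]
                    counts[alt] += alt_n
                for _ in range(err_n):
                    counts[rng.integers(4)] += 1
            elif d > 0:
                counts[4] = d
            rows.append((contig, pos + 1, ref, sum(counts), *counts,
                         int(indel[pos])))
    df = pd.DataFrame(rows, columns=["contig", "pos", "ref", "depth",
                                     "A", "C", "G", "T", "N", "indel"])
    return df, gene_truth


# ---------------------------------------------------------------------------
# expression counts

def generate_counts(gs: GenomeSet, cfg: SimConfig, truth: pd.DataFrame,
                    genome_id: str) -> tuple[dict[str, int], dict[str, float]]:
    """Multinomial read counts with a planted TRG share of mRNA.

    Returns (counts, planted shares).  The TRG share is split evenly over
    the genome's TRG genes, the RuBisCO share goes to the planted RuBisCO
    gene, and the remainder is spread uniformly over all other genes.
    """
    rng = np.random.default_rng(cfg.rng_seed + 3)
    sub = truth[truth["genome_id"] == genome_id]
    trg_genes = sorted(sub.loc[sub["category"] == "trg", "gene_id"])
    rub = sorted(sub.loc[sub["category"] == "rubisco", "gene_id"])
    all_genes = sorted(sub["gene_id"])
    shares = pd.Series(0.0, index=all_genes)
    trg_share = cfg.trg_mrna_share if trg_genes else 0.0
    rub_share = cfg.rubisco_mrna_share if rub else 0.0
    if trg_genes:
        shares[trg_genes] = trg_share / len(trg_genes)
    if rub:
        shares[rub] = rub_share / len(rub)
    others = [g for g in all_genes if g not in set(trg_genes) | set(rub)]
    shares[others] = (1.0 - trg_share - rub_share) / len(others)
    counts = rng.multinomial(cfg.total_reads, shares.to_numpy())
    return (dict(zip(all_genes, (int(c) for c in counts))),
            {"trg_share": trg_share, "rubisco_share": rub_share,
             "rubisco_gene": rub[0] if rub else ""})
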