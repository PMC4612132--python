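"""Readers and writers for the pipeline's external formats.

FASTA via Biopython, GFF3 via gffutils, tabular artifacts via pandas.  Hit
tables use the BLAST outfmt-6 column order with two appended columns
(raw_score, positives).  All serialized coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import AlignmentHit, GeneModel, GenomeSet, ProteinSeq, VariantCall

log = logging.getLogger(__name__)

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "raw_score", "positives",
]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (order preserved)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqrecs = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in records]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 + genome sets

def read_gene_models(gff_path: str | Path, fasta_path: str | Path,
                     genome_id: str) -> list[GeneModel]:
    """Parse CDS features from a GFF3 file against its contig FASTA.

    Raises if a feature references a contig absent from the FASTA.  CDS
    lengths not divisible by 3 are truncated to the last full codon with a
    warning (the gene is flagged partial).
    """
    contigs = read_fasta(fasta_path)
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if feat.seqid not in contigs:
            raise ValueError(
                f"CDS {feat.id or feat.attributes}: contig {feat.seqid!r} "
                f"missing from {fasta_path}")
        raw = contigs[feat.seqid][feat.start - 1:feat.end]
        if feat.strand == "-":
            cds = str(Seq(raw).reverse_complement())
            strand = "-"
        else:
            cds = raw
            strand = "+"
        gene_id = feat.attributes.get("ID", [f"{feat.seqid}:{feat.start}"])[0]
        annotation = feat.attributes.get("product", [""])[0]
        if len(cds) % 3:
            log.warning("CDS %s length %d not divisible by 3; truncating",
                        gene_id, len(cds))
        gene = GeneModel(
            gene_id=gene_id, genome_id=genome_id, contig=feat.seqid,
            start=feat.start, end=feat.end, strand=strand,
            nucleotide_seq=cds.upper(), annotation=annotation)
        gene.translate()
        genes.append(gene)
    return genes


def read_genome_set(fasta_paths: Sequence[str | Path],
                    gff_paths: Sequence[str | Path],
                    genome_ids: Sequence[str],
                    set_id: str) -> GenomeSet:
    """Assemble a GenomeSet from parallel lists of contig FASTA and GFF3 files."""
    if not len(fasta_paths) == len(gff_paths) == len(genome_ids):
        raise ValueError("fasta_paths, gff_paths and genome_ids must align")
    genes: list[GeneModel] = []
    proteins: list[ProteinSeq] = []
    for fasta, gff, gid in zip(fasta_paths, gff_paths, genome_ids):
        for gene in read_gene_models(gff, fasta, gid):
            genes.append(gene)
            if gene.protein_seq:
                proteins.append(ProteinSeq(gene.gene_id, gid, gene.protein_seq))
    gs = GenomeSet(set_id=set_id, genomes=list(genome_ids),
                   proteins=proteins, genes=genes)
    gs.check_complete()
    return gs


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.annotation:
                attrs += f";product={g.annotation}"
            fh.write("\t".join([
                g.contig, "symtox", "CDS", str(g.start), str(g.end),
                ".", g.strand, "0", attrs]) + "\n")


# ---------------------------------------------------------------------------
# Hit tables (outfmt-6 dialect)

def hits_to_frame(hits: Iterable[AlignmentHit]) -> pd.DataFrame:
    rows = [{
        "qseqid": h.query_id, "sseqid": h.subject_id,
        "pident": round(h.percent_identity, 3), "length": h.length,
        "mismatch": h.mismatch, "gapopen": h.gapopen,
        "qstart": h.query_start, "qend": h.query_end,
        "sstart": h.subject_start, "send": h.subject_end,
        "evalue": h.evalue, "bitscore": round(h.bitscore, 2),
        "raw_score": h.raw_score, "positives": round(h.percent_similarity, 3),
    } for h in hits]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path,
              query_lengths: dict[str, int] | None = None,
              subject_lengths: dict[str, int] | None = None,
              ) -> list[AlignmentHit]:
    """Read a hit table; coverages are recomputed when lengths are supplied."""
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table {path}: missing columns {sorted(missing)}")
    hits = []
    for row in df.itertuples(index=False):
        qspan = abs(row.qend - row.qstart) + 1
        sspan = abs(row.send - row.sstart) + 1
        qcov = qspan / query_lengths[row.qseqid] if query_lengths else 1.0
        scov = sspan / subject_lengths[row.sseqid] if subject_lengths else 1.0
        hits.append(AlignmentHit(
            query_id=str(row.qseqid), subject_id=str(row.sseqid),
            raw_score=float(row.raw_score), bitscore=float(row.bitscore),
            evalue=float(row.evalue), percent_identity=float(row.pident),
            percent_similarity=float(row.positives),
            query_coverage=qcov, subject_coverage=scov,
            query_start=int(row.qstart), query_end=int(row.qend),
            subject_start=int(row.sstart), subject_end=int(row.send),
            length=int(row.length), mismatch=int(row.mismatch),
            gapopen=int(row.gapopen)))
    return hits


# ---------------------------------------------------------------------------
# VCF 4.2

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=symtox
##FILTER=<ID=near_indel,Description="Within {mask} bp of indel evidence">
##FILTER=<ID=low_depth,Description="Depth below coverage floor">
##FILTER=<ID=high_depth,Description="Depth above coverage cap before downsampling">
##FILTER=<ID=low_qual,Description="Below minimum variant confidence">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=AC,Number=1,Type=Integer,Description="Alternate base count">
"""


def write_vcf(calls: Iterable[VariantCall], contig_lengths: dict[str, int],
              path: str | Path, indel_mask_bp: int = 5) -> None:
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(mask=indel_mask_bp))
        for contig in sorted(contig_lengths):
            fh.write(f"##contig=<ID={contig},length={contig_lengths[contig]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.contig, c.pos)):
            fh.write(f"{c.contig}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t"
                     f"{c.qual:.1f}\t{c.filter}\tDP={c.depth};AC={c.alt_count}\n")


# ---------------------------------------------------------------------------
# Pileups and metadata

PILEUP_COLUMNS = ["contig", "pos", "ref", "depth", "A", "C", "G", "T", "N",
                  "indel"]


def write_pileups(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=PILEUP_COLUMNS)


def read_pileups(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup table {path}: missing columns {sorted(missing)}")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Genome metadata table: lifestyle / pathogen / biofilm / taxonomy."""
    df = pd.read_csv(path, sep="\t")
    required = {"genome_id", "total_genes", "lifestyle"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path}: missing columns {sorted(missing)}")
    return df
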