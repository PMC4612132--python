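"""Detection and classification of toxin-related genes (TRGs).

Three classes are recognised:

* **YD repeat / Rhs** proteins — repeated tyrosine-aspartate dipeptides in
  an Rhs-core context.  Neither the dipeptide alone (too common) nor the
  core alone is sufficient: a call requires a near-tandem run of YD-type
  dipeptides *and* an Rhs-core profile hit.
* **RTX** toxins — tandem copies of the glycine/asparagine-rich
  calcium-binding nonapeptide (consensus GGxGxDxUx, U hydrophobic).  The
  repeat is too variable for profile methods, so a tolerant regex scan with
  a copy-count threshold is used.
* **MARTX** toxins — RTX-family giants carrying characterised effector
  domains (ACD, RID, CPD) detected by PSSM profiles; an RTX-repeat protein
  longer than ``martx_min_len`` is also called MARTX even without a domain
  hit.

RTX accessory genes (dedicated transporters/activators) are recognised from
their functional annotation, as they carry neither repeat.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import DomainHit, GeneModel, ProteinSeq, RepeatHit, TrgAnnotation
from .profiles import Pssm, load_default_profiles

MIN_PROTEIN_LEN = 50

YD_MOTIF = r"[YFH]D"
# calcium-binding nonapeptide GGxGxDxUx with +-2 per-copy length tolerance
RTX_MOTIF = r"G{1,2}.{1,2}G.{1,2}[DN].{1,2}[LIVF]"

MOBILE_ELEMENT_PATTERN = re.compile(
    r"transposase|integrase|insertion sequence|mobile element|recombinase|phage",
    re.IGNORECASE)

RTX_ACCESSORY_PATTERN = re.compile(
    r"(rtx|toxin|hemolysin).*(activat|transport|secretion)|"
    r"(activat|transport|secretion).*(rtx|hemolysin)",
    re.IGNORECASE)


@dataclass
class ClassifierParams:
    yd_min_copies: int = 4
    yd_max_spacing: int = 60      # max aa gap between consecutive YD motifs
    yd_require_rhs_core: bool = True
    rtx_min_copies: int = 3
    rtx_max_gap: int = 30         # max aa gap between consecutive RTX copies
    martx_min_len: int = 1500
    yd_motif: str = YD_MOTIF
    rtx_motif: str = RTX_MOTIF


def _best_chain(matches: list[tuple[int, int]], max_gap: int
                ) -> list[tuple[int, int]]:
    """Longest run of motif matches whose consecutive gaps are <= max_gap.

    Matches are (start, end) 0-based half-open; ties keep the earliest run.
    """
    if not matches:
        return []
    best: list[tuple[int, int]] = []
    current = [matches[0]]
    for m in matches[1:]:
        if m[0] - current[-1][1] <= max_gap:
            current.append(m)
        else:
            if len(current) > len(best):
                best = current
            current = [m]
    if len(current) > len(best):
        best = current
    return best


def detect_yd_repeats(protein: ProteinSeq, params: ClassifierParams,
                      rhs_profile: Optional[Pssm] = None
                      ) -> Optional[RepeatHit]:
    """YD-repeat detection: clustered [YFH]D dipeptides plus an Rhs-core hit."""
    seq = protein.residues
    if len(seq) < MIN_PROTEIN_LEN:
        return None
    matches = [(m.start(), m.end())
               for m in re.finditer(params.yd_motif, seq)]
    chain = _best_chain(matches, params.yd_max_spacing)
    if len(chain) < params.yd_min_copies:
        return None
    if params.yd_require_rhs_core:
        if rhs_profile is None:
            raise ValueError("Rhs-core profile required but not provided")
        if not rhs_profile.search(seq):
            return None
    return RepeatHit(
        protein_id=protein.protein_id, repeat_class="YD",
        copies=len(chain),
        intervals=[(s + 1, e) for s, e in chain],
        score=float(len(chain)))


def detect_rtx_repeats(protein: ProteinSeq, params: ClassifierParams
                       ) -> Optional[RepeatHit]:
    """RTX-repeat detection: near-tandem glycine-rich nonapeptide copies."""
    seq = protein.residues
    if len(seq) < MIN_PROTEIN_LEN:
        return None
    matches = [(m.start(), m.end())
               for m in re.finditer(params.rtx_motif, seq)]
    chain = _best_chain(matches, params.rtx_max_gap)
    if len(chain) < params.rtx_min_copies:
        return None
    return RepeatHit(
        protein_id=protein.protein_id, repeat_class="RTX",
        copies=len(chain),
        intervals=[(s + 1, e) for s, e in chain],
        score=float(len(chain)))


def score_martx_domains(protein: ProteinSeq,
                        profiles: dict[str, Pssm]) -> list[DomainHit]:
    """Scan a protein with the MARTX effector-domain profiles (ACD/RID/CPD)."""
    hits: list[DomainHit] = []
    for domain in ("ACD", "RID", "CPD"):
        profile = profiles.get(domain)
        if profile is None:
            continue
        for start, end, score in profile.search(protein.residues):
            hits.append(DomainHit(protein_id=protein.protein_id,
                                  domain=domain, profile_score=score,
                                  interval=(start, end)))
    return hits


@dataclass
class GeneContext:
    """Per-gene annotation context used for accessory and adjacency calls."""
    annotation: str = ""
    mobile_adjacent: bool = False


def classify_trg(protein: ProteinSeq,
                 repeat_hits: Sequence[RepeatHit],
                 domain_hits: Sequence[DomainHit],
                 context: GeneContext | None = None,
                 params: ClassifierParams | None = None
                 ) -> Optional[TrgAnnotation]:
    """Combine detector evidence into a final class call.

    Priority: MARTX (domain evidence, or RTX repeats on a giant ORF), then
    RTX vs YD repeats (a conflict is resolved by the higher evidence score
    and recorded), then annotation-based RTX accessory genes.
    """
    if params is None:
        params = ClassifierParams()
    if context is None:
        context = GeneContext()
    yd = next((h for h in repeat_hits if h.repeat_class == "YD"), None)
    rtx = next((h for h in repeat_hits if h.repeat_class == "RTX"), None)
    martx_domains = [d for d in domain_hits if d.domain in ("ACD", "RID", "CPD")]
    evidence: list = []
    conflict = ""

    if martx_domains or (rtx and len(protein) > params.martx_min_len):
        cls = "MARTX"
        evidence = list(martx_domains) + ([rtx] if rtx else [])
    elif yd and rtx:
        if rtx.score > yd.score:
            cls, evidence = "RTX", [rtx]
        else:
            cls, evidence = "YD", [yd]
        conflict = (f"both YD (score {yd.score:g}) and RTX "
                    f"(score {rtx.score:g}) evidence")
    elif rtx:
        cls, evidence = "RTX", [rtx]
    elif yd:
        cls, evidence = "YD", [yd]
    elif RTX_ACCESSORY_PATTERN.search(context.annotation):
        cls = "RTX_accessory"
    else:
        return None
    return TrgAnnotation(protein_id=protein.protein_id, trg_class=cls,
                         evidence=evidence,
                         mobile_adjacent=context.mobile_adjacent,
                         conflict=conflict)


def mobile_adjacency(genes: Sequence[GeneModel]) -> set[str]:
    """Gene ids lying within one gene of a mobile-element gene on their contig."""
    adjacent: set[str] = set()
    by_contig: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault((g.genome_id, g.contig), []).append(g)
    for contig_genes in by_contig.values():
        contig_genes.sort(key=lambda g: g.start)
        mobile = [bool(MOBILE_ELEMENT_PATTERN.search(g.annotation))
                  for g in contig_genes]
        for i, g in enumerate(contig_genes):
            if mobile[i]:
                continue
            if (i > 0 and mobile[i - 1]) or (i + 1 < len(mobile) and mobile[i + 1]):
                adjacent.add(g.gene_id)
    return adjacent


def classify_proteins(proteins: Iterable[ProteinSeq],
                      genes: Sequence[GeneModel] = (),
                      profiles: dict[str, Pssm] | None = None,
                      params: ClassifierParams | None = None
                      ) -> list[TrgAnnotation]:
    """Run all detectors over a proteome and return the TRG annotations."""
    if profiles is None:
        profiles = load_default_profiles()
    if params is None:
        params = ClassifierParams()
    adjacent = mobile_adjacency(genes) if genes else set()
    annotations_by_gene = {g.gene_id: g.annotation for g in genes}
    calls: list[TrgAnnotation] = []
    for protein in proteins:
        repeat_hits = []
        yd = detect_yd_repeats(protein, params, profiles.get("RHS"))
        if yd:
            repeat_hits.append(yd)
        rtx = detect_rtx_repeats(protein, params)
        if rtx:
            repeat_hits.append(rtx)
        domain_hits = score_martx_domains(protein, profiles)
        context = GeneContext(
            annotation=annotations_by_gene.get(protein.protein_id, ""),
            mobile_adjacent=protein.protein_id in adjacent)
        call = classify_trg(protein, repeat_hits, domain_hits, context, params)
        if call is not None:
            calls.append(call)
    return calls
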