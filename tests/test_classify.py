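"""TRG detectors and the class-assignment rule."""

import re

import numpy as np
import pytest

from symtox.classify import (ClassifierParams, GeneContext, classify_proteins,
                             classify_trg, detect_rtx_repeats,
                             detect_yd_repeats, mobile_adjacency,
                             score_martx_domains)
from symtox.model import DomainHit, GeneModel, ProteinSeq, RepeatHit
from symtox.profiles import load_default_profiles, read_pssm, write_pssm

AA = "ACDEFGHIKLMNPQRSTVWY"
PARAMS = ClassifierParams()


def prot(seq, pid="p1"):
    return ProteinSeq(pid, "g", seq)


def random_protein(rng, length):
    return "".join(AA[i] for i in rng.integers(20, size=length))


# ---------------------------------------------------------------------------
# YD repeats

def test_poly_alanine_has_no_yd_hit():
    p = prot("A" * 500)
    params = ClassifierParams(yd_require_rhs_core=False)
    assert detect_yd_repeats(p, params) is None


def test_planted_yd_motifs_counted():
    # six YD dipeptides spaced 40 aa apart
    seq = ("YD" + "A" * 38) * 6 + "A" * 20
    params = ClassifierParams(yd_require_rhs_core=False)
    hit = detect_yd_repeats(prot(seq), params)
    assert hit is not None and hit.copies == 6
    assert hit.intervals[0] == (1, 2)


def test_yd_spacing_limit_breaks_chain():
    # copies 100 aa apart exceed the 60-aa spacing default
    seq = ("YD" + "A" * 98) * 6
    params = ClassifierParams(yd_require_rhs_core=False)
    assert detect_yd_repeats(prot(seq), params) is None


def test_yd_requires_rhs_core_when_enabled():
    profiles = load_default_profiles()
    seq_no_core = ("YD" + "A" * 20) * 6 + "A" * 30
    assert detect_yd_repeats(prot(seq_no_core), PARAMS,
                             profiles["RHS"]) is None
    seq_core = profiles["RHS"].consensus + ("YD" + "A" * 20) * 6
    hit = detect_yd_repeats(prot(seq_core), PARAMS, profiles["RHS"])
    assert hit is not None and hit.copies >= 6


def test_mutated_yd_repeats_recovered():
    rng = np.random.default_rng(0)
    profiles = load_default_profiles()
    core = profiles["RHS"].consensus
    recovered = 0
    for _ in range(100):
        units = []
        for _ in range(12):
            u = list(random_protein(rng, 19))
            u[5], u[6] = "Y", "D"
            units.append("".join(u))
        seq = list(core + "".join(units))
        for i in range(len(seq)):
            if rng.random() < 0.2:
                seq[i] = AA[rng.integers(20)]
        if detect_yd_repeats(prot("".join(seq)), PARAMS, profiles["RHS"]):
            recovered += 1
    assert recovered >= 90


# ---------------------------------------------------------------------------
# RTX repeats

def test_three_exact_tandem_nonapeptides_counted():
    seq = "GGAGNDNLS" * 3 + "A" * 30
    hit = detect_rtx_repeats(prot(seq), PARAMS)
    assert hit is not None and hit.copies == 3
    # independent check: the canonical unit starts at 0, 9, 18
    starts = [m.start() for m in re.finditer(r"(?=GGAGNDNL)", seq)]
    assert starts == [0, 9, 18]


def test_single_isolated_copy_below_min_copies():
    seq = "A" * 30 + "GGAGNDNLS" + "A" * 30
    assert detect_rtx_repeats(prot(seq), PARAMS) is None


def test_distant_copies_not_chained():
    seq = ("GGAGNDNLS" + "A" * 50) * 3
    assert detect_rtx_repeats(prot(seq), PARAMS) is None


def test_repeat_hit_invariants():
    seq = "GGAGNDNLS" * 4 + "A" * 20
    hit = detect_rtx_repeats(prot(seq), PARAMS)
    assert hit.copies == len(hit.intervals)
    for (s1, e1), (s2, e2) in zip(hit.intervals, hit.intervals[1:]):
        assert s2 > e1


@pytest.mark.parametrize("detector,seq", [
    (detect_rtx_repeats, "GGAGNDNLS" * 6 + "A" * 20),
    (lambda p, prm: detect_yd_repeats(p, prm), ("YD" + "A" * 20) * 8),
])
def test_raising_min_copies_never_adds_hits(detector, seq):
    p = prot(seq)
    hits = []
    for mc in range(2, 12):
        params = ClassifierParams(rtx_min_copies=mc, yd_min_copies=mc,
                                  yd_require_rhs_core=False)
        h = detector(p, params)
        hits.append(0 if h is None else h.copies)
    present = [1 if h else 0 for h in hits]
    assert present == sorted(present, reverse=True)


# ---------------------------------------------------------------------------
# MARTX domains

def test_consensus_scores_profile_maximum():
    profiles = load_default_profiles()
    acd = profiles["ACD"]
    hits = score_martx_domains(prot(acd.consensus), profiles)
    assert any(h.domain == "ACD"
               and h.profile_score == pytest.approx(acd.max_score)
               for h in hits)


def test_reversed_consensus_not_detected():
    profiles = load_default_profiles()
    for name in ("ACD", "RID", "CPD"):
        p = prot(profiles[name].consensus[::-1])
        assert score_martx_domains(p, profiles) == []


def test_mutated_martx_domains_recovered():
    rng = np.random.default_rng(1)
    profiles = load_default_profiles()
    recovered = 0
    for _ in range(100):
        seq = list(random_protein(rng, 40) + profiles["RID"].consensus
                   + random_protein(rng, 40))
        for i in range(len(seq)):
            if rng.random() < 0.25:
                seq[i] = AA[rng.integers(20)]
        if score_martx_domains(prot("".join(seq)), profiles):
            recovered += 1
    assert recovered >= 90


def test_malformed_profile_file_rejected(tmp_path):
    profiles = load_default_profiles()
    path = tmp_path / "acd.pssm"
    write_pssm(profiles["ACD"], path)
    roundtrip = read_pssm(path)
    assert roundtrip.consensus == profiles["ACD"].consensus
    assert roundtrip.cutoff == pytest.approx(profiles["ACD"].cutoff)
    bad = path.read_text().replace("pos\tA\t", "pos\tB\t")
    bad_path = tmp_path / "bad.pssm"
    bad_path.write_text(bad)
    with pytest.raises(ValueError, match="column"):
        read_pssm(bad_path)


# ---------------------------------------------------------------------------
# classification rule

def _repeat(pid, cls, copies, unit_len=9):
    intervals = [(1 + i * unit_len, (i + 1) * unit_len) for i in range(copies)]
    return RepeatHit(pid, cls, copies, intervals, float(copies))


def test_yd_repeats_alone_give_yd_class():
    p = prot("A" * 200)
    ann = classify_trg(p, [_repeat("p1", "YD", 5)], [])
    assert ann.trg_class == "YD"


def test_rtx_repeats_with_effector_domain_give_martx():
    p = prot("A" * 200)
    dom = DomainHit("p1", "ACD", 50.0, (10, 59))
    ann = classify_trg(p, [_repeat("p1", "RTX", 4)], [dom])
    assert ann.trg_class == "MARTX"


def test_rtx_repeats_on_giant_orf_give_martx():
    p = prot("A" * 1600)
    ann = classify_trg(p, [_repeat("p1", "RTX", 4)], [])
    assert ann.trg_class == "MARTX"
    ann2 = classify_trg(prot("A" * 1200), [_repeat("p1", "RTX", 4)], [])
    assert ann2.trg_class == "RTX"


def test_conflicting_repeat_evidence_resolved_by_score():
    p = prot("A" * 300)
    ann = classify_trg(p, [_repeat("p1", "YD", 6, 2),
                           _repeat("p1", "RTX", 4)], [])
    assert ann.trg_class == "YD"
    assert "RTX" in ann.conflict


def test_accessory_annotation_recognised():
    p = prot("A" * 100)
    ctx = GeneContext(annotation="RTX toxin transporter")
    ann = classify_trg(p, [], [], ctx)
    assert ann.trg_class == "RTX_accessory"
    assert classify_trg(p, [], [], GeneContext("hypothetical")) is None


def test_detection_is_deterministic():
    rng = np.random.default_rng(5)
    seq = "GGAGNDNLS" * 5 + random_protein(rng, 100)
    p = prot(seq)
    h1 = detect_rtx_repeats(p, PARAMS)
    h2 = detect_rtx_repeats(p, PARAMS)
    assert h1 == h2


# ---------------------------------------------------------------------------
# mobile-element adjacency

def _gene(gid, start, annotation=""):
    return GeneModel(gene_id=gid, genome_id="g", contig="c1", start=start,
                     end=start + 299, strand="+", nucleotide_seq="",
                     annotation=annotation)


def test_mobile_adjacency_within_one_gene():
    genes = [_gene("g1", 1), _gene("g2", 400, "IS3 family transposase"),
             _gene("g3", 800), _gene("g4", 1200), _gene("g5", 1600)]
    adjacent = mobile_adjacency(genes)
    assert adjacent == {"g1", "g3"}


def test_planted_classes_recovered_from_small_bundle(small_bundle):
    gs, truth = small_bundle
    calls = {c.protein_id: c.trg_class
             for c in classify_proteins(gs.proteins_of("F01"),
                                        gs.genes_of("F01"))}
    sub = truth[truth.genome_id == "F01"]
    for cls, n_planted in (("YD", 6), ("RTX", 3), ("MARTX", 4)):
        planted = sub.loc[sub.trg_class == cls, "gene_id"]
        assert len(planted) == n_planted
        assert sum(calls.get(g) == cls for g in planted) >= n_planted - 1
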