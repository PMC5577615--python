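"""Signal-peptide heuristic, dibasic sites, annotation and maturation."""

import random

import pytest

from mytimine.precursor import (
    AnnotationConfig,
    Rejection,
    SignalPrediction,
    annotate_precursor,
    apply_maturation,
    find_dibasic_sites,
    mature_from_annotation,
    predict_signal_peptide,
    read_signal_overrides,
)
from mytimine.seqcore import ProteinRecord
from mytimine.synthetic import SIGNAL_TEMPLATE

CONSENSUS_SIGNAL = SIGNAL_TEMPLATE.replace("X", "A")
CORE = "RPRPYRPRPYRPRPYRPRPYRPRPY"
TAIL = "DDEEDDEEDDEE"


# ---------------------------------------------------------------- signal

def test_no_hydrophobic_core_means_no_signal():
    assert not predict_signal_peptide("M" + "D" * 39).present


def test_consensus_signal_cleaved_at_23():
    protein = CONSENSUS_SIGNAL + CORE + "GKR" + TAIL
    pred = predict_signal_peptide(protein)
    assert pred.present and pred.cleavage_pos == 23
    assert pred.source == "heuristic"
    # -1 residue G, -3 residue C per the von Heijne rule
    assert protein[22] == "G" and protein[20] == "C"


def test_override_wins(tmp_path):
    protein = "M" + "D" * 50
    pred = predict_signal_peptide(protein, protein_id="p1", overrides={"p1": 19})
    assert pred.present and pred.cleavage_pos == 19 and pred.source == "external"
    path = tmp_path / "ov.tsv"
    path.write_text("protein_id\tcleavage_pos\np1\t19\n")
    assert read_signal_overrides(path) == {"p1": 19}


def test_short_protein_never_called():
    assert not predict_signal_peptide("MKGAALLLLTIAAALCM").present


def test_non_initiator_start_rejected():
    assert not predict_signal_peptide("K" + CONSENSUS_SIGNAL + CORE).present


# ---------------------------------------------------------------- dibasic

def test_single_kr_site():
    (site,) = find_dibasic_sites("AAAKRAAA")
    assert site.motif == "KR" and site.start == 3 and site.tail_start == 5


def test_overlapping_sites_each_reported():
    sites = find_dibasic_sites("RRR")
    assert [(s.motif, s.start) for s in sites] == [("RR", 0), ("RR", 1)]


def test_dibasic_sites_match_double_loop_oracle():
    rng = random.Random(9)
    pep = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(80))
    expected = []
    for i in range(len(pep) - 1):
        for motif in ("KR", "RR", "RK", "KK"):
            if pep[i] == motif[0] and pep[i + 1] == motif[1]:
                expected.append((motif, i))
    assert [(s.motif, s.start) for s in find_dibasic_sites(pep)] == expected


# ---------------------------------------------------------------- annotation

def _signal23():
    return SignalPrediction(present=True, cleavage_pos=23, source="heuristic")


def test_annotation_regions_tile_the_precursor():
    protein = ProteinRecord(id="p", sequence=CONSENSUS_SIGNAL + CORE + "KR" + TAIL)
    ann = annotate_precursor(protein, _signal23())
    assert not isinstance(ann, Rejection)
    assert ann.signal_region == CONSENSUS_SIGNAL
    assert ann.mature_core == CORE
    assert ann.dibasic_region == "KR"
    assert ann.tail == TAIL
    assert len(ann.signal_region) + len(ann.mature_core) + 2 + len(ann.tail) == len(
        protein.sequence
    )
    assert ann.tail_net_charge_ph7 < 0
    assert ann.tail_de_fraction == 1.0


def test_basic_tail_rejected():
    protein = ProteinRecord(id="p", sequence=CONSENSUS_SIGNAL + CORE + "KR" + "KKKKKKKK")
    outcome = annotate_precursor(protein, _signal23())
    assert isinstance(outcome, Rejection) and outcome.reason == "tail_not_anionic"


def test_no_dibasic_rejected():
    protein = ProteinRecord(id="p", sequence=CONSENSUS_SIGNAL + CORE + TAIL)
    outcome = annotate_precursor(protein, _signal23())
    assert isinstance(outcome, Rejection) and outcome.reason == "no_dibasic"


def test_mature_too_short_rejected():
    protein = ProteinRecord(id="p", sequence=CONSENSUS_SIGNAL + "RPRPY" + "KR" + TAIL)
    outcome = annotate_precursor(protein, _signal23())
    assert isinstance(outcome, Rejection) and outcome.reason == "mature_too_short"


def test_first_anionic_site_selected_among_two():
    # the first KR is followed by enough additional cationic core that its
    # remainder stays positive; only the second KR precedes an anionic tail
    inter = "RP" * 14
    seq = CONSENSUS_SIGNAL + CORE + "KR" + inter + "KR" + TAIL
    protein = ProteinRecord(id="p", sequence=seq)
    ann = annotate_precursor(protein, _signal23())
    assert not isinstance(ann, Rejection)
    assert ann.site.start == 23 + len(CORE) + 2 + len(inter)
    assert ann.tail == TAIL


def test_annotation_requires_signal():
    protein = ProteinRecord(id="p", sequence=CONSENSUS_SIGNAL + CORE + "KR" + TAIL)
    with pytest.raises(ValueError):
        annotate_precursor(protein, SignalPrediction(present=False))


# ---------------------------------------------------------------- maturation

def test_gly_lys_arg_terminus_yields_amidated_peptide():
    mature = apply_maturation("YGWPRHPTIYAG" + "KR")
    assert mature.sequence == "YGWPRHPTIYA"
    assert mature.amidated
    assert mature.trace == (
        "convertase_cut",
        "cpe_removed:R",
        "cpe_removed:K",
        "pam_amidation",
    )


def test_core_without_terminal_g_k_r_left_untouched():
    mature = apply_maturation("GRRGVTIQERSKSSTLNTED")
    assert mature.sequence == "GRRGVTIQERSKSSTLNTED"
    assert not mature.amidated
    assert mature.trace == ("convertase_cut",)


def test_multi_step_trace():
    mature = apply_maturation("AAAGRKR")
    assert mature.sequence == "AAA" and mature.amidated
    assert mature.trace == (
        "convertase_cut",
        "cpe_removed:R",
        "cpe_removed:K",
        "cpe_removed:R",
        "pam_amidation",
    )


def test_pam_removes_exactly_one_glycine():
    mature = apply_maturation("AAGGKR")
    assert mature.sequence == "AAG" and mature.amidated


def test_processing_consuming_everything_is_an_error():
    with pytest.raises(ValueError, match="empty after processing"):
        apply_maturation("KR")
    with pytest.raises(ValueError, match="empty after processing"):
        apply_maturation("GKR")


def test_maturation_is_idempotent_and_never_leaves_free_terminal_kr():
    rng = random.Random(13)
    for _ in range(50):
        core = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(12))
        suffix = rng.choice(["", "G", "KR", "GKR", "RKR", "GG"])
        try:
            mature = apply_maturation(core + suffix)
        except ValueError:
            continue  # everything consumed: legitimate for basic-only cores
        if not mature.amidated:  # a terminal basic may persist only amide-capped
            assert mature.sequence[-1] not in "KR"
        again = apply_maturation(mature.sequence, already_amidated=mature.amidated)
        assert again.sequence == mature.sequence
        assert again.amidated == mature.amidated


def test_pam_caps_a_preceding_basic_residue():
    # CPE cannot act on an amide-capped terminus: ...K-G-KR matures to an
    # amidated peptide ending in Lys
    mature = apply_maturation("WPRIPAKG" + "KR")
    assert mature.sequence == "WPRIPAK" and mature.amidated


def test_trace_order_invariant():
    mature = apply_maturation("WPRIPRAG" + "KR")
    assert mature.trace[0] == "convertase_cut"
    assert mature.trace.count("pam_amidation") == 1
    assert mature.trace[-1] == "pam_amidation"
    cpe_idx = [i for i, e in enumerate(mature.trace) if e.startswith("cpe")]
    assert all(i < mature.trace.index("pam_amidation") for i in cpe_idx)


def test_mature_from_annotation_matches_manual_cut(reference):
    protein = ProteinRecord(
        id="p", sequence=CONSENSUS_SIGNAL + "YGWPRMPRHPTIYAG" + "KR" + TAIL
    )
    ann = annotate_precursor(protein, _signal23())
    mature = mature_from_annotation(ann)
    assert mature.sequence == "YGWPRMPRHPTIYA"
    assert mature.amidated
    assert mature.source_annotation is ann
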