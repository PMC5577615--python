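"""Sequence I/O, translation and six-frame ORF extraction."""

import random

import pytest
from Bio.Seq import Seq

from mytimine.seqcore import (
    AlphabetError,
    DuplicateIdError,
    OrfCandidate,
    TranscriptRecord,
    extract_orfs,
    read_fasta,
    reverse_complement,
    translate,
)


# ---------------------------------------------------------------- oracles

def orf_oracle(sequence, min_codons, max_codons, require_stop):
    """Brute-force enumeration: every ATG..first-stop span in all six
    frames, reduced to the first ATG per stop (or per stop-less tail)."""
    n = len(sequence)
    results = []
    for strand in "+-":
        seq = sequence if strand == "+" else reverse_complement(sequence)
        spans = {}  # (frame, end-key) -> earliest start
        for i in range(n - 2):
            if seq[i : i + 3] != "ATG":
                continue
            frame = i % 3
            j = i
            stop = None
            while j + 3 <= n:
                codon = seq[j : j + 3]
                if "N" not in codon and codon in ("TAA", "TAG", "TGA"):
                    stop = j
                    break
                j += 3
            key = (frame, stop if stop is not None else "tail")
            if key not in spans or i < spans[key]:
                spans[key] = i
        for (frame, stop), start in spans.items():
            has_stop = stop != "tail"
            end = stop + 3 if has_stop else start + 3 * ((n - start) // 3)
            protein = translate(seq[start : end - 3] if has_stop else seq[start:end])
            if require_stop and not has_stop:
                continue
            if not (min_codons < len(protein) < max_codons):
                continue
            s, e = (start, end) if strand == "+" else (n - end, n - start)
            results.append((strand, frame, s, e, protein, has_stop))
    return sorted(results, key=lambda r: (r[2], r[0]))


def as_tuples(orfs):
    return [
        (o.strand, o.frame, o.start, o.end, o.protein, o.has_stop_codon) for o in orfs
    ]


def random_transcript(rng, length):
    return "".join(rng.choice("ACGT") for _ in range(length))


# ---------------------------------------------------------------- FASTA I/O

def test_read_fasta_joins_wrapped_lines(tmp_path):
    path = tmp_path / "in.fasta"
    path.write_text(">t1 first\nACGT\nACGT\n>t2\nggggttt\n")
    records = read_fasta(path, alphabet="nucleotide")
    assert [r.id for r in records] == ["t1", "t2"]
    assert records[0].sequence == "ACGTACGT"
    assert records[1].sequence == "GGGGTTT"  # uppercased


def test_read_fasta_protein_amidation_marker(tmp_path, reference):
    assert reference["A3"].sequence == "YGWPRMPRIPRKPRYPRYPRYPRWPRHPTIYA"
    assert reference["A3"].amidated is True
    assert reference["C10"].amidated is False
    path = tmp_path / "p.fasta"
    path.write_text(">x\nMKWVTF-NH2\n")
    (rec,) = read_fasta(path, alphabet="protein")
    assert rec.sequence == "MKWVTF" and rec.amidated


def test_read_fasta_duplicate_id_raises(tmp_path):
    path = tmp_path / "dup.fasta"
    path.write_text(">a\nACGT\n>a\nTTTT\n")
    with pytest.raises(DuplicateIdError):
        read_fasta(path, alphabet="nucleotide")


def test_read_fasta_maps_u_to_t_with_warning(tmp_path):
    path = tmp_path / "rna.fasta"
    path.write_text(">r\nAUGGCU\n")
    with pytest.warns(UserWarning, match="U"):
        (rec,) = read_fasta(path, alphabet="nucleotide")
    assert rec.sequence == "ATGGCT"


def test_read_fasta_rejects_bad_letters_and_missing_file(tmp_path):
    bad = tmp_path / "bad.fasta"
    bad.write_text(">b\nACGTZ\n")
    with pytest.raises(AlphabetError):
        read_fasta(bad, alphabet="nucleotide")
    with pytest.raises(FileNotFoundError):
        read_fasta(tmp_path / "absent.fasta")
    empty = tmp_path / "empty.fasta"
    empty.write_text("")
    with pytest.raises(ValueError, match="no FASTA records"):
        read_fasta(empty)


# ---------------------------------------------------------------- translation

@pytest.mark.parametrize(
    "codons,expected",
    [
        ("ATG", "M"),
        ("TAA", "*"),
        ("TAG", "*"),
        ("TGA", "*"),
        ("AAN", "X"),
        ("GGN", "X"),  # ambiguity is never resolved, even for 4-fold codons
        ("ATGAAATAA", "MK*"),
    ],
)
def test_translate_examples(codons, expected):
    assert translate(codons) == expected


def test_translate_rejects_partial_codons():
    with pytest.raises(ValueError, match="divisible by 3"):
        translate("ATGA")


def test_translate_matches_codon_table_oracle():
    rng = random.Random(7)
    seq = random_transcript(rng, 300)
    assert translate(seq) == str(Seq(seq).translate())


# ---------------------------------------------------------------- ORFs

def test_extract_minimal_orf():
    t = TranscriptRecord(id="t1", sequence="ATGAAATAA")
    (orf,) = extract_orfs(t, min_codons=1, max_codons=10)
    assert orf.protein == "MK"
    assert orf.codon_length == 2
    assert orf.has_stop_codon
    assert (orf.start, orf.end) == (0, 9)


def test_length_gate_is_strict():
    # 50 codons excluded, 51 included, 119 included, 120 excluded
    for n_codons, kept in [(50, False), (51, True), (119, True), (120, False)]:
        cds = "ATG" + "AAA" * (n_codons - 1) + "TAA"
        t = TranscriptRecord(id="t", sequence=cds)
        orfs = extract_orfs(t, min_codons=50, max_codons=120, both_strands=False)
        assert bool(orfs) is kept, n_codons


def test_stopless_orf_kept_unless_required():
    t = TranscriptRecord(id="t", sequence="ATGAAAAAA")  # runs off the end
    (orf,) = extract_orfs(t, min_codons=1, max_codons=10)
    assert not orf.has_stop_codon and orf.protein == "MKK"
    assert extract_orfs(t, min_codons=1, max_codons=10, require_stop=True) == []


def test_nested_atg_absorbed():
    # ATG ATG AAA TAA: one ORF from the first ATG (longest-per-stop)
    t = TranscriptRecord(id="t", sequence="ATGATGAAATAA")
    (orf,) = extract_orfs(t, min_codons=1, max_codons=10, both_strands=False)
    assert orf.protein == "MMK" and orf.start == 0


def test_orfs_match_bruteforce_oracle_on_random_transcripts():
    rng = random.Random(11)
    for _ in range(50):
        t = TranscriptRecord(id="t", sequence=random_transcript(rng, 600))
        got = as_tuples(extract_orfs(t, min_codons=5, max_codons=60))
        assert got == orf_oracle(t.sequence, 5, 60, False)


def test_reverse_complement_symmetry():
    rng = random.Random(23)
    for _ in range(20):
        seq = random_transcript(rng, 400)
        fwd = extract_orfs(TranscriptRecord(id="f", sequence=seq), 5, 80)
        rev = extract_orfs(
            TranscriptRecord(id="r", sequence=reverse_complement(seq)), 5, 80
        )
        n = len(seq)
        mirrored = sorted(
            ("+-"["+-".index(o.strand) ^ 1], n - o.end, n - o.start, o.protein)
            for o in rev
        )
        assert mirrored == sorted((o.strand, o.start, o.end, o.protein) for o in fwd)


def test_reported_proteins_start_with_m_and_have_no_stop():
    rng = random.Random(5)
    for _ in range(20):
        t = TranscriptRecord(id="t", sequence=random_transcript(rng, 500))
        for orf in extract_orfs(t, min_codons=3, max_codons=100):
            assert orf.protein.startswith("M")
            assert "*" not in orf.protein
            assert orf.codon_length == len(orf.protein)
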