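"""Sequence I/O, genetic-code translation and six-frame ORF extraction.

FASTA parsing is delegated to :mod:`Bio.SeqIO`; everything downstream works
on plain Python strings.  ORF extraction scans all six reading frames and
applies a strict codon-length gate (``min_codons < length < max_codons``),
the window used to enrich for short secreted peptide precursors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable

NUCLEOTIDE_LETTERS = frozenset("ACGTN")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# '*' only legal in pseudogene-screening contexts, 'X' from ambiguous codons
PROTEIN_LETTERS = frozenset(AMINO_ACIDS + "X*")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TABLE: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TABLE.update({codon: "*" for codon in _STANDARD.stop_codons})
STOP_CODONS = frozenset(_STANDARD.stop_codons)
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class DuplicateIdError(ValueError):
    """Two FASTA records share the same identifier."""


class AlphabetError(ValueError):
    """A sequence contains letters outside the declared alphabet."""


@dataclass(frozen=True)
class TranscriptRecord:
    """A nucleotide contig (candidate mRNA) read from FASTA."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"invalid transcript id: {self.id!r}")
        if not self.sequence:
            raise ValueError(f"empty sequence for transcript {self.id!r}")
        bad = set(self.sequence) - NUCLEOTIDE_LETTERS
        if bad:
            raise AlphabetError(
                f"transcript {self.id!r} contains non-nucleotide letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence; a trailing ``-NH2`` marker on input denotes
    C-terminal amidation and is stored as a flag, not in the sequence."""

    id: str
    sequence: str
    amidated: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"invalid protein id: {self.id!r}")
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.id!r}")
        bad = set(self.sequence) - PROTEIN_LETTERS
        if bad:
            raise AlphabetError(
                f"protein {self.id!r} contains invalid letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfCandidate:
    """A translated open reading frame.

    ``start``/``end`` are 0-based half-open coordinates on the FORWARD
    strand of the transcript regardless of the ORF's strand; ``frame`` is
    the offset (0..2) on the strand the ORF was read from.  ``end``
    includes the stop codon when ``has_stop_codon`` is true.
    """

    transcript_id: str
    strand: str
    frame: int
    start: int
    end: int
    protein: str
    codon_length: int
    has_stop_codon: bool

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        span = self.end - self.start
        expected = 3 * (self.codon_length + 1) if self.has_stop_codon else 3 * self.codon_length
        if span != expected:
            raise ValueError(
                f"ORF span {span} inconsistent with codon_length {self.codon_length}"
            )
        if not self.protein.startswith("M"):
            raise ValueError("ORF protein must start with M")
        if "*" in self.protein:
            raise ValueError("ORF protein must not contain internal stops")


AMIDATION_SUFFIX = "-NH2"


def read_fasta(path: str | Path, alphabet: str = "nucleotide"):
    """Read a FASTA file into :class:`TranscriptRecord` or :class:`ProteinRecord`.

    Parameters
    ----------
    path:
        FASTA file; wrapped sequence lines are joined, lowercase is
        uppercased.
    alphabet:
        ``"nucleotide"`` (U mapped to T with a warning) or ``"protein"``
        (a trailing ``-NH2`` sets the amidated flag).

    Raises
    ------
    FileNotFoundError, DuplicateIdError, AlphabetError, ValueError
        for missing/empty files, repeated ids and out-of-alphabet letters.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        desc = rec.description[len(rec.id):].strip()
        if alphabet == "nucleotide":
            if "U" in seq:
                warnings.warn(
                    f"record {rec.id!r}: RNA letters (U) mapped to T", stacklevel=2
                )
                seq = seq.replace("U", "T")
            records.append(TranscriptRecord(id=rec.id, sequence=seq, description=desc))
        else:
            amidated = seq.endswith(AMIDATION_SUFFIX)
            if amidated:
                seq = seq[: -len(AMIDATION_SUFFIX)]
            records.append(
                ProteinRecord(id=rec.id, sequence=seq, amidated=amidated, description=desc)
            )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def translate(codons: str) -> str:
    """Translate a nucleotide string (length divisible by 3, letters ACGTN).

    Stop codons render ``*``; any codon containing ``N`` renders ``X``
    (ambiguity is never resolved, even when all expansions agree).
    """
    if len(codons) % 3:
        raise ValueError(f"sequence length {len(codons)} not divisible by 3")
    out = []
    for i in range(0, len(codons), 3):
        codon = codons[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            try:
                out.append(CODON_TABLE[codon])
            except KeyError:
                raise AlphabetError(f"invalid codon {codon!r}") from None
    return "".join(out)


def _scan_frame(seq: str, frame: int):
    """Yield (start, end, protein, has_stop) spans on one strand/frame.

    An ORF runs from the first ATG after the previous stop to the next
    in-frame stop (longest-per-stop convention: nested ATGs are absorbed).
    Coordinates are on the given sequence; ``end`` includes the stop codon.
    """
    n = len(seq)
    orf_start: int | None = None
    i = frame
    while i + 3 <= n:
        codon = seq[i : i + 3]
        if "N" not in codon and codon in STOP_CODONS:
            if orf_start is not None:
                yield orf_start, i + 3, translate(seq[orf_start:i]), True
                orf_start = None
        elif codon == START_CODON and orf_start is None:
            orf_start = i
        i += 3
    if orf_start is not None:
        yield orf_start, i, translate(seq[orf_start:i]), False


def extract_orfs(
    transcript: TranscriptRecord,
    min_codons: int = 50,
    max_codons: int = 120,
    require_stop: bool = False,
    both_strands: bool = True,
) -> list[OrfCandidate]:
    """Extract ORFs from all six frames with a strict length gate.

    Only ORFs with ``min_codons < codon_length < max_codons`` are returned
    (codon_length excludes the stop codon).  ORFs running off the
    transcript end are kept with ``has_stop_codon=False`` unless
    ``require_stop`` is set.  Results are sorted by (start, strand).
    """
    if min_codons < 1 or max_codons <= min_codons:
        raise ValueError("require min_codons >= 1 and max_codons > min_codons")
    n = len(transcript.sequence)
    found: list[OrfCandidate] = []
    strands = [("+", transcript.sequence)]
    if both_strands:
        strands.append(("-", reverse_complement(transcript.sequence)))
    for strand, seq in strands:
        for frame in range(3):
            for s, e, protein, has_stop in _scan_frame(seq, frame):
                if require_stop and not has_stop:
                    continue
                codon_length = len(protein)
                if not (min_codons < codon_length < max_codons):
                    continue
                if strand == "+":
                    start, end = s, e
                else:
                    start, end = n - e, n - s
                found.append(
                    OrfCandidate(
                        transcript_id=transcript.id,
                        strand=strand,
                        frame=frame,
                        start=start,
                        end=end,
                        protein=protein,
                        codon_length=codon_length,
                        has_stop_codon=has_stop,
                    )
                )
    found.sort(key=lambda o: (o.start, o.strand))
    return found


ORF_TSV_COLUMNS = [
    "transcript_id",
    "strand",
    "frame",
    "start",
    "end",
    "codon_length",
    "has_stop_codon",
    "protein",
]


def write_orf_table(orfs: Iterable[OrfCandidate], path: str | Path) -> None:
    """Write an ORF report as TSV."""
    import pandas as pd

    rows = [{col: getattr(o, col) for col in ORF_TSV_COLUMNS} for o in orfs]
    pd.DataFrame(rows, columns=ORF_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
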