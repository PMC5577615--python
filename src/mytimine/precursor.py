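"""Precursor architecture annotation and proteolytic maturation.

A myticalin-like precursor decomposes into four regions::

    signal peptide | mature core | dibasic site | anionic tail

The signal peptide is detected with an explicit, offline heuristic
(hydrophobic core + von Heijne (-3,-1) rule) that can be overridden with
externally computed cleavage positions.  A proprotein convertase cleaves
C-terminal to a dibasic pair (KR/RR/RK/KK); carboxypeptidase E (CPE) then
trims the exposed C-terminal basic residues, and peptidylglycine
alpha-amidating monooxygenase (PAM) converts a now-terminal glycine into a
C-terminal amide on the preceding residue.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .physchem import KYTE_DOOLITTLE, net_charge, composition
from .seqcore import ProteinRecord

__all__ = [
    "SignalPrediction",
    "CleavageSite",
    "PrecursorAnnotation",
    "MaturePeptide",
    "Rejection",
    "AnnotationConfig",
    "predict_signal_peptide",
    "find_dibasic_sites",
    "annotate_precursor",
    "apply_maturation",
    "mature_from_annotation",
    "read_signal_overrides",
    "DIBASIC_MOTIFS",
]

DIBASIC_MOTIFS = ("KR", "RR", "RK", "KK")

# von Heijne (-3,-1) rule residue sets: the -1 residue must be small
# (A/G/S); the -3 residue small or moderately hydrophobic.
_MINUS1_RESIDUES = frozenset("AGS")
_MINUS3_RESIDUES = frozenset("AGSTVCIL")

# hydrophobic-core requirement: some 8-residue window inside positions
# 2..20 (0-based) with mean Kyte-Doolittle hydropathy >= this threshold
_HCORE_WINDOW = 8
_HCORE_SPAN = (2, 20)
_HCORE_MIN_MEAN_KD = 1.5

# candidate cleavage positions scanned (number of signal residues)
_CLEAVAGE_SCAN = range(15, 31)

_MIN_SIGNAL_PROTEIN_LEN = 18


@dataclass(frozen=True)
class SignalPrediction:
    """Presence and cleavage position of an N-terminal signal peptide.

    ``cleavage_pos`` is the number of signal residues: the mature region
    starts at that 0-based index.
    """

    present: bool
    cleavage_pos: Optional[int] = None
    score: float = 0.0
    source: str = "heuristic"

    def __post_init__(self) -> None:
        if self.present:
            if self.cleavage_pos is None or not (12 <= self.cleavage_pos <= 35):
                raise ValueError(
                    f"signal cleavage position {self.cleavage_pos} outside 12..35"
                )
        if self.source not in ("heuristic", "external"):
            raise ValueError(f"bad source {self.source!r}")


@dataclass(frozen=True)
class CleavageSite:
    """A dibasic convertase site: precursor[start:start+2] == motif."""

    motif: str
    start: int

    def __post_init__(self) -> None:
        if self.motif not in DIBASIC_MOTIFS:
            raise ValueError(f"bad dibasic motif {self.motif!r}")

    @property
    def tail_start(self) -> int:
        return self.start + 2


@dataclass(frozen=True)
class PrecursorAnnotation:
    """Four-region decomposition of an accepted precursor protein."""

    protein_id: str
    sequence: str
    signal: SignalPrediction
    site: CleavageSite
    tail_net_charge_ph7: float
    tail_de_fraction: float

    def __post_init__(self) -> None:
        if not self.signal.present:
            raise ValueError("annotation requires a present signal peptide")
        if self.sequence[self.site.start : self.site.tail_start] != self.site.motif:
            raise ValueError("dibasic site does not match precursor sequence")

    @property
    def signal_region(self) -> str:
        return self.sequence[: self.signal.cleavage_pos]

    @property
    def mature_core(self) -> str:
        return self.sequence[self.signal.cleavage_pos : self.site.start]

    @property
    def dibasic_region(self) -> str:
        return self.sequence[self.site.start : self.site.tail_start]

    @property
    def tail(self) -> str:
        return self.sequence[self.site.tail_start :]


@dataclass(frozen=True)
class Rejection:
    """Machine-readable rejection of a candidate precursor."""

    protein_id: str
    reason: str  # no_dibasic | mature_too_short | tail_not_anionic


@dataclass(frozen=True)
class MaturePeptide:
    """A post-processed peptide with its ordered processing trace."""

    sequence: str
    amidated: bool
    trace: tuple[str, ...]
    source_annotation: Optional[PrecursorAnnotation] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("mature peptide is empty")
        # a terminal basic residue is only legal when the amide caps it
        if self.sequence[-1] in "KR" and not self.amidated:
            raise ValueError("free-acid mature peptide must not end in K or R")


@dataclass(frozen=True)
class AnnotationConfig:
    """Thresholds for precursor acceptance."""

    min_mature: int = 10
    min_tail: int = 5


def predict_signal_peptide(
    protein: str | ProteinRecord,
    protein_id: Optional[str] = None,
    overrides: Optional[Mapping[str, int]] = None,
) -> SignalPrediction:
    """Detect an N-terminal secretion signal.

    If ``overrides`` holds an entry for this protein id (e.g. from an
    external predictor run), it wins with ``source="external"``.
    Otherwise the heuristic requires, on the initiator-anchored sequence:

    (a) position 0 is M;
    (b) a hydrophobic core: some 8-residue window within positions 2..20
        with mean Kyte-Doolittle hydropathy >= 1.5;
    (c) a cleavage position p in 15..30 (the smallest) with residue p-1 in
        {A,G,S} and residue p-3 in {A,G,S,T,V,C,I,L}.

    Proteins shorter than 18 residues are never called.
    """
    if isinstance(protein, ProteinRecord):
        protein_id = protein_id or protein.id
        protein = protein.sequence
    if overrides and protein_id is not None and protein_id in overrides:
        return SignalPrediction(
            present=True,
            cleavage_pos=int(overrides[protein_id]),
            score=1.0,
            source="external",
        )
    if len(protein) < _MIN_SIGNAL_PROTEIN_LEN:
        return SignalPrediction(present=False)
    if protein[0] != "M":
        return SignalPrediction(present=False)
    lo, hi = _HCORE_SPAN
    best_kd = float("-inf")
    for s in range(lo, hi - _HCORE_WINDOW + 2):
        window = protein[s : s + _HCORE_WINDOW]
        if len(window) < _HCORE_WINDOW:
            break
        kd = sum(KYTE_DOOLITTLE.get(aa, 0.0) for aa in window) / _HCORE_WINDOW
        best_kd = max(best_kd, kd)
    if best_kd < _HCORE_MIN_MEAN_KD:
        return SignalPrediction(present=False)
    for p in _CLEAVAGE_SCAN:
        if p >= len(protein):
            break
        if protein[p - 1] in _MINUS1_RESIDUES and protein[p - 3] in _MINUS3_RESIDUES:
            return SignalPrediction(
                present=True, cleavage_pos=p, score=best_kd, source="heuristic"
            )
    return SignalPrediction(present=False)


def find_dibasic_sites(protein: str, search_from: int = 0) -> list[CleavageSite]:
    """All (possibly overlapping) dibasic pairs at index >= search_from."""
    if search_from >= len(protein):
        raise ValueError("search_from beyond end of protein")
    sites = []
    for i in range(max(search_from, 0), len(protein) - 1):
        pair = protein[i : i + 2]
        if pair in DIBASIC_MOTIFS:
            sites.append(CleavageSite(motif=pair, start=i))
    return sites


def annotate_precursor(
    protein: ProteinRecord,
    signal: SignalPrediction,
    config: AnnotationConfig = AnnotationConfig(),
) -> PrecursorAnnotation | Rejection:
    """Select the dibasic site separating mature core from anionic tail.

    Among sites giving a mature core of at least ``min_mature`` residues
    and a tail of at least ``min_tail``, the FIRST site whose tail has
    negative net charge at pH 7 (side chains only, the tail being judged
    as part of the precursor) is selected.  Rejections carry the reason of
    the furthest test reached: no_dibasic, mature_too_short, or
    tail_not_anionic.
    """
    if not signal.present:
        raise ValueError("annotate_precursor requires a present signal peptide")
    seq = protein.sequence
    cleavage = signal.cleavage_pos
    assert cleavage is not None
    if cleavage >= len(seq) - 1:
        return Rejection(protein_id=protein.id, reason="no_dibasic")
    sites = find_dibasic_sites(seq, search_from=cleavage)
    if not sites:
        return Rejection(protein_id=protein.id, reason="no_dibasic")
    long_enough = [s for s in sites if s.start - cleavage >= config.min_mature]
    if not long_enough:
        return Rejection(protein_id=protein.id, reason="mature_too_short")
    eligible = [s for s in long_enough if len(seq) - s.tail_start >= config.min_tail]
    for site in eligible:
        tail = seq[site.tail_start :]
        charge = net_charge(tail, ph=7.0, include_termini=False)
        if charge < 0.0:
            return PrecursorAnnotation(
                protein_id=protein.id,
                sequence=seq,
                signal=signal,
                site=site,
                tail_net_charge_ph7=charge,
                tail_de_fraction=composition(tail).fraction("DE"),
            )
    return Rejection(protein_id=protein.id, reason="tail_not_anionic")


def apply_maturation(
    sequence: str,
    already_amidated: bool = False,
    source_annotation: Optional[PrecursorAnnotation] = None,
) -> MaturePeptide:
    """Run the convertase/CPE/PAM cascade on a core+dibasic sequence.

    The convertase cut exposes the dibasic pair at the C-terminus; CPE
    iteratively removes C-terminal K/R; PAM then removes exactly one
    terminal glycine (a single amide donor) and amidates the preceding
    residue — whatever it is, including a basic one, whose amide cap then
    blocks any further CPE trimming.  An already-amidated peptide offers
    neither enzyme a substrate, so re-application is a no-op and
    maturation is idempotent.
    """
    trace: list[str] = ["convertase_cut"]
    seq = sequence
    if already_amidated:
        if not seq:
            raise ValueError("mature peptide empty after processing")
        return MaturePeptide(
            sequence=seq, amidated=True, trace=tuple(trace),
            source_annotation=source_annotation,
        )
    while seq and seq[-1] in "KR":
        trace.append(f"cpe_removed:{seq[-1]}")
        seq = seq[:-1]
    amidated = already_amidated
    if not already_amidated and seq and seq[-1] == "G":
        trace.append("pam_amidation")
        seq = seq[:-1]
        amidated = True
    if not seq:
        raise ValueError("mature peptide empty after processing")
    return MaturePeptide(
        sequence=seq,
        amidated=amidated,
        trace=tuple(trace),
        source_annotation=source_annotation,
    )


def mature_from_annotation(annotation: PrecursorAnnotation) -> MaturePeptide:
    """Mature peptide from an accepted annotation (cut after the dibasic pair)."""
    start = annotation.signal.cleavage_pos
    assert start is not None
    substrate = annotation.sequence[start : annotation.site.tail_start]
    return apply_maturation(substrate, source_annotation=annotation)


def read_signal_overrides(path: str | Path) -> dict[str, int]:
    """Read an override TSV with columns protein_id, cleavage_pos."""
    overrides: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {
            "protein_id",
            "cleavage_pos",
        } <= set(reader.fieldnames):
            raise ValueError(
                "override TSV needs columns: protein_id, cleavage_pos"
            )
        for row in reader:
            overrides[row["protein_id"]] = int(row["cleavage_pos"])
    return overrides
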