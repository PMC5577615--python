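"""Seeded synthetic-transcriptome generator with ground truth.

Plants myticalin-like precursors (signal peptide from the family's
consensus template, a subfamily-constrained cationic core, an optional
amidation glycine, a Lys-Arg convertase site and an anionic tail) inside
random-UTR transcripts, next to adversarial decoys that each violate
exactly one named pipeline gate.  Identical (config, seed) pairs produce
byte-identical output.

Construction guarantees (no rejection against the pipeline is needed):

* the core contains Arg as its only basic residue, never adjacent to
  another basic, and never ends in K/R/G, so the planted Lys-Arg pair is
  the only dibasic site in the precursor;
* every core carries >=13% Arg, so some 15-residue window holds an Arg
  and no Asp/Glu, pushing the window isoelectric point above 8;
* mature (23-42) and tail (35-75) lengths are sampled jointly so the
  precursor stays inside the strict 50 < codons < 120 ORF gate;
* an in-frame stop codon immediately 5' of the start codon pins the
  reported ORF to the planted protein.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .seqcore import CODON_TABLE, TranscriptRecord, reverse_complement
from .precursor import apply_maturation

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "DecoyTruth",
    "SimulatedTranscriptome",
    "RecoveryMetrics",
    "simulate_precursor",
    "simulate_transcriptome",
    "evaluate_recovery",
    "write_fasta",
    "write_truth_table",
    "SIGNAL_TEMPLATE",
    "DECOY_CLASSES",
]

#: Family consensus signal peptide; X positions are filled at random.
SIGNAL_TEMPLATE = "MKGXXLLLLTIXXALCMIXECEG"
SIGNAL_LENGTH = len(SIGNAL_TEMPLATE)

DECOY_CLASSES = (
    "no_signal",
    "no_dibasic",
    "low_cationicity",
    "cationic_but_basic_tail",
)

_X_FILL = "ALSV"
_HYDROPHOBIC_SUBS = "LIVFM"
_SUB_POSITIONS = (5, 6, 7, 8, 9)  # inside the Leu run; keeps the core hydrophobic

# residue pools (no D/E/C/K in cores: Arg is the only basic, Tyr the only
# acidic group, so windows holding an Arg stay cationic)
_CORE_POOLS = {
    "A": "GSANQTILVFHMW",
    "B": "GSANQILVFHM",
    "C": "GSANQTILVFHMWY",
    "D": "GSANQILVFHM",
}
_TAIL_POOL = "GSANQTLIV"
_BLAND_POOL = "GSANQTLIV"

_CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for codon, aa in sorted(CODON_TABLE.items()):
    _CODONS_BY_AA.setdefault(aa, ())
    _CODONS_BY_AA[aa] += (codon,)
_STOPS = _CODONS_BY_AA["*"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic benchmark."""

    n_planted: int = 50
    n_decoys: int = 500
    seed: int = 42
    mature_length_range: tuple[int, int] = (23, 42)
    tail_length_range: tuple[int, int] = (35, 75)
    tail_de_fraction: float = 0.30
    subfamily_mix: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.35, "B": 0.05, "C": 0.35, "D": 0.25}
    )
    utr_length_range: tuple[int, int] = (25, 80)
    amidation_probability: float = 0.7
    strand_flip_probability: float = 0.5
    decoy_classes: tuple[str, ...] = DECOY_CLASSES
    max_precursor_codons: int = 119  # strict "<120 codons" ORF gate

    def __post_init__(self) -> None:
        total = sum(self.subfamily_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subfamily mix sums to {total}, expected 1")
        for name in ("mature_length_range", "tail_length_range", "utr_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"empty range for {name}")
        unknown = set(self.decoy_classes) - set(DECOY_CLASSES)
        if unknown:
            raise ValueError(f"unknown decoy classes {sorted(unknown)}")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one planted precursor."""

    transcript_id: str
    precursor: str
    mature: str
    amidated: bool
    subfamily: str
    signal_length: int = SIGNAL_LENGTH


@dataclass(frozen=True)
class DecoyTruth:
    transcript_id: str
    decoy_class: str
    protein: str


@dataclass(frozen=True)
class SimulatedTranscriptome:
    transcripts: tuple[TranscriptRecord, ...]
    truth: tuple[PlantedTruth, ...]
    decoys: tuple[DecoyTruth, ...]
    config: SimulationConfig


# --------------------------------------------------------------------------
# building blocks

def _choice(rng: np.random.Generator, letters: str, size: int) -> list[str]:
    return [letters[i] for i in rng.integers(0, len(letters), size)]


def _simulate_signal(rng: np.random.Generator) -> str:
    signal = [
        rng.choice(list(_X_FILL)) if aa == "X" else aa for aa in SIGNAL_TEMPLATE
    ]
    for pos in rng.choice(_SUB_POSITIONS, size=int(rng.integers(0, 3)), replace=False):
        signal[pos] = str(rng.choice(list(_HYDROPHOBIC_SUBS)))
    return "".join(signal)


def _shuffle_core(rng: np.random.Generator, residues: list[str]) -> str:
    """Shuffle so no two basic residues are adjacent and the last residue
    is not K, R or G (which would perturb the maturation boundary)."""
    for _ in range(1000):
        rng.shuffle(residues)
        core = "".join(residues)
        if core[-1] in "KRG":
            continue
        if any(a in "KR" and b in "KR" for a, b in zip(core, core[1:])):
            continue
        return core
    raise RuntimeError("could not arrange core without adjacent basic residues")


def _subfamily_core(rng: np.random.Generator, subfamily: str, length: int) -> str:
    """Sample a mature core guaranteed to satisfy its subfamily predicate."""
    need = int(np.ceil(0.13 * length))
    if subfamily == "A":
        forced = ["R"] * need + ["P"] * need + ["Y"] * need
    elif subfamily == "B":
        forced = ["R"] * need + ["P"] * need + ["T"] * need
    elif subfamily == "C":
        forced = ["R"] * int(np.ceil(0.25 * length))
    elif subfamily == "D":
        forced = ["R"] * need + ["P"] * need + ["W"] * int(np.ceil(0.08 * length))
    else:
        raise ValueError(f"unknown subfamily {subfamily!r}")
    fill = _choice(rng, _CORE_POOLS[subfamily], length - len(forced))
    return _shuffle_core(rng, forced + fill)


def _anionic_tail(rng: np.random.Generator, length: int, de_fraction: float) -> str:
    n_de = int(round(de_fraction * length))
    acidic = _choice(rng, "DE", n_de)
    fill = _choice(rng, _TAIL_POOL, length - n_de)
    residues = acidic + fill
    rng.shuffle(residues)
    return "".join(residues)


def _patterned_bland(rng: np.random.Generator, length: int, period: int = 3) -> str:
    """Non-cationic sequence with an acidic residue every ``period``
    positions, so every 15-residue window is guaranteed anionic."""
    return "".join(
        str(rng.choice(list("DE"))) if i % period == 0 else str(rng.choice(list(_BLAND_POOL)))
        for i in range(length)
    )


def _basic_tail(rng: np.random.Generator, length: int) -> str:
    """Tail with interspersed Lys and no acidic residues: every suffix has
    non-negative net charge, so no convertase site can look anionic."""
    return "".join(
        "K" if i % 5 == 0 else str(rng.choice(list(_BLAND_POOL)))
        for i in range(length)
    )


def _sample_lengths(
    rng: np.random.Generator, config: SimulationConfig, overhead: int
) -> tuple[int, int]:
    """Joint (core, tail) lengths keeping the precursor under the ORF gate."""
    lo, hi = config.mature_length_range
    core_len = int(rng.integers(lo, hi + 1))
    t_lo, t_hi = config.tail_length_range
    t_cap = min(t_hi, config.max_precursor_codons - overhead - core_len)
    if t_cap < t_lo:
        raise ValueError("length budget cannot accommodate tail range")
    tail_len = int(rng.integers(t_lo, t_cap + 1))
    return core_len, tail_len


# --------------------------------------------------------------------------
# precursor and transcript simulation

def simulate_precursor(
    subfamily: str, rng: np.random.Generator, config: SimulationConfig = SimulationConfig()
) -> tuple[str, str, bool]:
    """Sample one precursor; returns (precursor, expected mature, amidated).

    The expected mature peptide equals the planted core: the convertase
    cuts after the Lys-Arg pair, CPE trims R then K, and PAM (when the
    amidation glycine was planted) removes it and amidates the core.
    """
    signal = _simulate_signal(rng)
    amidated = bool(rng.random() < config.amidation_probability)
    overhead = SIGNAL_LENGTH + (3 if amidated else 2)
    core_len, tail_len = _sample_lengths(rng, config, overhead)
    core = _subfamily_core(rng, subfamily, core_len)
    tail = _anionic_tail(rng, tail_len, config.tail_de_fraction)
    junction = "GKR" if amidated else "KR"
    precursor = signal + core + junction + tail
    # invariant: maturation of core+junction reproduces the planted core
    check = apply_maturation(core + junction)
    assert check.sequence == core and check.amidated == amidated
    return precursor, core, amidated


def _decoy_protein(
    rng: np.random.Generator, decoy_class: str, config: SimulationConfig
) -> str:
    subfamily = str(rng.choice(list("ACD")))
    if decoy_class == "no_signal":
        # hydrophilic N-terminus: the hydrophobic-core condition fails
        pad = "M" + "".join(_choice(rng, "DENQSTG", 19))
        core_len, tail_len = _sample_lengths(rng, config, len(pad) + 2)
        return (
            pad
            + _subfamily_core(rng, subfamily, core_len)
            + "KR"
            + _anionic_tail(rng, tail_len, config.tail_de_fraction)
        )
    signal = _simulate_signal(rng)
    if decoy_class == "no_dibasic":
        core_len, tail_len = _sample_lengths(rng, config, SIGNAL_LENGTH)
        return (
            signal
            + _subfamily_core(rng, subfamily, core_len)
            + _anionic_tail(rng, tail_len, config.tail_de_fraction)
        )
    if decoy_class == "low_cationicity":
        core_len, tail_len = _sample_lengths(rng, config, SIGNAL_LENGTH + 2)
        return (
            signal
            + _patterned_bland(rng, core_len)
            + "KR"
            + _patterned_bland(rng, tail_len)
        )
    if decoy_class == "cationic_but_basic_tail":
        core_len, tail_len = _sample_lengths(rng, config, SIGNAL_LENGTH + 2)
        return (
            signal
            + _subfamily_core(rng, subfamily, core_len)
            + "KR"
            + _basic_tail(rng, tail_len)
        )
    raise ValueError(f"unknown decoy class {decoy_class!r}")


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [str(rng.choice(_CODONS_BY_AA[aa])) for aa in protein]
    codons.append(str(rng.choice(_STOPS)))
    return "".join(codons)


def _wrap_transcript(
    rng: np.random.Generator, name: str, protein: str, config: SimulationConfig
) -> TranscriptRecord:
    lo, hi = config.utr_length_range
    utr5 = "".join(_choice(rng, "ACGT", int(rng.integers(lo, hi + 1))))
    utr3 = "".join(_choice(rng, "ACGT", int(rng.integers(lo, hi + 1))))
    # in-frame stop immediately 5' of ATG pins the reported ORF start
    seq = utr5 + "TAA" + _reverse_translate(rng, protein) + utr3
    if rng.random() < config.strand_flip_probability:
        seq = reverse_complement(seq)
    return TranscriptRecord(id=name, sequence=seq)


def simulate_transcriptome(config: SimulationConfig) -> SimulatedTranscriptome:
    """Generate the full benchmark: planted precursors plus decoys.

    Deterministic in (config, seed): the same pair always yields
    byte-identical transcripts and truth tables.
    """
    rng = np.random.default_rng(config.seed)
    labels = sorted(config.subfamily_mix)
    probs = np.array([config.subfamily_mix[k] for k in labels], dtype=float)
    transcripts: list[TranscriptRecord] = []
    truth: list[PlantedTruth] = []
    decoys: list[DecoyTruth] = []
    for i in range(config.n_planted):
        subfamily = labels[int(rng.choice(len(labels), p=probs))]
        precursor, mature, amidated = simulate_precursor(subfamily, rng, config)
        name = f"syn_p{i:04d}"
        transcripts.append(_wrap_transcript(rng, name, precursor, config))
        truth.append(
            PlantedTruth(
                transcript_id=name,
                precursor=precursor,
                mature=mature,
                amidated=amidated,
                subfamily=subfamily,
            )
        )
    classes = config.decoy_classes
    for i in range(config.n_decoys):
        decoy_class = classes[i % len(classes)]
        protein = _decoy_protein(rng, decoy_class, config)
        name = f"syn_d{i:04d}"
        transcripts.append(_wrap_transcript(rng, name, protein, config))
        decoys.append(
            DecoyTruth(transcript_id=name, decoy_class=decoy_class, protein=protein)
        )
    return SimulatedTranscriptome(
        transcripts=tuple(transcripts),
        truth=tuple(truth),
        decoys=tuple(decoys),
        config=config,
    )


# --------------------------------------------------------------------------
# recovery metrics

@dataclass(frozen=True)
class RecoveryMetrics:
    sensitivity: float
    precision: Optional[float]  # None when nothing was reported
    exact_mature_match_rate: float
    n_planted: int
    n_reported: int


def evaluate_recovery(reports, truth: Sequence[PlantedTruth]) -> RecoveryMetrics:
    """Compare pipeline reports against the planted truth table.

    ``sensitivity``: planted transcripts with at least one report;
    ``precision``: reports whose transcript was planted; the exact-match
    rate additionally requires byte-identical mature sequence and
    matching amidation.
    """
    ids = [t.transcript_id for t in truth]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids in truth table")
    by_id = {t.transcript_id: t for t in truth}
    reported_ids = {r.transcript_id for r in reports}
    matched = sum(1 for t in truth if t.transcript_id in reported_ids)
    exact = 0
    for t in truth:
        for r in reports:
            if (
                r.transcript_id == t.transcript_id
                and r.mature.sequence == t.mature
                and r.mature.amidated == t.amidated
            ):
                exact += 1
                break
    n_reports = len(list(reports))
    true_reports = sum(1 for r in reports if r.transcript_id in by_id)
    return RecoveryMetrics(
        sensitivity=matched / len(truth) if truth else 1.0,
        precision=(true_reports / n_reports) if n_reports else None,
        exact_mature_match_rate=exact / len(truth) if truth else 1.0,
        n_planted=len(truth),
        n_reported=n_reports,
    )


# --------------------------------------------------------------------------
# serialization

def write_fasta(records: Iterable[TranscriptRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_truth_table(truth: Iterable[PlantedTruth], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "transcript_id": t.transcript_id,
            "precursor": t.precursor,
            "mature": t.mature,
            "amidated": t.amidated,
            "subfamily": t.subfamily,
        }
        for t in truth
    ]
    pd.DataFrame(
        rows, columns=["transcript_id", "precursor", "mature", "amidated", "subfamily"]
    ).to_csv(path, sep="\t", index=False)


def config_to_json(config: SimulationConfig, path: str | Path) -> None:
    data = asdict(config)
    data["subfamily_mix"] = dict(config.subfamily_mix)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)


def config_from_json(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = json.load(fh)
    for key in ("mature_length_range", "tail_length_range", "utr_length_range",
                "decoy_classes"):
        if key in data:
            data[key] = tuple(data[key])
    return SimulationConfig(**data)
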