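"""End-to-end discovery pipeline, subfamily classifier, consensus builder
and pseudogene screen.

The discovery chain mirrors the original mining strategy:

1. six-frame ORF extraction with a strict 50 < codons < 120 gate;
2. signal-peptide gate (secretory-pathway targeting);
3. cationicity filter on the post-signal region: a 15-residue sliding
   window must exceed 30% combined Arg/Pro content OR reach a window
   isoelectric point above 8;
4. precursor annotation (dibasic convertase site followed by an anionic
   tail) and maturation (convertase/CPE/PAM);
5. physicochemical characterization, subfamily classification and
   reporting flags.

Every ORF entering the chain is accounted for: rejected candidates are
logged with the stage (and reason) at which they fell out.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import physchem
from .physchem import (
    EXPASY_PKA,
    PkaTable,
    composition,
    floor_percent,
    isoelectric_point,
    net_charge,
    window_scan,
)
from .precursor import (
    AnnotationConfig,
    MaturePeptide,
    PrecursorAnnotation,
    Rejection,
    annotate_precursor,
    apply_maturation,
    mature_from_annotation,
    predict_signal_peptide,
)
from .seqcore import OrfCandidate, ProteinRecord, TranscriptRecord, extract_orfs

__all__ = [
    "FilterConfig",
    "CandidateReport",
    "RejectionRecord",
    "ScreenResult",
    "SubfamilyCall",
    "SubfamilyRule",
    "DEFAULT_SUBFAMILY_RULES",
    "ConsensusResult",
    "PseudogeneCall",
    "screen_transcriptome",
    "classify_subfamily",
    "majority_consensus",
    "screen_pseudogene",
    "characterize",
    "CHARACTERIZE_COLUMNS",
]


# --------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the discovery filter chain.

    The codon bounds are strict (an ORF of exactly ``min_codons`` or
    ``max_codons`` is excluded).  ``filter_mode`` selects between the
    combined Arg+Pro window fraction (default) and requiring either
    residue alone to exceed the threshold.  ``window_region`` applies the
    cationicity windows to the region after the predicted signal cleavage
    (default) or to the whole precursor.
    """

    min_codons: int = 50
    max_codons: int = 120
    require_stop: bool = False
    window: int = 15
    rp_fraction_threshold: float = 0.30
    window_pi_threshold: float = 8.0
    filter_mode: str = "combined_RP"  # or "either_R_or_P"
    window_region: str = "post_signal"  # or "full"
    min_mature: int = 10
    min_tail: int = 5
    mature_length_bounds: tuple[int, int] = (23, 42)
    pi_flag_threshold: float = 11.0
    arg_flag_threshold: float = 0.10

    def __post_init__(self) -> None:
        if self.filter_mode not in ("combined_RP", "either_R_or_P"):
            raise ValueError(f"bad filter_mode {self.filter_mode!r}")
        if self.window_region not in ("post_signal", "full"):
            raise ValueError(f"bad window_region {self.window_region!r}")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        for name in ("rp_fraction_threshold", "window_pi_threshold",
                     "pi_flag_threshold", "arg_flag_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def annotation_config(self) -> AnnotationConfig:
        return AnnotationConfig(min_mature=self.min_mature, min_tail=self.min_tail)


# --------------------------------------------------------------------------
# subfamily classification

Condition = tuple[str, str, float]  # (residue class, operator, threshold)


@dataclass(frozen=True)
class SubfamilyRule:
    """One classifier rule: all ``all_of`` conditions must hold, and at
    least one ``any_of`` condition when that list is non-empty."""

    label: str
    all_of: tuple[Condition, ...]
    any_of: tuple[Condition, ...] = ()


def _evaluate(cond: Condition, profile: physchem.CompositionProfile) -> tuple[bool, float]:
    residues, op, threshold = cond
    value = profile.fraction(residues)
    if op == ">":
        return value > threshold, value
    if op == "<=":
        return value <= threshold, value
    raise ValueError(f"unknown operator {op!r}")


#: Default rule table, evaluated in order with first match winning.
#: A: rich in Arg, Pro and Tyr (>10% each); B: rich in Pro, Arg and Thr
#: (and not Tyr/Trp-rich, which would indicate A or D); D: rich in Pro,
#: Arg and Trp (or Thr); C: rich in Arg but nearly devoid of Pro.
DEFAULT_SUBFAMILY_RULES: tuple[SubfamilyRule, ...] = (
    SubfamilyRule("A", (("R", ">", 0.10), ("P", ">", 0.10), ("Y", ">", 0.10))),
    SubfamilyRule(
        "B",
        (
            ("R", ">", 0.10),
            ("P", ">", 0.10),
            ("T", ">", 0.10),
            ("Y", "<=", 0.10),
            ("W", "<=", 0.05),
        ),
    ),
    SubfamilyRule(
        "D",
        (("R", ">", 0.10), ("P", ">", 0.10)),
        any_of=(("W", ">", 0.05), ("T", ">", 0.10)),
    ),
    SubfamilyRule("C", (("R", ">", 0.10), ("P", "<=", 0.05))),
)


@dataclass(frozen=True)
class SubfamilyCall:
    """A/B/C/D/unclassified label plus the rule-evaluation trace."""

    label: str
    trace: tuple[tuple[str, str, float, bool], ...]
    # trace entries: (rule label, condition repr, observed value, passed)


def classify_subfamily(
    mature: MaturePeptide | str,
    rules: Sequence[SubfamilyRule] = DEFAULT_SUBFAMILY_RULES,
) -> SubfamilyCall:
    """Classify a mature peptide by its composition fractions.

    Rules are tried in table order; the first rule whose predicate holds
    wins, otherwise the peptide is ``unclassified``.  The call depends on
    composition only, so permuting residues never changes the label.
    """
    sequence = mature.sequence if isinstance(mature, MaturePeptide) else mature
    if not sequence:
        raise ValueError("empty mature sequence")
    profile = composition(sequence)
    trace: list[tuple[str, str, float, bool]] = []
    for rule in rules:
        ok = True
        for cond in rule.all_of:
            passed, value = _evaluate(cond, profile)
            trace.append((rule.label, f"{cond[0]}{cond[1]}{cond[2]}", value, passed))
            ok = ok and passed
        if ok and rule.any_of:
            any_ok = False
            for cond in rule.any_of:
                passed, value = _evaluate(cond, profile)
                trace.append(
                    (rule.label, f"any:{cond[0]}{cond[1]}{cond[2]}", value, passed)
                )
                any_ok = any_ok or passed
            ok = any_ok
        if ok:
            return SubfamilyCall(label=rule.label, trace=tuple(trace))
    return SubfamilyCall(label="unclassified", trace=tuple(trace))


def load_subfamily_rules(path: str | Path) -> tuple[SubfamilyRule, ...]:
    """Load a rule table from JSON: a list of objects with keys
    ``label``, ``all_of`` and optional ``any_of``, each condition a
    ``[residues, op, threshold]`` triple."""
    with open(path) as fh:
        raw = json.load(fh)
    rules = []
    for entry in raw:
        rules.append(
            SubfamilyRule(
                label=entry["label"],
                all_of=tuple((c[0], c[1], float(c[2])) for c in entry["all_of"]),
                any_of=tuple((c[0], c[1], float(c[2])) for c in entry.get("any_of", ())),
            )
        )
    return tuple(rules)


# --------------------------------------------------------------------------
# candidate reports and the screening chain

#: Ordered pipeline stages (for rejection accounting).
STAGES = ("length_gate", "signal", "window_filter", "annotation", "passed")


@dataclass(frozen=True)
class RejectionRecord:
    transcript_id: str
    orf: OrfCandidate
    stage: str
    reason: str


@dataclass(frozen=True)
class CandidateReport:
    """One surviving candidate with everything needed to re-derive it."""

    transcript_id: str
    orf: OrfCandidate
    annotation: PrecursorAnnotation
    mature: MaturePeptide
    pi: float
    net_charge_ph7: float
    subfamily: SubfamilyCall
    flags: Mapping[str, bool]


@dataclass(frozen=True)
class ScreenResult:
    candidates: tuple[CandidateReport, ...]
    rejections: tuple[RejectionRecord, ...]
    config: FilterConfig

    @property
    def stage_counts(self) -> Counter:
        counts = Counter(r.stage for r in self.rejections)
        counts["passed"] = len(self.candidates)
        return counts


def compute_flags(mature: MaturePeptide, config: FilterConfig) -> dict[str, bool]:
    """Reporting flags, all recomputable from the mature peptide itself."""
    lo, hi = config.mature_length_bounds
    return {
        "pi_gt_11": isoelectric_point(mature.sequence, amidated=mature.amidated)
        > config.pi_flag_threshold,
        "arg_gt_10pct": composition(mature.sequence).fraction("R")
        > config.arg_flag_threshold,
        "length_in_23_42": lo <= len(mature.sequence) <= hi,
        "amidated": mature.amidated,
    }


def _passes_window_filter(region: str, config: FilterConfig, pka: PkaTable) -> bool:
    if not region:
        return False
    if config.filter_mode == "combined_RP":
        frac_ok = (
            window_scan(region, config.window, "fraction", "RP").max_value
            > config.rp_fraction_threshold
        )
    else:
        frac_ok = any(
            window_scan(region, config.window, "fraction", aa).max_value
            > config.rp_fraction_threshold
            for aa in ("R", "P")
        )
    if frac_ok:
        return True
    pi_max = window_scan(region, config.window, "pi", pka=pka).max_value
    return pi_max > config.window_pi_threshold


def screen_transcriptome(
    transcripts: Iterable[TranscriptRecord],
    config: FilterConfig = FilterConfig(),
    signal_overrides: Optional[Mapping[str, int]] = None,
    rules: Sequence[SubfamilyRule] = DEFAULT_SUBFAMILY_RULES,
    pka: PkaTable = EXPASY_PKA,
) -> ScreenResult:
    """Run the full discovery chain over a set of transcripts.

    Signal overrides are keyed by ``transcript_id|strand|frame|start`` or
    plain transcript id (the specific key wins); this lets externally
    computed cleavage positions be injected per ORF.
    """
    candidates: list[CandidateReport] = []
    rejections: list[RejectionRecord] = []
    overrides = dict(signal_overrides or {})
    for transcript in transcripts:
        orfs = extract_orfs(
            transcript,
            min_codons=config.min_codons,
            max_codons=config.max_codons,
            require_stop=config.require_stop,
        )
        for orf in orfs:
            orf_key = f"{orf.transcript_id}|{orf.strand}|{orf.frame}|{orf.start}"
            key = orf_key if orf_key in overrides else transcript.id
            signal = predict_signal_peptide(
                orf.protein, protein_id=key, overrides=overrides
            )
            if not signal.present:
                rejections.append(
                    RejectionRecord(transcript.id, orf, "signal", "no_signal_peptide")
                )
                continue
            region = (
                orf.protein[signal.cleavage_pos :]
                if config.window_region == "post_signal"
                else orf.protein
            )
            if not _passes_window_filter(region, config, pka):
                rejections.append(
                    RejectionRecord(transcript.id, orf, "window_filter", "not_cationic")
                )
                continue
            record = ProteinRecord(id=orf_key, sequence=orf.protein)
            outcome = annotate_precursor(record, signal, config.annotation_config())
            if isinstance(outcome, Rejection):
                rejections.append(
                    RejectionRecord(transcript.id, orf, "annotation", outcome.reason)
                )
                continue
            mature = mature_from_annotation(outcome)
            candidates.append(
                CandidateReport(
                    transcript_id=transcript.id,
                    orf=orf,
                    annotation=outcome,
                    mature=mature,
                    pi=isoelectric_point(mature.sequence, amidated=mature.amidated, pka=pka),
                    net_charge_ph7=net_charge(
                        mature.sequence, 7.0, amidated=mature.amidated, pka=pka
                    ),
                    subfamily=classify_subfamily(mature, rules),
                    flags=compute_flags(mature, config),
                )
            )
    return ScreenResult(
        candidates=tuple(candidates), rejections=tuple(rejections), config=config
    )


# --------------------------------------------------------------------------
# consensus and pseudogene screening

@dataclass(frozen=True)
class ConsensusResult:
    """50% majority-rule consensus of an alignment.

    Gap-majority columns are dropped; columns whose winning residue falls
    below 50% support are masked with X.  ``column_support`` reports the
    winning fraction for every retained column.
    """

    consensus: str
    column_support: tuple[float, ...]
    n_sequences: int
    tied_columns: tuple[int, ...] = ()


def majority_consensus(aligned: Sequence[str]) -> ConsensusResult:
    """Column-wise 50% majority-rule consensus (ties broken alphabetically)."""
    if len(aligned) < 2:
        raise ValueError("consensus needs at least 2 sequences")
    lengths = {len(s) for s in aligned}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
    n = len(aligned)
    consensus: list[str] = []
    support: list[float] = []
    ties: list[int] = []
    for col in range(lengths.pop()):
        counts = Counter(s[col].upper() for s in aligned)
        best = max(counts.values())
        winners = sorted(sym for sym, c in counts.items() if c == best)
        if len(winners) > 1:
            ties.append(col)
        winner = winners[0]  # '-' sorts before letters
        frac = best / n
        if winner == "-" and frac >= 0.5:
            continue  # gap-majority column dropped
        if winner == "-" or frac < 0.5:
            consensus.append("X")
        else:
            consensus.append(winner)
        support.append(frac)
    return ConsensusResult(
        consensus="".join(consensus),
        column_support=tuple(support),
        n_sequences=n,
        tied_columns=tuple(ties),
    )


@dataclass(frozen=True)
class PseudogeneCall:
    id: str
    internal_stop_count: int

    @property
    def verdict(self) -> str:
        return "pseudogene" if self.internal_stop_count >= 1 else "functional"


def screen_pseudogene(protein: ProteinRecord) -> PseudogeneCall:
    """Count in-frame stops ('*') before the final position."""
    internal = protein.sequence[:-1].count("*")
    return PseudogeneCall(id=protein.id, internal_stop_count=internal)


# --------------------------------------------------------------------------
# characterization report (also used by the CLI)

CHARACTERIZE_COLUMNS = [
    "id",
    "length",
    "pI",
    "net_charge_pH7",
    "frac_R",
    "frac_P",
    "frac_Y",
    "frac_W",
    "frac_T",
    "frac_DE",
    "amidated",
]


def characterize(
    proteins: Iterable[ProteinRecord], pka: PkaTable = EXPASY_PKA
) -> pd.DataFrame:
    """Per-peptide physicochemistry table.

    Composition columns hold percentages truncated (floored) to one
    decimal, matching how integer-percent figures are conventionally
    quoted; pI and net charge are kept at full precision.  Virtual
    peptides containing in-frame stops ('*') have no defined chemistry
    and are skipped with a warning.
    """
    import logging

    rows = []
    for rec in proteins:
        if "*" in rec.sequence:
            logging.getLogger(__name__).warning(
                "skipping %s: contains in-frame stops", rec.id
            )
            continue
        prof = composition(rec.sequence)
        rows.append(
            {
                "id": rec.id,
                "length": len(rec.sequence),
                "pI": isoelectric_point(rec.sequence, amidated=rec.amidated, pka=pka),
                "net_charge_pH7": net_charge(
                    rec.sequence, 7.0, amidated=rec.amidated, pka=pka
                ),
                "frac_R": floor_percent(prof.fraction("R"), 1),
                "frac_P": floor_percent(prof.fraction("P"), 1),
                "frac_Y": floor_percent(prof.fraction("Y"), 1),
                "frac_W": floor_percent(prof.fraction("W"), 1),
                "frac_T": floor_percent(prof.fraction("T"), 1),
                "frac_DE": floor_percent(prof.fraction("DE"), 1),
                "amidated": rec.amidated,
            }
        )
    return pd.DataFrame(rows, columns=CHARACTERIZE_COLUMNS)
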