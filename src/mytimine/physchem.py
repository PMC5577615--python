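"""Peptide physicochemistry.

Composition fractions, Henderson–Hasselbalch net charge, isoelectric point
by bisection, and the sliding-window scans used by the discovery filter.

The net charge of a peptide at a given pH sums the fractional protonation
of every ionizable group::

    Z(pH) =  sum_basic  1 / (1 + 10**(pH - pKa))
           - sum_acidic 1 / (1 + 10**(pKa - pH))

Basic groups: the free N-terminus (optional), K, R, H side chains.
Acidic groups: the free C-terminus (optional; suppressed by C-terminal
amidation), D, E, C, Y side chains.  The isoelectric point is the unique
root of Z, found by bisection (Z is strictly decreasing in pH).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, NamedTuple

from .seqcore import AMINO_ACIDS

__all__ = [
    "PkaTable",
    "EXPASY_PKA",
    "CompositionProfile",
    "WindowScan",
    "composition",
    "net_charge",
    "isoelectric_point",
    "window_scan",
    "floor_percent",
    "KYTE_DOOLITTLE",
    "PI_ALWAYS_POSITIVE",
    "PI_ALWAYS_NEGATIVE",
]

BASIC_RESIDUES = "KRH"
ACIDIC_RESIDUES = "DECY"

#: Kyte–Doolittle hydropathy index (used by the signal-peptide heuristic).
KYTE_DOOLITTLE: Mapping[str, float] = MappingProxyType(
    {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
        "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
        "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
        "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    }
)

#: Sentinels for peptides whose net charge never crosses zero under the
#: chosen settings (e.g. an amidated peptide with no acidic side chain).
PI_ALWAYS_POSITIVE = 14.0
PI_ALWAYS_NEGATIVE = 0.0


@dataclass(frozen=True)
class PkaTable:
    """An immutable set of pKa values for the ionizable groups.

    ``n_terminus`` is residue-independent (a single default value), as is
    ``c_terminus``.  Side-chain entries are required for D, E, H, C, Y, K, R.
    """

    name: str
    side_chain: Mapping[str, float]
    n_terminus: float
    c_terminus: float

    def __post_init__(self) -> None:
        required = set("DEHCYKR")
        missing = required - set(self.side_chain)
        if missing:
            raise ValueError(f"pKa table {self.name!r} missing {sorted(missing)}")
        values = list(self.side_chain.values()) + [self.n_terminus, self.c_terminus]
        if not all(0.0 < v < 14.0 for v in values):
            raise ValueError("all pKa values must lie in (0, 14)")
        object.__setattr__(self, "side_chain", MappingProxyType(dict(self.side_chain)))

    @classmethod
    def from_dict(cls, data: Mapping) -> "PkaTable":
        return cls(
            name=data.get("name", "custom"),
            side_chain=dict(data["side_chain"]),
            n_terminus=float(data["n_terminus"]),
            c_terminus=float(data["c_terminus"]),
        )


#: Bjellqvist-style values as used by the ExPASy Compute pI tool.
EXPASY_PKA = PkaTable(
    name="expasy",
    side_chain={
        "D": 4.05, "E": 4.45, "H": 5.98, "C": 9.00,
        "Y": 10.00, "K": 10.00, "R": 12.00,
    },
    n_terminus=7.50,
    c_terminus=3.55,
)


@dataclass(frozen=True)
class CompositionProfile:
    """Residue counts and fractions over the full sequence length.

    ``X`` (and any unknown letter) counts toward ``length`` but toward no
    named residue, so fractions sum to <= 1 with equality iff no X present.
    """

    counts: Mapping[str, int]
    length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", MappingProxyType(dict(self.counts)))

    @property
    def fractions(self) -> dict[str, float]:
        return {aa: self.counts.get(aa, 0) / self.length for aa in AMINO_ACIDS}

    def fraction(self, residues: str) -> float:
        """Summed fraction of a residue class, e.g. ``"RP"`` or ``"DE"``."""
        return sum(self.counts.get(aa, 0) for aa in residues) / self.length


def composition(peptide: str) -> CompositionProfile:
    """Count residues; unknown letters (X) dilute every fraction."""
    if not peptide:
        raise ValueError("empty sequence")
    counts = {aa: peptide.count(aa) for aa in AMINO_ACIDS if aa in peptide}
    return CompositionProfile(counts=counts, length=len(peptide))


def floor_percent(fraction: float, decimals: int = 0) -> float:
    """Percentage truncated (floored) to the given number of decimals."""
    scale = 10 ** decimals
    return math.floor(fraction * 100 * scale) / scale


def _ionizable_groups(
    peptide: str, amidated: bool, include_termini: bool, pka: PkaTable
) -> tuple[list[float], list[float]]:
    """Return (basic pKas, acidic pKas) for a peptide under the settings."""
    basic: list[float] = []
    acidic: list[float] = []
    if include_termini:
        basic.append(pka.n_terminus)
        if not amidated:
            acidic.append(pka.c_terminus)
    for aa in peptide:
        if aa in BASIC_RESIDUES:
            basic.append(pka.side_chain[aa])
        elif aa in ACIDIC_RESIDUES:
            acidic.append(pka.side_chain[aa])
        elif aa not in AMINO_ACIDS and aa != "X":
            raise ValueError(f"unknown residue {aa!r}")
    return basic, acidic


def net_charge(
    peptide: str,
    ph: float = 7.0,
    amidated: bool = False,
    include_termini: bool = True,
    pka: PkaTable = EXPASY_PKA,
) -> float:
    """Henderson–Hasselbalch net charge at the given pH.

    ``amidated`` removes the C-terminal carboxylate from the acidic sum;
    ``include_termini=False`` treats the peptide as an internal fragment
    (side chains only).  ``X`` contributes nothing.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH {ph} outside [0, 14]")
    basic, acidic = _ionizable_groups(peptide, amidated, include_termini, pka)
    z = sum(1.0 / (1.0 + 10 ** (ph - k)) for k in basic)
    z -= sum(1.0 / (1.0 + 10 ** (k - ph)) for k in acidic)
    return z


class PiResult(NamedTuple):
    value: float
    defined: bool


def isoelectric_point(
    peptide: str,
    amidated: bool = False,
    include_termini: bool = True,
    pka: PkaTable = EXPASY_PKA,
    return_flag: bool = False,
):
    """Isoelectric point by bisection of the net-charge curve on [0, 14].

    Requires at least one basic and one acidic group; otherwise the charge
    never crosses zero and a sentinel is returned (14.0 when always
    positive, 0.0 when always negative), flagged as undefined when
    ``return_flag`` is set.
    """
    basic, acidic = _ionizable_groups(peptide, amidated, include_termini, pka)
    if not acidic and not basic:
        raise ValueError("peptide has no ionizable groups")
    if not acidic:
        result = PiResult(PI_ALWAYS_POSITIVE, False)
        return result if return_flag else result.value
    if not basic:
        result = PiResult(PI_ALWAYS_NEGATIVE, False)
        return result if return_flag else result.value
    lo, hi = 0.0, 14.0
    # bisect well past 0.001 interval width so |Z| < 1e-3 holds even for
    # long, charge-dense peptides (|dZ/dpH| grows with group count)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if net_charge(peptide, mid, amidated, include_termini, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    result = PiResult(0.5 * (lo + hi), True)
    return result if return_flag else result.value


@dataclass(frozen=True)
class WindowScan:
    """Per-window statistics aligned to window start positions."""

    window: int
    values: tuple[float, ...]
    statistic: str

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("window scan produced no values")

    @property
    def max_value(self) -> float:
        return max(self.values)

    @property
    def argmax_start(self) -> int:
        return max(range(len(self.values)), key=lambda i: self.values[i])


def window_scan(
    peptide: str,
    window: int = 15,
    statistic: str = "fraction",
    residues: str = "RP",
    pka: PkaTable = EXPASY_PKA,
) -> WindowScan:
    """Slide a window and compute a per-window statistic.

    ``statistic="fraction"``: summed fraction of the residue class (e.g.
    ``"RP"``) per window.  ``statistic="pi"``: side-chain-only isoelectric
    point per window (windows are internal fragments, so termini are
    excluded); windows with no zero-crossing score the sentinel.

    A sequence shorter than the window yields a single window covering the
    whole sequence.
    """
    if not peptide:
        raise ValueError("empty sequence")
    if window < 1:
        raise ValueError("window must be >= 1")
    if statistic not in ("fraction", "pi"):
        raise ValueError(f"unknown statistic {statistic!r}")
    spans = (
        [peptide]
        if len(peptide) < window
        else [peptide[i : i + window] for i in range(len(peptide) - window + 1)]
    )
    if statistic == "fraction":
        values = tuple(composition(s).fraction(residues) for s in spans)
    else:
        values = tuple(_window_pi(s, pka) for s in spans)
    return WindowScan(window=window, values=values, statistic=statistic)


def _window_pi(span: str, pka: PkaTable) -> float:
    """Side-chain pI of a window; a window with no ionizable side chain at
    all is scored with the always-negative sentinel (it is not cationic)."""
    basic, acidic = _ionizable_groups(span, False, False, pka)
    if not basic:
        return PI_ALWAYS_NEGATIVE
    if not acidic:
        return PI_ALWAYS_POSITIVE
    return isoelectric_point(span, include_termini=False, pka=pka)
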