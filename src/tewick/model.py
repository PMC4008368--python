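"""Domain model: the Wicker TE taxonomy and the final classification record.

The taxonomy covers the twelve order-level TE categories of the Wicker
hierarchy that this tool can assign — nine autonomous orders (five class I
retrotransposon orders: LTR, DIRS, PLE, LINE, SINE; four class II DNA
transposon orders: TIR, Crypton, Helitron, Maverick) plus three
non-autonomous derivative categories (LARD, TRIM, MITE) — and three filter
categories used to flag repeats that are not TEs at all (SSR, rDNA,
HostGene).  Cross-scheme mappings onto the coarser TEclass and REPCLASS
vocabularies are provided for tool comparison.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .errors import ConfigError


class TEClass(str, Enum):
    I = "I"
    II = "II"
    NON_TE = "nonTE"


class Order(str, Enum):
    LTR = "LTR"
    DIRS = "DIRS"
    PLE = "PLE"
    LINE = "LINE"
    SINE = "SINE"
    LARD = "LARD"
    TRIM = "TRIM"
    TIR = "TIR"
    MITE = "MITE"
    CRYPTON = "Crypton"
    HELITRON = "Helitron"
    MAVERICK = "Maverick"
    SSR = "SSR"
    RDNA = "rDNA"
    HOST_GENE = "HostGene"
    UNKNOWN = "Unknown"


@dataclass(frozen=True)
class CategoryLabel:
    """One cell of the taxonomy: class, order and autonomy flag.

    ``te_class`` is ``None`` only for the Unknown order, which deliberately
    carries no class commitment.
    """

    te_class: Optional[TEClass]
    order: Order
    autonomous: bool = True


# Class I retrotransposon orders; LARD and TRIM are non-autonomous derivatives.
_CLASS_I = (
    (Order.LTR, True),
    (Order.DIRS, True),
    (Order.PLE, True),
    (Order.LARD, False),
    (Order.TRIM, False),
    (Order.LINE, True),
    (Order.SINE, True),
)
# Class II DNA transposon orders; MITE is the non-autonomous derivative.
_CLASS_II = (
    (Order.TIR, True),
    (Order.MITE, False),
    (Order.CRYPTON, True),
    (Order.HELITRON, True),
    (Order.MAVERICK, True),
)
_NON_TE = (Order.SSR, Order.RDNA, Order.HOST_GENE)

TAXONOMY: dict[Order, CategoryLabel] = {}
for _order, _auto in _CLASS_I:
    TAXONOMY[_order] = CategoryLabel(TEClass.I, _order, _auto)
for _order, _auto in _CLASS_II:
    TAXONOMY[_order] = CategoryLabel(TEClass.II, _order, _auto)
for _order in _NON_TE:
    TAXONOMY[_order] = CategoryLabel(TEClass.NON_TE, _order, False)
TAXONOMY[Order.UNKNOWN] = CategoryLabel(None, Order.UNKNOWN, False)

#: The twelve order-level TE categories that can be scored.
TE_ORDERS: tuple[Order, ...] = tuple(o for o, _ in _CLASS_I) + tuple(o for o, _ in _CLASS_II)
#: Categories used only to filter out non-TE repeats.
FILTER_ORDERS: tuple[Order, ...] = _NON_TE

UNKNOWN_LABEL = TAXONOMY[Order.UNKNOWN]

# Order-level cells of the cross-tool comparison table.  "na" marks orders
# the other scheme does not consider at all.
_TECLASS_MAP: dict[Order, str] = {
    Order.LTR: "LTR",
    Order.DIRS: "LTR",
    Order.PLE: "LINE",
    Order.LARD: "na",
    Order.TRIM: "na",
    Order.LINE: "LINE",
    Order.SINE: "SINE",
    Order.TIR: "DNA",
    Order.MITE: "DNA",
    Order.CRYPTON: "na",
    Order.HELITRON: "na",
    Order.MAVERICK: "na",
}
_REPCLASS_MAP: dict[Order, str] = {
    Order.LTR: "LTR/DIRS/PLE",
    Order.DIRS: "LTR/DIRS/PLE",
    Order.PLE: "LTR/DIRS/PLE",
    Order.LARD: "na",
    Order.TRIM: "na",
    Order.LINE: "LINE/SINE",
    Order.SINE: "LINE/SINE",
    Order.TIR: "TIR/Crypton/Polinton",
    Order.MITE: "TIR/Crypton/Polinton",
    Order.CRYPTON: "TIR/Crypton/Polinton",
    Order.HELITRON: "Helitron",
    Order.MAVERICK: "TIR/Crypton/Polinton",
}
_SCHEMES = {"TECLASS": _TECLASS_MAP, "REPCLASS": _REPCLASS_MAP}


def map_label(label: CategoryLabel, scheme: str) -> str:
    """Map a TE category onto the order vocabulary of a coarser scheme.

    Parameters
    ----------
    label:
        A TE category (filter categories are not mappable).
    scheme:
        ``"TEclass"`` or ``"REPCLASS"`` (case-insensitive).

    Returns
    -------
    str
        The target scheme's order-level name, or ``"na"`` when that scheme
        does not consider the order.
    """
    table = _SCHEMES.get(scheme.upper())
    if table is None:
        raise ConfigError(f"unknown classification scheme: {scheme!r}")
    if label.order not in table:
        raise ValueError(f"{label.order.value} is not a mappable TE category")
    return table[label.order]


_VALID_DNA = set("ACGTN")


@dataclass
class TEConsensus:
    """One input consensus sequence: identifier plus uppercase DNA."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"consensus id must be a non-empty token, got {self.id!r}")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _VALID_DNA
        if bad:
            raise ValueError(f"{self.id}: non-ACGTN residues {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


class Status(str, Enum):
    OK = "OK"
    POTENTIAL_CHIMERIC = "PotentialChimeric"


@dataclass
class ClassificationRecord:
    """Final per-consensus verdict, one output row.

    ``te_class`` and ``order`` are strings so that undecided calls can carry
    pipe-joined candidate lists (e.g. ``"Helitron|LARD"``); for such calls the
    confidence is that of the best candidate.
    """

    te_id: str
    length: int
    orientation: str  # "+", "-" or "." (undetermined)
    status: Status
    te_class: str
    order: str
    completeness: str  # "complete" | "incomplete"
    confidence: int
    evidence_summary: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.confidence <= 100:
            raise ValueError(f"{self.te_id}: confidence {self.confidence} outside [0,100]")
        if self.orientation not in ("+", "-", "."):
            raise ValueError(f"{self.te_id}: bad orientation {self.orientation!r}")
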