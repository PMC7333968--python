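"""Fatty-acid nomenclature: parsing, canonicalization, and classification.

Fatty acids (FA) are named ``C:D`` with chain length ``C`` (carbons) and the
number of double bonds ``D``; for unsaturated FA the position of the first
double bond counted from the methyl end is appended in omega notation
(``20:5w3``), and branched-chain FA carry an ``i`` (iso) or ``ai`` (anteiso)
prefix (``i15:0``).  Every downstream biomarker sum is computed from this
parsed structure rather than from string matching, so dialect variants
("22:6ω3", "22:6w3", "22:6n-3") all resolve to the same object.

Classification partitions FA into saturated (SFA), monounsaturated (MUFA),
polyunsaturated (PUFA), and odd-length/branched-chain (OBCFA) classes.  OBCFA
takes precedence: an odd chain or a branch puts an FA in the bacterial-marker
class regardless of unsaturation, and a per-label override registry handles
conventional exceptions such as 18:1w7, which is treated as a bacterial
marker rather than a plain MUFA.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping


class Branching(str, Enum):
    STRAIGHT = "straight"
    ISO = "iso"
    ANTEISO = "anteiso"
    OTHER_BRANCHED = "other_branched"


class FAClass(str, Enum):
    SFA = "SFA"
    MUFA = "MUFA"
    PUFA = "PUFA"
    OBCFA = "OBCFA"


_BRANCH_PREFIX = {"": Branching.STRAIGHT, "i": Branching.ISO, "ai": Branching.ANTEISO,
                  "a": Branching.ANTEISO, "br": Branching.OTHER_BRANCHED}
_PREFIX_FOR_BRANCH = {Branching.STRAIGHT: "", Branching.ISO: "i",
                      Branching.ANTEISO: "ai", Branching.OTHER_BRANCHED: "br"}

# grammar: [i|ai|br] C : D [w|ω|n- N]; whitespace tolerated around tokens;
# "a" accepted as a shorthand dialect for anteiso
_LABEL_RE = re.compile(
    r"""^\s*
        (?P<prefix>ai|a|i|br)?\s*-?\s*
        (?P<chain>\d{1,2})\s*:\s*(?P<dbonds>\d{1,2})
        (?:\s*(?:w|W|ω|Ω|n\s*[-−‐–])\s*(?P<omega>\d{1,2}))?
        \s*$""",
    re.VERBOSE,
)


class FAParseError(ValueError):
    """Raised when a fatty-acid label does not match the grammar."""


@dataclass(frozen=True)
class FattyAcid:
    """A parsed fatty acid.

    Attributes
    ----------
    chain_length : int
        Number of carbons (4–30).
    n_double_bonds : int
        Number of double bonds (0 for saturated FA).
    omega : int or None
        Position of the first double bond from the methyl end; ``None`` for
        saturated FA and for unsaturated FA whose omega position was not
        given in the label (see :attr:`omega_unknown`).
    branching : Branching
        Straight-chain, iso-, anteiso-, or other-branched.
    """

    chain_length: int
    n_double_bonds: int
    omega: int | None = None
    branching: Branching = Branching.STRAIGHT

    def __post_init__(self) -> None:
        if not (4 <= self.chain_length <= 30):
            raise FAParseError(
                f"chain length {self.chain_length} outside the supported 4-30 range"
            )
        if self.n_double_bonds < 0:
            raise FAParseError("negative double-bond count")
        if self.n_double_bonds == 0 and self.omega is not None:
            raise FAParseError("saturated FA cannot carry an omega position")
        if self.omega is not None and not (1 <= self.omega < self.chain_length):
            raise FAParseError(f"omega position {self.omega} impossible for C{self.chain_length}")

    @property
    def omega_unknown(self) -> bool:
        """True for unsaturated FA whose label gave no omega position."""
        return self.n_double_bonds > 0 and self.omega is None

    @property
    def label(self) -> str:
        """Canonical ASCII label, e.g. ``22:6w3``, ``i15:0``."""
        s = f"{_PREFIX_FOR_BRANCH[self.branching]}{self.chain_length}:{self.n_double_bonds}"
        if self.omega is not None:
            s += f"w{self.omega}"
        return s

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_fa_label(label: str) -> FattyAcid:
    """Parse an FA label in any supported dialect into a :class:`FattyAcid`.

    Accepts omega written as ``w``, ``ω`` or ``n-`` and tolerates internal
    whitespace (``"22 : 6ω3"``).  An unsaturated FA without an omega position
    parses successfully but is flagged ``omega_unknown``.

    Raises
    ------
    FAParseError
        If the label does not match the ``[prefix]C:D[wN]`` grammar.
    """
    if not isinstance(label, str):
        raise FAParseError(f"expected a string label, got {type(label).__name__}")
    m = _LABEL_RE.match(label)
    if m is None:
        raise FAParseError(f"malformed fatty-acid label: {label!r}")
    chain = int(m.group("chain"))
    dbonds = int(m.group("dbonds"))
    omega = m.group("omega")
    if dbonds == 0 and omega is not None:
        raise FAParseError(f"saturated FA with omega position: {label!r}")
    branching = _BRANCH_PREFIX[(m.group("prefix") or "").lower()]
    return FattyAcid(
        chain_length=chain,
        n_double_bonds=dbonds,
        omega=int(omega) if omega is not None else None,
        branching=branching,
    )


def canonical_label(label: str) -> str:
    """Canonicalize a label string (any dialect) to the ASCII ``w`` form."""
    return parse_fa_label(label).label


#: Labels whose class membership overrides the structural rule.  18:1w7 is
#: conventionally counted with the bacterial odd/branched-chain markers.
DEFAULT_CLASS_OVERRIDES: Mapping[str, FAClass] = {"18:1w7": FAClass.OBCFA}


def load_class_overrides(path: str | Path) -> dict[str, FAClass]:
    """Read a two-column CSV (label, class_override) of classification exceptions."""
    overrides: dict[str, FAClass] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            overrides[canonical_label(row["label"])] = FAClass(row["class_override"].strip())
    return overrides


def classify(
    fa: FattyAcid | str,
    overrides: Mapping[str, FAClass] = DEFAULT_CLASS_OVERRIDES,
) -> FAClass:
    """Assign an FA to exactly one of SFA / MUFA / PUFA / OBCFA.

    OBCFA (odd chain length or any branching, plus registry exceptions)
    takes precedence over the unsaturation-based classes.
    """
    if isinstance(fa, str):
        fa = parse_fa_label(fa)
    if fa.label in overrides:
        return overrides[fa.label]
    if fa.chain_length % 2 == 1 or fa.branching is not Branching.STRAIGHT:
        return FAClass.OBCFA
    if fa.n_double_bonds == 0:
        return FAClass.SFA
    if fa.n_double_bonds == 1:
        return FAClass.MUFA
    return FAClass.PUFA


def is_lcpufa(fa: FattyAcid | str) -> bool:
    """True for long-chain (>=C20) polyunsaturated FA such as EPA and DHA."""
    if isinstance(fa, str):
        fa = parse_fa_label(fa)
    return fa.chain_length >= 20 and fa.n_double_bonds >= 2


def canonicalize_labels(labels: Iterable[str]) -> list[str]:
    """Canonicalize a sequence of labels, preserving order."""
    return [canonical_label(lab) for lab in labels]
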