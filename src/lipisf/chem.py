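"""Molecular formulas, monoisotopic masses and ion-transform arithmetic.

Ion m/z values are computed from signed element compositions (what the
transform gains and loses relative to the neutral molecule) plus an explicit
charge-carrier rule that adds or removes one proton mass. The electron mass
is neglected throughout (< 0.6 mDa, below the 2-decimal reporting precision
and typical ppm tolerances of Orbitrap-class MSI data).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

#: IUPAC monoisotopic masses (Da) of the elements that occur in lipids and
#: in the bundled ion transforms, plus the implausible-element pool used for
#: decoy construction.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376200,
    "S": 31.97207100,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885268,
    # decoy pool: elements essentially absent from biological lipids
    "B": 11.00930536,
    "Si": 27.97692653,
    "Sc": 44.95591190,
    "Ti": 47.94794630,
    "Mn": 54.93804510,
}

#: Mass of a proton (Da); added on protonation, removed on deprotonation.
PROTON_MASS = 1.00727646

#: Average spacing of heavy-isotope satellites (Da), the C13-C12 difference.
ISOTOPE_SPACING = 1.0033548

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formulas or unknown element symbols."""


@dataclass(frozen=True)
class ElementComposition:
    """An element → count map representing a molecular formula.

    Counts are non-negative; elements absent from the map have count 0.
    The Hill-notation string form (C first, H second, the rest
    alphabetically) round-trips through :func:`parse_formula`.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {el: int(n) for el, n in self.counts.items() if n != 0}
        for el, n in clean.items():
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}: {n}")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementComposition(merged)

    def hill(self) -> str:
        """Hill-notation string (carbon, hydrogen, then alphabetical)."""
        parts = []
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> ElementComposition:
    """Parse a Hill-notation molecular formula such as ``"C47H85O13P"``.

    Raises :class:`FormulaError` on empty input, unknown element symbols or
    stray characters, naming the offending token.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"unparseable fragment {text[pos:m.start()]!r} in {text!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(text):
        raise FormulaError(f"unparseable fragment {text[pos:]!r} in {text!r}")
    return ElementComposition(counts)


def monoisotopic_mass(comp: ElementComposition) -> float:
    """Monoisotopic mass (Da): sum of tabulated element masses; additive."""
    try:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in comp.counts.items())
    except KeyError as exc:  # pragma: no cover - guarded by parse_formula
        raise FormulaError(f"no tabulated mass for element {exc.args[0]!r}") from exc


#: charge-carrier rules → proton-mass adjustment applied to the neutral shift
CHARGE_CARRIERS = {
    "protonation": +PROTON_MASS,
    "deprotonation": -PROTON_MASS,
    "cation_exchange": 0.0,       # e.g. [M+Na]+, [M+Na-2H]-: atoms in delta
    "anion_attachment": 0.0,      # e.g. [M+Cl]-
    "neutral_loss_anion": 0.0,    # e.g. [M-CH3]-: homolytic loss leaves anion
    "none": 0.0,
}


@dataclass(frozen=True)
class IonTransform:
    """A named mass transformation of a neutral lipid.

    ``gain`` and ``loss`` are element compositions applied to the neutral
    molecule; ``charge_carrier`` selects whether one proton mass is added,
    removed or left untouched. ``plausible=False`` marks decoy transforms.
    """

    name: str
    polarity: str  # "positive" | "negative"
    kind: str      # "adduct" | "fragment"
    gain: ElementComposition = field(default_factory=ElementComposition)
    loss: ElementComposition = field(default_factory=ElementComposition)
    charge_carrier: str = "none"
    plausible: bool = True

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if self.kind not in ("adduct", "fragment"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.charge_carrier not in CHARGE_CARRIERS:
            raise ValueError(f"unknown charge carrier {self.charge_carrier!r}")
        if self.polarity == "negative" and self.charge_carrier == "protonation":
            raise ValueError(
                f"{self.name}: negative-mode transform cannot add a proton")
        if self.polarity == "positive" and self.charge_carrier == "deprotonation":
            raise ValueError(
                f"{self.name}: positive-mode transform cannot remove a proton")

    def mass_shift(self) -> float:
        """Signed m/z shift (Da) relative to the neutral monoisotopic mass."""
        return (
            monoisotopic_mass(self.gain)
            - monoisotopic_mass(self.loss)
            + CHARGE_CARRIERS[self.charge_carrier]
        )


def ion_mz(neutral_mass: float, transform: IonTransform) -> float:
    """m/z of a singly charged ion: neutral mass plus the transform shift."""
    return neutral_mass + transform.mass_shift()


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    return 1e6 * (observed - theoretical) / theoretical
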