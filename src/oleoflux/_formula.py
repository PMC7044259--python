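"""Hill-notation chemical formulas and molar masses."""

from __future__ import annotations

import re

# Standard atomic weights (g/mol), 2021 IUPAC abridged values.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "K": 39.098,
    "Na": 22.990,
    "Mg": 24.305,
    "Fe": 55.845,
    "Ca": 40.078,
    "Cl": 35.45,
}

#: element symbols accepted by the parser; anything else (e.g. a metabolite id
#: mistaken for a formula) is rejected rather than guessed
KNOWN_ELEMENTS = frozenset(ATOMIC_MASS) | frozenset(
    "B F Si V Cr Mn Co Ni Cu Zn Se Br Mo I W".split()
)

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int] | None:
    """Parse a Hill-notation formula string into an element -> count map.

    Returns ``None`` when the string is not a plain element/count sequence
    (charges, dots, parentheses, isotopes are all rejected, never guessed).
    An empty string parses to an empty map: a legitimate carbon-free
    pseudo-species such as a redox or energy carrier.
    """
    if formula is None:
        return None
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            return None
        element, digits = m.groups()
        if element not in KNOWN_ELEMENTS:
            return None
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(formula):
        return None
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Render an element map as a Hill-notation string (C, H, then alphabetic)."""
    order = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(
        f"{e}{counts[e]}" if counts[e] != 1 else e for e in order if counts[e]
    )


def molar_mass(counts: dict[str, int]) -> float:
    """Molar mass in g/mol of an element-count map."""
    try:
        return sum(ATOMIC_MASS[e] * n for e, n in counts.items())
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"no atomic mass tabulated for element {exc}") from exc
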