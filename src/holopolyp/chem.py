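"""Molecular formulas, monoisotopic masses, adduct m/z, and ppm errors.

High-resolution LC-MS work constantly round-trips between a molecular
formula, its neutral monoisotopic mass, and the m/z actually observed for
an ionized adduct.  This module provides those three primitives so that
formula/mass pairs reported for features (e.g. an observed positive-mode
m/z against a proposed elemental composition) can be checked to ppm
accuracy.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Dict, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
]

# Monoisotopic atomic masses in Da (most abundant isotope), IUPAC/CODATA
# tabulated values truncated to ~7 decimals.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885271,
    "F": 18.99840322,
    "Br": 78.9183376,
    "I": 126.904473,
    "Se": 79.9165218,
    "Si": 27.9769265327,
}

#: Mass of a proton in Da; the [M+H]+ shift.
PROTON_MASS = 1.007276466

# Registry of supported adducts: name -> (multiplier on M, mass shift, charge).
_ADDUCTS: Dict[str, tuple] = {
    "[M+H]+": (1, PROTON_MASS, 1),
    "M+H": (1, PROTON_MASS, 1),
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a molecular formula string into an element -> count mapping.

    Accepts plain Hill-style strings like ``"C25H35O3N3S"``.  Counts default
    to 1; repeated element symbols accumulate.  Raises ``ValueError`` for an
    empty string, an unknown element symbol, or trailing garbage.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise ValueError("empty molecular formula")
    s = formula.strip()
    counts: Counter = Counter()
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {element!r} in {formula!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise ValueError(f"non-positive count for {element} in {formula!r}")
        counts[element] += n
        pos = m.end()
    return dict(counts)


def format_formula(counts: Mapping[str, int]) -> str:
    """Render an element-count mapping in Hill order (C, H, then alphabetical)."""
    counts = {k: v for k, v in counts.items() if v}
    parts = []
    for el in ("C", "H"):
        if el in counts:
            n = counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
    for el in sorted(k for k in counts if k not in ("C", "H")):
        n = counts[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Neutral monoisotopic mass in Da of a formula string or count mapping."""
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    if not counts:
        raise ValueError("empty molecular formula")
    mass = 0.0
    for element, n in counts.items():
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {element!r}")
        mass += n * MONOISOTOPIC_MASS[element]
    return mass


def adduct_mz(neutral_mass: float, adduct: str = "[M+H]+") -> float:
    """m/z of an adduct ion formed from a neutral of the given mass.

    Only protonation (positive mode) is registered by default.
    """
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if adduct not in _ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct!r}; known: {sorted(_ADDUCTS)}")
    mult, shift, charge = _ADDUCTS[adduct]
    return (mult * neutral_mass + shift) / charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical
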