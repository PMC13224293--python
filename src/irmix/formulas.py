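"""Molecular formulas in Hill notation and formula-level misidentification classes.

Misidentified components in spectral deconvolution cluster into a few
chemically interpretable classes: structural isomers (identical formula,
different connectivity), single-atom substitutions (one element swapped for
another, e.g. Cl for Br), and homologue confusion (one more or one fewer
carbon).  These are decided here purely at the formula level; connectivity
is out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .exceptions import FormulaParseError

__all__ = [
    "MolecularFormula",
    "parse_formula",
    "classify_misidentification",
    "CATEGORIES",
]

# All IUPAC element symbols, for parse validation.
ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn "
    "Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I Xe Cs Ba La "
    "Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt Au Hg Tl Pb Bi Po "
    "At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg "
    "Cn Nh Fl Mc Lv Ts Og".split()
)

#: Misidentification categories, in reporting order.
CATEGORIES = ("isomer", "substitution", "carbon_difference", "mixed", "other")

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element → atom count mapping with Hill-notation rendering."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "MolecularFormula":
        for sym, n in d.items():
            if sym not in ELEMENTS:
                raise FormulaParseError(f"unknown element symbol {sym!r}")
            if n < 1:
                raise FormulaParseError(f"count for {sym} must be >= 1, got {n}")
        return cls(tuple(sorted(d.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def elements(self) -> frozenset[str]:
        return frozenset(sym for sym, _ in self.counts)

    def hill(self) -> str:
        """Canonical Hill string: C, then H, then other elements alphabetically
        (all alphabetical when no carbon is present)."""
        d = self.as_dict()
        parts: list[str] = []
        if "C" in d:
            order = ["C"] + (["H"] if "H" in d else []) + sorted(k for k in d if k not in ("C", "H"))
        else:
            order = sorted(d)
        for sym in order:
            n = d[sym]
            parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation molecular formula such as ``"C6H13N3"``.

    Implicit counts of 1 are allowed (``"CH4"``).  Repeated element symbols
    are summed.  Raises :class:`FormulaParseError` on unknown symbols or
    malformed input; parentheses and isotopes are not supported.
    """
    if not text or not text.strip():
        raise FormulaParseError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaParseError(f"malformed formula {text!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        if sym not in ELEMENTS:
            raise FormulaParseError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaParseError(f"zero count for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return MolecularFormula.from_dict(counts)


def classify_misidentification(
    true_f: MolecularFormula,
    pred_f: MolecularFormula,
    h_tolerance: int = 0,
) -> str:
    """Classify a (true, falsely-predicted) formula pair.

    Returns one of ``"isomer"`` (identical formulas), ``"substitution"``
    (exactly one atom of one element replaced by one atom of another),
    ``"carbon_difference"`` (only the carbon count differs, by exactly one),
    or ``"other"``.  The ``"mixed"`` label applies at the mixture level, when
    a mixture's true–false pairs span two or more of the named categories,
    and is never returned here.  All three decisions are symmetric in the
    argument order.

    ``h_tolerance`` relaxes the literal one-carbon rule to also admit a
    hydrogen-count difference up to the given value (e.g. 2 admits CH2
    homologues); it defaults to 0, the strict reading.
    """
    a, b = true_f.as_dict(), pred_f.as_dict()
    if a == b:
        return "isomer"
    diff = {sym: b.get(sym, 0) - a.get(sym, 0) for sym in set(a) | set(b)}
    diff = {sym: d for sym, d in diff.items() if d != 0}
    if sorted(diff.values()) == [-1, 1]:
        # one atom of one element swapped for one atom of another (a C-for-X
        # swap counts: it is a substitution, not a homologue difference)
        return "substitution"
    if set(diff) <= {"C", "H"} and abs(diff.get("C", 0)) == 1:
        if abs(diff.get("H", 0)) <= h_tolerance:
            return "carbon_difference"
    return "other"
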