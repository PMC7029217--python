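"""Elemental formulas for metabolites.

Formulas are multisets of element counts ("C4H6O5").  Counts may be
fractional: pseudo-metabolites such as the symbiosis product carry the
coefficient-weighted elemental sum of their components, which is rarely
integral.  The pseudo-element ``R`` denotes a generic side group; it takes
part in balancing (an R introduced on one side must cancel on the other)
but has no molecular weight.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping

# Standard atomic weights (g/mol) for the elements that occur in bacteroid
# metabolism; R groups are massless placeholders.
ATOMIC_WEIGHTS: Dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Mg": 24.305,
    "K": 39.098,
    "Na": 22.990,
    "Ca": 40.078,
    "Cl": 35.45,
    "Fe": 55.845,
    "Zn": 65.38,
    "Mo": 95.95,
    "Co": 58.933,
    "Mn": 54.938,
    "Cu": 63.546,
    "Se": 78.971,
    "R": 0.0,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d+\.\d+|\d+)?")


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown elements."""


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element -> count mapping.

    An empty formula is permitted but reported as unknown, so reactions
    touching such a metabolite are marked "unchecked" by the balance
    validator rather than silently treated as balanced.
    """

    counts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for element, count in dict(self.counts).items():
            if element not in ATOMIC_WEIGHTS:
                raise FormulaError(f"unknown element {element!r}")
            if count < 0:
                raise FormulaError(f"negative count for {element!r}")
            if count != 0:
                clean[element] = float(count)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``C6H12O6`` or ``Fe``.

        Decimal counts (``C3.5``) are accepted so that pseudo-metabolite
        formulas survive a round-trip through file formats.
        """
        text = (text or "").strip()
        if not text:
            return cls({})
        counts: Dict[str, float] = {}
        pos = 0
        for match in _TOKEN.finditer(text):
            if match.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at {pos}")
            element, num = match.groups()
            counts[element] = counts.get(element, 0.0) + (float(num) if num else 1.0)
            pos = match.end()
        if pos != len(text):
            raise FormulaError(f"cannot parse formula {text!r} at {pos}")
        return cls(counts)

    @property
    def is_unknown(self) -> bool:
        return not self.counts

    def molecular_weight(self) -> float:
        """Molecular weight in g/mmol (numerically equal to g/mol / 1000... ).

        Returned in g/mmol because all model fluxes are mmol gDW^-1 h^-1:
        ``flux * MW`` is then g gDW^-1 h^-1 directly.
        """
        return sum(ATOMIC_WEIGHTS[el] * n for el, n in self.counts.items()) / 1000.0

    def scaled(self, factor: float) -> "ElementalFormula":
        if factor < 0:
            raise FormulaError("negative scaling factor")
        return ElementalFormula({el: n * factor for el, n in self.counts.items()})

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0.0) + n
        return ElementalFormula(counts)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __getitem__(self, element: str) -> float:
        return self.counts.get(element, 0.0)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        def key(el: str):
            return {"C": (0, ""), "H": (1, "")}.get(el, (2, el))

        parts = []
        for el in sorted(self.counts, key=key):
            n = self.counts[el]
            if n == 1:
                parts.append(el)
            elif float(n).is_integer():
                parts.append(f"{el}{int(n)}")
            else:
                # enough digits that residuals of reactions built from the
                # parsed-back formula stay below the balance tolerance
                parts.append(f"{el}{n:.12g}")
        return "".join(parts)


def weighted_sum(terms) -> ElementalFormula:
    """Coefficient-weighted elemental sum over (formula, coefficient) pairs,
    e.g. for pseudo-product formulas."""
    total = ElementalFormula({})
    for formula, coeff in terms:
        total = total + formula.scaled(coeff)
    return total
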