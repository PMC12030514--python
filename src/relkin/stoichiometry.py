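"""Molecular-formula arithmetic for host-guest inclusion complexes.

Converts complex doses into drug content: a matrix tablet may carry the
drug either free or as a cyclodextrin inclusion complex, and release
percentages must be normalized to the drug mass actually present.  The
guest mass fraction of an r:1 guest-host complex is

    w_guest = r * M_guest / (r * M_guest + M_host)

with molar masses computed from the packaged atomic-weight table (the
2005/2007 IUPAC standard values, which reproduce the printed molar masses
of the organic compounds involved: ketoprofen C16H14O3 254.281 g/mol,
beta-cyclodextrin (C6H10O5)7 1134.98 g/mol, hypromellose C56H108O30
1261.4 g/mol).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .errors import ValidationError

#: 2005/2007 IUPAC standard atomic weights (g/mol); single source of truth.
ATOMIC_WEIGHTS: Mapping[str, float] = MappingProxyType({
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "F": 18.9984032,
    "Na": 22.98977,
    "Mg": 24.3050,
    "P": 30.973762,
    "S": 32.065,
    "Cl": 35.453,
    "K": 39.0983,
    "Ca": 40.078,
})

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


def _parse_formula(s: str) -> Counter:
    """Parse a Hill-like formula with parenthesized repeat groups.

    Accepts e.g. ``C16H14O3``, ``(C6H10O5)7``, ``Mg(C18H35O2)2``.
    """
    stack: list[Counter] = [Counter()]
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or m.end() == pos:
            raise ValidationError(f"cannot parse formula {s!r} at position {pos}")
        element, count, open_p, close_p, group_count = m.groups()
        if element:
            stack[-1][element] += int(count) if count else 1
        elif open_p:
            stack.append(Counter())
        elif close_p:
            if len(stack) < 2:
                raise ValidationError(f"unbalanced ')' in formula {s!r}")
            group = stack.pop()
            mult = int(group_count) if group_count else 1
            for el, n in group.items():
                stack[-1][el] += n * mult
        pos = m.end()
    if len(stack) != 1:
        raise ValidationError(f"unbalanced '(' in formula {s!r}")
    return stack[0]


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map with positive integer counts."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        frozen = {}
        for el, n in dict(self.counts).items():
            if el not in ATOMIC_WEIGHTS:
                raise ValidationError(f"unknown element {el!r} (not in atomic-weight table)")
            if not isinstance(n, int) or n < 1:
                raise ValidationError(f"count for {el} must be a positive integer, got {n!r}")
            frozen[el] = n
        if not frozen:
            raise ValidationError("empty molecular formula")
        object.__setattr__(self, "counts", MappingProxyType(frozen))

    @classmethod
    def parse(cls, s: str) -> "MolecularFormula":
        return cls(dict(_parse_formula(s)))

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = Counter(dict(self.counts))
        merged.update(dict(other.counts))
        return MolecularFormula(dict(merged))

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n > 1 else ''}" for el, n in sorted(self.counts.items())
        )


@dataclass(frozen=True)
class ComplexSpec:
    """Guest-host inclusion complex with a guest_per_host molar ratio."""

    guest: MolecularFormula
    host: MolecularFormula
    guest_per_host: float

    def __post_init__(self):
        if not self.guest_per_host >= 0:
            raise ValidationError("guest_per_host must be >= 0")


def molar_mass(f: MolecularFormula) -> float:
    """Molar mass in g/mol, unrounded; display rounding is the caller's concern."""
    return sum(n * ATOMIC_WEIGHTS[el] for el, n in f.counts.items())


def guest_mass_fraction(c: ComplexSpec) -> float:
    """Mass fraction of the guest drug in the complex, in [0, 1)."""
    mg = molar_mass(c.guest)
    mh = molar_mass(c.host)
    r = c.guest_per_host
    return r * mg / (r * mg + mh)


# The compounds this package is normally used with.
KETOPROFEN = MolecularFormula.parse("C16H14O3")
BETA_CYCLODEXTRIN = MolecularFormula.parse("(C6H10O5)7")
HYPROMELLOSE_K4M = MolecularFormula.parse("C56H108O30")


def ketoprofen_bcd_complex(guest_per_host: float) -> ComplexSpec:
    """Ketoprofen-beta-cyclodextrin complex at the given molar ratio (2 or 1)."""
    return ComplexSpec(KETOPROFEN, BETA_CYCLODEXTRIN, guest_per_host)
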