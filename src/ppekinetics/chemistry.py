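"""Built-in chemical identities for the cyclic phosphoester monomer set.

Molar masses are derived from molecular formulas using IUPAC standard
atomic weights, never typed in as totals, so the repeat-unit arithmetic in
:mod:`ppekinetics.report` is exact and auditable.  Ring-opening preserves
the molecular formula, so a repeat unit has the mass of its monomer.

The seven monomers covered:

========  =============================================  ==================
name      compound                                       subclass
========  =============================================  ==================
MePPn     2-methyl-2-oxo-1,3,2-dioxaphospholane          side-chain phosphonate
EtPPn     2-ethyl-2-oxo-1,3,2-dioxaphospholane           side-chain phosphonate
PhPPn     2-phenyl-2-oxo-1,3,2-dioxaphospholane          side-chain phosphonate
MEP       2-methoxy-2-oxo-1,3,2-dioxaphospholane         phosphate
EEP       2-ethoxy-2-oxo-1,3,2-dioxaphospholane          phosphate
ETP       2-ethoxy-2-thiono-1,3,2-dioxaphospholane       thiophosphate
EPP       2-ethoxy-1,2-oxaphospholane 2-oxide            in-chain phosphonate
========  =============================================  ==================

31P chemical shifts, where known, are carried as optional metadata only.
"""

from __future__ import annotations

import re

# IUPAC 2021 standard atomic weights (conventional values), g/mol
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973761998,
    "S": 32.06,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str) -> float:
    """Molar mass (g/mol) of a Hill-notation molecular formula, e.g. 'C8H9O3P'."""
    mass = 0.0
    consumed = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.group(0) == "":
            continue
        element, count = m.group(1), m.group(2)
        if element not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        mass += ATOMIC_WEIGHTS[element] * (int(count) if count else 1)
        consumed += len(m.group(0))
    if consumed != len(formula):
        raise ValueError(f"could not parse formula {formula!r}")
    return mass


# name -> (formula, 31P shift of monomer / ppm, 31P shift of repeat unit / ppm)
MONOMER_FORMULAS: dict[str, tuple[str, float | None, float | None]] = {
    "MePPn": ("C3H7O3P", 48.7, 32.3),
    "EtPPn": ("C4H9O3P", None, 35.2),
    "PhPPn": ("C8H9O3P", 36.7, 19.8),
    "MEP": ("C3H7O4P", None, -1.3),
    "EEP": ("C4H9O4P", None, -1.3),
    "ETP": ("C4H9O3PS", None, 68.1),
    "EPP": ("C5H11O3P", None, 31.9),
}

INITIATOR_FORMULAS: dict[str, str] = {
    "2-methoxyethanol": "C3H8O2",
    "2-(benzyloxy)ethanol": "C9H12O2",
}

MONOMER_MASSES: dict[str, float] = {
    name: formula_mass(f) for name, (f, _, _) in MONOMER_FORMULAS.items()
}
INITIATOR_MASSES: dict[str, float] = {
    name: formula_mass(f) for name, f in INITIATOR_FORMULAS.items()
}


def monomer_mass(name: str) -> float:
    try:
        return MONOMER_MASSES[name]
    except KeyError:
        raise KeyError(
            f"unknown monomer {name!r}; known: {sorted(MONOMER_MASSES)}"
        ) from None


def initiator_mass(name: str) -> float:
    try:
        return INITIATOR_MASSES[name]
    except KeyError:
        raise KeyError(
            f"unknown initiator {name!r}; known: {sorted(INITIATOR_MASSES)}"
        ) from None
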