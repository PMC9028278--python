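"""Monoisotopic mass arithmetic for the 2PCA soft-spot workflow.

All masses in this package are monoisotopic and expressed in daltons (Da).
The charge carrier used for m/z computation is the mass of a *hydrogen atom*
(1.007825 Da), i.e. no electron-mass correction is applied: printed values in
the cyclic-peptide metabolite-ID literature (e.g. the imidazolidinone marker
ion C6H7N2 at m/z 107.0609) are plain atomic-mass sums of the ion formula.
Under this convention ``PROTON == H_ATOM``.

Element masses come from :mod:`pyteomics.mass` (``nist_mass``) and residue
masses are evaluated from the standard amino-acid elemental compositions
(``std_aa_comp``) through the package's own :data:`ELEMENTS` table, so a
single source of truth underlies every m/z the package prints.
"""

from __future__ import annotations

import re
from typing import Mapping

from pyteomics import mass as _pt_mass

__all__ = [
    "ELEMENTS",
    "RESIDUES",
    "RESIDUE_COMPOSITIONS",
    "WATER",
    "CO",
    "PROTON",
    "H_ATOM",
    "PCA_RESIDUAL",
    "DIAG_ION_MZ",
    "CONSTANTS",
    "formula_mass",
    "peptide_mass",
    "mz",
]

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: symbol -> monoisotopic mass (Da); C is exactly 12 by definition.
ELEMENTS: Mapping[str, float] = {
    sym: _pt_mass.nist_mass[sym][0][0] for sym in ("C", "H", "N", "O", "S", "P")
}

#: one-letter code -> elemental composition of the residue (peptide-bond form).
RESIDUE_COMPOSITIONS: Mapping[str, Mapping[str, int]] = {
    aa: dict(_pt_mass.std_aa_comp[aa]) for aa in _STANDARD_RESIDUES
}

#: one-letter code -> residue monoisotopic mass (Da), derived from ELEMENTS.
RESIDUES: Mapping[str, float] = {
    aa: sum(n * ELEMENTS[el] for el, n in comp.items())
    for aa, comp in RESIDUE_COMPOSITIONS.items()
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str, elements: Mapping[str, float] = ELEMENTS) -> float:
    """Monoisotopic mass of an elemental formula string such as ``"C6H3N"``.

    Parameters
    ----------
    formula:
        Hill-style formula; element symbols followed by optional counts.
        The empty string has mass 0.
    elements:
        Symbol -> mass table; defaults to :data:`ELEMENTS`. Pass an extended
        mapping to support additional elements.

    Raises
    ------
    ValueError
        If the string contains anything but known element symbols with
        non-negative integer counts; the offending symbol is named.
    """
    total = 0.0
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(
                f"malformed formula {formula!r} at position {pos}: "
                f"{formula[pos:]!r}"
            )
        pos = m.end()
        sym, count = m.group(1), m.group(2)
        if sym not in elements:
            raise ValueError(f"unknown element symbol {sym!r} in formula {formula!r}")
        total += elements[sym] * (int(count) if count else 1)
    if pos != len(formula):
        raise ValueError(
            f"malformed formula {formula!r} at position {pos}: {formula[pos:]!r}"
        )
    return total


# -- chemical constants of the 2PCA workflow (all derived from ELEMENTS) ------

#: hydrolysis / linearization mass shift, mass(H2O) = 18.0106 Da
WATER: float = formula_mass("H2O")
#: diagnostic a/b doublet spacing, mass(CO) = 27.9949 Da
CO: float = formula_mass("CO")
#: hydrogen-transfer offset, mass of one H atom = 1.0078 Da
H_ATOM: float = formula_mass("H")
#: charge carrier (no electron-mass correction; see module docstring)
PROTON: float = H_ATOM
#: residual mass added by 2PCA imidazolidinone conjugation, mass(C6H3N) = 89.0265 Da
PCA_RESIDUAL: float = formula_mass("C6H3N")
#: imidazolidinone-specific marker ion, mass(C6H7N2) = m/z 107.0609 (the
#: printed formula is the singly charged ion itself)
DIAG_ION_MZ: float = formula_mass("C6H7N2")

#: name -> value, for CLI display and config echo.
CONSTANTS: Mapping[str, float] = {
    "WATER": WATER,
    "CO": CO,
    "PROTON": PROTON,
    "H_ATOM": H_ATOM,
    "PCA_RESIDUAL": PCA_RESIDUAL,
    "DIAG_ION_MZ": DIAG_ION_MZ,
}


def residue_masses(sequence: str) -> list[float]:
    """Per-residue monoisotopic masses, rejecting unknown residues by position."""
    out = []
    for i, aa in enumerate(sequence, start=1):
        try:
            out.append(RESIDUES[aa])
        except KeyError:
            raise ValueError(
                f"unknown residue {aa!r} at position {i} in sequence {sequence!r}"
            ) from None
    return out


def peptide_mass(sequence: str, topology: str = "linear") -> float:
    """Neutral monoisotopic mass of a residue string.

    ``topology="linear"`` adds one water (free N/C termini); ``"cyclic"``
    is the head-to-tail ring (sum of residue masses only). A head-to-tail
    ring plus one water therefore equals the linear peptide of the same
    string — the ring-opening hydrolysis identity.
    """
    total = sum(residue_masses(sequence))
    if topology == "linear":
        return total + WATER
    if topology == "cyclic":
        return total
    raise ValueError(f"topology must be 'linear' or 'cyclic', got {topology!r}")


def mz(neutral_mass: float, charge: int) -> float:
    """m/z of a neutral mass at a positive charge state.

    ``(M + z * PROTON) / z`` with the H-atom charge carrier (module docstring).
    """
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (neutral_mass + charge * PROTON) / charge
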