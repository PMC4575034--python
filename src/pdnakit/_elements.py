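"""Element masses and van der Waals radii used throughout the package.

Masses are standard atomic weights (amu); radii are the Bondi set (Å).
Unknown elements fall back to carbon-like values so that parsing exotic
hetero-groups never aborts a whole-structure analysis.
"""

from __future__ import annotations

ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "ZN": 65.38,
    "FE": 55.845,
    "MN": 54.938,
    "SE": 78.971,
}

# Bondi (1964) van der Waals radii, Å.
VDW_RADIUS: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "ZN": 1.39,
    "FE": 2.00,
    "MN": 2.00,
    "SE": 1.90,
}

_FALLBACK_MASS = 12.011
_FALLBACK_RADIUS = 1.70


def element_mass(element: str) -> float:
    return ATOMIC_MASS.get(element.upper().strip(), _FALLBACK_MASS)


def element_vdw_radius(element: str) -> float:
    return VDW_RADIUS.get(element.upper().strip(), _FALLBACK_RADIUS)


def guess_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name when the element column is blank."""
    name = atom_name.strip().lstrip("0123456789")
    if not name:
        return "C"
    two = name[:2].upper()
    if two in ("CL", "BR", "NA", "MG", "ZN", "FE", "MN", "SE") and len(name) <= 2:
        return two
    return name[0].upper()
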