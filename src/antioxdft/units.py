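"""Unit conventions and conversions.

Everything inside the package is atomic units (Hartree, Bohr, electrons/Bohr^3).
kcal/mol, eV and Angstrom appear only at report boundaries.
"""

from decimal import ROUND_HALF_UP, Decimal

HARTREE_TO_KCAL = 627.509
BOHR_TO_ANGSTROM = 0.529177
HARTREE_TO_EV = 27.2114


def hartree_to_kcal(x: float) -> float:
    return x * HARTREE_TO_KCAL


def kcal_to_hartree(x: float) -> float:
    return x / HARTREE_TO_KCAL


def bohr_to_angstrom(x: float) -> float:
    return x * BOHR_TO_ANGSTROM


def angstrom_to_bohr(x: float) -> float:
    return x / BOHR_TO_ANGSTROM


def hartree_to_ev(x: float) -> float:
    return x * HARTREE_TO_EV


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention used by the
    printed report tables), as opposed to Python's banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
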