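"""Second-order perturbation (donor -> acceptor) stabilization energies.

For a filled donor NBO sigma with occupancy n and an acceptor sigma* the
hyperconjugative stabilization is

    E(2) = n * F_ij^2 / (eps_j* - eps_i)

with F_ij the Fock matrix element between the two orbitals. Values are
reported as positive magnitudes in kcal/mol, the convention of NBO tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .units import HARTREE_TO_KCAL

__all__ = ["OrbitalInteraction", "e2", "e2_table"]


@dataclass(frozen=True)
class OrbitalInteraction:
    """One donor -> acceptor NBO pair (atomic units)."""

    donor: str
    acceptor: str
    occupancy: float      # n, electrons in the donor orbital, 0 < n <= 2
    fock_element: float   # F_ij, a.u.
    donor_energy: float   # eps_i, a.u.
    acceptor_energy: float  # eps_j*, a.u.

    def __post_init__(self):
        if not 0 < self.occupancy <= 2:
            raise ValueError(f"occupancy must be in (0, 2], got {self.occupancy}")
        if self.acceptor_energy <= self.donor_energy:
            raise ValueError(
                f"acceptor energy ({self.acceptor_energy}) must exceed donor "
                f"energy ({self.donor_energy})"
            )


def e2(interaction: OrbitalInteraction) -> float:
    """Stabilization energy magnitude in kcal/mol."""
    gap = interaction.acceptor_energy - interaction.donor_energy
    if gap == 0:
        raise ZeroDivisionError("degenerate donor/acceptor energies")
    value_au = interaction.occupancy * interaction.fock_element**2 / gap
    return abs(value_au) * HARTREE_TO_KCAL


def e2_table(interactions: list[OrbitalInteraction]) -> pd.DataFrame:
    rows = [{
        "donor": it.donor, "acceptor": it.acceptor, "occupancy": it.occupancy,
        "fock_au": it.fock_element, "gap_au": it.acceptor_energy - it.donor_energy,
        "e2_kcal": e2(it),
    } for it in interactions]
    return pd.DataFrame(rows)
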