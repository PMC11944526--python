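"""Core domain types: atoms, geometries, density grids, enthalpy ledgers,
frontier orbitals.

All positions are in Bohr, all enthalpies/orbital energies in Hartree,
densities in electrons/Bohr^3 (see :mod:`antioxdft.units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "ELEMENT_Z",
    "Z_ELEMENT",
    "AtomSite",
    "MoleculeGeometry",
    "DensityGrid",
    "EnthalpyLedger",
    "LedgerBook",
    "FrontierOrbitals",
    "SPECIES",
    "REFERENCE_SPECIES",
]

# Minimal symbol <-> nuclear charge table for the elements this package meets
# (organic molecules, common solvents). Hand-kept; extend as needed.
ELEMENT_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Fe": 26, "Zn": 30,
    "Br": 35, "I": 53,
}
Z_ELEMENT = {z: el for el, z in ELEMENT_Z.items()}

#: species bookkeeping used by enthalpy ledgers: the parent antioxidant AH,
#: its phenoxyl radical A*, the radical cation [AH*]+ and the anion [A:]-.
SPECIES = ("AH", "A_radical", "cation", "anion")
#: reference particles entering the mechanism enthalpy differences.
REFERENCE_SPECIES = ("H_radical", "proton", "electron")


@dataclass(frozen=True)
class AtomSite:
    """One nucleus: element symbol, nuclear charge Z, position in Bohr."""

    element: str
    position: np.ndarray
    nuclear_charge: int = 0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if self.element not in ELEMENT_Z:
            raise ValueError(f"unknown element symbol {self.element!r}")
        z = self.nuclear_charge or ELEMENT_Z[self.element]
        if z != ELEMENT_Z[self.element]:
            raise ValueError(
                f"nuclear charge {z} does not match element {self.element!r} "
                f"(expected {ELEMENT_Z[self.element]})"
            )
        object.__setattr__(self, "nuclear_charge", z)


@dataclass(frozen=True)
class MoleculeGeometry:
    """Ordered collection of atoms with a text label."""

    atoms: tuple[AtomSite, ...]
    label: str = ""

    MIN_SEPARATION_BOHR = 0.1

    def __post_init__(self):
        atoms = tuple(self.atoms)
        if len(atoms) < 1:
            raise ValueError("geometry needs at least one atom")
        object.__setattr__(self, "atoms", atoms)
        if len(atoms) > 1:
            pos = self.positions
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < self.MIN_SEPARATION_BOHR:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise ValueError(
                    f"atoms {i} and {j} are {d.min():.4f} Bohr apart "
                    f"(< {self.MIN_SEPARATION_BOHR})"
                )

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class DensityGrid:
    """Volumetric electron density on a (possibly skewed) regular lattice.

    ``values[i, j, k]`` sits at ``origin + i*axes[0] + j*axes[1] + k*axes[2]``;
    axes rows are the voxel step vectors in Bohr.
    """

    origin: np.ndarray
    axes: np.ndarray
    counts: tuple[int, int, int]
    values: np.ndarray
    geometry: MoleculeGeometry

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.counts = tuple(int(n) for n in self.counts)
        if any(n <= 0 for n in self.counts):
            raise ValueError(f"voxel counts must be positive, got {self.counts}")
        if abs(np.linalg.det(self.axes)) < 1e-14:
            raise ValueError("axis vectors are linearly dependent")
        vals = np.asarray(self.values, dtype=float)
        if vals.size != int(np.prod(self.counts)):
            raise ValueError(
                f"value count {vals.size} != n1*n2*n3 = {int(np.prod(self.counts))}"
            )
        self.values = vals.reshape(self.counts)
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.axes)))

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) Cartesian positions of all lattice nodes, C-order."""
        n1, n2, n3 = self.counts
        idx = np.stack(
            np.meshgrid(np.arange(n1), np.arange(n2), np.arange(n3), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        return self.origin + idx @ self.axes

    def integrated_density(self) -> float:
        return float(self.values.sum() * self.voxel_volume)


class LedgerError(KeyError):
    """A requested (compound, environment, site, species) enthalpy is absent."""


@dataclass
class EnthalpyLedger:
    """Enthalpies (Hartree) of the species of one compound in one environment.

    ``site_enthalpies[site][species]`` holds the per-deprotonation-site species
    (``AH``/``A_radical``/``cation``/``anion``); ``references`` holds the
    hydrogen atom, proton and electron enthalpies, which are explicit inputs
    (different bookkeeping conventions circulate and none is baked in).
    """

    compound: str
    environment: str
    site_enthalpies: dict[str, dict[str, float]] = field(default_factory=dict)
    references: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for site, spmap in self.site_enthalpies.items():
            for sp, h in spmap.items():
                if sp not in SPECIES:
                    raise ValueError(f"unknown species {sp!r} at site {site!r}")
                if not np.isfinite(h):
                    raise ValueError(f"non-finite enthalpy for {site}/{sp}")
        for sp, h in self.references.items():
            if sp not in REFERENCE_SPECIES:
                raise ValueError(f"unknown reference species {sp!r}")
            if not np.isfinite(h):
                raise ValueError(f"non-finite reference enthalpy {sp}")

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(self.site_enthalpies)

    def enthalpy(self, site: str, species: str) -> float:
        try:
            return self.site_enthalpies[site][species]
        except KeyError:
            raise LedgerError(
                f"{self.compound}/{self.environment}: no {species!r} enthalpy "
                f"for site {site!r}"
            ) from None

    def reference(self, species: str) -> float:
        try:
            return self.references[species]
        except KeyError:
            raise LedgerError(
                f"{self.compound}/{self.environment}: reference species "
                f"{species!r} not supplied"
            ) from None

    def n_species(self) -> int:
        return sum(len(v) for v in self.site_enthalpies.values())


class LedgerBook:
    """Collection of :class:`EnthalpyLedger` keyed by (compound, environment)."""

    def __init__(self, ledgers: Iterable[EnthalpyLedger] = ()):
        self._ledgers: dict[tuple[str, str], EnthalpyLedger] = {}
        for led in ledgers:
            self.add(led)

    def add(self, ledger: EnthalpyLedger) -> None:
        key = (ledger.compound, ledger.environment)
        if key in self._ledgers:
            raise ValueError(f"duplicate ledger for {key}")
        self._ledgers[key] = ledger

    def select(self, compound: str, environment: str) -> EnthalpyLedger:
        try:
            return self._ledgers[(compound, environment)]
        except KeyError:
            raise LedgerError(f"no ledger for {(compound, environment)}") from None

    def keys(self):
        return self._ledgers.keys()

    def __iter__(self):
        return iter(self._ledgers.values())

    def __len__(self) -> int:
        return len(self._ledgers)


@dataclass(frozen=True)
class FrontierOrbitals:
    """HOMO/LUMO energies (Hartree) in a given environment."""

    e_homo: float
    e_lumo: float
    environment: str = "vacuum"

    def __post_init__(self):
        if not (np.isfinite(self.e_homo) and np.isfinite(self.e_lumo)):
            raise ValueError("orbital energies must be finite")
        if self.e_homo > self.e_lumo:
            raise ValueError(
                f"E_HOMO ({self.e_homo}) must not exceed E_LUMO ({self.e_lumo})"
            )
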