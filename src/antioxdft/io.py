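"""Readers and writers: Gaussian cube volumetric files and structured
CSV/JSON tables (enthalpy ledgers, frontier orbitals, interaction tables).

The cube dialect handled here is the common one: two comment lines, an
atom-count + origin record, three axis records, the atom block, then values
with the last (z) index fastest. A negative atom count marks an orbital cube
(the extra orbital-index record is consumed; only single-orbital files are
accepted). Negative voxel counts mark Angstrom headers and are converted;
written files always use the positive-count Bohr convention.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    SPECIES,
    REFERENCE_SPECIES,
    Z_ELEMENT,
    AtomSite,
    DensityGrid,
    EnthalpyLedger,
    FrontierOrbitals,
    LedgerBook,
    MoleculeGeometry,
)
from .units import angstrom_to_bohr

__all__ = [
    "CubeParseError",
    "read_cube",
    "write_cube",
    "load_ledger",
    "load_frontier_orbitals",
    "load_interaction_table",
]


class CubeParseError(ValueError):
    """Malformed cube file; carries the byte offset of the offending token."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (byte offset {offset})")
        self.offset = offset


class _Tokens:
    """Whitespace token stream over the file text, tracking byte offsets."""

    def __init__(self, text: str, base: int):
        self._matches = list(re.finditer(rb"\S+", text.encode()))
        self._text = text
        self._base = base
        self._i = 0

    @property
    def offset(self) -> int:
        if self._i < len(self._matches):
            return self._base + self._matches[self._i].start()
        return self._base + len(self._text.encode())

    def next_float(self, what: str) -> float:
        if self._i >= len(self._matches):
            raise CubeParseError(f"unexpected end of file while reading {what}", self.offset)
        tok = self._matches[self._i].group().decode()
        self._i += 1
        try:
            return float(tok.replace("D", "E").replace("d", "e"))
        except ValueError:
            raise CubeParseError(f"non-numeric token {tok!r} while reading {what}",
                                 self._base + self._matches[self._i - 1].start()) from None

    def next_int(self, what: str) -> int:
        v = self.next_float(what)
        if v != int(v):
            raise CubeParseError(f"expected integer while reading {what}, got {v}",
                                 self._base + self._matches[self._i - 1].start())
        return int(v)

    def remaining(self) -> int:
        return len(self._matches) - self._i


def read_cube(path) -> DensityGrid:
    path = Path(path)
    text = path.read_text()
    # first two lines are free-text comments; the rest is a token stream
    nl1 = text.find("\n")
    nl2 = text.find("\n", nl1 + 1)
    if nl1 < 0 or nl2 < 0:
        raise CubeParseError("missing comment lines", 0)
    label = text[:nl1].strip()
    body = text[nl2 + 1:]
    toks = _Tokens(body, base=nl2 + 1)

    natoms = toks.next_int("atom count")
    origin = np.array([toks.next_float("origin") for _ in range(3)])
    # optional NVal field: some writers put a 5th integer on the third line;
    # detect it by peeking at the first axis record layout (count + 3 floats).
    orbital_cube = natoms < 0
    natoms = abs(natoms)

    counts, axes = [], []
    for ax in range(3):
        counts.append(toks.next_int(f"axis {ax} count"))
        axes.append([toks.next_float(f"axis {ax} vector") for _ in range(3)])
    axes = np.array(axes)

    angstrom = any(n < 0 for n in counts)
    counts = [abs(n) for n in counts]

    atoms = []
    for i in range(natoms):
        z = toks.next_int(f"atom {i} charge")
        toks.next_float(f"atom {i} charge column")
        pos = np.array([toks.next_float(f"atom {i} position") for _ in range(3)])
        if z not in Z_ELEMENT:
            raise CubeParseError(f"unsupported nuclear charge {z}", toks.offset)
        atoms.append((Z_ELEMENT[z], pos))

    if orbital_cube:
        norb = toks.next_int("orbital count")
        if norb != 1:
            raise CubeParseError(f"multi-orbital cubes unsupported (found {norb})", toks.offset)
        toks.next_int("orbital index")

    if angstrom:
        origin = angstrom_to_bohr(origin)
        axes = angstrom_to_bohr(axes)
        atoms = [(el, angstrom_to_bohr(p)) for el, p in atoms]

    nval = counts[0] * counts[1] * counts[2]
    if toks.remaining() > nval:
        raise CubeParseError(
            f"trailing tokens: expected {nval} values, found {toks.remaining()}", toks.offset
        )
    values = np.empty(nval)
    for i in range(nval):
        values[i] = toks.next_float("density value")

    geometry = MoleculeGeometry(
        atoms=tuple(AtomSite(element=el, position=p) for el, p in atoms),
        label=label,
    )
    return DensityGrid(origin=origin, axes=axes, counts=tuple(counts),
                       values=values, geometry=geometry)


def write_cube(grid: DensityGrid, path) -> Path:
    """Write a Bohr-convention cube. Floats are printed with 17 significant
    digits so a read-back reproduces every value bit for bit."""
    path = Path(path)
    g = grid.geometry
    lines = [
        g.label or "electron density, atomic units",
        "cube file written by antioxdft",
        f"{len(g):5d} " + " ".join(f"{x: .16E}" for x in grid.origin),
    ]
    for n, ax in zip(grid.counts, grid.axes):
        lines.append(f"{n:5d} " + " ".join(f"{x: .16E}" for x in ax))
    for atom in g.atoms:
        lines.append(
            f"{atom.nuclear_charge:5d} {float(atom.nuclear_charge): .16E} "
            + " ".join(f"{x: .16E}" for x in atom.position)
        )
    flat = grid.values.reshape(-1)
    for i in range(0, flat.size, 6):
        lines.append(" ".join(f"{x: .16E}" for x in flat[i:i + 6]))
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# structured tables

_LEDGER_COLUMNS = ["compound", "environment", "site", "species", "enthalpy_hartree"]


def load_ledger(path) -> LedgerBook:
    """Load a long-format enthalpy table (CSV or JSON records) into a
    :class:`LedgerBook`.

    Species rows use the ``AH``/``A_radical``/``cation``/``anion`` labels with
    their site; reference rows (``H_radical``/``proton``/``electron``) leave
    the site empty or set it to ``"reference"``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, dtype={"site": str}, keep_default_na=False)
    missing = [c for c in _LEDGER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ledger table missing columns: {missing}")
    if len(df) == 0:
        return LedgerBook()

    dup = df.duplicated(subset=["compound", "environment", "site", "species"])
    if dup.any():
        rows = df.loc[dup, ["compound", "environment", "site", "species"]]
        raise ValueError(f"duplicate ledger rows:\n{rows.to_string(index=False)}")

    book = LedgerBook()
    for (compound, environment), sub in df.groupby(["compound", "environment"], sort=False):
        sites: dict[str, dict[str, float]] = {}
        refs: dict[str, float] = {}
        for _, row in sub.iterrows():
            sp = row["species"]
            h = float(row["enthalpy_hartree"])
            if sp in REFERENCE_SPECIES:
                refs[sp] = h
            elif sp in SPECIES:
                sites.setdefault(str(row["site"]), {})[sp] = h
            else:
                raise ValueError(f"unknown species {sp!r} in ledger table")
        book.add(EnthalpyLedger(compound=str(compound), environment=str(environment),
                                site_enthalpies=sites, references=refs))
    return book


def load_frontier_orbitals(path) -> dict[str, FrontierOrbitals]:
    """CSV/JSON with columns environment, e_homo_hartree, e_lumo_hartree."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        env = str(row["environment"])
        out[env] = FrontierOrbitals(
            e_homo=float(row["e_homo_hartree"]),
            e_lumo=float(row["e_lumo_hartree"]),
            environment=env,
        )
    return out


def load_interaction_table(path) -> pd.DataFrame:
    """Load a bond-critical-point interaction table (CSV) as a DataFrame."""
    return pd.read_csv(path, comment="#")
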