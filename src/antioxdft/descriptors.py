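"""Frontier-orbital reactivity descriptors and molecular electrostatic
potential (MEP) metrics.

Descriptors use the frontier approximations I = -E_HOMO, A = -E_LUMO:
hardness eta = (I - A)/2, chemical potential mu = -(I + A)/2 = -chi, and the
global electrophilicity index omega = mu^2 / (2 eta). All are computed in
atomic units; eV is a report-boundary conversion.

The MEP is V(r) = sum_a Z_a / |r_a - r| - integral rho(r') / |r' - r| dr',
with the electronic term by midpoint quadrature over voxels for gridded
densities, or an exact Coulomb sum for point-charge stand-ins. The molecular
polarity index (MPI) is the area-weighted mean of |V| over a density
isosurface (default isovalue 4.0e-4 electrons/Bohr^3, the contour commonly
used for MEP maps); the "polar area" is the fraction of surface area where
|V| meets a threshold, by default the surface mean of |V| itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import measure

from .model import AtomSite, DensityGrid, FrontierOrbitals
from .units import HARTREE_TO_KCAL

__all__ = [
    "ReactivityDescriptors",
    "ElectronPointCharges",
    "MepField",
    "descriptors_from_orbitals",
    "mep_at_points",
    "mpi_and_polar_area",
    "isosurface",
    "surface_polarity",
]

MIN_NUCLEAR_DISTANCE_BOHR = 0.05
DEFAULT_ISOVALUE = 4.0e-4


@dataclass(frozen=True)
class ReactivityDescriptors:
    """Global conceptual-DFT descriptors, atomic units.

    ``omega`` is ``None`` (undefined) in the degenerate eta = 0 limit.
    """

    ionization_potential: float      # I = -E_HOMO
    electron_affinity: float         # A = -E_LUMO
    gap: float                       # I - A = E_LUMO - E_HOMO
    hardness: float                  # eta = (I - A) / 2
    chemical_potential: float        # mu = -(I + A) / 2
    electronegativity: float         # chi = -mu
    electrophilicity: float | None   # omega = mu^2 / (2 eta)
    environment: str = "vacuum"

    def in_ev(self) -> dict[str, float | None]:
        from .units import HARTREE_TO_EV
        out = {}
        for k in ("ionization_potential", "electron_affinity", "gap",
                  "hardness", "chemical_potential", "electronegativity",
                  "electrophilicity"):
            v = getattr(self, k)
            out[k] = None if v is None else v * HARTREE_TO_EV
        return out


def descriptors_from_orbitals(orbitals: FrontierOrbitals) -> ReactivityDescriptors:
    I = -orbitals.e_homo
    A = -orbitals.e_lumo
    eta = (I - A) / 2.0
    mu = -(I + A) / 2.0
    omega = None if eta == 0 else mu * mu / (2.0 * eta)
    return ReactivityDescriptors(
        ionization_potential=I, electron_affinity=A, gap=I - A,
        hardness=eta, chemical_potential=mu, electronegativity=-mu,
        electrophilicity=omega, environment=orbitals.environment,
    )


@dataclass(frozen=True)
class ElectronPointCharges:
    """Electron distribution as point charges: ``charges`` are electron
    counts (>= 0) and contribute negatively to V."""

    positions: np.ndarray  # (N, 3) Bohr
    charges: np.ndarray    # (N,) electrons

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        q = np.asarray(self.charges, dtype=float).reshape(-1)
        if len(pos) != len(q):
            raise ValueError("positions/charges length mismatch")
        if np.any(q < 0):
            raise ValueError("electron counts must be >= 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", q)


@dataclass(frozen=True)
class MepField:
    """Electrostatic potential values (a.u.) at a set of points."""

    points: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        vals = np.asarray(self.values, dtype=float).reshape(-1)
        if len(pts) != len(vals):
            raise ValueError("points/values length mismatch")
        if not np.all(np.isfinite(vals)):
            raise ValueError("MEP values must be finite")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "values", vals)


def _electronic_potential_grid(density: DensityGrid, points: np.ndarray,
                               pair_budget: int = 8_000_000) -> np.ndarray:
    """Midpoint-quadrature electronic potential, chunked so the pairwise
    distance workspace stays within a fixed element budget."""
    centers = density.voxel_centers()
    weights = density.values.reshape(-1) * density.voxel_volume
    out = np.zeros(len(points))
    vox_chunk = max(1, pair_budget // max(1, len(points)))
    for start in range(0, len(centers), vox_chunk):
        c = centers[start:start + vox_chunk]
        w = weights[start:start + vox_chunk]
        d = np.linalg.norm(points[:, None, :] - c[None, :, :], axis=-1)
        np.maximum(d, 1e-12, out=d)
        out += (w[None, :] / d).sum(axis=1)
    return out


def mep_at_points(nuclei: Sequence[AtomSite], density, points,
                  min_nuclear_distance: float = MIN_NUCLEAR_DISTANCE_BOHR) -> MepField:
    """Evaluate V at ``points`` from nuclei plus an electron distribution
    (a :class:`DensityGrid`, an :class:`ElectronPointCharges`, or ``None``
    for bare nuclei).

    Points closer than ``min_nuclear_distance`` to any nucleus are rejected,
    reporting the offending point index.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("empty point set")
    V = np.zeros(len(pts))
    if len(nuclei) > 0:
        npos = np.array([a.position for a in nuclei])
        z = np.array([a.nuclear_charge for a in nuclei], dtype=float)
        d = np.linalg.norm(pts[:, None, :] - npos[None, :, :], axis=-1)
        too_close = d < min_nuclear_distance
        if too_close.any():
            idx = int(np.flatnonzero(too_close.any(axis=1))[0])
            raise ValueError(
                f"point {idx} is within {min_nuclear_distance} Bohr of a nucleus"
            )
        V += (z[None, :] / d).sum(axis=1)
    if isinstance(density, DensityGrid):
        V -= _electronic_potential_grid(density, pts)
    elif isinstance(density, ElectronPointCharges):
        d = np.linalg.norm(pts[:, None, :] - density.positions[None, :, :], axis=-1)
        np.maximum(d, 1e-12, out=d)
        V -= (density.charges[None, :] / d).sum(axis=1)
    elif density is not None:
        raise TypeError(f"unsupported electron source {type(density).__name__}")
    return MepField(points=pts, values=V)


def mpi_and_polar_area(mep: MepField, areas, polar_threshold: float | None = None
                       ) -> dict[str, float]:
    """Molecular polarity index and polar-area fraction over a surface
    point set with per-point areas.

    MPI (kcal/mol) is the area-weighted mean of |V|; the polar fraction is
    the percentage of area where |V| >= ``polar_threshold`` (default: the
    area-weighted surface mean of |V|, in a.u.).
    """
    areas = np.asarray(areas, dtype=float).reshape(-1)
    if len(areas) == 0:
        raise ValueError("empty surface point set")
    if len(areas) != len(mep.values):
        raise ValueError("areas length != number of surface points")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    absv = np.abs(mep.values)
    total = areas.sum()
    mean_abs_v = float((areas * absv).sum() / total)
    if polar_threshold is None:
        polar_threshold = mean_abs_v
    polar_fraction = float(100.0 * areas[absv >= polar_threshold].sum() / total)
    return {
        "mpi_kcal": mean_abs_v * HARTREE_TO_KCAL,
        "mean_abs_v_au": mean_abs_v,
        "polar_threshold_au": float(polar_threshold),
        "polar_fraction_percent": polar_fraction,
    }


def isosurface(grid: DensityGrid, isovalue: float = DEFAULT_ISOVALUE):
    """Marching-cubes isosurface of the density: returns (centroids, areas),
    one entry per triangle, Cartesian Bohr."""
    verts_idx, faces, _, _ = measure.marching_cubes(grid.values, level=isovalue)
    verts = grid.origin + verts_idx @ grid.axes
    tri = verts[faces]
    centroids = tri.mean(axis=1)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    keep = areas > 0
    return centroids[keep], areas[keep]


def surface_polarity(grid: DensityGrid, isovalue: float = DEFAULT_ISOVALUE,
                     polar_threshold: float | None = None,
                     electron_source=None) -> dict[str, float]:
    """MPI and polar-area fraction of a gridded density: extract the
    isosurface, evaluate V at triangle centroids (nuclei from the grid's
    geometry, electrons from the grid itself unless overridden), aggregate."""
    centroids, areas = isosurface(grid, isovalue)
    mep = mep_at_points(grid.geometry.atoms,
                        grid if electron_source is None else electron_source,
                        centroids)
    out = mpi_and_polar_area(mep, areas, polar_threshold)
    out["n_triangles"] = float(len(areas))
    out["isovalue"] = float(isovalue)
    return out
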