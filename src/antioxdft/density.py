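"""Electron-density fields exposing value, gradient and Hessian anywhere.

Two field flavours:

* :class:`PromolecularDensity` — a sum of spherical single-exponential atomic
  densities (Slater-type by default, optionally Gaussian-type). This is a
  transparent analytic stand-in for an SCF density: every derivative is exact,
  so it makes an ideal test bed for critical-point searches. The packaged
  per-element amplitudes/decay lengths are conventional constants, not fitted
  physics.
* :class:`GridField` — a cube-file density interpolated with a tensor-product
  cubic B-spline (prefiltered so the interpolant passes through the grid
  values). The B-spline is C2, so the Newton search downstream sees smooth
  second derivatives; gradients/Hessians are obtained by differentiating the
  spline analytically.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

from .model import DensityGrid, MoleculeGeometry

__all__ = [
    "DensityProbe",
    "PromolecularDensity",
    "GridField",
    "OutOfDomainError",
    "evaluate",
    "load_radial_parameters",
]


class OutOfDomainError(ValueError):
    """Probe point outside the interpolable region of a grid field."""


@dataclass(frozen=True)
class DensityProbe:
    """Density, gradient and Hessian of rho at one point (atomic units)."""

    value: float
    gradient: np.ndarray
    hessian: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.gradient, dtype=float).reshape(3)
        h = np.asarray(self.hessian, dtype=float).reshape(3, 3)
        object.__setattr__(self, "gradient", g)
        object.__setattr__(self, "hessian", h)
        if not np.allclose(h, h.T, atol=1e-10):
            raise ValueError("Hessian must be symmetric")

    @property
    def laplacian(self) -> float:
        return float(np.trace(self.hessian))


def load_radial_parameters() -> pd.DataFrame:
    """Packaged per-element (amplitude, decay length) table for the
    promolecular model."""
    with resources.files("antioxdft.data").joinpath("radial_params.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


class PromolecularDensity:
    """Sum of spherical exponential atomic densities.

    ``form="slater"``: rho_atom(r) = a * exp(-r / lam)   (cusp at the nucleus)
    ``form="gaussian"``: rho_atom(r) = a * exp(-r^2 / lam^2)  (smooth maximum)

    Per-atom overrides of (amplitude, decay) may be given; otherwise the
    packaged per-element table is used.
    """

    def __init__(
        self,
        geometry: MoleculeGeometry,
        parameters: dict[str, tuple[float, float]] | None = None,
        per_atom: list[tuple[float, float]] | None = None,
        form: str = "slater",
    ):
        if form not in ("slater", "gaussian"):
            raise ValueError(f"unknown radial form {form!r}")
        self.geometry = geometry
        self.form = form
        if per_atom is not None:
            if len(per_atom) != len(geometry):
                raise ValueError("per_atom parameter list length != atom count")
            params = list(per_atom)
        else:
            if parameters is None:
                tab = load_radial_parameters()
                parameters = {
                    r.element: (float(r.amplitude), float(r.decay_bohr))
                    for r in tab.itertuples()
                }
            params = [parameters[a.element] for a in geometry.atoms]
        for a, lam in params:
            if a <= 0 or lam <= 0:
                raise ValueError("amplitudes and decay lengths must be positive")
        self.amplitudes = np.array([p[0] for p in params])
        self.decays = np.array([p[1] for p in params])
        self.centers = geometry.positions

    # radial profile and its first/second derivatives wrt r
    def _radial(self, r: np.ndarray, a: float, lam: float):
        if self.form == "slater":
            f = a * np.exp(-r / lam)
            return f, -f / lam, f / lam**2
        f = a * np.exp(-(r**2) / lam**2)
        return f, -2.0 * r / lam**2 * f, (-2.0 / lam**2 + 4.0 * r**2 / lam**4) * f

    def probe(self, point) -> DensityProbe:
        p = np.asarray(point, dtype=float).reshape(3)
        value = 0.0
        grad = np.zeros(3)
        hess = np.zeros((3, 3))
        eye = np.eye(3)
        for c, a, lam in zip(self.centers, self.amplitudes, self.decays):
            d = p - c
            r = float(np.linalg.norm(d))
            if r < 1e-12:
                # coincident with the nucleus: spherical-average limit. For the
                # cusped Slater form a negative-definite curvature of the
                # natural scale a/lam^2 is substituted so nuclei behave as
                # density attractors, matching the QTAIM convention.
                value += a
                hess += -(a / lam**2) * eye
                continue
            f, f1, f2 = self._radial(np.array(r), a, lam)
            u = d / r
            value += float(f)
            grad += float(f1) * u
            uu = np.outer(u, u)
            hess += float(f2) * uu + float(f1) / r * (eye - uu)
        return DensityProbe(value=value, gradient=grad, hessian=hess)

    def values_at(self, points: np.ndarray) -> np.ndarray:
        """Vectorised density values (no derivatives) at (N, 3) points."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        r = np.linalg.norm(pts[:, None, :] - self.centers[None, :, :], axis=-1)
        if self.form == "slater":
            contrib = self.amplitudes[None, :] * np.exp(-r / self.decays[None, :])
        else:
            contrib = self.amplitudes[None, :] * np.exp(-(r**2) / self.decays[None, :] ** 2)
        return contrib.sum(axis=1)

    def sample(self, origin, axes, counts, label: str = "") -> DensityGrid:
        """Sample the field on a lattice, returning a :class:`DensityGrid`."""
        origin = np.asarray(origin, dtype=float)
        axes = np.asarray(axes, dtype=float).reshape(3, 3)
        n1, n2, n3 = counts
        idx = np.stack(
            np.meshgrid(np.arange(n1), np.arange(n2), np.arange(n3), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        pts = origin + idx @ axes
        vals = self.values_at(pts)
        return DensityGrid(origin=origin, axes=axes, counts=tuple(counts),
                           values=vals, geometry=self.geometry)


# cubic B-spline basis on t in [0, 1): weights for taps at offsets -1..2
def _bspline_weights(t: float):
    t2, t3 = t * t, t * t * t
    w = np.array([
        (1 - t) ** 3 / 6.0,
        (3 * t3 - 6 * t2 + 4) / 6.0,
        (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
        t3 / 6.0,
    ])
    dw = np.array([
        -((1 - t) ** 2) / 2.0,
        (9 * t2 - 12 * t) / 6.0,
        (-9 * t2 + 6 * t + 3) / 6.0,
        t2 / 2.0,
    ])
    d2w = np.array([1 - t, 3 * t - 2, -3 * t + 1, t])
    return w, dw, d2w


class GridField:
    """C2 interpolant over a :class:`DensityGrid` with analytic derivatives.

    Points must lie at least one voxel inside the lattice; the field never
    extrapolates.
    """

    def __init__(self, grid: DensityGrid):
        self.grid = grid
        self.coeffs = ndimage.spline_filter(grid.values, order=3, mode="mirror")
        # fractional-index transform: r = origin + idx @ axes  =>  idx = (r-o) @ B
        self._B = np.linalg.inv(grid.axes)  # right-multiplication inverse
        # jacobian d idx_k / d r_m = B[m, k]
        self._J = self._B

    @property
    def geometry(self) -> MoleculeGeometry:
        return self.grid.geometry

    def fractional(self, point) -> np.ndarray:
        p = np.asarray(point, dtype=float).reshape(3)
        return (p - self.grid.origin) @ self._B

    def contains(self, point) -> bool:
        u = self.fractional(point)
        return all(1.0 <= u[k] <= self.grid.counts[k] - 2 for k in range(3))

    def probe(self, point) -> DensityProbe:
        u = self.fractional(point)
        n = self.grid.counts
        for k in range(3):
            if not (1.0 <= u[k] <= n[k] - 2):
                raise OutOfDomainError(
                    f"point {np.asarray(point)} maps to fractional index {u} "
                    f"outside the one-voxel-margin domain of a {n} grid"
                )
        base = np.minimum(np.floor(u).astype(int), np.array(n) - 3)
        t = u - base
        W = [_bspline_weights(tk) for tk in t]
        block = self.coeffs[
            base[0] - 1: base[0] + 3,
            base[1] - 1: base[1] + 3,
            base[2] - 1: base[2] + 3,
        ]

        def tensor(d0, d1, d2):
            return float(np.einsum("i,j,k,ijk->", W[0][d0], W[1][d1], W[2][d2], block))

        value = tensor(0, 0, 0)
        g_idx = np.array([tensor(1, 0, 0), tensor(0, 1, 0), tensor(0, 0, 1)])
        h_idx = np.empty((3, 3))
        h_idx[0, 0] = tensor(2, 0, 0)
        h_idx[1, 1] = tensor(0, 2, 0)
        h_idx[2, 2] = tensor(0, 0, 2)
        h_idx[0, 1] = h_idx[1, 0] = tensor(1, 1, 0)
        h_idx[0, 2] = h_idx[2, 0] = tensor(1, 0, 1)
        h_idx[1, 2] = h_idx[2, 1] = tensor(0, 1, 1)

        J = self._J  # d idx / d r (rows: r component, cols: idx component)
        grad = J @ g_idx
        hess = J @ h_idx @ J.T
        hess = 0.5 * (hess + hess.T)  # kill last-bit asymmetry
        return DensityProbe(value=value, gradient=grad, hessian=hess)


def evaluate(field, point) -> DensityProbe:
    """Probe any density field (promolecular, grid wrapper, or raw grid)."""
    if isinstance(field, DensityGrid):
        field = GridField(field)
    return field.probe(point)
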