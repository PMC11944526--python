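# Methods and modelling notes

## Scope and data flow

The package implements the analysis layer that sits downstream of an
electronic-structure code: it never computes SCF densities, orbital energies
or enthalpies. Its inputs are (a) volumetric electron densities in Gaussian
cube format, (b) long-format enthalpy ledgers (one species per row:
`compound, environment, site, species, enthalpy_hartree`), (c) frontier
orbital energies, and (d) BCP parameter tables. Internally everything is in
Hartree and Bohr; kcal/mol, eV and Ångström appear only at report
boundaries (1 Hartree = 627.509 kcal/mol, 1 Bohr = 0.529177 Å,
1 Hartree = 27.2114 eV).

## Promolecular densities

Real SCF densities are expensive to regenerate, so the test bed uses
promolecular fields: sums of spherical single-exponential atomic densities
ρ_atom(r) = a·e^(−r/λ). Amplitudes are normalized so each atom integrates
to Z electrons (a = Z/8πλ³); hydrogen uses the exact ground-state density
(1/π)e^(−2r). The parameters are packaged constants
(`data/radial_params.csv`) — a transparent, analytic stand-in, not fitted
physics. Every derivative is computed in closed form, which makes the
promolecular field the reference oracle for the grid machinery.

What this emulates: the saddle/maximum topology of ρ between bonded and
hydrogen-bonded atoms, with critical points whose positions are known
independently (by symmetry or a dense line scan). What it does not emulate:
charge transfer, lone-pair anisotropy, density relaxation — so tests passing
on promolecular fields validate the *search and arithmetic*, not chemical
accuracy on real molecules.

A Slater-type atom has a density cusp at its nucleus: no smooth (3,−3)
critical point exists there, and a Newton iteration cannot converge onto it.
Two provisions follow. The generator also offers a Gaussian radial form
(a·e^(−r²/λ²)), smooth at the nucleus, for which nuclear maxima are genuine
critical points; and for Slater fields the search reports a conventional
nuclear-attractor record (rank 3, signature −3) whenever an iterate falls
within a 0.05 Bohr capture radius of a nucleus. At an exact nuclear
coincidence the cusp is regularized with a negative-definite curvature of
natural scale a/λ² so that probes remain well-defined.

## Grid interpolation

Cube densities are interpolated with a tensor-product cubic B-spline
(coefficients by `scipy.ndimage.spline_filter`, mirror boundaries). The
interpolant passes through the grid values and is C², so the Newton search
sees continuous Hessians; gradients and Hessians are obtained by
differentiating the spline basis analytically and mapping through the
(possibly skewed) voxel axes. Points must lie at least one voxel inside the
lattice — the field never extrapolates, and no positivity clamp is applied
(the suite checks that interpolated values never undershoot zero by more
than 1e−12 on its fixtures). Self-consistency of the analytic derivatives is
checked against central differences at step 1e−3 Bohr; the comparison floor
of ~1e−6 absolute is the h² truncation error of the difference scheme
itself.

## Critical-point search

Newton iteration on ∇ρ with the exact (analytic or spline) Hessian,
convergence at ‖∇ρ‖ < 1e−8 a.u. within 200 steps, steps capped at 1 Bohr
and halved whenever a trial point leaves the domain or reaches non-positive
density. Rank and signature come from the Hessian eigenvalues with an
eigenvalue threshold of 1e−10; rank-deficient stationary points raise a
degenerate-critical-point error, and non-convergence raises an error
carrying the last iterate and gradient norm. Search seeds are midpoints of
H⋯acceptor pairs prescreened geometrically (distance < 3.5 Å, donor angle
> 90°), bounds that comfortably contain all tabulated H-bond geometries
(max length 2.34 Å, min angle ≈ 118°).

## Energy densities and classification

When a table supplies G and v directly, the supplied values take precedence
and the Abramov estimate is only a cross-check (reference G values may be
wavefunction-derived; the density-only estimate agrees with the tabulated
strongest water contact to ≈3e−4 a.u.). The classification thresholds
(ρ cutoff 0.015 a.u. between weak H-bond and van der Waals; |v|/G bounds 1
and 2) are fixed constants exposed in config; they reproduce the reference
classifications of both the moderate intramolecular H-bond
(ρ = 0.0425, h = −0.0034, |v|/G = 1.1) and the van der Waals radical–water
contact (ρ = 0.0121, h = +0.0012).

Two BE ~ ρ coefficient sets ship, deliberately labeled. The default
(−223.08, 0.7423) reproduces the intramolecular-contact estimate
(ρ = 0.0425 → −8.74 ≈ −8.7 kcal/mol) but *not* the solvent-interaction BE
column of the packaged topology table; a least-squares fit over those 25
rows recovers the steeper regression actually behind that column
(≈ −332.4 ρ − 1.06, max residual 0.02 kcal/mol). The package never presents
default-regression output as matching the tabulated column.

Report tables round half-away-from-zero (a.u. columns at 4 decimals, |v|/G
at 1, BE at 2) in table-matching mode; note that a ratio of 0.851 prints as
"0.9" under this convention.

## MEP, MPI and polar area

The electronic term of V(r) uses midpoint quadrature over voxels (chunked to
a fixed pairwise-workspace budget) for grids and exact Coulomb sums for
point-charge electron stand-ins; points within 0.05 Bohr of a nucleus are
rejected. Quadrature accuracy is validated against the closed form
V = −erf(√α r)/r of a unit spherical Gaussian cloud (≤1e−4 a.u. at exterior
points on an 81³ grid). The molecular polarity index is the area-weighted
mean of |V| over a marching-cubes isosurface of the density, default
isovalue 4.0e−4 electrons/Bohr³; triangle areas come from the transformed
vertices and V is evaluated at triangle centroids. The polar-area threshold
is explicit config, defaulting to the surface mean of |V| itself — published
polar-area percentages depend on an unstated criterion, so no fixed
threshold is hard-coded. MPI values from promolecular densities exercise the
pipeline but are not comparable to SCF-density MPI values (neutral spherical
atoms carry no bond polarity).

## Mechanism thermodynamics

The H•/H⁺/e⁻ reference enthalpies are required explicit inputs, never baked
in: published tables rarely state them, and different bookkeeping
conventions circulate. The packaged luteolin reference ledgers place H• at
−0.5 Hartree and fix H⁺ so that (PA+ETE) − BDE equals the 2.989 kcal/mol
offset the reference mechanism table carries on every row; the IP split is
an arbitrary plausible constant (only BDE and the sums are meaningful
there). Two genuine inconsistencies of the reference table are preserved,
flagged, and not corrected: the tabulated IP+PDE exceeds PA+ETE by a
constant ≈0.071 kcal/mol on luteolin rows although the sums are
algebraically identical, and the BHT/TBHQ rows carry (IP+PDE) − BDE offsets
(8.8, 14.3 kcal/mol) wildly different from every other compound.

Dispersion statistics use the sample (n−1) standard deviation — the
population convention gives ≈4.37/4.68 kcal/mol for the luteolin BDE
columns and is inconsistent with the reference values 5.04/5.40. Percent
changes are relative to the no-water/reference value. One reported figure
deserves a note: the exact SD percent change of the luteolin columns is
7.0661%, which the reference prints truncated as 7.06 (half-away rounding
would give 7.07); the package reports the computed value. Mechanism
preference is purely enthalpic (argmin over BDE, IP+PDE, PA+ETE of the
per-mechanism minima; site preference is argmin BDE), with ties at
1e−9 kcal/mol flagged rather than silently broken.

## Synthetic ledgers

`make_ledger` inverts the mechanism equations: given per-site BDE/IP/PA
targets (kcal/mol) and a reference triple, it draws a base H(AH) from the
seed and places the radical/cation/anion enthalpies so the targets are
recovered to better than 1e−10 kcal/mol; PDE and ETE then follow from the
identities. All generators are pure functions of (parameters, seed).

## Problem sizes

Test and analysis grids are 21³–41³ voxels and quadrature uses ≤1e6 voxel
centers per evaluation batch; these sizes keep every oracle comparison
(line scans at 10⁴ samples, erf closed forms, extended-precision arithmetic)
exact to the tolerances above while the whole suite runs in seconds.

## Known limitations

- No wavefunction formats (wfn/wfx), no Gaussian log/fchk parsing, no spin
  densities, no basin integration or atomic charges, no ring/cage searching
  beyond signature reporting.
- Orbital cubes are read only in the single-orbital case.
- The NBO module implements the E(2) arithmetic only; Fock elements and
  orbital energies must be supplied (reference tables print E(2) without
  them, so those rows are data, not recomputable results).
- Docking and pharmacophore stages of antioxidant pipelines are out of
  scope.
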