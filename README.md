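# antioxdft

Post-quantum-chemistry analysis toolkit for phenolic antioxidant studies,
built around the flavone **luteolin**: QTAIM bond-critical-point topology and
hydrogen-bond energetics, conceptual-DFT reactivity descriptors, molecular
electrostatic potential (MEP) polarity metrics, NBO second-order perturbation
arithmetic, and the HAT / SET-PT / SPLET free-radical-scavenging
thermodynamics with explicit-water effect statistics.

The quantum-chemistry step itself (geometry optimization, SCF densities,
enthalpies at M06-2X/6-311++G(d,p)) is *not* performed here. This package is
everything that comes after it: it consumes volumetric densities (Gaussian
cube files), enthalpy ledgers and orbital/BCP tables, and it ships analytic
promolecular densities plus inverse-constructed ledgers so that every stage
is fully testable on a desktop.

## Who it is for

Computational chemists analysing radical-scavenging antioxidants who want
the standard post-processing arithmetic — reproducible, unit-safe, and
covered by tests — instead of spreadsheets around Multiwfn/NBO output.

## The science in brief

**QTAIM.** A bond critical point (BCP) is a stationary point of the electron
density ρ(r) with Hessian signature (3,−1). At a BCP the kinetic, potential
and total energy densities obey h = G + v, with G estimated density-only by
the Abramov form G = (3/10)(3π²)^{2/3} ρ^{5/3} + ∇²ρ/6 and v from the local
virial relation v = ¼∇²ρ − 2G. Classification: ∇²ρ > 0, h < 0 and
1 < |v|/G < 2 marks a moderate, partially covalent H-bond; h ≥ 0 with
|v|/G ≤ 1 is purely closed-shell (weak H-bond if ρ ≥ 0.015 a.u., van der
Waals below); |v|/G ≥ 2 or ∇²ρ < 0 is the shared-shell (covalent) regime.
H-bond strength is estimated from the density by the linear regression
BE ≈ −223.08 ρ + 0.7423 kcal/mol.

**Conceptual DFT.** From frontier orbital energies, I ≈ −E_HOMO,
A ≈ −E_LUMO, hardness η = (I−A)/2, chemical potential μ = −(I+A)/2 = −χ,
electrophilicity ω = μ²/2η. The MEP
V(r) = Σ_α Z_α/|r_α−r| − ∫ ρ(r′)/|r′−r| dr′ is evaluated by exact Coulomb
sums (point charges) or voxel quadrature (grids); the molecular polarity
index is the area-weighted mean of |V| over a density isosurface.

**Mechanism thermodynamics.** Per phenolic site (kcal/mol):
BDE = H(A•) + H(H•) − H(AH) (HAT);
IP = H([AH•]⁺) + H(e⁻) − H(AH), PDE = H(A•) + H(H⁺) − H([AH•]⁺) (SET-PT);
PA = H([A:]⁻) + H(H⁺) − H(AH), ETE = H(A•) + H(e⁻) − H([A:]⁻) (SPLET).
IP+PDE ≡ PA+ETE algebraically, and both exceed BDE by a site-independent
constant fixed by the H•/H⁺/e⁻ references — identities the test suite
enforces exactly.

## Worked example

```python
from antioxdft.fixtures import SITES, luteolin_reference_ledger
from antioxdft.thermo import bde, mechanism_summary, water_effect

dry = luteolin_reference_ledger(with_water=False)
wet = luteolin_reference_ledger(with_water=True)
print(mechanism_summary(dry).preferred_site,
      mechanism_summary(dry).preferred_mechanism)
stats = water_effect([bde(dry, s) for s in SITES],
                     [bde(wet, s) for s in SITES], sites=SITES)
print(f"mean BDE shift {stats.mean_percent_change:+.2f}%, "
      f"SD {stats.sd_without:.2f} -> {stats.sd_with:.2f} kcal/mol "
      f"({stats.sd_percent_change:+.2f}%)")
```

prints

```
O3-H HAT
mean BDE shift +0.75%, SD 5.04 -> 5.40 kcal/mol (+7.07%)
```

i.e. hydrogen-atom transfer from the catechol 3-OH group (lowest BDE,
80.662 kcal/mol) is the thermodynamically preferred scavenging channel;
explicit water molecules barely move the average dissociation cost but widen
the spread across sites by ~7%.

The numbered drivers under `analysis/` run the full stages and write their
tables under `results/`:

```bash
python analysis/01_qtaim_topology.py        # BCP search + topology audit
python analysis/02_reactivity_descriptors.py  # descriptors + MEP polarity
python analysis/03_antioxidant_mechanisms.py  # mechanisms + water effect
```

A `antioxdft` console command exposes the same stages
(`qtaim`, `descriptors`, `mechanism`, `fixtures`) for file-based pipelines.

## Layout

- `src/antioxdft/` — the library: `model`/`io` (types, cube + table I/O),
  `density` (promolecular + B-spline grid fields), `qtaim` (BCP search,
  energy densities, classification), `descriptors` (conceptual DFT, MEP,
  polarity), `thermo` (mechanisms, water effect), `nbo` (E(2)),
  `fixtures` (generators + packaged reference tables), `cli`/`config`.
- `analysis/` — narrative drivers; `tests/` — pytest suite;
  `docs/methods.md` — modelling assumptions and numerical choices.
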