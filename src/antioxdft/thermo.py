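"""Free-radical scavenging thermodynamics: HAT / SET-PT / SPLET descriptors,
solvent enthalpy shifts, and the explicit-water effect statistics.

For an antioxidant AH with phenolic site enthalpies in Hartree, the three
mechanisms are quantified (in kcal/mol) by

* HAT:     BDE = H(A*) + H(H*) - H(AH)
* SET-PT:  IP  = H([AH*]+) + H(e-) - H(AH);  PDE = H(A*) + H(H+) - H([AH*]+)
* SPLET:   PA  = H([A:]-) + H(H+) - H(AH);   ETE = H(A*) + H(e-) - H([A:]-)

IP + PDE and PA + ETE are algebraically identical (both equal
H(A*) + H(H+) + H(e-) - H(AH)), and (IP + PDE) - BDE is a site-independent
constant fixed by the H*/H+/e- reference enthalpies. The thermodynamically
preferred mechanism is the one whose total enthalpy demand is lowest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import EnthalpyLedger
from .units import HARTREE_TO_KCAL

__all__ = [
    "MechanismTable",
    "WaterEffectStats",
    "bde",
    "ip",
    "pde",
    "pa",
    "ete",
    "relative_solution_enthalpy",
    "percent_difference",
    "water_effect",
    "mechanism_summary",
]

MECHANISMS = ("HAT", "SET-PT", "SPLET")


def bde(ledger: EnthalpyLedger, site: str) -> float:
    """Homolytic O-H bond dissociation enthalpy, kcal/mol."""
    return (
        ledger.enthalpy(site, "A_radical")
        + ledger.reference("H_radical")
        - ledger.enthalpy(site, "AH")
    ) * HARTREE_TO_KCAL


def ip(ledger: EnthalpyLedger, site: str) -> float:
    """Adiabatic ionization potential (first SET-PT step), kcal/mol."""
    return (
        ledger.enthalpy(site, "cation")
        + ledger.reference("electron")
        - ledger.enthalpy(site, "AH")
    ) * HARTREE_TO_KCAL


def pde(ledger: EnthalpyLedger, site: str) -> float:
    """Proton dissociation enthalpy of the radical cation, kcal/mol."""
    return (
        ledger.enthalpy(site, "A_radical")
        + ledger.reference("proton")
        - ledger.enthalpy(site, "cation")
    ) * HARTREE_TO_KCAL


def pa(ledger: EnthalpyLedger, site: str) -> float:
    """Proton affinity (first SPLET step), kcal/mol."""
    return (
        ledger.enthalpy(site, "anion")
        + ledger.reference("proton")
        - ledger.enthalpy(site, "AH")
    ) * HARTREE_TO_KCAL


def ete(ledger: EnthalpyLedger, site: str) -> float:
    """Electron transfer enthalpy of the anion (second SPLET step), kcal/mol."""
    return (
        ledger.enthalpy(site, "A_radical")
        + ledger.reference("electron")
        - ledger.enthalpy(site, "anion")
    ) * HARTREE_TO_KCAL


def relative_solution_enthalpy(h_solution: float, h_vacuum: float) -> float:
    """Solvation enthalpy shift dH = H(solution) - H(vacuum), kcal/mol from
    Hartree inputs."""
    return (h_solution - h_vacuum) * HARTREE_TO_KCAL


def percent_difference(value: float, reference: float) -> float:
    """100 * (value - reference) / reference."""
    if reference == 0:
        raise ZeroDivisionError("percent difference needs a nonzero reference")
    return 100.0 * (value - reference) / reference


@dataclass(frozen=True)
class WaterEffectStats:
    """How explicit water molecules shift the per-site BDEs.

    Standard deviations are the sample (n-1) convention; percent changes are
    relative to the without-water values.
    """

    sites: tuple[str, ...]
    bde_without: np.ndarray
    bde_with: np.ndarray
    site_percent_change: np.ndarray
    mean_percent_change: float
    sd_without: float
    sd_with: float
    sd_percent_change: float


def water_effect(bde_no_water, bde_water, sites=None) -> WaterEffectStats:
    """Per-site and aggregate statistics of the explicit-water BDE shift."""
    a = np.asarray(bde_no_water, dtype=float).reshape(-1)
    b = np.asarray(bde_water, dtype=float).reshape(-1)
    if len(a) != len(b):
        raise ValueError(f"BDE vectors differ in length ({len(a)} vs {len(b)})")
    if len(a) < 2:
        raise ValueError("need at least two sites for dispersion statistics")
    if sites is None:
        sites = tuple(f"site{i + 1}" for i in range(len(a)))
    site_pc = 100.0 * (b - a) / a
    mean_pc = percent_difference(b.mean(), a.mean())
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    return WaterEffectStats(
        sites=tuple(sites), bde_without=a, bde_with=b,
        site_percent_change=site_pc, mean_percent_change=float(mean_pc),
        sd_without=sd_a, sd_with=sd_b,
        sd_percent_change=float(percent_difference(sd_b, sd_a)),
    )


@dataclass(frozen=True)
class MechanismTable:
    """Per-site mechanism descriptors with preference verdicts."""

    compound: str
    environment: str
    table: pd.DataFrame  # index: site; columns: bde, ip, pde, pa, ete, ip_plus_pde, pa_plus_ete
    preferred_site: str
    preferred_mechanism: str
    site_tie: bool
    mechanism_tie: bool


_TIE_TOL = 1e-9  # kcal/mol


def mechanism_summary(ledger: EnthalpyLedger, sites=None) -> MechanismTable:
    """Compute all descriptors for each site and pick the preferred site
    (argmin BDE) and mechanism (argmin over the per-mechanism minima of BDE,
    IP+PDE, PA+ETE). Ties go to the earliest site / to HAT order, flagged."""
    if sites is None:
        sites = ledger.sites
    gaps = []
    for s in sites:
        for sp in ("AH", "A_radical", "cation", "anion"):
            if sp not in ledger.site_enthalpies.get(s, {}):
                gaps.append(f"{s}/{sp}")
    for sp in ("H_radical", "proton", "electron"):
        if sp not in ledger.references:
            gaps.append(f"reference/{sp}")
    if gaps:
        raise KeyError(
            f"{ledger.compound}/{ledger.environment}: incomplete ledger, "
            f"missing {', '.join(gaps)}"
        )
    rows = {}
    for s in sites:
        vals = {
            "bde": bde(ledger, s), "ip": ip(ledger, s), "pde": pde(ledger, s),
            "pa": pa(ledger, s), "ete": ete(ledger, s),
        }
        vals["ip_plus_pde"] = vals["ip"] + vals["pde"]
        vals["pa_plus_ete"] = vals["pa"] + vals["ete"]
        rows[s] = vals
    df = pd.DataFrame.from_dict(rows, orient="index")

    bdes = df["bde"].to_numpy()
    best = int(np.argmin(bdes))
    site_tie = bool(np.sum(np.abs(bdes - bdes[best]) < _TIE_TOL) > 1)

    mech_minima = np.array([
        df["bde"].min(), df["ip_plus_pde"].min(), df["pa_plus_ete"].min(),
    ])
    mbest = int(np.argmin(mech_minima))
    mech_tie = bool(np.sum(np.abs(mech_minima - mech_minima[mbest]) < _TIE_TOL) > 1)

    return MechanismTable(
        compound=ledger.compound, environment=ledger.environment, table=df,
        preferred_site=list(sites)[best], preferred_mechanism=MECHANISMS[mbest],
        site_tie=site_tie, mechanism_tie=mech_tie,
    )
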