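"""Mechanism thermodynamics: enthalpy differences, algebraic identities,
water-effect statistics, preference verdicts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from antioxdft.fixtures import SITES, make_ledger, luteolin_reference_ledger
from antioxdft.model import EnthalpyLedger
from antioxdft.thermo import (bde, ete, ip, mechanism_summary, pa, pde,
                              percent_difference, relative_solution_enthalpy,
                              water_effect)
from antioxdft.units import HARTREE_TO_KCAL


def _ledger(seed=0):
    rng = np.random.default_rng(seed)
    sites = {}
    for s in ("O1-H", "O2-H", "O3-H"):
        h_ah = -1000 + rng.normal()
        sites[s] = {
            "AH": h_ah,
            "A_radical": h_ah + 0.13 + 0.01 * rng.random(),
            "cation": h_ah + 0.25 + 0.01 * rng.random(),
            "anion": h_ah + 0.05 + 0.01 * rng.random(),
        }
    refs = {"H_radical": -0.5, "proton": -0.49, "electron": -0.01}
    return EnthalpyLedger("synthetic", "model", sites, refs)


class TestDescriptorArithmetic:
    def test_bde_hand_arithmetic(self):
        led = EnthalpyLedger("x", "v",
                             {"s": {"AH": -1000.0, "A_radical": -999.4}},
                             {"H_radical": -0.5})
        assert bde(led, "s") == pytest.approx(0.1 * HARTREE_TO_KCAL, abs=1e-9)
        assert bde(led, "s") == pytest.approx(62.7509, abs=1e-6)

    def test_thermoneutral_bde_is_zero(self):
        led = EnthalpyLedger("x", "v",
                             {"s": {"AH": -1000.0, "A_radical": -999.5}},
                             {"H_radical": -0.5})
        assert bde(led, "s") == pytest.approx(0.0, abs=1e-9)

    def test_zero_cost_ionization(self):
        led = EnthalpyLedger("x", "v", {"s": {"AH": -1000.0, "cation": -1000.0}},
                             {"electron": 0.0})
        assert ip(led, "s") == 0.0

    def test_missing_species_error_names_site_and_species(self):
        led = _ledger()
        del led.site_enthalpies["O2-H"]["cation"]
        with pytest.raises(KeyError, match="cation.*O2-H|O2-H.*cation"):
            ip(led, "O2-H")

    @pytest.mark.parametrize("seed", range(10))
    def test_setpt_and_splet_sums_identical(self, seed):
        led = _ledger(seed)
        for s in led.sites:
            lhs = ip(led, s) + pde(led, s)
            rhs = pa(led, s) + ete(led, s)
            assert abs(lhs - rhs) < 1e-10

    @pytest.mark.parametrize("seed", range(10))
    def test_sum_minus_bde_constant_across_sites(self, seed):
        led = _ledger(seed)
        refs = led.references
        expected = (refs["proton"] + refs["electron"]
                    - refs["H_radical"]) * HARTREE_TO_KCAL
        offsets = [ip(led, s) + pde(led, s) - bde(led, s) for s in led.sites]
        assert np.ptp(offsets) < 1e-10
        assert offsets[0] == pytest.approx(expected, abs=1e-9)


class TestSolventShift:
    def test_equal_enthalpies_give_zero(self):
        assert relative_solution_enthalpy(-1000.0, -1000.0) == 0.0

    def test_millihartree_stabilization(self):
        assert relative_solution_enthalpy(-1000.001, -1000.0) == pytest.approx(
            -0.627509, abs=1e-9)

    def test_order_preserving_over_solvent_series(self):
        h_vac = -1000.0
        shifts = [relative_solution_enthalpy(h_vac - d * 1e-3, h_vac)
                  for d in (0.2, 0.5, 1.1, 2.3)]
        assert shifts == sorted(shifts, reverse=True)


class TestPercentDifference:
    @pytest.mark.parametrize("value,reference,expected", [
        (83.605, 80.662, 3.649),   # O4-H vs O3-H dissociation cost
        (88.072, 80.662, 9.187),   # O1-H vs O3-H
        (92.153, 80.662, 14.246),  # O2-H vs O3-H
    ])
    def test_site_comparisons(self, value, reference, expected):
        assert percent_difference(value, reference) == pytest.approx(expected, abs=1e-3)

    def test_identity_is_zero(self):
        assert percent_difference(42.0, 42.0) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_difference(1.0, 0.0)


class TestWaterEffect:
    def test_reference_bde_columns_reproduce_printed_statistics(self, tables):
        t3 = tables["table3"]
        lut = t3[t3["compound"] == "luteolin"]
        stats = water_effect(lut["bde_no_water"], lut["bde_water"],
                             sites=lut["site"])
        assert stats.mean_percent_change == pytest.approx(0.75, abs=5e-3)
        assert stats.sd_without == pytest.approx(5.04, abs=5e-3)
        assert stats.sd_with == pytest.approx(5.40, abs=5e-3)
        # the published 7.06 truncates the exact 7.0661
        assert stats.sd_percent_change == pytest.approx(7.06, abs=1e-2)
        by_site = dict(zip(stats.sites, stats.site_percent_change))
        assert by_site["O3-H"] == pytest.approx(2.60, abs=5e-3)
        assert by_site["O1-H"] == pytest.approx(0.69, abs=5e-3)
        assert by_site["O4-H"] == pytest.approx(-1.80, abs=5e-3)

    def test_identical_vectors_give_all_zero_changes(self):
        v = [80.0, 85.0, 90.0]
        stats = water_effect(v, v)
        assert np.allclose(stats.site_percent_change, 0.0)
        assert stats.mean_percent_change == 0.0
        assert stats.sd_without == stats.sd_with

    def test_matches_direct_formula_recomputation(self, rng):
        a = rng.uniform(75, 95, size=6)
        b = a + rng.normal(0, 2, size=6)
        stats = water_effect(a, b)
        mean_pc = 100 * (b.mean() - a.mean()) / a.mean()
        sd_a = np.sqrt(((a - a.mean()) ** 2).sum() / (len(a) - 1))
        sd_b = np.sqrt(((b - b.mean()) ** 2).sum() / (len(b) - 1))
        assert stats.mean_percent_change == pytest.approx(mean_pc, abs=1e-12)
        assert stats.sd_without == pytest.approx(sd_a, abs=1e-12)
        assert stats.sd_with == pytest.approx(sd_b, abs=1e-12)
        assert stats.sd_percent_change == pytest.approx(
            100 * (sd_b - sd_a) / sd_a, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            water_effect([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_sample_not_population_convention(self, tables):
        """Population (n) standard deviations would give ~4.37/4.68, far from
        the tabulated values; only the sample (n-1) convention matches."""
        t3 = tables["table3"]
        lut = t3[t3["compound"] == "luteolin"]
        pop_sd = lut["bde_no_water"].to_numpy().std(ddof=0)
        assert pop_sd == pytest.approx(4.37, abs=5e-3)
        assert abs(pop_sd - 5.04) > 0.5


class TestMechanismSummary:
    def test_reference_ledger_prefers_hat_at_catechol_site(self):
        led = luteolin_reference_ledger()
        summ = mechanism_summary(led)
        assert summ.preferred_site == "O3-H"
        assert summ.preferred_mechanism == "HAT"
        assert not summ.site_tie and not summ.mechanism_tie
        assert summ.table.loc["O3-H", "bde"] == pytest.approx(80.662, abs=1e-9)
        assert summ.table["pa_plus_ete"].to_numpy() == pytest.approx(
            [91.061, 95.142, 83.651, 86.594], abs=1e-3)

    def test_all_mechanisms_equal_sets_tie_flag(self):
        # thermoneutral everything: BDE = IP+PDE = PA+ETE = 0
        led = make_ledger({"s1": {"BDE": 0.0, "IP": 0.0, "PA": 0.0}},
                          references={"H_radical": -0.5, "proton": -0.5,
                                      "electron": 0.0})
        summ = mechanism_summary(led)
        assert summ.mechanism_tie

    def test_incomplete_ledger_lists_gaps(self):
        led = _ledger()
        del led.site_enthalpies["O3-H"]["anion"]
        with pytest.raises(KeyError, match="O3-H/anion"):
            mechanism_summary(led)

    @pytest.mark.parametrize("seed", range(20))
    def test_argmin_agrees_with_exhaustive_comparison(self, seed):
        rng = np.random.default_rng(seed + 1000)
        targets = {f"s{i}": {"BDE": float(rng.uniform(70, 100)),
                             "IP": float(rng.uniform(150, 200)),
                             "PA": float(rng.uniform(30, 60))}
                   for i in range(4)}
        led = make_ledger(targets, seed=seed)
        summ = mechanism_summary(led)
        best_site = min(targets, key=lambda s: targets[s]["BDE"])
        assert summ.preferred_site == best_site
        minima = {"HAT": summ.table["bde"].min(),
                  "SET-PT": summ.table["ip_plus_pde"].min(),
                  "SPLET": summ.table["pa_plus_ete"].min()}
        assert summ.preferred_mechanism == min(minima, key=minima.get)


class TestLedgerInverseConstruction:
    @pytest.mark.parametrize("seed", range(10))
    def test_targets_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        targets = {f"s{i}": {"BDE": float(rng.uniform(-50, 150)),
                             "IP": float(rng.uniform(-50, 250)),
                             "PA": float(rng.uniform(-50, 80))}
                   for i in range(3)}
        led = make_ledger(targets, seed=seed)
        for s, tgt in targets.items():
            assert abs(bde(led, s) - tgt["BDE"]) < 1e-10
            assert abs(ip(led, s) - tgt["IP"]) < 1e-10
            assert abs(pa(led, s) - tgt["PA"]) < 1e-10

    def test_zero_targets_give_thermoneutral_ledger(self):
        led = make_ledger({"s": {"BDE": 0.0, "IP": 0.0, "PA": 0.0}},
                          references={"H_radical": -0.5, "proton": -0.5,
                                      "electron": 0.0})
        assert bde(led, "s") == pytest.approx(0.0, abs=1e-10)
        assert ip(led, "s") == pytest.approx(0.0, abs=1e-10)
        assert pa(led, "s") == pytest.approx(0.0, abs=1e-10)
        assert pde(led, "s") == pytest.approx(0.0, abs=1e-10)
        assert ete(led, "s") == pytest.approx(0.0, abs=1e-10)

    def test_same_spec_and_seed_reproduce_identical_ledger(self):
        targets = {s: {"BDE": 80.0 + i, "IP": 170.0, "PA": 40.0}
                   for i, s in enumerate(SITES)}
        a = make_ledger(targets, seed=7)
        b = make_ledger(targets, seed=7)
        assert a.site_enthalpies == b.site_enthalpies

    def test_reference_ledger_bdes_match_printed_column(self):
        led = luteolin_reference_ledger(with_water=True)
        got = [bde(led, s) for s in SITES]
        assert got == pytest.approx([88.681, 93.544, 82.757, 82.096], abs=1e-9)


@given(st.integers(0, 10_000))
def test_mechanism_sum_identity_property(seed):
    """IP + PDE == PA + ETE for any ledger, by construction of the cycle."""
    rng = np.random.default_rng(seed)
    targets = {"s": {"BDE": float(rng.uniform(-100, 200)),
                     "IP": float(rng.uniform(-100, 300)),
                     "PA": float(rng.uniform(-100, 100))}}
    led = make_ledger(targets, seed=seed)
    assert abs((ip(led, "s") + pde(led, "s"))
               - (pa(led, "s") + ete(led, "s"))) < 1e-9
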