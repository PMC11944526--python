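"""Critical-point search, topological energy densities, interaction
classification and binding-energy regression."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from antioxdft.fixtures import make_diatomic_density
from antioxdft.density import GridField
from antioxdft.qtaim import (BE_REGRESSION_DEFAULT, InteractionCategory,
                             InteractionRecord, TopologicalParameters,
                             abramov_G, classify_interaction, energy_density_h,
                             estimate_BE, find_bcp, fit_be_coefficients,
                             interaction_table, seed_pairs, virial_v)


class TestFindBcp:
    def test_symmetric_diatomic_saddle_at_midpoint(self, hh_diatomic):
        cp = find_bcp(hh_diatomic.density, [0.1, -0.1, 0.2])
        assert np.linalg.norm(cp.position) < 1e-6
        assert (cp.rank, cp.signature) == (3, -1)
        assert cp.kind == "bond"
        assert cp.grad_norm < 1e-8

    def test_midpoint_on_perpendicular_bisector(self, hh_diatomic):
        cp = find_bcp(hh_diatomic.density, [0.3, 0.2, -0.4])
        assert abs(cp.position[2]) < 1e-6  # bisector plane of a homonuclear pair

    def test_unequal_atoms_match_line_scan_oracle(self):
        fx = make_diatomic_density(("H", "H"), separation=3.0,
                                   amplitudes=(2.0, 1.0), decays=(0.5, 0.5))
        assert fx.method == "line_scan"
        cp = find_bcp(fx.density, [0.05, 0.02, 0.3])
        assert abs(cp.position[2] - fx.reference_bcp[2]) < 1e-4
        assert (cp.rank, cp.signature) == (3, -1)

    def test_nuclear_guess_reports_attractor_not_bcp(self):
        fx = make_diatomic_density(("H", "H"), separation=3.0, form="gaussian")
        cp = find_bcp(fx.density, [0.0, 0.0, 1.5])
        assert cp.signature == -3
        assert cp.kind == "attractor"

    def test_slater_cusp_capture_reports_nuclear_attractor(self, hh_diatomic):
        cp = find_bcp(hh_diatomic.density, [0.02, 0.0, 1.47])
        assert cp.signature == -3
        assert cp.is_nuclear_attractor

    def test_grid_field_search_agrees_with_analytic(self, hh_diatomic, hh_grid):
        cp_grid = find_bcp(GridField(hh_grid), [0.1, -0.05, 0.2])
        cp_ana = find_bcp(hh_diatomic.density, [0.1, -0.05, 0.2])
        assert np.linalg.norm(cp_grid.position - cp_ana.position) < 5e-3
        assert cp_grid.signature == -1


class TestEnergyDensities:
    def test_abramov_first_term_vanishes_at_zero_density(self):
        assert abramov_G(0.0, 0.06) == pytest.approx(0.01, abs=1e-15)

    def test_abramov_reproduces_tabulated_G_within_model_error(self):
        # density-only estimate vs the wavefunction value 0.0346 for the
        # strongest luteolin-water contact
        G = abramov_G(0.0389, 0.1314)
        assert G == pytest.approx(0.0346, abs=3e-4)

    def test_abramov_extended_precision_oracle(self):
        from decimal import Decimal, getcontext
        getcontext().prec = 50
        rho, lap = 0.0222, 0.0952
        c = Decimal(3) / Decimal(10) * (Decimal(3) * Decimal(str(np.pi)) ** 2) ** (
            Decimal(2) / Decimal(3))
        expected = float(c * Decimal(rho) ** (Decimal(5) / Decimal(3))
                         + Decimal(lap) / 6)
        assert abramov_G(rho, lap) == pytest.approx(expected, abs=1e-12)

    def test_abramov_rejects_negative_density(self):
        with pytest.raises(ValueError):
            abramov_G(-0.01, 0.1)

    def test_virial_balance_point(self):
        lap = 0.08
        assert virial_v(lap / 8.0, lap) == pytest.approx(0.0, abs=1e-15)

    def test_virial_matches_tabulated_row(self):
        assert virial_v(0.0346, 0.1314) == pytest.approx(-0.0363, abs=2e-4)

    @given(G=st.floats(0, 1), lap=st.floats(-1, 1))
    def test_virial_identity(self, G, lap):
        v = virial_v(G, lap)
        assert abs(v + 2 * G - 0.25 * lap) < 1e-15

    @pytest.mark.parametrize("G,v,expected", [
        (0.0346, -0.0363, -0.0017),   # strongest water contact
        (0.0429, -0.0484, -0.0055),   # strongest DMSO contact
        (0.02, -0.02, 0.0),
    ])
    def test_energy_density_sum(self, G, v, expected):
        assert energy_density_h(G, v) == pytest.approx(expected, abs=1e-12)


class TestClassification:
    def test_moderate_partial_covalent_hbond(self):
        p = TopologicalParameters(rho=0.0425, laplacian=0.1373,
                                  G=0.0339, v=-0.0373)  # h=-0.0034, ratio 1.1
        assert p.h == pytest.approx(-0.0034, abs=1e-12)
        assert classify_interaction(p) == InteractionCategory.MODERATE_HBOND_PARTIAL_COVALENT

    def test_thin_closed_shell_contact_is_van_der_waals(self):
        p = TopologicalParameters(rho=0.0121, laplacian=0.0457,
                                  G=0.0102, v=-0.0090)  # h=+0.0012, ratio 0.88
        assert classify_interaction(p) == InteractionCategory.VAN_DER_WAALS

    def test_weak_noncovalent_hbond(self):
        p = TopologicalParameters(rho=0.0222, laplacian=0.0952,
                                  G=0.0208, v=-0.0177)
        assert classify_interaction(p) == InteractionCategory.WEAK_HBOND_NONCOVALENT

    def test_shared_shell_regime_is_covalent(self):
        p = TopologicalParameters(rho=0.3, laplacian=-0.5, G=0.05, v=-0.15)
        assert classify_interaction(p) == InteractionCategory.COVALENT

    def test_tabulated_rows_classify_closed_shell(self, tables):
        """Every solvent-contact row has a positive Laplacian, so none may
        classify as covalent."""
        for row in tables["table1"].itertuples():
            p = TopologicalParameters(rho=row.rho, laplacian=row.laplacian,
                                      G=row.G, v=row.v)
            assert classify_interaction(p) != InteractionCategory.COVALENT


class TestBindingEnergy:
    def test_intramolecular_density_gives_printed_value(self):
        assert estimate_BE(0.0425) == pytest.approx(-8.7386, abs=1e-4)

    def test_zero_density_returns_intercept(self):
        assert estimate_BE(0.0) == BE_REGRESSION_DEFAULT[1]

    def test_default_regression_does_not_match_solvent_table(self):
        """The tabulated solvent BE column follows a different regression:
        at rho = 0.0222 the default coefficients give -4.21, far from the
        tabulated -8.43."""
        assert estimate_BE(0.0222) == pytest.approx(-4.21, abs=0.01)

    def test_fitted_coefficients_reproduce_solvent_table(self, tables):
        t1 = tables["table1"]
        slope, intercept = fit_be_coefficients(t1["rho"], t1["be_kcal"])
        assert slope == pytest.approx(-332.4, abs=1.0)
        predicted = slope * t1["rho"] + intercept
        assert np.abs(predicted - t1["be_kcal"]).max() < 0.06

    @given(st.floats(0, 0.2), st.floats(0, 0.2))
    def test_strictly_decreasing_in_density(self, r1, r2):
        if r2 - r1 > 1e-12:  # resolvable separation at double precision
            assert estimate_BE(r1) > estimate_BE(r2)


class TestInteractionTable:
    def _record(self):
        p = TopologicalParameters(rho=0.0222, laplacian=0.0952,
                                  G=0.0208, v=-0.0177)
        return InteractionRecord.from_params("O1...H-Ow", 1.92185, 176.9067, p)

    def test_empty_list_gives_header_only(self):
        df = interaction_table([])
        assert len(df) == 0
        assert "ratio" in df.columns

    def test_ratio_rounds_half_away_to_one_decimal(self):
        df = interaction_table([self._record()], rounding="table")
        # |v|/G = 0.0177/0.0208 = 0.851 -> "0.9" at one decimal
        assert df.loc[0, "ratio"] == pytest.approx(0.9)
        assert df.loc[0, "be_kcal"] == pytest.approx(-4.21)

    def test_h_column_recomputes_from_G_plus_v(self, tables):
        df = interaction_table([self._record()], rounding="full")
        assert df.loc[0, "h"] == pytest.approx(
            df.loc[0, "G"] + df.loc[0, "v"], abs=1e-15)

    def test_category_consistency_enforced(self):
        p = TopologicalParameters(rho=0.0222, laplacian=0.0952,
                                  G=0.0208, v=-0.0177)
        with pytest.raises(ValueError, match="inconsistent"):
            InteractionRecord(label="x", length_angstrom=2.0, angle_deg=170.0,
                              params=p, be_kcal=-4.0,
                              category=InteractionCategory.COVALENT)


class TestSeedPairs:
    def test_diatomic_pairs_prescreened_by_geometry(self):
        from antioxdft.model import AtomSite, MoleculeGeometry
        # O-H covalent donor with an acceptor O at H...A ~ 1.9 A, angle ~ 180
        geom = MoleculeGeometry(atoms=(
            AtomSite("O", np.array([0.0, 0.0, 0.0])),
            AtomSite("H", np.array([0.0, 0.0, 1.83])),
            AtomSite("O", np.array([0.0, 0.0, 5.4])),
        ))
        pairs = seed_pairs(geom)
        assert len(pairs) == 1
        assert pairs[0]["donor"] == 0 and pairs[0]["acceptor"] == 2
        assert pairs[0]["angle_deg"] == pytest.approx(180.0)

    def test_distant_acceptor_filtered(self):
        from antioxdft.model import AtomSite, MoleculeGeometry
        geom = MoleculeGeometry(atoms=(
            AtomSite("O", np.array([0.0, 0.0, 0.0])),
            AtomSite("H", np.array([0.0, 0.0, 1.83])),
            AtomSite("O", np.array([0.0, 0.0, 12.0])),
        ))
        assert seed_pairs(geom) == []
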