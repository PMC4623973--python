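"""Wyman linkage: charge curves, profile integration, closed-form and exact oracles."""

import numpy as np
import pytest

import protolink as pl
from protolink.binding import LN10
from protolink.titration import hill_curve
from tests.conftest import exact_curves

KT = pl.ThermoParams().kT
KT_LN10 = pl.ThermoParams().kT_ln10


def hh_charge(label, pKa, grid):
    """Henderson-Hasselbalch proton-bound curve Z = 1/(1 + 10^(pH - pKa))."""
    grid = np.asarray(grid, float)
    return pl.ChargeCurve(label, grid, 1.0 / (1.0 + 10.0 ** (grid - pKa)))


class TestChargeCurves:
    def test_half_titrated_site(self):
        grid = np.arange(1.0, 13.0)
        c = pl.TitrationCurve("s", grid, np.full(12, 0.5))
        assert np.allclose(pl.charge_curve([c], "P").Z, 0.5)

    def test_fully_deprotonated_sites_carry_no_protons(self):
        grid = np.arange(1.0, 13.0)
        curves = [pl.TitrationCurve(f"s{i}", grid, np.ones(12)) for i in range(10)]
        assert np.allclose(pl.charge_curve(curves, "P").Z, 0.0)

    def test_coupled_dyad_exact_charge(self, dyad_model):
        dist = pl.enumerate_states(dyad_model, 4.0)
        grid = np.array([3.0, 4.0, 5.0])
        curves = []
        for sid in dyad_model.site_ids:
            s = np.array([pl.exact_site_fraction(dyad_model, p, sid) for p in grid])
            curves.append(pl.TitrationCurve(sid, grid, s))
        z = pl.charge_curve(curves, "dyad").Z[1]
        assert z == pytest.approx(dist.mean_protons(), rel=1e-12)
        assert z == pytest.approx(2.02 / 3.01, rel=1e-10)

    def test_mismatched_grids_rejected(self):
        a = pl.TitrationCurve("a", np.arange(1.0, 13.0), np.full(12, 0.5))
        b = pl.TitrationCurve("b", np.arange(2.0, 14.0), np.full(12, 0.5))
        with pytest.raises(ValueError, match="grid"):
            pl.charge_curve([a, b], "P")


class TestDeltaZ:
    def test_identical_species_give_zero(self):
        grid = np.arange(1.0, 13.0)
        z = hh_charge("P", 5.0, grid)
        assert np.allclose(pl.delta_z(z, z).dZ, 0.0)

    def test_single_site_shift_closed_form(self):
        # pKa 5 -> 9 shift: dZ(7) = 1/(1+10^-2) - 1/(1+10^2)
        grid = np.arange(1.0, 13.0)
        dz = pl.delta_z(hh_charge("PL", 9.0, grid), hh_charge("P", 5.0, grid))
        assert dz.dZ[6] == pytest.approx(0.980198, abs=1e-6)

    def test_saturated_limit_vanishes(self):
        grid = np.array([-22.0, -21.0, -20.0])
        dz = pl.delta_z(hh_charge("PL", 9.0, grid), hh_charge("P", 5.0, grid))
        assert np.all(np.abs(dz.dZ) < 1e-10)


class TestIntegrateProfile:
    def test_zero_dz_gives_flat_profile(self):
        grid = np.arange(1.0, 13.0)
        prof = pl.integrate_profile(
            pl.DeltaZCurve(grid, np.zeros(12)), pl.ReferenceBinding(-9.0, 4.5)
        )
        assert np.allclose(prof.dG, -9.0, atol=1e-12)

    def test_unit_dz_integrates_linearly(self):
        # dZ = 1 over [4.5, 7]: dG(7) - dG(4.5) = kT ln10 * 2.5 ~ 3.432 kcal/mol
        grid = np.linspace(4.5, 7.0, 11)
        prof = pl.integrate_profile(
            pl.DeltaZCurve(grid, np.ones(11)), pl.ReferenceBinding(-9.0, 4.5)
        )
        assert prof.dG[-1] - prof.dG[0] == pytest.approx(KT_LN10 * 2.5, rel=1e-10)
        assert prof.dG[-1] - prof.dG[0] == pytest.approx(3.432, abs=1e-3)

    def test_reference_outside_span_rejected(self):
        grid = np.arange(5.0, 10.0)
        with pytest.raises(ValueError, match="outside"):
            pl.integrate_profile(
                pl.DeltaZCurve(grid, np.zeros(5)), pl.ReferenceBinding(0.0, 2.0)
            )

    def test_no_extrapolation_beyond_span(self):
        grid = np.arange(4.0, 10.0)
        prof = pl.integrate_profile(
            pl.DeltaZCurve(grid, np.zeros(6)), pl.ReferenceBinding(0.0, 4.5)
        )
        with pytest.raises(ValueError, match="extrapolation"):
            prof(12.0)

    def test_matches_single_site_closed_form(self, oracle_grid):
        # numerical linkage integral vs the two-state binding-polynomial ratio
        pKa_F, pKa_C = 5.0, 9.7
        dz = pl.delta_z(
            hh_charge("PL", pKa_C, oracle_grid), hh_charge("P", pKa_F, oracle_grid)
        )
        ref = pl.ReferenceBinding(-13.0, 4.5)
        prof = pl.integrate_profile(dz, ref)
        closed = pl.closed_form_single_site(pKa_F, pKa_C, 0.0, oracle_grid)
        expected = ref.dG_ref + (closed.dG - closed(4.5))
        assert np.max(np.abs(prof.dG - expected)) < 1e-4
        # and the published-scale increment: dG(7) - dG(4.5) ~ +2.59 kcal/mol
        assert prof(7.0) - prof(4.5) == pytest.approx(2.586, abs=2e-3)

    def test_additivity_for_independent_sites(self, oracle_grid):
        # multi-site uncoupled: profile equals the sum of per-site closed forms
        shifts = [(4.0, 6.5), (5.5, 9.0), (9.6, 10.2)]
        z_p = np.zeros(len(oracle_grid))
        z_pl = np.zeros(len(oracle_grid))
        expected = np.zeros(len(oracle_grid))
        for pKa_F, pKa_C in shifts:
            z_p += hh_charge("P", pKa_F, oracle_grid).Z
            z_pl += hh_charge("PL", pKa_C, oracle_grid).Z
            closed = pl.closed_form_single_site(pKa_F, pKa_C, 0.0, oracle_grid)
            expected += closed.dG - closed(4.5)
        prof = pl.integrate_profile(
            pl.DeltaZCurve(np.asarray(oracle_grid, float), z_pl - z_p),
            pl.ReferenceBinding(0.0, 4.5),
        )
        assert np.max(np.abs(prof.dG - expected)) < 1e-4

    def test_path_independence_of_reference(self, oracle_grid):
        dz = pl.delta_z(
            hh_charge("PL", 9.7, oracle_grid), hh_charge("P", 5.0, oracle_grid)
        )
        direct = pl.integrate_profile(dz, pl.ReferenceBinding(-13.0, 4.5))
        via_7 = pl.integrate_profile(
            dz, pl.ReferenceBinding(float(direct(7.0)), 7.0)
        )
        assert abs(via_7(10.0) - direct(10.0)) < 1e-6

    def test_positive_dz_raises_free_energy_monotonically(self, oracle_grid):
        # protons taken up on binding => binding weakens as pH rises
        dz = pl.delta_z(
            hh_charge("PL", 9.7, oracle_grid), hh_charge("P", 5.0, oracle_grid)
        )
        prof = pl.integrate_profile(dz, pl.ReferenceBinding(-13.0, 4.5))
        above = prof.pH >= 4.5
        assert np.all(np.diff(prof.dG[above]) > 0)


class TestClosedForm:
    def test_no_shift_means_no_ph_dependence(self):
        grid = np.arange(1.0, 13.0)
        prof = pl.closed_form_single_site(5.0, 5.0, -7.0, grid)
        assert np.allclose(prof.dG, -7.0, atol=1e-12)

    def test_acidic_plateau(self):
        pKa_F, pKa_C = 5.0, 9.0
        grid = np.array([pKa_F - 15.0, 0.0, 5.0])
        prof = pl.closed_form_single_site(pKa_F, pKa_C, -7.0, grid)
        assert prof.dG[0] == pytest.approx(-7.0 - KT_LN10 * (pKa_C - pKa_F), abs=1e-6)

    def test_basic_plateau_returns_reference_reaction(self):
        prof = pl.closed_form_single_site(5.0, 9.0, -7.0, np.array([20.0, 25.0, 30.0]))
        assert prof.dG[0] == pytest.approx(-7.0, abs=1e-9)


class TestExactProfile:
    def test_identical_models_give_flat_profile(self, dyad_model, oracle_grid):
        prof = pl.exact_profile_from_models(
            dyad_model, dyad_model, pl.ReferenceBinding(-5.0, 4.5), oracle_grid
        )
        assert np.allclose(prof.dG, -5.0, atol=1e-12)

    def test_single_site_pair_equals_closed_form(self, oracle_grid):
        def site(pka, label):
            return pl.validate_model(
                pl.SystemModel(
                    label=label,
                    sites=(pl.SiteSpec("S", "custom", pKa_ref=pka),),
                    conformers=(pl.ConformerSpec("c0"),),
                )
            )

        prof = pl.exact_profile_from_models(
            site(5.0, "P"), site(9.7, "PL"), pl.ReferenceBinding(0.0, 4.5), oracle_grid
        )
        closed = pl.closed_form_single_site(5.0, 9.7, 0.0, oracle_grid)
        rel = (prof.dG - prof(4.5)) - (closed.dG - closed(4.5))
        assert np.max(np.abs(rel)) < 1e-10

    def test_integration_of_exact_fractions_matches_polynomials(
        self, bace_pair, oracle_grid
    ):
        # Eq-by-integration vs binding-polynomial ratio on the enumerable pair
        apo, holo = bace_pair
        ref = pl.ReferenceBinding(-13.0, 4.5)
        dz = pl.delta_z(
            pl.charge_curve(exact_curves(holo, oracle_grid), "PL"),
            pl.charge_curve(exact_curves(apo, oracle_grid), "P"),
        )
        numerical = pl.integrate_profile(dz, ref)
        exact = pl.exact_profile_from_models(apo, holo, ref, oracle_grid)
        assert np.max(np.abs(numerical.dG - exact.dG)) < 1e-3


class TestWymanResiduals:
    def test_integrated_profile_is_self_consistent(self, oracle_grid):
        dz = pl.delta_z(
            hh_charge("PL", 9.7, oracle_grid), hh_charge("P", 5.0, oracle_grid)
        )
        prof = pl.integrate_profile(dz, pl.ReferenceBinding(-13.0, 4.5))
        assert pl.wyman_residuals(prof, dz) < 1e-3

    def test_flat_profile_zero_dz(self):
        grid = np.arange(1.0, 13.0)
        dz = pl.DeltaZCurve(grid, np.zeros(12))
        prof = pl.integrate_profile(dz, pl.ReferenceBinding(0.0, 4.5))
        assert pl.wyman_residuals(prof, dz) == pytest.approx(0.0, abs=1e-12)

    def test_corrupted_profile_detected(self):
        grid = np.arange(4.0, 10.0, 0.5)
        dz = pl.DeltaZCurve(grid, np.zeros(len(grid)))
        dg = np.zeros(len(grid))
        dg[5] += 1.0  # one knot shifted by 1 kcal/mol
        corrupted = pl.BindingProfile(grid, dg, pl.ReferenceBinding(0.0, 4.5))
        assert pl.wyman_residuals(corrupted, dz) > 0.5


class TestFixedStateScenario:
    def test_fixing_identical_curves_changes_nothing(self, oracle_grid):
        grid = np.asarray(oracle_grid, float)
        shared = hill_curve(grid, 6.0, 1.0)
        apo = [
            pl.TitrationCurve("same", grid, shared),
            pl.TitrationCurve("moves", grid, hill_curve(grid, 5.0, 1.0)),
        ]
        holo = [
            pl.TitrationCurve("same", grid, shared),
            pl.TitrationCurve("moves", grid, hill_curve(grid, 9.0, 1.0)),
        ]
        ref = pl.ReferenceBinding(-9.0, 4.5)
        _, dev = pl.fixed_state_profile(apo, holo, {"same": "protonated"}, ref)
        assert np.max(np.abs(dev["deviation"])) < 1e-12

    def test_fixing_all_sites_flattens_profile(self, oracle_grid):
        grid = np.asarray(oracle_grid, float)
        apo = [pl.TitrationCurve("S", grid, hill_curve(grid, 5.0, 1.0))]
        holo = [pl.TitrationCurve("S", grid, hill_curve(grid, 9.0, 1.0))]
        ref = pl.ReferenceBinding(-9.0, 4.5)
        prof, _ = pl.fixed_state_profile(apo, holo, {"S": "protonated"}, ref)
        assert np.allclose(prof.dG, -9.0, atol=1e-12)

    def test_deviation_matches_closed_form_area(self, oracle_grid):
        # fixing a shifted single site: deviation(pH) = -(dG_full(pH) - dG_ref)
        grid = np.asarray(oracle_grid, float)
        pKa_F, pKa_C = 5.0, 9.0
        apo = [pl.TitrationCurve("S", grid, hill_curve(grid, pKa_F, 1.0))]
        holo = [pl.TitrationCurve("S", grid, hill_curve(grid, pKa_C, 1.0))]
        ref = pl.ReferenceBinding(-9.0, 4.5)
        _, dev = pl.fixed_state_profile(apo, holo, {"S": "protonated"}, ref)
        closed = pl.closed_form_single_site(pKa_F, pKa_C, 0.0, grid)
        expected = -(closed.dG - closed(4.5))
        i10 = int(np.argmin(np.abs(grid - 10.0)))
        assert dev["deviation"].iloc[i10] == pytest.approx(expected[i10], abs=1e-4)
        # deviation grows in magnitude with pH above the reference
        above = grid >= 4.5
        assert np.all(np.diff(dev["deviation"].to_numpy()[above]) <= 1e-12)
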