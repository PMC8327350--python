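"""Competing homo/heterodimer equilibrium: solver, populations, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmdimer.equilibrium import (EquilibriumParams, SpeciesFractions,
                                 TitrationPoint, TitrationSeries,
                                 cs_perturbation, fit_titration,
                                 monomer_closed_form,
                                 populations_from_intensities,
                                 solve_equilibrium)
from tmdimer.synthetic import TitrationSimSpec, gen_titration

from oracles import grid_fractions


class TestSolver:
    def test_no_partner_reduces_to_closed_form_quadratic(self):
        p = EquilibriumParams(0.01, 0.02, 0.03)
        fa, _ = solve_equilibrium(p, 0.0125, 0.0)
        a_expected = monomer_closed_form(0.0125, 0.01)
        assert fa.f_mono * 0.0125 == pytest.approx(a_expected, rel=1e-12)
        assert fa.f_het == 0.0

    def test_all_constants_huge_gives_pure_monomer(self):
        p = EquilibriumParams(np.inf, np.inf, np.inf)
        fa, fb = solve_equilibrium(p, 0.0125, 0.05)
        assert fa.f_mono == pytest.approx(1.0)
        assert fb.f_mono == pytest.approx(1.0)

    def test_matches_grid_oracle_on_symmetric_instance(self):
        k = 0.01
        fa, _ = solve_equilibrium(EquilibriumParams(k, k, k), 0.0125, 0.0125)
        oracle = grid_fractions(k, k, k, 0.0125, 0.0125)
        np.testing.assert_allclose(fa.as_array(), oracle, atol=1e-6)

    def test_matches_grid_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            ks = 10.0 ** rng.uniform(-4, 0, 3)
            a_tot, b_tot = 10.0 ** rng.uniform(-3, -1, 2)
            fa, _ = solve_equilibrium(EquilibriumParams(*ks), a_tot, b_tot)
            oracle = grid_fractions(*ks, a_tot, b_tot)
            np.testing.assert_allclose(fa.as_array(), oracle, atol=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        k=st.tuples(*[st.floats(1e-5, 1.0) for _ in range(3)]),
        totals=st.tuples(st.floats(1e-5, 0.2), st.floats(0.0, 0.2)),
    )
    def test_mass_balance_property(self, k, totals):
        p = EquilibriumParams(*k)
        a_tot, b_tot = totals
        fa, fb = solve_equilibrium(p, a_tot, b_tot)
        assert fa.f_mono + fa.f_homo + fa.f_het == pytest.approx(1.0, abs=1e-9)
        assert fb.f_mono + fb.f_homo + fb.f_het == pytest.approx(1.0, abs=1e-9)

    def test_adding_partner_never_raises_homodimer_fraction(self):
        p = EquilibriumParams(0.01, 0.02, 0.005)
        homo = [solve_equilibrium(p, 0.0125, bt)[0].f_homo
                for bt in np.linspace(0, 0.06, 15)]
        assert all(b <= a + 1e-12 for a, b in zip(homo, homo[1:]))

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            solve_equilibrium(EquilibriumParams(1, 1, 1), -0.1, 0.0)


class TestPopulations:
    def _point(self, mono, homo, het, residues=(259, 263)):
        return TitrationPoint(1.0, {r: {"monomer": mono, "homodimer": homo,
                                        "heterodimer": het}
                                    for r in residues})

    def test_equal_dimer_intensities_split_evenly(self):
        est = populations_from_intensities(self._point(0.0, 1.0, 1.0),
                                           denominator="dimer_only")
        assert est.fractions.dimer_relative == pytest.approx(0.5)

    def test_equal_three_states_give_thirds(self):
        est = populations_from_intensities(self._point(2.0, 2.0, 2.0))
        np.testing.assert_allclose(est.fractions.as_array(), [1 / 3] * 3)

    def test_zero_denominator_residue_excluded_with_warning(self):
        point = TitrationPoint(1.0, {
            259: {"monomer": 1.0, "homodimer": 0.0, "heterodimer": 0.0},
            263: {"monomer": 0.0, "homodimer": 1.0, "heterodimer": 1.0},
        })
        with pytest.warns(UserWarning, match="excluded"):
            est = populations_from_intensities(point, residues=(259, 263),
                                               denominator="dimer_only")
        assert est.excluded == [259]
        assert est.fractions.dimer_relative == pytest.approx(0.5)

    def test_noise_free_generator_recovers_solver_truth(self):
        series = gen_titration(TitrationSimSpec(noise_sd=0.0, seed=3))
        for point, truth in zip(series.points, series.truth["fractions"]):
            est = populations_from_intensities(point)
            np.testing.assert_allclose(est.fractions.as_array(),
                                       truth.as_array(), atol=1e-12)


class TestFitTitration:
    def test_noise_free_recovers_heterodimer_constant(self):
        series = gen_titration(TitrationSimSpec(noise_sd=0.0, seed=1))
        fit = fit_titration(series, fixed={"k_aa": 0.01, "k_bb": 0.01})
        assert fit.params.k_ab == pytest.approx(0.01, rel=1e-6)
        assert fit.identifiable

    def test_no_heterodimer_signal_flags_nonidentifiable(self):
        series = gen_titration(TitrationSimSpec(
            params=EquilibriumParams(0.01, 0.01, 1e6), noise_sd=0.0, seed=2))
        fit = fit_titration(series, fixed={"k_aa": 0.01, "k_bb": 0.01})
        assert not fit.identifiable
        assert fit.params.k_ab >= 10.0  # driven to the upper bound

    def test_too_few_points_rejected(self):
        series = gen_titration(TitrationSimSpec(ratios=(0.0, 1.0), seed=0))
        with pytest.raises(ValueError):
            fit_titration(series)


class TestSeriesValidation:
    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            TitrationSeries([TitrationPoint(0.0, {259: {
                "monomer": -1.0, "homodimer": 1.0, "heterodimer": 0.0}})])

    def test_non_increasing_ratios_rejected(self):
        pt = {259: {"monomer": 1.0, "homodimer": 0.0, "heterodimer": 0.0}}
        with pytest.raises(ValueError, match="increasing"):
            TitrationSeries([TitrationPoint(1.0, pt), TitrationPoint(1.0, pt)])


class TestShiftPerturbation:
    @staticmethod
    def _table(rows):
        import pandas as pd
        return pd.DataFrame(rows, columns=["residue", "h_ref", "n_ref",
                                           "h_pert", "n_pert"])

    def test_identical_states_give_zero_everywhere(self):
        tbl = self._table([(259, 8.1, 120.0, 8.1, 120.0),
                           (263, 7.9, 118.0, 7.9, 118.0)])
        out, excluded = cs_perturbation(tbl)
        assert (out["delta"] == 0).all()
        assert not out["flagged"].any()
        assert excluded == []

    def test_flagging_is_strictly_greater_than_threshold(self):
        tbl = self._table([(259, 8.0, 120.0, 8.1, 120.0)])
        out, _ = cs_perturbation(tbl, threshold=0.1)
        assert out.loc[0, "delta"] == pytest.approx(0.1)
        assert not out.loc[0, "flagged"]

    def test_combined_shift_hand_value(self):
        # dH 0.06 ppm, dN 0.5 ppm, weight 0.154:
        # sqrt(0.0036 + 0.005929) = 0.09762
        tbl = self._table([(266, 8.0, 120.0, 8.06, 120.5)])
        out, _ = cs_perturbation(tbl, weight_n=0.154)
        assert out.loc[0, "delta"] == pytest.approx(0.09762, abs=5e-5)

    def test_residue_missing_one_state_listed(self):
        tbl = self._table([(259, 8.0, 120.0, None, None),
                           (263, 8.0, 120.0, 8.2, 121.0)])
        out, excluded = cs_perturbation(tbl)
        assert excluded == [259]
        assert list(out["residue"]) == [263]
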