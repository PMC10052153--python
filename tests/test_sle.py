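"""Liquidus, eutectic and deviation-statistic checks."""
import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import bisect

from camphase import (BinarySystem, FusionProperties, deviation_statistics,
                      eutectic_point, liquidus_temperature, phase_diagram,
                      solubility_rhs)
from camphase.constants import R
from camphase.sle import liquidus_at, stable_liquidus


class TestSolubilityRhs:
    def test_zero_at_melting_point(self, registry):
        fus = registry["NAP"].fusion
        assert solubility_rhs(fus, fus.melting_temperature) == 0.0

    def test_vant_hoff_term_by_hand(self):
        # dCp = 0 leaves only the enthalpic term
        fus = FusionProperties(melting_temperature=429.15,
                               fusion_enthalpy=32.4e3,
                               heat_capacity_difference=0.0)
        expected = -32.4e3 / (R * 400.0) * (1 - 400.0 / 429.15)
        assert solubility_rhs(fus, 400.0) == pytest.approx(expected,
                                                           rel=1e-12)

    def test_closed_form_integrals_match_quadrature(self, registry):
        fus = registry["IND"].fusion
        T, tm, dcp = 380.0, fus.melting_temperature, \
            fus.heat_capacity_difference
        i1 = quad(lambda t: dcp, tm, T)[0]
        i2 = quad(lambda t: dcp / t, tm, T)[0]
        expected = (-fus.fusion_enthalpy / (R * T) * (1 - T / tm)
                    - i1 / (R * T) + i2 / R)
        assert solubility_rhs(fus, T) == pytest.approx(expected, abs=1e-10)

    def test_above_melting_rejected(self, registry):
        fus = registry["IBU"].fusion
        with pytest.raises(ValueError):
            solubility_rhs(fus, fus.melting_temperature + 1.0)


class TestLiquidus:
    def test_pure_endpoint_is_melting_point(self, nap_ind):
        # IND melts at 160.2 C
        t = liquidus_temperature(nap_ind, 1, 1.0)
        assert t == pytest.approx(433.35, abs=1e-12)

    def test_ideal_branch_against_independent_bisection(self, nap_ind):
        fus = nap_ind.fusion(0)
        t_pkg = liquidus_temperature(nap_ind, 0, 0.8, "ideal")
        t_ref = bisect(lambda T: np.log(0.8) - solubility_rhs(fus, T),
                       300.0, fus.melting_temperature - 1e-9, xtol=1e-10)
        assert t_pkg == pytest.approx(t_ref, abs=1e-3)

    def test_ideal_branch_is_partner_independent(self, nap_ind, nap_ibu):
        for x in (0.6, 0.8):
            assert liquidus_temperature(nap_ind, 0, x, "ideal") == \
                pytest.approx(liquidus_temperature(nap_ibu, 0, x, "ideal"),
                              abs=2e-4)

    def test_larger_dcp_lowers_ideal_liquidus(self, registry):
        base = registry["NAP"]
        hot = base.model_copy(update={"fusion": base.fusion.model_copy(
            update={"heat_capacity_difference": 150.0})})
        s1 = BinarySystem(base, registry["IND"])
        s2 = BinarySystem(hot, registry["IND"])
        for x in (0.3, 0.5, 0.7, 0.9):
            assert liquidus_temperature(s2, 0, x, "ideal") < \
                liquidus_temperature(s1, 0, x, "ideal")

    def test_composition_domain(self, nap_ind):
        with pytest.raises(ValueError):
            liquidus_temperature(nap_ind, 0, 0.0)
        with pytest.raises(ValueError):
            liquidus_temperature(nap_ind, 0, 1.2)


class TestEutectic:
    def test_identical_components_symmetric(self, registry):
        s = BinarySystem(registry["NAP"], registry["NAP"])
        e = eutectic_point(s, "ideal")
        assert e.composition == pytest.approx(0.5, abs=1e-6)
        assert e.temperature < registry["NAP"].fusion.melting_temperature

    def test_ideal_agrees_with_brute_force_grid(self, nap_ind):
        e = eutectic_point(nap_ind, "ideal")
        xs = np.arange(0.001, 1.0, 0.001)
        diff = [liquidus_temperature(nap_ind, 0, x, "ideal")
                - liquidus_temperature(nap_ind, 1, 1 - x, "ideal")
                for x in xs]
        x_grid = xs[int(np.argmin(np.abs(diff)))]
        assert abs(e.composition - x_grid) <= 0.001

    def test_newton_and_scan_agree(self, nap_ind):
        a = eutectic_point(nap_ind, "pcsaft", method="newton")
        b = eutectic_point(nap_ind, "pcsaft", method="scan")
        assert a.temperature == pytest.approx(b.temperature, abs=0.01)
        assert a.composition == pytest.approx(b.composition, abs=1e-3)

    def test_below_both_melting_points(self, nap_ibu):
        e = eutectic_point(nap_ibu, "ideal")
        tms = [nap_ibu.fusion(i).melting_temperature for i in range(2)]
        assert e.temperature < min(tms)
        assert 0.0 < e.composition < 1.0

    def test_non_crossing_system_raises(self, registry):
        # an (artificial) enormous fusion enthalpy pins branch 1 at its
        # melting point for every x, so it never meets branch 2
        flat = registry["NAP"].model_copy(update={
            "fusion": FusionProperties(melting_temperature=500.0,
                                       fusion_enthalpy=1e9,
                                       heat_capacity_difference=0.0)})
        s = BinarySystem(flat, registry["IBU"])
        with pytest.raises(RuntimeError, match="cross"):
            eutectic_point(s, "ideal")


class TestPhaseDiagram:
    def test_structure_and_metastable_flags(self, nap_ind):
        d = phase_diagram(nap_ind, "ideal", grid=41)
        assert len(d.branch_1.compositions) == 41
        # branch endpoints hit the pure melting points
        assert d.branch_1.temperatures[-1] == pytest.approx(
            nap_ind.fusion(0).melting_temperature, abs=1e-6)
        assert d.branch_2.temperatures[0] == pytest.approx(
            nap_ind.fusion(1).melting_temperature, abs=1e-6)
        x = d.branch_1.compositions
        assert np.all(d.branch_1.metastable == (x < d.eutectic.composition))
        # stable envelope is the max of the branches and dips at x_E
        env = stable_liquidus(d)
        assert np.nanmin(env) >= d.eutectic.temperature - 0.05

    def test_eutectic_invariant_under_grid_refinement(self, nap_ind):
        t1 = phase_diagram(nap_ind, "ideal", grid=101).eutectic.temperature
        t2 = phase_diagram(nap_ind, "ideal", grid=1001).eutectic.temperature
        assert abs(t1 - t2) < 0.01

    def test_stable_liquidus_at_composition(self, nap_ind):
        e = eutectic_point(nap_ind, "ideal")
        # just above the eutectic composition component 1 governs
        t = liquidus_at(nap_ind, e.composition + 0.05, "ideal")
        assert t == pytest.approx(
            liquidus_temperature(nap_ind, 0, e.composition + 0.05, "ideal"),
            abs=1e-6)


class TestDeviationStatistics:
    def test_identity_gives_zero(self):
        r = deviation_statistics([400.0, 410.0], [0.4, 0.5], [400.0, 410.0])
        assert np.all(r.per_point_deviation == 0.0)
        assert r.average_absolute_deviation == 0.0

    def test_toy_mean_absolute(self):
        r = deviation_statistics([401.0, 408.0, 412.0], [0.3, 0.5, 0.7],
                                 [400.0, 410.0, 412.5])
        assert r.per_point_deviation == pytest.approx([1.0, -2.0, -0.5])
        assert r.average_absolute_deviation == pytest.approx(3.5 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            deviation_statistics([400.0], [0.4, 0.5], [400.0, 401.0])
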