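"""Fluxes, response functions and type invariants of the core model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shrimpdeb.core import (
    DEBParams,
    ForcingCoverageError,
    ForcingSeries,
    InvalidInput,
    OrganismState,
    assimilation_flux,
    catabolic_flux,
    holling_response,
    length_from_structure,
    maturity_maintenance_flux,
    somatic_maintenance_flux,
    state_derivatives,
    structure_from_length,
    temp_correction,
    ultimate_length,
    wet_weight,
)


class TestTempCorrection:
    @pytest.mark.parametrize("T, expected", [(293.0, 0.811), (301.0, 1.003)])
    def test_known_factors(self, params, T, expected):
        assert temp_correction(T, params) == pytest.approx(expected, rel=1e-3)

    def test_normalized_is_one_at_reference(self, params):
        assert temp_correction(params.T1, params, normalized=True) == pytest.approx(1.0)

    def test_high_boundary_suppression(self, params):
        assert 0 < temp_correction(350.0, params) < temp_correction(301.0, params)

    def test_continuous_and_positive_over_tolerance_range(self, params):
        grid = np.arange(275.0, 315.0, 0.01)
        vals = np.array([temp_correction(t, params) for t in grid])
        assert np.all(vals > 0)
        # no jumps: neighbouring factors differ by < 1% on a 0.01 K grid
        assert np.max(np.abs(np.diff(vals)) / vals[:-1]) < 0.01

    @pytest.mark.parametrize("bad", [0.0, -5.0, math.nan, math.inf])
    def test_invalid_temperature(self, params, bad):
        with pytest.raises(InvalidInput):
            temp_correction(bad, params)


class TestHollingResponse:
    @pytest.mark.parametrize("X, XK, expected", [
        (2.0, 2.0, 0.5), (0.0, 1.0, 0.0), (6.0, 2.0, 0.75),
    ])
    def test_examples(self, X, XK, expected):
        assert holling_response(X, XK) == pytest.approx(expected)

    @given(ratio=st.floats(0, 1e6), XK=st.floats(1e-9, 1e12))
    def test_bounded_below_one(self, ratio, XK):
        # X spans 0 to a million times the half-saturation density
        f = holling_response(ratio * XK, XK)
        assert 0.0 <= f < 1.0

    @given(XK=st.floats(1e-6, 1e6), x1=st.floats(0, 1e6), x2=st.floats(0, 1e6))
    def test_monotone_in_food(self, XK, x1, x2):
        lo, hi = sorted([x1, x2])
        assert holling_response(lo, XK) <= holling_response(hi, XK)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInput):
            holling_response(-1.0, 1.0)
        with pytest.raises(InvalidInput):
            holling_response(1.0, 0.0)


class TestFluxes:
    def test_assimilation_at_unit_volume_equals_pam(self, params):
        s = OrganismState(E=1.0, V=1.0, EH=params.EHp)
        assert assimilation_flux(s, 1.0, 1.0, params) == pytest.approx(1823.0)

    def test_assimilation_scales_with_f_and_surface(self, params):
        s = OrganismState(E=1.0, V=8.0, EH=params.EHp)
        assert assimilation_flux(s, 0.5, 1.0, params) == pytest.approx(3646.0)
        assert assimilation_flux(s, 0.0, 1.0, params) == 0.0

    def test_embryo_does_not_feed(self, params):
        embryo = OrganismState(E=0.1, V=1e-5, EH=0.5 * params.EHb)
        assert assimilation_flux(embryo, 1.0, 1.0, params) == 0.0

    def test_male_assimilation_scaled_by_zoom_ratio(self, params):
        f, m = (OrganismState(E=1.0, V=1.0, EH=params.EHp, sex=s)
                for s in ("female", "male"))
        ratio = assimilation_flux(m, 1.0, 1.0, params) / assimilation_flux(f, 1.0, 1.0, params)
        assert ratio == pytest.approx(params.zm / params.z)

    def test_catabolic_at_equilibrium_density(self, params):
        s = OrganismState(E=13235.0, V=1.0, EH=params.EHp)
        assert catabolic_flux(s, 1.0, params) == pytest.approx(897.4, rel=1e-3)

    def test_catabolic_zero_reserve_and_linearity_in_tc(self, params):
        s0 = OrganismState(E=0.0, V=1.0)
        assert catabolic_flux(s0, 1.0, params) == 0.0
        s = OrganismState(E=5000.0, V=2.0)
        assert catabolic_flux(s, 2.0, params) == pytest.approx(
            2.0 * catabolic_flux(s, 1.0, params))

    def test_somatic_maintenance(self, params):
        assert somatic_maintenance_flux(OrganismState(E=1, V=1.0), 1.0, params) \
            == pytest.approx(569.0)
        assert somatic_maintenance_flux(OrganismState(E=1, V=2.0), 0.5, params) \
            == pytest.approx(569.0)

    def test_maturity_maintenance_below_and_above_puberty_volume(self, params):
        s1 = OrganismState(E=1, V=1.0)
        assert maturity_maintenance_flux(s1, 1.0, params) == pytest.approx(
            569.0 * 0.02 / 0.98, rel=1e-6)
        vp = params.structure_at_puberty
        s_at = OrganismState(E=1, V=vp)
        s_above = OrganismState(E=1, V=2 * vp)
        assert maturity_maintenance_flux(s_above, 1.0, params) == pytest.approx(
            maturity_maintenance_flux(s_at, 1.0, params))


class TestStateDerivatives:
    def test_growth_rate_at_unit_volume(self, params):
        s = OrganismState(E=13235.0, V=1.0, EH=params.EHp)
        d = state_derivatives(s, params.T1, 1.0, params)
        tc = temp_correction(params.T1, params)
        assert d.dV / tc == pytest.approx(0.0699, rel=2e-3)

    @given(
        e_density=st.floats(0.3, 1.0),
        V=st.floats(1e-4, 30.0),
        EH=st.floats(0.0, 3000.0),
        T=st.floats(283.0, 302.0),
        f=st.floats(0.0, 1.0),
    )
    def test_kappa_rule_conservation(self, params, e_density, V, EH, f, T):
        """Mobilized power is exactly partitioned: pA − dE = pC and
        pC = pM + EG·dV + pJ + (maturation or reproduction flux)."""
        s = OrganismState(E=e_density * params.EM * V, V=V, EH=EH,
                          ER=100.0 if EH >= params.EHp else 0.0)
        d = state_derivatives(s, T, f, params)
        if params.kappa * d.pC < d.pM_flux:  # starvation handled separately
            return
        assert d.pA - d.dE == pytest.approx(d.pC, rel=1e-9, abs=1e-12)
        routed = d.dEH if EH < params.EHp else d.dER
        assert d.pC == pytest.approx(
            d.pM_flux + params.EG * d.dV + d.pJ + routed, rel=1e-9, abs=1e-12)

    def test_starvation_pays_from_buffer_then_structure(self, params):
        tc = temp_correction(params.T1, params)
        hungry = OrganismState(E=0.0, V=1.0, EH=params.EHp, ER=50.0)
        d = state_derivatives(hungry, params.T1, 0.0, params)
        assert d.dV == 0.0
        assert d.dER == pytest.approx(-tc * params.pM * 1.0 - d.pJ, rel=1e-9)
        broke = OrganismState(E=0.0, V=1.0, EH=params.EHp, ER=0.0)
        d2 = state_derivatives(broke, params.T1, 0.0, params)
        # structure mobilized at EG per unit volume covers maintenance exactly
        assert -params.EG * d2.dV == pytest.approx(tc * params.pM * 1.0, rel=1e-9)

    def test_aging_derivatives(self, params):
        from shrimpdeb.core import aging_hazard_derivatives

        s = OrganismState(E=13235.0, V=1.0, EH=params.EHp, q=0.0, h=0.0)
        dq1, _ = aging_hazard_derivatives(s, params.T1, 1.0, params)
        frozen = params.replace(ha=0.0)
        dq0, dh0 = aging_hazard_derivatives(s, params.T1, 1.0, frozen)
        assert dq0 == 0.0 and dh0 == 0.0
        doubled = params.replace(ha=2 * params.ha)
        dq2, _ = aging_hazard_derivatives(s, params.T1, 1.0, doubled)
        assert dq2 == pytest.approx(2 * dq1, rel=1e-12)


class TestObservables:
    def test_length_from_unit_volume(self, params):
        assert length_from_structure(1.0, params) == pytest.approx(6.309, rel=1e-3)
        assert length_from_structure(0.0, params) == 0.0

    @given(V=st.floats(1e-9, 1e3))
    def test_length_structure_round_trip(self, params, V):
        assert structure_from_length(length_from_structure(V, params), params) \
            == pytest.approx(V, rel=1e-12)

    def test_wet_weight_components(self, params):
        bare = OrganismState(E=0.0, V=1.0, EH=params.EHp)
        assert wet_weight(bare, params) == pytest.approx(1.0)
        with_buffer = OrganismState(E=0.0, V=1.0, EH=params.EHp, ER=100.0)
        assert wet_weight(with_buffer, params) - wet_weight(bare, params) \
            == pytest.approx(params.kappaR * 100.0 / params.muE)

    def test_ultimate_length_values(self, params):
        assert ultimate_length(1.0, params, "female") == pytest.approx(19.81, rel=1e-3)
        assert ultimate_length(1.0, params, "male") == pytest.approx(18.5, rel=1e-2)
        assert ultimate_length(0.5, params) == pytest.approx(
            0.5 * ultimate_length(1.0, params))
        assert ultimate_length(0.0, params) == 0.0


class TestTypes:
    @pytest.mark.parametrize("override", [
        {"kappa": 1.5}, {"kappa": 0.0}, {"deltaM": 1.2}, {"pM": -1.0},
        {"TL": 295.0}, {"EHb": 5000.0}, {"kappaR": 0.0},
    ])
    def test_parameter_validation(self, override):
        with pytest.raises(InvalidInput):
            DEBParams(**override)

    def test_mu_e_calibration(self, params):
        assert params.muE == pytest.approx(3919.3, rel=1e-4)

    def test_state_validation(self):
        with pytest.raises(InvalidInput):
            OrganismState(E=1.0, V=0.0)
        with pytest.raises(InvalidInput):
            OrganismState(E=-1.0, V=1.0)
        with pytest.raises(InvalidInput):
            OrganismState(E=1.0, V=1.0, sex="other")

    def test_forcing_validation_and_lookup(self):
        with pytest.raises(InvalidInput):
            ForcingSeries([0, 0], [293, 293], f=0.5)
        with pytest.raises(InvalidInput):
            ForcingSeries([0, 1], [293, 293], f=1.5)
        with pytest.raises(InvalidInput):
            ForcingSeries([0, 1], [100, 100], f=0.5)
        fs = ForcingSeries([0, 10], [290, 300], X=[1.0, 3.0], XK=1.0)
        assert fs.at(5.0) == (pytest.approx(295.0), pytest.approx(0.625))
        with pytest.raises(ForcingCoverageError):
            fs.at(11.0)
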