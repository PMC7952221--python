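"""Unit tests for the stock-flow core: state, parameters, couplings, flows."""

import numpy as np
import pytest

import sbdyn
from sbdyn.model_core import (ADULT_BANDS, I_C, I_CUM_SD, I_CUM_SH, I_D,
                              I_EMP, I_UNEMP, EPS_MODIFIER, ModelState,
                              N_STATE, NIC, ParameterSet,
                              ConfigurationError, InvalidStateError)


def _zeroed_params(params: ParameterSet) -> ParameterSet:
    """All flow-rate parameters zeroed (the null system)."""
    zero = {n: 0.0 for n in params.names()
            if params[n].unit in ("1/y", "per 100,000/y", "elasticity",
                                  "consultations/y")
            or n.startswith("capacity0") or n == "birth_rate"}
    return params.with_values(zero, clip=True)


def _single_band_state(band: str, level: str, count: float,
                       care_state: int = NIC) -> ModelState:
    y = np.zeros(N_STATE)
    bi = ADULT_BANDS.index(band)
    li = ("low", "moderate", "high").index(level)
    y[I_D + 3 * bi + li] = count
    if li > 0:  # distressed people must occupy a care state
        y[I_C + 10 * bi + care_state] = count
    return ModelState(y)


class TestModelState:
    def test_population_is_partition_sum(self, initial):
        pop = initial.population
        assert pop[0] == pytest.approx(initial.child_risk.sum())
        np.testing.assert_allclose(pop[1:], initial.distress.sum(axis=1))

    def test_validate_rejects_negative_stock(self, initial):
        st = initial.copy()
        st.y[I_D] = -50.0
        with pytest.raises(InvalidStateError):
            st.validate()

    def test_validate_rejects_care_partition_mismatch(self, initial):
        st = initial.copy()
        st.y[I_C] += 5000.0  # extra people in care with no matching distress
        with pytest.raises(InvalidStateError):
            st.validate()

    def test_validate_rejects_nonfinite(self, initial):
        st = initial.copy()
        st.y[0] = np.nan
        with pytest.raises(InvalidStateError):
            st.validate()


class TestParameterSet:
    def test_unknown_name_raises(self, params):
        with pytest.raises(ConfigurationError):
            params.value("no_such_parameter")

    def test_bounds_enforced_on_set(self, params):
        ps = params.copy()
        with pytest.raises(ConfigurationError):
            ps.set_value("case_fatality_adult", 1.5)
        ps.set_value("case_fatality_adult", 1.5, clip=True)
        assert ps.value("case_fatality_adult") == 1.0

    def test_yaml_roundtrip_preserves_values_and_flags(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        ps = params.with_values({"attempt_hazard_high": 0.0123})
        ps.to_yaml(path)
        back = ParameterSet.from_yaml(str(path))
        assert back.value("attempt_hazard_high") == pytest.approx(0.0123)
        assert back["attempt_hazard_high"].calibrate
        assert back.names() == ps.names()

    def test_csv_export_has_one_row_per_parameter(self, params, tmp_path):
        text = params.to_csv()
        assert len(text.strip().splitlines()) == len(params) + 1
        assert "source" in text.splitlines()[0]

    def test_with_values_is_pure(self, params):
        before = params.value("ed_rate")
        params.with_values({"ed_rate": 0.5})
        assert params.value("ed_rate") == before


class TestRateModifiers:
    def test_neutral_when_drivers_at_reference(self, params, initial):
        # pin the reference levels to the state's actual driver values
        st = initial
        ps = params.with_values({
            "ref_unemployment_youth": st.unemployment_rate("youth"),
            "ref_unemployment_adult": st.unemployment_rate("adult"),
            "ref_unemployment_total": st.unemployment_rate(),
            # with every other driver at reference the DV chain sits at base
            "ref_dv_rate": params.value("dv_base_rate"),
            "ref_homeless_per10k":
                st.homeless.sum() / st.total_population * 1e4,
            "ref_high_distress_prev":
                st.distress[:, 2].sum() / st.population[1:].sum(),
            "ref_substance_prev":
                st.substance_misuse.sum() / st.population[1:].sum(),
        }, clip=True)
        mods = sbdyn.compute_rate_modifiers(st, ps)
        for name, value in mods.as_dict().items():
            assert value == pytest.approx(1.0, abs=1e-9), name

    def test_zero_elasticities_give_unit_modifiers(self, params, initial):
        betas = {n: 0.0 for n in params.names() if n.startswith("beta_")}
        mods = sbdyn.compute_rate_modifiers(initial, params.with_values(betas))
        assert all(v == pytest.approx(1.0) for v in mods.as_dict().values())

    def test_doubled_unemployment_with_half_elasticity(self, params):
        # unemployment at exactly twice its reference, beta = 0.5 -> 1.5
        ps = params.with_values(
            {n: 0.0 for n in params.names() if n.startswith("beta_")})
        ps = ps.with_values({"beta_unemployment_distress": 0.5})
        y = np.zeros(N_STATE)
        bi = 0  # youth
        y[I_D + 3 * bi] = 1000.0
        y[I_EMP] = 1000.0 * (1 - 2 * ps.value("ref_unemployment_youth"))
        y[I_UNEMP] = 1000.0 * 2 * ps.value("ref_unemployment_youth")
        mods = sbdyn.compute_rate_modifiers(ModelState(y), ps)
        assert mods.distress_incidence[0] == pytest.approx(1.5)

    def test_modifier_floor(self, params):
        # driver collapsing to zero with a strong elasticity floors at eps
        ps = params.with_values(
            {n: 0.0 for n in params.names() if n.startswith("beta_")})
        ps = ps.with_values({"beta_unemployment_distress": 2.0})
        y = np.zeros(N_STATE)
        y[I_D] = 100.0
        y[I_EMP] = 100.0  # zero unemployment
        mods = sbdyn.compute_rate_modifiers(ModelState(y), ps)
        assert mods.distress_incidence[0] == pytest.approx(EPS_MODIFIER)


class TestDerivatives:
    def test_null_system_has_zero_derivatives(self, params, initial):
        d = sbdyn.derivatives(initial, _zeroed_params(params), 0.0)
        np.testing.assert_array_equal(d, np.zeros(N_STATE))

    def test_single_distress_onset_flow(self, params):
        # lone onset flow: lambda=0.1/y on 1000 low-distress adults
        ps = _zeroed_params(params).with_values({"distress_onset_adult": 0.1})
        st = _single_band_state("adult", "low", 1000.0)
        d = ModelState(sbdyn.derivatives(st, ps, 0.0))
        assert d.distress[1, 0] == pytest.approx(-100.0)
        assert d.distress[1, 1] == pytest.approx(100.0)
        assert d.distress[1, 2] == 0.0
        assert d.distress[0].sum() == 0.0 and d.distress[2].sum() == 0.0

    def test_attempt_split_between_deaths_and_hospitalisations(self, params):
        # hazard 0.02/y on 500 high-distress people, case fatality 8%
        ps = _zeroed_params(params).with_values({
            "attempt_hazard_high": 0.02,
            "attempt_band_mult_adult": 1.0,
            "case_fatality_adult": 0.08,
            "hazard_mult_not_in_care": 1.0,
        })
        st = _single_band_state("adult", "high", 500.0)
        d = sbdyn.derivatives(st, ps, 0.0)
        assert d[I_CUM_SD + 2] == pytest.approx(0.8)
        assert d[I_CUM_SH + 2] == pytest.approx(9.2)

    def test_rejects_negative_input_state(self, params, initial):
        st = initial.copy()
        st.y[I_D] = -1000.0
        with pytest.raises(InvalidStateError):
            sbdyn.derivatives(st, params, 0.0)

    @pytest.mark.parametrize("scale", [1.0, 1.5, 2.0, 4.0])
    def test_attempt_hazard_monotonicity(self, params, initial, scale):
        # raising the high-distress attempt hazard never lowers the
        # instantaneous suicide-death flow at a fixed state
        base = sbdyn.derivatives(initial, params, 0.0)
        ps = params.with_values(
            {"attempt_hazard_high": params.value("attempt_hazard_high") * scale},
            clip=True)
        d = sbdyn.derivatives(initial, ps, 0.0)
        base_sd = base[I_CUM_SD:I_CUM_SD + 4].sum()
        assert d[I_CUM_SD:I_CUM_SD + 4].sum() >= base_sd - 1e-12

    def test_flow_balance_across_partitions(self, params, initial):
        # d(care pool) must track d(distress mod+high) exactly
        d = ModelState(sbdyn.derivatives(initial, params, 0.0))
        np.testing.assert_allclose(
            d.care.sum(axis=1),
            d.distress[:, 1] + d.distress[:, 2],
            rtol=0, atol=1e-9)


class TestServiceCapacity:
    def test_constant_without_growth(self, params):
        ps = params.with_values(
            {f"capacity_growth_{s}": 0.0
             for s in ("gp", "specialist", "community", "online", "inpatient")})
        pop0 = ps.value("init_population")
        c0 = sbdyn.service_capacity_at(0.0, ps, pop0)
        c5 = sbdyn.service_capacity_at(5.0, ps, pop0)
        np.testing.assert_allclose(c5, c0)

    def test_compound_growth_two_years(self, params):
        ps = params.with_values({"capacity_growth_gp": 0.05})
        pop0 = ps.value("init_population")
        c0 = sbdyn.service_capacity_at(0.0, ps, pop0)
        c2 = sbdyn.service_capacity_at(2.0, ps, pop0)
        assert c2[0] / c0[0] == pytest.approx(1.1025)

    def test_per_capita_constancy_under_population_doubling(self, params):
        ps = params.with_values(
            {f"capacity_growth_{s}": 0.0
             for s in ("gp", "specialist", "community", "online", "inpatient")})
        pop0 = ps.value("init_population")
        np.testing.assert_allclose(
            sbdyn.service_capacity_at(3.0, ps, 2 * pop0),
            2 * sbdyn.service_capacity_at(3.0, ps, pop0))
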