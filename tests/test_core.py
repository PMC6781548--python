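"""Rate laws, environmental couplings and unit conversions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pegsax.core import (
    ArrheniusRate,
    Environment,
    KineticParameters,
    PhMode,
    R_GAS,
    SpeciesState,
    arrhenius,
    compute_rates,
    default_parameters,
    hydrogen_hydroxide,
    mixing_enthalpy,
    ode_rhs,
    out_of_phase_fraction,
    ph_from_fa,
    reactive_peg_fraction,
)
from pegsax.units import MOLAR_MASS, UnitError, convert_units, display_round


def make_env(**kw):
    defaults = dict(aw=0.1, peg_saxa_ratio=1.0, peg_hpmc_ratio=1.0 / 3.0)
    defaults.update(kw)
    return Environment.at_celsius(40.0, **defaults)


def make_params(**kw):
    zero = ArrheniusRate(0.0)
    defaults = dict(k1=zero, k2=zero, k3=zero, k4=zero, k5=zero, k6=zero,
                    k7=zero, kHp=zero)
    defaults.update({k: ArrheniusRate(v) if isinstance(v, float) else v
                     for k, v in kw.items()})
    return KineticParameters(**defaults)


class TestArrhenius:
    def test_zero_barrier_gives_prefactor(self):
        assert arrhenius(5.0, 0.0, 313.15) == 5.0

    def test_temperature_ratio_matches_closed_form(self):
        # independent closed-form oracle for the 30->40 degC acceleration
        k40 = arrhenius(1.0, 88.54, 313.15)
        k30 = arrhenius(1.0, 88.54, 303.15)
        expected = math.exp(-88.54e3 / R_GAS * (1 / 313.15 - 1 / 303.15))
        assert k40 / k30 == pytest.approx(expected, rel=1e-10)

    def test_infinite_barrier_limit(self):
        assert arrhenius(2.0, 1e6, 300.0) == pytest.approx(0.0, abs=1e-300)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            arrhenius(1.0, 50.0, 0.0)

    def test_rate_parameterization_equivalent_to_prefactor_form(self):
        rate = ArrheniusRate(k_ref=0.04, Ea=95.0)
        for T in (293.15, 313.15, 333.15):
            assert rate.k(T) == pytest.approx(arrhenius(rate.A, rate.Ea, T), rel=1e-12)
        back = ArrheniusRate.from_A(rate.A, rate.Ea)
        assert back.k_ref == pytest.approx(rate.k_ref, rel=1e-12)


class TestPhClosure:
    def test_zero_fa_returns_intercept(self):
        assert ph_from_fa(0.0) == 5.6703

    def test_linear_evaluation(self):
        # direct-arithmetic oracle
        assert ph_from_fa(3.5e-4) == pytest.approx(5.6703 - 570.45 * 3.5e-4, rel=1e-12)

    @given(st.floats(min_value=0.0, max_value=5e-3),
           st.floats(min_value=1e-6, max_value=3e-3))
    def test_strictly_decreasing(self, a, delta):
        assert ph_from_fa(a) > ph_from_fa(a + delta) or ph_from_fa(a) == 1.0

    def test_floor_clip(self, caplog):
        with caplog.at_level("WARNING"):
            assert ph_from_fa(1.0) == 1.0
        assert "clip" in caplog.text.lower()


class TestAcidBase:
    def test_neutral_water(self):
        assert hydrogen_hydroxide(7.0, 1e-14) == (pytest.approx(1e-7), pytest.approx(1e-7))

    def test_ion_product_identity(self):
        ch, coh = hydrogen_hydroxide(5.6703, 1e-14)
        assert ch * coh == pytest.approx(1e-14, rel=1e-15)

    def test_measured_ph_value(self):
        ch, _ = hydrogen_hydroxide(5.43, 1e-14)
        assert ch == pytest.approx(3.715352e-6, rel=1e-6)


class TestPhaseLookup:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.10, 0.00), (0.30, 0.22), (0.20, 0.05), (0.25, 0.135), (0.05, 0.0)],
    )
    def test_anchors_and_interpolation(self, ratio, expected):
        assert out_of_phase_fraction(ratio) == pytest.approx(expected, abs=1e-12)

    def test_extrapolation_clipped_to_unity(self):
        assert out_of_phase_fraction(10.0) == 1.0

    @given(st.floats(min_value=0.10, max_value=2.0),
           st.floats(min_value=0.0, max_value=0.5))
    def test_non_decreasing(self, r, dr):
        assert out_of_phase_fraction(r + dr) >= out_of_phase_fraction(r)


class TestReactiveFraction:
    def test_dry_film_has_no_reactive_peg(self):
        params = make_params(kHp=5.0)
        assert reactive_peg_fraction(make_env(aw=0.0), params) == 0.0

    def test_base_mode_is_humidity_product(self):
        params = make_params(kHp=2.0).with_updates(phase_corrected=False)
        assert reactive_peg_fraction(make_env(aw=0.10), params) == pytest.approx(0.20)

    def test_clipped_at_unity(self):
        params = make_params(kHp=50.0).with_updates(phase_corrected=False)
        assert reactive_peg_fraction(make_env(aw=0.5), params) == 1.0

    def test_phase_correction_multiplies_lookup(self):
        params = make_params(kHp=2.0)
        env = make_env(aw=0.10, peg_hpmc_ratio=1.0 / 3.0)  # 25% of polymer
        expected = 0.20 * out_of_phase_fraction(0.25)
        assert reactive_peg_fraction(env, params) == pytest.approx(expected)


class TestMixingEnthalpy:
    @pytest.mark.parametrize(
        "x1,dh1,x2,dh2,expected",
        [(1.0, 200.0, 0.0, 0.0, 200.0),
         (0.5, 100.0, 0.5, 0.0, 50.0),
         (0.3, 190.0, 0.7, 0.0, 57.0)],
    )
    def test_weighted_sum(self, x1, dh1, x2, dh2, expected):
        assert mixing_enthalpy(x1, dh1, x2, dh2) == pytest.approx(expected)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            mixing_enthalpy(0.5, 100.0, 0.6, 0.0)


ZERO_STATE = SpeciesState(0, 0, 0, 0, 0, 0, 0, 0, 0)


class TestRates:
    def test_zero_state_zero_rates(self):
        r = compute_rates(ZERO_STATE, default_parameters(), make_env())
        assert all(getattr(r, f"r{i}") == 0.0 for i in range(1, 8))

    def test_irreversible_formylation_ignores_sfa(self):
        # with no reverse constant the net rate equals the forward law
        params = make_params(k7=100.0).with_updates(
            ph_slope=None, ph_intercept=None
        )
        env = make_env(ph_mode=PhMode.MEASURED, ph_measured=5.5)
        s1 = SpeciesState(0, 0, 0, 0, 1e-3, 0.5, 0, 0, 0.0)
        s2 = SpeciesState(0, 0, 0, 0, 1e-3, 0.5, 0, 0, 0.3)
        assert compute_rates(s1, params, env).r7 == compute_rates(s2, params, env).r7

    def test_reverse_term_subtracts(self):
        params = make_params(k7=100.0, k8=0.5)
        env = make_env(ph_mode=PhMode.MEASURED, ph_measured=5.5)
        s = SpeciesState(0, 0, 0, 0, 1e-3, 0.5, 0, 0, 0.2)
        ch = 10 ** -5.5
        assert compute_rates(s, params, env).r7 == pytest.approx(
            100.0 * ch * 0.5 * 1e-3 - 0.5 * 0.2
        )

    def test_single_reaction_arithmetic(self):
        params = make_params(k1=0.02)
        s = SpeciesState(0.1, 0, 0, 0, 0, 0, 0, 0, 0)
        r = compute_rates(s, params, make_env())
        assert r.r1 == pytest.approx(0.002)
        assert all(getattr(r, f"r{i}") == 0.0 for i in range(2, 8))

    def test_first_order_homogeneity_in_peg(self):
        params = default_parameters()
        env = make_env(ph_mode=PhMode.MEASURED, ph_measured=5.6)
        s = SpeciesState(0.05, 0, 0, 0, 0, 0, 0, 0, 0)
        s2 = SpeciesState(0.10, 0, 0, 0, 0, 0, 0, 0, 0)
        ra, rb = compute_rates(s, params, env), compute_rates(s2, params, env)
        for i in (1, 2, 3):
            assert getattr(rb, f"r{i}") == pytest.approx(2 * getattr(ra, f"r{i}"), rel=1e-14)

    def test_dynamic_mode_without_closure_is_an_error(self):
        params = make_params(k5=1.0).with_updates(ph_slope=None, ph_intercept=None)
        with pytest.raises(Exception, match="closure"):
            compute_rates(ZERO_STATE, params, make_env())


@st.composite
def random_state(draw):
    vals = [draw(st.floats(min_value=0.0, max_value=5.0)) for _ in range(9)]
    return SpeciesState(*vals)


class TestOdeRhs:
    def test_zero_parameters_zero_derivative(self):
        d = ode_rhs(SpeciesState(1, 1, 1, 1, 1, 1, 1, 1, 1), make_params(), make_env())
        assert np.all(d == 0.0)

    @given(random_state(), st.booleans())
    def test_family_conservation(self, state, consume_fa):
        params = default_parameters().with_updates(consume_fa=consume_fa)
        d = ode_rhs(state, params, make_env())
        # SAXA skeleton: indices SAXA, SCA, ESCA, SFA
        assert abs(d[5] + d[6] + d[7] + d[8]) < 1e-15 * max(1.0, np.abs(d).max())
        if consume_fa:
            peg_sum = d[0] + d[1] + d[2] + d[3] + d[4] + d[8]
            assert abs(peg_sum) < 1e-12 * max(1.0, np.abs(d).max())

    def test_single_reaction_substitution(self):
        # only cyclization active at a fixed measured pH
        coh = 1e-14 / 10**-5.6
        params = make_params(k5=2.0)
        env = make_env(ph_mode=PhMode.MEASURED, ph_measured=5.6)
        s = SpeciesState(0, 0, 0, 0, 0, 0.4, 0, 0, 0)
        d = ode_rhs(s, params, env)
        assert d[5] == pytest.approx(-2.0 * coh * 0.4, rel=1e-14)
        assert d[6] == pytest.approx(+2.0 * coh * 0.4, rel=1e-14)


ATOMIC = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}


def formula_mass(formula: dict) -> float:
    return sum(ATOMIC[el] * n for el, n in formula.items())


class TestUnits:
    def test_kcal_to_kj_worked_example(self):
        value = convert_units(39.28, "kcal/mol", "kJ/mol")
        assert value == pytest.approx(39.28 * 4.184, rel=1e-12)
        assert display_round(value) == 164.35

    def test_zero_is_zero_in_any_pair(self):
        assert convert_units(0.0, "kcal/mol", "kJ/mol") == 0.0
        assert convert_units(0.0, "ppm_ww", "molkg", species="FA") == 0.0

    def test_ppm_definition(self):
        assert convert_units(350.0, "ppm_ww", "massfrac") == pytest.approx(3.5e-4)

    @pytest.mark.parametrize(
        "species,formula",
        [
            ("FA", {"C": 1, "H": 2, "O": 2}),
            ("F", {"C": 1, "H": 2, "O": 1}),
            ("A", {"C": 2, "H": 4, "O": 1}),
            ("GA", {"C": 2, "H": 4, "O": 3}),
            ("PEG", {"C": 2, "H": 4, "O": 1}),
            ("SAXA", {"C": 18, "H": 25, "N": 3, "O": 2}),
            ("SCA", {"C": 18, "H": 23, "N": 3, "O": 1}),
            ("SFA", {"C": 19, "H": 25, "N": 3, "O": 3}),
        ],
    )
    def test_molar_masses_against_periodic_table(self, species, formula):
        assert MOLAR_MASS[species] == pytest.approx(formula_mass(formula), abs=5e-3)

    @given(st.floats(min_value=1e-9, max_value=1e3))
    def test_round_trips(self, value):
        via = convert_units(value, "ppm_ww", "molkg", species="SAXA")
        assert convert_units(via, "molkg", "ppm_ww", species="SAXA") == pytest.approx(
            value, rel=1e-12
        )

    def test_unknown_pair_and_missing_species(self):
        with pytest.raises(UnitError):
            convert_units(1.0, "ppm_ww", "kJ/mol")
        with pytest.raises(UnitError):
            convert_units(1.0, "massfrac", "molkg")


class TestDomainTypes:
    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            SpeciesState(-1e-3, 0, 0, 0, 0, 0, 0, 0, 0)

    def test_measured_mode_requires_ph(self):
        with pytest.raises(Exception):
            make_env(ph_mode=PhMode.MEASURED)

    def test_environment_validation(self):
        with pytest.raises(ValueError):
            make_env(aw=1.5)

    def test_kw_override_table(self):
        params = make_params().with_updates(kw_table={303.15: 1.5e-14, 323.15: 3e-14})
        assert params.kw_at(305.0) == 1.5e-14
        assert params.kw_at(322.0) == 3e-14

    def test_state_family_totals(self):
        s = SpeciesState(1, 2, 3, 4, 5, 6, 7, 8, 9)
        assert s.peg_family_total == 1 + 2 + 3 + 4 + 5 + 9
        assert s.saxa_family_total == 6 + 7 + 8 + 9
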