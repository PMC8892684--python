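"""Deterministic energy-system equations and unit conversions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ruminergy.energetics import (
    DEFAULT_UNITS,
    NetEnergyCoefficients,
    UnitConstants,
    convert_methane,
    eq4_rate,
    me_from_de,
    multiple_of_maintenance,
    neg_from_me,
    nem_from_me,
    predict_methane,
)


class TestMeFromDe:
    @pytest.mark.parametrize(
        "de, method, kwargs, expected",
        [
            (3.05, "eq2", {}, 2.66),
            (3.00, "eq1", {}, 2.6077),
            (3.00, "hemphill", {}, 2.6679),
            (3.00, "gt_linear", {}, 2.5834),
            (3.00, "factor_082", {}, 2.46),
            (3.00, "dairy_nrc", {}, 2.58),
            (3.00, "reynolds_ratio", dict(dmi=8, ndf=30, cp=13), 2.6850),
        ],
    )
    def test_printed_coefficients(self, de, method, kwargs, expected):
        assert me_from_de(de, method, **kwargs) == pytest.approx(expected, abs=1e-9)

    def test_default_method_subtracts_constant(self):
        assert me_from_de(3.44) == pytest.approx(3.05)

    def test_unknown_method_and_missing_covariates(self):
        with pytest.raises(ValueError, match="unknown"):
            me_from_de(3.0, "nope")
        with pytest.raises(ValueError, match="covariates"):
            me_from_de(3.0, "reynolds_ratio")
        with pytest.raises(ValueError):
            me_from_de(0.0)

    @given(st.floats(min_value=1.8, max_value=3.9))
    def test_updated_regression_and_constant_offset_agree_closely(self, de):
        # 0.0001·DE − 0.0026 stays within (−0.0026, −0.0022) over the data range
        assert abs(me_from_de(de, "eq1") - me_from_de(de, "eq2")) < 0.01


class TestNetEnergyChain:
    def test_identity_and_constant_polynomials(self):
        ident = NetEnergyCoefficients(nem=(0, 1, 0, 0), neg=(0, 1, 0, 0), provenance="test")
        const = NetEnergyCoefficients(nem=(1.0, 0, 0, 0), neg=(1.0, 0, 0, 0), provenance="test")
        assert nem_from_me(2.5, ident) == 2.5
        assert nem_from_me(3.3, const) == 1.0
        assert neg_from_me(2.5, ident) == 2.5

    def test_default_nem_strictly_increasing_over_feeding_range(self):
        grid = np.linspace(1.5, 3.7, 200)
        vals = [nem_from_me(m) for m in grid]
        assert np.all(np.diff(vals) > 0)

    def test_me_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nem_from_me(0.0)
        with pytest.raises(ValueError):
            nem_from_me(6.5)

    def test_multiple_of_maintenance_hand_values(self):
        # 256^0.75 = 64 exactly, so the requirement is 0.077·64 = 4.928 Mcal/d
        assert multiple_of_maintenance(256, 2.0, 2.464) == pytest.approx(1.0)
        assert multiple_of_maintenance(256, 4.0, 2.464) == pytest.approx(2.0)

    def test_multiple_of_maintenance_linear_in_dmi(self):
        a = multiple_of_maintenance(420, 5.0, 2.1)
        b = multiple_of_maintenance(420, 10.0, 2.1)
        assert b == pytest.approx(2 * a)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            multiple_of_maintenance(0, 5.0, 2.1)


class TestPredictMethane:
    @pytest.mark.parametrize(
        "method, kwargs, scale, expected",
        [
            ("eq3", dict(dmi=10), "mcal_d", 2.433),
            ("eq3", dict(dmi=10), "g_d", 184.3415873),
            ("eq4", dict(dmi=10, mom=2), "mcal_d", 2.2162),
            ("ipcc_tier2", dict(ge_intake_mj_d=100), "g_d", 116.8014376),
            ("global_tier2", dict(ge_intake_mj_d=100), "g_d", 109.6136568),
            ("ellis_2c", dict(dmi=0), "mj_d", 3.27),
            ("dmi_c", dict(dmi=10), "g_d", 180.2),
        ],
    )
    def test_printed_equations(self, method, kwargs, scale, expected):
        pred = predict_methane(method, **kwargs)
        assert pred.value(scale) == pytest.approx(expected, abs=1e-6)

    def test_intake_adjusted_rate_at_maintenance(self):
        assert eq4_rate(1.0) == pytest.approx(0.27801)

    def test_intake_adjusted_rate_strictly_decreasing(self):
        moms = np.linspace(0.5, 4.0, 50)
        assert np.all(np.diff([eq4_rate(m) for m in moms]) < 0)

    def test_negative_prediction_flagged_not_clamped(self):
        with pytest.warns(UserWarning, match="negative"):
            pred = predict_methane("eq4", dmi=8, mom=7.0)
        assert pred.negative
        assert pred.mcal_per_d < 0

    @pytest.mark.parametrize("method, key", [("eq3", "dmi"), ("ipcc_tier2", "ge_intake_mj_d"),
                                             ("global_tier2", "ge_intake_mj_d")])
    def test_homogeneous_through_origin(self, method, key):
        one = predict_methane(method, **{key: 7.3})
        two = predict_methane(method, **{key: 14.6})
        assert two.g_per_d == pytest.approx(2 * one.g_per_d, rel=1e-12)

    def test_missing_required_input_errors(self):
        with pytest.raises(ValueError, match="requires"):
            predict_methane("eq3")
        with pytest.raises(ValueError, match="requires"):
            predict_methane("eq4", dmi=10)
        with pytest.raises(ValueError, match="unknown"):
            predict_methane("nope", dmi=10)

    @pytest.mark.parametrize(
        "method, kwargs",
        [
            ("eq3", dict(dmi=9.2)),
            ("eq4", dict(dmi=9.2, mom=1.7)),
            ("ipcc_tier2", dict(ge_intake_mj_d=130.0)),
            ("global_tier2", dict(ge_intake_mj_d=130.0)),
            ("dmi_c", dict(dmi=9.2)),
            ("ellis_2c", dict(dmi=9.2)),
        ],
    )
    def test_scales_mutually_consistent_along_recorded_route(self, method, kwargs):
        u = DEFAULT_UNITS
        p = predict_methane(method, **kwargs)
        assert p.mj_per_d == pytest.approx(p.mcal_per_d * u.mj_per_mcal, rel=1e-9)
        assert p.g_per_d == pytest.approx(p.l_per_d * u.g_per_l_ch4, rel=1e-9)
        if p.route == "calorimetric":
            assert p.l_per_d == pytest.approx(p.mcal_per_d * 1000 / u.kcal_per_l_ch4, rel=1e-9)
        else:
            assert p.mj_per_d == pytest.approx(p.g_per_d * u.mj_per_g_ch4, rel=1e-9)


class TestConvertMethane:
    def test_calorimetric_chain_hand_value(self):
        # 0.2433 Mcal = 243.3 kcal → /9.45 = 25.746 L → ×0.716 = 18.434 g
        assert convert_methane(0.2433, "mcal_d", "g_d") == pytest.approx(18.43415873, abs=1e-6)

    def test_tier_convention_gram_energy_content(self):
        assert convert_methane(1.0, "g_d", "mj_d", convention="tier") == pytest.approx(0.05565)

    def test_conventions_differ_by_under_one_percent_and_are_distinct(self):
        cal = convert_methane(1.0, "g_d", "mj_d", convention="calorimetric")
        tier = convert_methane(1.0, "g_d", "mj_d", convention="tier")
        assert cal != tier
        assert abs(tier / cal - 1) < 0.01

    @given(
        st.floats(min_value=1e-3, max_value=1e3),
        st.sampled_from(["mcal_d", "mj_d", "g_d", "l_d"]),
        st.sampled_from(["mcal_d", "mj_d", "g_d", "l_d"]),
        st.sampled_from(["calorimetric", "tier"]),
    )
    def test_round_trips_are_identities(self, value, a, b, conv):
        back = convert_methane(convert_methane(value, a, b, convention=conv), b, a, convention=conv)
        assert back == pytest.approx(value, rel=1e-12)

    def test_unknown_scale_pair_rejected(self):
        with pytest.raises(ValueError):
            convert_methane(1.0, "mcal_d", "furlongs")
        with pytest.raises(ValueError):
            convert_methane(1.0, "mcal_d", "g_d", convention="mixed")

    def test_unit_constants_immutable_and_positive(self):
        u = UnitConstants()
        with pytest.raises(AttributeError):
            u.kcal_per_l_ch4 = 1.0
        with pytest.raises(ValueError):
            UnitConstants(g_per_l_ch4=-1)
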