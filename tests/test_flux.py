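"""Chamber flux estimation: rates, refill mixing, O2 regression, controls."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tracerflux import (
    IncubationRecord,
    IsotopeConstants,
    control_corrected,
    delta_to_atom_fraction,
    net_release_rate,
    oxygen_consumption_rate,
    refill_corrected_start,
    respiration_from_oxygen,
    standardize_to_biomass,
    tracer_release_rate,
)
from tracerflux.errors import (
    InsufficientSeriesError,
    InvalidBiomassError,
    InvalidGeometryError,
    InvalidRefillError,
    MissingIsotopeError,
)


class TestNetReleaseRate:
    def test_no_change_is_zero(self):
        assert net_release_rate(73.5, 73.5, 4.8, 10.0) == 0.0

    def test_ambient_doc_release_hand_value(self):
        assert net_release_rate(73.5, 75.5, 4.8, 10.0) == pytest.approx(0.96, rel=1e-12)

    def test_concentration_drop_means_net_uptake(self):
        assert net_release_rate(80.0, 70.0, 1.3, 5.0) < 0

    @pytest.mark.parametrize("vol,dur", [(0.0, 1.0), (1.0, 0.0), (-1.0, 2.0)])
    def test_invalid_geometry_rejected(self, vol, dur):
        with pytest.raises(InvalidGeometryError):
            net_release_rate(1.0, 2.0, vol, dur)


class TestRefillCorrection:
    def test_no_refill_leaves_start_unchanged(self):
        assert refill_corrected_start(100.0, 50.0, 0.0, 4.8) == 100.0

    def test_identical_refill_water_is_identity(self):
        assert refill_corrected_start(100.0, 100.0, 2.0, 4.8) == pytest.approx(100.0)

    def test_mixing_balance_hand_value(self):
        expected = 100.0 * (3.8 / 4.8) + 50.0 * (1.0 / 4.8)  # 89.583...
        assert refill_corrected_start(100.0, 50.0, 1.0, 4.8) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("refill", [4.8, 5.0, -0.1])
    def test_invalid_refill_volume_rejected(self, refill):
        with pytest.raises(InvalidRefillError):
            refill_corrected_start(100.0, 50.0, refill, 4.8)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(min_value=0.0, max_value=500.0),
        st.floats(min_value=0.0, max_value=500.0),
        st.floats(min_value=0.0, max_value=4.79),
    )
    def test_result_is_convex_combination(self, c_meas, c_ref, refill):
        out = refill_corrected_start(c_meas, c_ref, refill, 4.8)
        lo, hi = min(c_meas, c_ref), max(c_meas, c_ref)
        assert lo - 1e-9 <= out <= hi + 1e-9


class TestOxygenRegression:
    def test_perfect_line(self):
        series = [(t, 250.0 - 10.0 * t) for t in (0.0, 0.5, 1.0, 1.5, 2.0)]
        rate, r2 = oxygen_consumption_rate(series, 1.3)
        assert rate == pytest.approx(13.0, rel=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_constant_series_zero_rate(self):
        rate, _ = oxygen_consumption_rate([(0, 250.0), (1, 250.0), (2, 250.0)], 1.3)
        assert rate == 0.0

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 6, 40)
        c = 260.0 - 4.5 * t + rng.normal(0, 1.0, t.size)
        # analytic OLS slope: cov(t, c) / var(t)
        slope = np.sum((t - t.mean()) * (c - c.mean())) / np.sum((t - t.mean()) ** 2)
        rate, r2 = oxygen_consumption_rate(np.column_stack([t, c]), 2.0)
        assert rate == pytest.approx(-slope * 2.0, rel=1e-10)
        assert 0 < r2 <= 1

    def test_short_or_flat_series_rejected(self):
        with pytest.raises(InsufficientSeriesError):
            oxygen_consumption_rate([(0, 250.0), (1, 240.0)], 1.3)
        with pytest.raises(InsufficientSeriesError):
            oxygen_consumption_rate([(1, 250.0), (1, 249.0), (1, 251.0)], 1.3)


class TestRespirationFromOxygen:
    def test_unit_quotient_is_identity(self):
        assert respiration_from_oxygen(13.0) == 13.0

    def test_zero_rate(self):
        assert respiration_from_oxygen(0.0) == 0.0

    def test_quotient_override(self):
        c = IsotopeConstants(respiratory_quotient=0.8)
        assert respiration_from_oxygen(10.0, c) == pytest.approx(8.0)


def _record(**kw):
    base = dict(
        chamber_id="ch1",
        specimen_id="sp1",
        group="g",
        chamber_volume=4.8,
        duration=10.0,
        dic_start=2100.0,
        dic_end=2150.0,
        dic_d13c_start=0.5,
        dic_d13c_end=5.5,
        poc_start=2.0,
        poc_end=18.0,
        poc_d13c_start=-22.0,
        poc_d13c_end=200.0,
    )
    base.update(kw)
    return IncubationRecord(**base)


class TestTracerReleaseRate:
    def test_no_change_is_zero(self):
        rec = _record(dic_end=2100.0, dic_d13c_end=0.5)
        assert tracer_release_rate(rec, "dic", None, 0.25) == pytest.approx(0.0, abs=1e-12)

    def test_concentration_change_at_background_delta_is_zero(self):
        # all added carbon is unlabelled: delta stays at the chamber-start value
        rec = _record(dic_end=2200.0, dic_d13c_end=0.5)
        assert tracer_release_rate(rec, "dic", None, 0.25) == pytest.approx(0.0, abs=1e-12)

    def test_hand_mass_balance(self):
        rec = _record()
        f0 = delta_to_atom_fraction(0.5)
        f1 = delta_to_atom_fraction(5.5)
        expected = (f1 - f0) * 2150.0 * 4.8 / 10.0 / 0.25
        assert tracer_release_rate(rec, "dic", None, 0.25) == pytest.approx(
            expected, rel=1e-12
        )

    def test_missing_isotope_rejected(self):
        rec = _record(dic_d13c_end=None)
        with pytest.raises(MissingIsotopeError):
            tracer_release_rate(rec, "dic", None, 0.25)

    def test_doc_pool_has_no_tracer_flux(self):
        with pytest.raises(ValueError):
            tracer_release_rate(_record(), "doc", None, 0.25)

    def test_linearity_in_concentrations(self):
        # scaling every concentration by k scales the tracer rate by k
        rec1 = _record()
        k = 3.0
        rec2 = _record(
            dic_start=2100.0 * k, dic_end=2150.0 * k,
            poc_start=2.0 * k, poc_end=18.0 * k,
        )
        r1 = tracer_release_rate(rec1, "dic", None, 0.25)
        r2 = tracer_release_rate(rec2, "dic", None, 0.25)
        assert r2 == pytest.approx(k * r1, rel=1e-12)
        assert net_release_rate(2.0 * k, 18.0 * k, 4.8, 10.0) == pytest.approx(
            k * net_release_rate(2.0, 18.0, 4.8, 10.0), rel=1e-12
        )


class TestControlCorrection:
    def test_zero_controls_leave_rate_unchanged(self):
        assert control_corrected(5.0, [0.0, 0.0]) == 5.0

    def test_mean_subtraction(self):
        assert control_corrected(5.0, [1.0, 3.0]) == pytest.approx(3.0)

    def test_apparent_uptake_after_correction(self):
        assert control_corrected(1.0, [2.0, 2.0]) == pytest.approx(-1.0)

    def test_empty_control_list_warns(self):
        with pytest.warns(UserWarning, match="uncorrected"):
            assert control_corrected(5.0, []) == 5.0


class TestStandardize:
    def test_hand_division(self):
        assert standardize_to_biomass(2.0, 0.02) == pytest.approx(100.0)

    def test_zero_rate(self):
        assert standardize_to_biomass(0.0, 0.02) == 0.0

    def test_doubling_biomass_halves_rate(self):
        assert standardize_to_biomass(2.0, 0.04) == pytest.approx(
            standardize_to_biomass(2.0, 0.02) / 2.0
        )

    @pytest.mark.parametrize("oc", [0.0, -0.1])
    def test_invalid_biomass_rejected(self, oc):
        with pytest.raises(InvalidBiomassError):
            standardize_to_biomass(1.0, oc)


def test_refill_applies_only_to_self_sampled_chambers():
    rec = _record(
        start_strategy="self_with_refill",
        refill_volume=1.0,
        refill_dic=2000.0,
    )
    assert rec.effective_start("dic") == pytest.approx(
        refill_corrected_start(2100.0, 2000.0, 1.0, 4.8)
    )
    assert _record().effective_start("dic") == 2100.0
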