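"""Superposition pharmacokinetics: concentration, AUC, relative-AUC table."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from tgisim import (
    DoseSchedule,
    PKParams,
    auc,
    concentration,
    half_life_to_rate,
    rate_to_half_life,
    relative_auc_table,
)
from tgisim.pk import auc_table_to_frame, read_schedule_csv, write_schedule_csv

K69 = math.log(2) / 6.9


# --- schedules strategy: 1..6 doses at sorted distinct times in [0, 40] ----
@st.composite
def schedules(draw):
    n = draw(st.integers(1, 6))
    times = draw(
        st.lists(
            st.floats(0.0, 40.0, allow_nan=False), min_size=n, max_size=n, unique=True
        )
    )
    amounts = draw(st.lists(st.floats(0.1, 10.0), min_size=n, max_size=n))
    return DoseSchedule(sorted(zip(sorted(times), amounts)))


class TestRateConversions:
    def test_published_half_life(self):
        assert half_life_to_rate(6.9) == pytest.approx(0.100456, abs=5e-7)

    def test_closed_form(self):
        assert half_life_to_rate(7.0) == pytest.approx(math.log(2) / 7)

    @given(st.floats(1e-3, 1e3))
    @settings(max_examples=50)
    def test_round_trip(self, t_half):
        assert rate_to_half_life(half_life_to_rate(t_half)) == pytest.approx(
            t_half, rel=1e-14
        )

    @pytest.mark.parametrize("bad", [0.0, -1.0, math.inf, math.nan])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            half_life_to_rate(bad)


class TestDoseSchedule:
    def test_validation(self):
        with pytest.raises(ValueError):
            DoseSchedule([(0, 1), (0, 1)])  # non-increasing times
        with pytest.raises(ValueError):
            DoseSchedule([(0, 0.0)])  # non-positive amount
        with pytest.raises(ValueError):
            DoseSchedule([(-1, 1.0)])  # negative time

    def test_empty_control_allowed(self):
        s = DoseSchedule([], name="control")
        assert len(s) == 0 and s.total_dose == 0.0

    def test_csv_round_trip(self, tmp_path):
        s = DoseSchedule([(0.0, 2.5), (7.0, 2.5)], name="split2")
        path = tmp_path / "split2.csv"
        write_schedule_csv(s, path)
        back = read_schedule_csv(path)
        assert back.events == s.events and back.name == "split2"


class TestConcentration:
    def test_one_half_life_halves_a_bolus(self, pk):
        s = DoseSchedule([(0.0, 5.0)])
        assert concentration(s, pk, 6.9) == pytest.approx(2.5)

    def test_zero_before_first_dose(self, pk):
        s = DoseSchedule([(3.0, 5.0)])
        assert concentration(s, pk, 2.999) == 0.0

    def test_two_dose_superposition_value(self, pk):
        # frozen from the closed form: 2.5 e^{-7 ln2/6.9} + 2.5
        s = DoseSchedule([(0.0, 2.5), (7.0, 2.5)])
        assert concentration(s, pk, 7.0) == pytest.approx(
            2.5 * math.exp(-7 * K69) + 2.5, rel=1e-12
        )
        assert concentration(s, pk, 7.0) == pytest.approx(3.7375, abs=5e-5)

    def test_vectorized_and_jump(self, pk):
        s = DoseSchedule([(0.0, 5.0), (7.0, 2.5)])
        t = np.array([6.999999, 7.0])
        c = concentration(s, pk, t)
        assert c[1] - c[0] == pytest.approx(2.5, abs=1e-4)

    def test_nonfinite_time_rejected(self, pk):
        with pytest.raises(ValueError):
            concentration(DoseSchedule([(0, 5)]), pk, math.nan)

    @given(schedules(), schedules(), st.floats(0.0, 60.0))
    @settings(max_examples=100, deadline=None)
    def test_superposition_linearity(self, a, b, t):
        """Concentration of a merged schedule is the sum of its parts."""
        pk = PKParams()
        merged = a.merged(b)
        assert concentration(merged, pk, t) == pytest.approx(
            concentration(a, pk, t) + concentration(b, pk, t), rel=1e-10, abs=1e-12
        )


class TestAUC:
    def test_single_dose_infinite_interval(self, pk):
        s = DoseSchedule([(0.0, 5.0)])
        assert auc(s, pk, 0.0, math.inf) == pytest.approx(5.0 / K69, rel=1e-12)
        assert auc(s, pk, 0.0, math.inf) == pytest.approx(49.773, abs=5e-4)

    def test_single_dose_day_50(self, pk):
        # the relative-AUC normalization denominator
        s = DoseSchedule([(0.0, 5.0)])
        expect = 5.0 / K69 * (1 - math.exp(-50 * K69))
        assert auc(s, pk, 0.0, 50.0) == pytest.approx(expect, rel=1e-12)
        assert auc(s, pk, 0.0, 50.0) == pytest.approx(49.445, abs=5e-4)

    def test_additivity_over_schedules(self, pk):
        two = DoseSchedule([(0.0, 2.5), (7.0, 2.5)])
        first = DoseSchedule([(0.0, 2.5)])
        second = DoseSchedule([(7.0, 2.5)])
        assert auc(two, pk, 0.0, 50.0) == pytest.approx(
            auc(first, pk, 0.0, 50.0) + auc(second, pk, 0.0, 50.0), rel=1e-12
        )

    def test_bad_interval_rejected(self, pk):
        with pytest.raises(ValueError):
            auc(DoseSchedule([(0, 5)]), pk, 10.0, 10.0)

    @given(schedules(), st.floats(0.0, 20.0), st.floats(25.0, 80.0))
    @settings(max_examples=100, deadline=None)
    def test_matches_numerical_quadrature(self, s, t0, t1):
        """Closed form agrees with adaptive quadrature to 1e-8 relative."""
        pk = PKParams()
        expected, _ = quad(
            lambda t: concentration(s, pk, t),
            t0,
            t1,
            points=[t for t in s.times if t0 < t < t1],
            limit=200,
        )
        assert auc(s, pk, t0, t1) == pytest.approx(expected, rel=1e-8, abs=1e-10)

    @given(schedules())
    @settings(max_examples=50, deadline=None)
    def test_total_exposure_is_dose_over_rate(self, s):
        """AUC over [0, inf) equals total dose x scale / k_e."""
        pk = PKParams()
        assert auc(s, pk, 0.0, math.inf) == pytest.approx(
            s.total_dose * pk.concentration_scale / pk.k_e, rel=1e-12
        )

    @given(schedules(), st.floats(0.0, 10.0), st.floats(20.0, 50.0), st.floats(1.0, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_interval_monotonicity(self, s, t0, t1, extra):
        """Enlarging the interval never decreases the AUC."""
        pk = PKParams()
        inner = auc(s, pk, t0, t1)
        assert auc(s, pk, max(0.0, t0 - extra), t1 + extra) >= inner - 1e-12


class TestRelativeAUCTable:
    def test_reference_maps_to_anchor(self, pk, library):
        rows = relative_auc_table(
            list(library), pk, 0.0, 50.0, reference=library["bolus"], anchor_value=2.433
        )
        by_name = {r.schedule: r for r in rows}
        assert by_name["bolus"].auc_relative == pytest.approx(2.433, rel=1e-14)

    @pytest.mark.parametrize(
        "name, printed",
        [("split2", 2.425), ("metro_low", 2.140)],
    )
    def test_published_rows(self, pk, library, name, printed):
        rows = relative_auc_table(
            list(library), pk, 0.0, 50.0, reference=library["bolus"], anchor_value=2.433
        )
        by_name = {r.schedule: r.auc_relative for r in rows}
        assert round(by_name[name], 3) == printed

    def test_zero_reference_rejected(self, pk, library):
        late = DoseSchedule([(100.0, 5.0)])
        with pytest.raises(ValueError):
            relative_auc_table([late], pk, 0.0, 50.0, reference=late)

    def test_frame_presentation_column(self, pk, library):
        rows = relative_auc_table(
            list(library), pk, 0.0, 50.0, reference=library["bolus"], anchor_value=2.433
        )
        df = auc_table_to_frame(rows)
        assert list(df.columns) == ["schedule", "auc_raw", "auc_relative", "auc_relative_3dp"]
        # raw values retained unrounded alongside the 3-dp presentation column
        assert (df["auc_relative_3dp"] == df["auc_relative"].round(3)).all()
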