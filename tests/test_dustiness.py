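import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dustbox import (
    DustinessRecord,
    EmissionSpec,
    corrected_h,
    di_ratio_stats,
    emission_rate,
    reduction_pct_from_retained,
    retained_from_reduction_pct,
)
from dustbox.dustiness import records_from_frame, records_to_frame


def make_spec(**overrides):
    base = dict(
        dustiness=DustinessRecord("m", "CD", 1000.0, 100.0),
        fraction="inhalable",
        h=1.0,
        mass_flow_kg_min=5.0,
        lc_bag_retained=0.5,
        lc_lev_retained=0.5,
    )
    base.update(overrides)
    return EmissionSpec(**base)


class TestEmissionRate:
    def test_tabulated_filling_case(self, clay1_cd_inhalable):
        # DI 1733 mg/kg * H 1 * 800 kg/min * 0.3 * 0.3
        assert emission_rate(clay1_cd_inhalable, 10.0) == pytest.approx(124_776.0)

    def test_zero_mass_flow_gives_zero_source(self):
        assert emission_rate(make_spec(mass_flow_kg_min=0.0), 1.0) == 0.0

    def test_outside_schedule_gives_zero(self):
        spec = make_spec(schedule=((10.0, 20.0), (30.0, 40.0)))
        assert emission_rate(spec, 5.0) == 0.0
        assert emission_rate(spec, 25.0) == 0.0
        assert emission_rate(spec, 15.0) > 0.0
        # half-open intervals: active at start, inactive at end
        assert emission_rate(spec, 10.0) > 0.0
        assert emission_rate(spec, 20.0) == 0.0
        np.testing.assert_array_equal(
            emission_rate(spec, np.array([5.0, 15.0, 25.0])) > 0,
            [False, True, False],
        )

    def test_negative_time_rejected(self, simple_spec):
        with pytest.raises(ValueError):
            emission_rate(simple_spec, -1.0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_spec(fraction="thoracic")

    def test_overlapping_schedule_rejected(self):
        with pytest.raises(ValueError):
            make_spec(schedule=((0.0, 10.0), (5.0, 15.0)))

    @given(
        di=st.floats(1.0, 1e5),
        h=st.floats(0.01, 2.0),
        flow=st.floats(0.1, 1000.0),
        bag=st.floats(0.01, 1.0),
        lev=st.floats(0.01, 1.0),
        k=st.floats(0.1, 10.0),
    )
    def test_linearity_in_every_factor(self, di, h, flow, bag, lev, k):
        """Doubling any single factor doubles the source strength."""
        rec = DustinessRecord("m", "CD", di, 0.0)
        base = EmissionSpec(rec, "inhalable", h, flow, min(bag, 1.0), min(lev, 1.0))
        s0 = emission_rate(base, 0.0)
        assert s0 >= 0.0
        scaled = EmissionSpec(rec, "inhalable", h * k, flow, base.lc_bag_retained,
                              base.lc_lev_retained)
        assert emission_rate(scaled, 0.0) == pytest.approx(k * s0, rel=1e-12)
        scaled_flow = EmissionSpec(rec, "inhalable", h, flow * k,
                                   base.lc_bag_retained, base.lc_lev_retained)
        assert emission_rate(scaled_flow, 0.0) == pytest.approx(k * s0, rel=1e-12)


class TestDustinessRecord:
    def test_respirable_must_not_exceed_inhalable(self):
        with pytest.raises(ValueError):
            DustinessRecord("m", "CD", w_inhalable=10.0, w_respirable=20.0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            DustinessRecord("m", "VS", 10.0, 1.0)

    def test_csv_frame_round_trip(self, bundle):
        records = bundle.dustiness_records()
        again = records_from_frame(records_to_frame(records))
        assert sorted(records, key=lambda r: (r.material, r.method)) == sorted(
            again, key=lambda r: (r.material, r.method)
        )


class TestDiRatioStats:
    def test_published_table_inhalable(self, bundle):
        st_ = di_ratio_stats(
            bundle.dustiness_records("CD"), bundle.dustiness_records("RD"), "inhalable"
        )
        assert st_.mean == pytest.approx(25.10, abs=0.01)
        assert st_.min == pytest.approx(17.09, abs=0.01)
        assert st_.max == pytest.approx(53.50, abs=0.01)
        ratios = dict(st_.per_material_ratio)
        assert ratios["Kaolin 2"] == pytest.approx(12325 / 721)
        assert ratios["Kaolin 1"] == pytest.approx(18886 / 353)

    def test_published_table_respirable(self, bundle):
        st_ = di_ratio_stats(
            bundle.dustiness_records("CD"), bundle.dustiness_records("RD"), "respirable"
        )
        assert st_.mean == pytest.approx(1.24, abs=0.01)
        assert st_.min == pytest.approx(0.46, abs=0.01)
        assert st_.max == pytest.approx(2.44, abs=0.01)

    def test_mean_matches_brute_force(self, bundle):
        cd = bundle.dustiness_records("CD")
        rd = bundle.dustiness_records("RD")
        st_ = di_ratio_stats(cd, rd, "inhalable")
        rd_by_name = {r.material: r for r in rd}
        brute = [
            c.w_inhalable / rd_by_name[c.material].w_inhalable for c in cd
        ]
        assert st_.mean == pytest.approx(sum(brute) / len(brute), rel=1e-12)
        assert len(st_.per_material_ratio) == len(cd)

    def test_identical_lists_give_unit_ratios(self, bundle):
        cd = bundle.dustiness_records("CD")
        st_ = di_ratio_stats(cd, cd, "respirable")
        assert st_.mean == st_.min == st_.max == 1.0

    def test_mismatched_materials_rejected(self, simple_record):
        other = DustinessRecord("other", "RD", 10.0, 1.0)
        with pytest.raises(ValueError):
            di_ratio_stats([simple_record], [other], "inhalable")

    def test_zero_rd_index_reported(self, simple_record):
        zero = DustinessRecord("test powder", "RD", 0.0, 0.0)
        with pytest.raises(ZeroDivisionError, match="test powder"):
            di_ratio_stats([simple_record], [zero], "inhalable")


class TestCorrectedH:
    @pytest.mark.parametrize(
        "h, ratio, expected", [(1.0, 25.10, 0.04), (0.5, 25.10, 0.02)]
    )
    def test_published_rescaling(self, h, ratio, expected):
        assert corrected_h(h, ratio, 2) == expected

    def test_unit_ratio_is_identity(self):
        assert corrected_h(0.73, 1.0, 6) == 0.73

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            corrected_h(1.0, 0.0, 2)


class TestControlConversion:
    @given(pct=st.floats(0.0, 100.0))
    def test_round_trip(self, pct):
        assert reduction_pct_from_retained(
            retained_from_reduction_pct(pct)
        ) == pytest.approx(pct, abs=1e-9)

    def test_seventy_percent_reduction_retains_30pct(self):
        assert retained_from_reduction_pct(70.0) == pytest.approx(0.3)
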