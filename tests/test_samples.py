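import io
import math

import numpy as np
import pytest

from aquarisk.errors import DomainError, EmptyStratumError, IntegrityError, ParseError
from aquarisk.samples import (
    BELOW_DETECTION,
    NOT_DETECTED,
    WaterSample,
    classify_correlation,
    read_sample_table,
    samples_to_csv_text,
    summarize,
    violation_rate,
    write_sample_table,
)

HEADER = "location_id,district,source_type,replicate,x,y,Pb[ug/L],Cr[mg/L],pH\n"


def _read(text):
    return read_sample_table(io.StringIO(text))


def _well(loc, rep, pb, district="Atan"):
    return WaterSample(loc, district, "well", rep, 0.0, 0.0, {"Pb": pb})


class TestReadSampleTable:
    def test_full_synthetic_roundtrip(self, study_samples):
        text = samples_to_csv_text(study_samples)
        back = _read(text)
        assert len(back) == 108
        assert len({s.location_id for s in back}) == 36
        for a, b in zip(study_samples, back):
            assert a.location_id == b.location_id
            assert a.values == b.values
            assert a.detection_flags == b.detection_flags

    def test_header_only_gives_empty_list(self):
        assert _read(HEADER) == []

    def test_censored_cell_records_detection_limit(self):
        rows = _read(HEADER + "L1,Iju,well,1,0,0,12.0,<0.00001,6.5\n")
        (s,) = rows
        assert s.flag("Cr") == BELOW_DETECTION
        # mg/L column: the 0.00001 limit converts to canonical µg/L
        assert s.detection_limits["Cr"] == pytest.approx(0.01)
        assert "Cr" not in s.values

    def test_nd_cell_flags_not_detected(self):
        (s,) = _read(HEADER + "L1,Atan,well,1,0,0,ND,ND,6.5\n")
        assert s.flag("Pb") == NOT_DETECTED

    def test_unit_conversion_on_metal_columns(self):
        (s,) = _read(HEADER + "L1,Atan,well,1,0,0,5.0,0.003,6.5\n")
        assert s.values["Pb"] == 5.0          # already µg/L
        assert s.values["Cr"] == pytest.approx(3.0)  # mg/L -> µg/L

    def test_malformed_cell_names_row_and_column(self):
        with pytest.raises(ParseError, match="Pb"):
            _read(HEADER + "L1,Atan,well,1,0,0,oops,0.003,6.5\n")

    def test_duplicate_location_replicate_rejected(self):
        body = "L1,Atan,well,1,0,0,5.0,0.003,6.5\n" * 2
        with pytest.raises(IntegrityError):
            _read(HEADER + body)


class TestWaterSampleInvariants:
    def test_negative_measured_value_rejected(self):
        with pytest.raises(DomainError):
            WaterSample("L1", "Atan", "well", 1, 0, 0, {"Pb": -1.0})

    def test_ph_outside_scale_rejected(self):
        with pytest.raises(DomainError):
            WaterSample("L1", "Atan", "well", 1, 0, 0, {"pH": 15.0})


class TestSummarize:
    def test_hand_arithmetic(self):
        samples = [_well(f"L{i}", 1, v) for i, v in enumerate((1.0, 2.0, 3.0))]
        st = summarize(samples, "Pb")
        assert (st.min, st.mean, st.max) == (1.0, 2.0, 3.0)
        assert st.sd == pytest.approx(1.0)

    def test_matches_two_pass_oracle_to_12_digits(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(1.0, 0.8, 100)
        samples = [_well(f"L{i}", 1, v) for i, v in enumerate(vals)]
        st = summarize(samples, "Pb")
        # independent two-pass oracle with compensated summation
        mean = math.fsum(vals) / len(vals)
        var = math.fsum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
        assert st.mean == pytest.approx(mean, rel=1e-12)
        assert st.sd == pytest.approx(math.sqrt(var), rel=1e-12)

    def test_generated_stratum_respects_configured_bounds(self, study_samples):
        st = summarize(study_samples, "Pb", district="Iju")
        assert st.min >= 11.7 and st.max <= 427.2

    def test_censored_values_enter_at_half_detection_limit(self):
        s = WaterSample("L1", "Iju", "well", 1, 0, 0, {},
                        {"Cr": BELOW_DETECTION}, {"Cr": 0.01})
        st = summarize([s], "Cr")
        assert st.mean == pytest.approx(0.005)

    def test_empty_stratum_raises(self):
        with pytest.raises(EmptyStratumError):
            summarize([_well("L1", 1, 5.0)], "Pb", district="Iju")

    def test_self_concatenation_invariant_population_sd(self):
        samples = [_well(f"L{i}", 1, v) for i, v in enumerate((1.0, 2.0, 7.0))]
        doubled = samples + [_well(f"M{i}", 1, v)
                             for i, v in enumerate((1.0, 2.0, 7.0))]
        a = summarize(samples, "Pb", ddof=0)
        b = summarize(doubled, "Pb", ddof=0)
        assert (a.min, a.max, a.mean) == (b.min, b.max, b.mean)
        assert a.sd == pytest.approx(b.sd, rel=1e-12)


class TestViolationRate:
    def _boreholes(self, loc_values):
        out = []
        for i, v in enumerate(loc_values):
            for rep in (1, 2, 3):
                out.append(WaterSample(f"B{i}", "Atan", "borehole", rep,
                                       0, 0, {"Pb": v}))
        return out

    def test_four_of_nine_locations(self):
        samples = self._boreholes([20.0] * 4 + [5.0] * 5)
        assert violation_rate(samples, "Pb", 10.0) == pytest.approx(400.0 / 9)

    def test_none_above(self):
        assert violation_rate(self._boreholes([5.0] * 9), "Pb", 10.0) == 0.0

    def test_all_above(self):
        assert violation_rate(self._boreholes([20.0] * 9), "Pb", 10.0) == 100.0

    def test_replicates_average_before_counting(self):
        # one replicate spikes above the limit but the location mean stays below
        samples = [
            WaterSample("B0", "Atan", "borehole", r, 0, 0, {"Pb": v})
            for r, v in [(1, 12.0), (2, 5.0), (3, 5.0)]
        ]
        assert violation_rate(samples, "Pb", 10.0) == 0.0

    def test_reorder_and_rescale_invariance(self):
        vals = [20.0, 3.0, 15.0, 8.0, 30.0, 2.0, 9.0, 11.0, 1.0]
        base = self._boreholes(vals)
        rate = violation_rate(base, "Pb", 10.0)
        assert violation_rate(base[::-1], "Pb", 10.0) == rate
        scaled = self._boreholes([v * 7.5 for v in vals])
        assert violation_rate(scaled, "Pb", 75.0) == rate


class TestClassifyCorrelation:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.9125, "strong"), (0.6738, "moderate"), (0.4999, "weak"),
         (0.7, "strong"), (0.5, "moderate"), (0.0, "weak"), (1.0, "strong")],
    )
    def test_published_boundaries(self, r, expected):
        assert classify_correlation(r) == expected

    @pytest.mark.parametrize("r", [0.9125, 0.6738, 0.4999, 0.61])
    def test_sign_symmetric(self, r):
        assert classify_correlation(-r) == classify_correlation(r)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            classify_correlation(1.2)


def test_write_preserves_nd_and_censored_tokens(tmp_path):
    s = WaterSample("L1", "Iju", "well", 1, 1.0, 2.0, {"Pb": 12.0},
                    {"Pb": "measured", "Cd": NOT_DETECTED,
                     "Cr": BELOW_DETECTION},
                    {"Cr": 0.01})
    path = tmp_path / "t.csv"
    write_sample_table([s], path)
    (back,) = read_sample_table(path)
    assert back.flag("Cd") == NOT_DETECTED
    assert back.flag("Cr") == BELOW_DETECTION
    assert back.detection_limits["Cr"] == pytest.approx(0.01)
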