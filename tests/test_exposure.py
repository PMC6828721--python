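from fractions import Fraction

import numpy as np
import pytest

from aquarisk.errors import (
    ConfigurationError,
    DomainError,
    RouteError,
    ToxicityTableError,
)
from aquarisk.exposure import (
    DoseResult,
    ExposureProfile,
    cdi_dermal,
    cdi_ingestion,
    classify_ltcr,
    default_adult_profile,
    default_child_profile,
    default_toxicity,
    hazard_quotient,
    lifetime_cancer_risk,
)

ADULT = ExposureProfile("adult", ir_w=2.0, ef_r=350.0, ed=30.0, bw=70.0,
                        at_r=10950.0)


class TestIngestionDose:
    def test_hand_computed_value(self):
        # 70 µg/L × 2 L/d × 350 d/y × 30 y / (70 kg × 10950 d)
        expected = Fraction(70 * 2 * 350 * 30, 70 * 10950)
        dose = cdi_ingestion(70.0, ADULT)
        assert dose.cdi == pytest.approx(float(expected), rel=1e-12)
        assert dose.cdi == pytest.approx(1.91781, rel=1e-5)

    def test_zero_concentration(self):
        assert cdi_ingestion(0.0, ADULT).cdi == 0.0

    def test_doubling_body_weight_halves_dose(self):
        heavy = ExposureProfile("adult", ir_w=2.0, ef_r=350.0, ed=30.0,
                                bw=140.0, at_r=10950.0)
        assert cdi_ingestion(70.0, heavy).cdi == pytest.approx(
            cdi_ingestion(70.0, ADULT).cdi / 2, rel=1e-12)

    def test_independent_of_ed_under_noncarcinogenic_averaging(self):
        a = ExposureProfile("a", ir_w=2.0, ef_r=350.0, ed=30.0, bw=70.0).noncarcinogenic()
        b = ExposureProfile("a", ir_w=2.0, ef_r=350.0, ed=6.0, bw=70.0).noncarcinogenic()
        assert cdi_ingestion(70.0, a).cdi == pytest.approx(
            cdi_ingestion(70.0, b).cdi, rel=1e-12)

    def test_nonfinite_concentration_rejected(self):
        with pytest.raises(DomainError):
            cdi_ingestion(float("nan"), ADULT)

    def test_missing_averaging_time_rejected(self):
        p = ExposureProfile("a", ir_w=2.0, ef_r=350.0, ed=30.0, bw=70.0)
        with pytest.raises(ConfigurationError):
            cdi_ingestion(70.0, p)


class TestDermalDose:
    def test_hand_computed_value(self):
        expected = (Fraction(1000) * 18000 * Fraction(1, 1000) * 350 * 30
                    * Fraction(58, 100) * Fraction(1, 1000)
                    / (70 * 10950))
        p = ExposureProfile("adult", ir_w=2.0, ef_r=350.0, ed=30.0, bw=70.0,
                            at_r=10950.0, sa=18000.0, k_p=0.001, et=0.58)
        dose = cdi_dermal(1000.0, p)
        assert dose.cdi == pytest.approx(float(expected), rel=1e-12)

    def test_zero_concentration(self):
        assert cdi_dermal(0.0, ADULT).cdi == 0.0

    @pytest.mark.parametrize("factor", ["sa", "k_p", "ef_r", "ed", "et"])
    def test_linear_in_each_numerator_factor(self, factor):
        from dataclasses import replace

        base = cdi_dermal(500.0, ADULT).cdi
        doubled = replace(ADULT, **{factor: getattr(ADULT, factor) * 2})
        assert cdi_dermal(500.0, doubled).cdi == pytest.approx(2 * base, rel=1e-12)

    def test_missing_permeability_rejected(self):
        from dataclasses import replace

        p = replace(ADULT, k_p=None)
        with pytest.raises(ConfigurationError):
            cdi_dermal(500.0, p)


class TestHazardQuotient:
    def test_identity_threshold(self):
        tox = default_toxicity()
        dose = DoseResult(1.4, "ingestion", metal="Pb")
        assert hazard_quotient(dose, tox) == 1.0

    def test_nickel_quotient(self):
        tox = default_toxicity()
        dose = DoseResult(0.2, "ingestion", metal="Ni")
        assert hazard_quotient(dose, tox) == pytest.approx(0.01, rel=1e-12)

    def test_unit_cancellation(self):
        # expressing both CDI and RfD in mg/kg·day leaves HQ unchanged
        from aquarisk.exposure import ToxicityReference

        hq_ug = hazard_quotient(DoseResult(0.2, "ingestion", metal="Ni"),
                                default_toxicity())
        tox_mg = ToxicityReference(rfd_ingestion={"Ni": 0.02})
        hq_mg = hazard_quotient(DoseResult(0.0002, "ingestion", metal="Ni"), tox_mg)
        assert hq_ug == pytest.approx(hq_mg, rel=1e-12)

    def test_quotient_times_rfd_recovers_dose(self):
        tox = default_toxicity()
        cdi = 0.7312
        hq = hazard_quotient(DoseResult(cdi, "ingestion", metal="Mn"), tox)
        assert hq * tox.rfd("Mn", "ingestion") == pytest.approx(cdi, rel=1e-15)

    def test_absent_rfd_is_an_error_not_zero(self):
        with pytest.raises(ToxicityTableError):
            hazard_quotient(DoseResult(0.2, "ingestion", metal="Cd"),
                            default_toxicity())


class TestLifetimeCancerRisk:
    def test_nickel_product_and_classification(self):
        # 1e-4 mg/kg·day = 0.1 µg/kg·day; SF(Ni) = 1.7 -> 1.7e-4, above band
        ltcr, label = lifetime_cancer_risk(
            DoseResult(0.1, "ingestion", metal="Ni"), default_toxicity())
        assert ltcr == pytest.approx(1.7e-4, rel=1e-12)
        assert label == "above_acceptable"

    def test_chromium_inside_acceptable_band(self):
        # 2e-5 mg/kg·day with SF(Cr) = 0.5 -> 1e-5
        ltcr, label = lifetime_cancer_risk(
            DoseResult(0.02, "ingestion", metal="Cr"), default_toxicity())
        assert ltcr == pytest.approx(1e-5, rel=1e-12)
        assert label == "acceptable"

    def test_zero_dose(self):
        ltcr, label = lifetime_cancer_risk(
            DoseResult(0.0, "ingestion", metal="Ni"), default_toxicity())
        assert ltcr == 0.0 and label == "below_acceptable"

    def test_dermal_route_rejected(self):
        with pytest.raises(RouteError):
            lifetime_cancer_risk(DoseResult(0.1, "dermal", metal="Ni"),
                                 default_toxicity())

    def test_absent_slope_factor_rejected(self):
        with pytest.raises(ToxicityTableError):
            lifetime_cancer_risk(DoseResult(0.1, "ingestion", metal="Fe"),
                                 default_toxicity())


def test_risk_linear_in_concentration():
    """Dose, HQ and LTCR all scale linearly with concentration."""
    rng = np.random.default_rng(2)
    tox = default_toxicity()
    for _ in range(20):
        ir, ef, ed, bw = rng.uniform(0.5, 3), rng.uniform(200, 365), \
            rng.uniform(5, 40), rng.uniform(10, 100)
        p = ExposureProfile("p", ir_w=ir, ef_r=ef, ed=ed, bw=bw,
                            at_r=70 * 365.0)
        c, k = rng.uniform(1, 500), rng.uniform(0.1, 10)
        hq1 = hazard_quotient(cdi_ingestion(c, p, metal="Ni"), tox)
        hqk = hazard_quotient(cdi_ingestion(k * c, p, metal="Ni"), tox)
        assert hqk == pytest.approx(k * hq1, rel=1e-12)
        l1, _ = lifetime_cancer_risk(cdi_ingestion(c, p, metal="Ni"), tox)
        lk, _ = lifetime_cancer_risk(cdi_ingestion(k * c, p, metal="Ni"), tox)
        assert lk == pytest.approx(k * l1, rel=1e-12)


def test_default_toxicity_tables_reflect_configuration_flag():
    assert default_toxicity().rfd("Pb", "ingestion") == 1.4
    assert default_toxicity(pb_rfd_printed=True).rfd("Pb", "ingestion") == 140.0
    tox = default_toxicity()
    assert tox.sf("Ni") == 1.7 and tox.sf("Pb") == 0.0085 and tox.sf("Cr") == 0.5
    # dermal falls back to the oral value unless configured
    assert tox.rfd("Ni", "dermal") == tox.rfd("Ni", "ingestion")


def test_default_profiles():
    adult, child = default_adult_profile(), default_child_profile()
    assert adult.ir_w == 2.0 and adult.bw == 70.0
    assert child.ed <= adult.ed
    assert adult.cf == 0.001


def test_classify_ltcr_band_edges():
    assert classify_ltcr(5e-7) == "below_acceptable"
    assert classify_ltcr(5e-5) == "acceptable"
    assert classify_ltcr(2e-4) == "above_acceptable"
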