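"""AMS reduction: normalisation, background and blank corrections, precision."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bombpulse import (AMSRecord, BlankModel, F14CValue, PrecisionPolicy,
                       background_correct, batch_precision, blank_mass_correct,
                       fraction_modern, reduce_record)
from bombpulse.ams import fractionation_factor, read_ams_records, write_f14c_table
from bombpulse.errors import (CorrectionError, ParameterError, ParseError,
                              ReductionError)


def _record(ratio_sample, ratio_standard=1.0, delta13c=-25.0, mass=100.0,
            **kw):
    return AMSRecord(sample_id="s1", ratio_sample=ratio_sample,
                     ratio_standard=ratio_standard, delta13c=delta13c,
                     carbon_mass_total=mass, **kw)


class TestFractionModern:
    def test_definition_of_modern(self):
        # sample ratio exactly 0.95 x normalised standard, delta13C = -25
        rec = _record(ratio_sample=0.95 * 2.0, ratio_standard=2.0)
        assert fraction_modern(rec).f14c == pytest.approx(1.0, abs=1e-15)

    def test_fractionation_fixed_point(self):
        assert fractionation_factor(-25.0) == pytest.approx(1.0, abs=1e-15)

    def test_scales_linearly_with_sample_ratio(self):
        rec = _record(ratio_sample=1.10 * 0.95 * 2.0, ratio_standard=2.0)
        assert fraction_modern(rec).f14c == pytest.approx(1.10, abs=1e-12)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(derandomize=True, max_examples=40)
    def test_invariant_under_common_ratio_scaling(self, scale):
        a = fraction_modern(_record(1.2, 1.0, delta13c=-21.0))
        b = fraction_modern(_record(1.2 * scale, 1.0 * scale, delta13c=-21.0))
        assert b.f14c == pytest.approx(a.f14c, rel=1e-12)

    def test_counting_statistics_sigma_when_supplied(self):
        rec = _record(ratio_sample=0.95, sigma_ratio_sample=0.0095)
        v = fraction_modern(rec)
        assert v.sigma == pytest.approx(v.f14c * 0.01, rel=1e-12)

    def test_rejects_non_positive_ratios(self):
        with pytest.raises(ReductionError):
            _record(ratio_sample=0.0)
        with pytest.raises(ReductionError):
            _record(ratio_sample=1.0, ratio_standard=-1.0)


class TestBackgroundCorrect:
    def test_zero_background_is_identity(self):
        v = background_correct(F14CValue(1.300, 0.010), F14CValue(0.0, 0.0))
        assert (v.f14c, v.sigma) == (1.300, 0.010)

    def test_subtraction_with_quadrature_sigma(self):
        v = background_correct(F14CValue(1.300, 0.010), F14CValue(0.005, 0.001))
        assert v.f14c == pytest.approx(1.295, abs=1e-12)
        assert v.sigma == pytest.approx(math.hypot(0.010, 0.001), abs=1e-12)
        assert v.sigma == pytest.approx(0.01005, abs=5e-6)

    def test_background_above_raw_clips_to_zero_with_flag(self):
        v = background_correct(F14CValue(0.003, 0.001), F14CValue(0.005, 0.001))
        assert v.f14c == 0.0
        assert "clipped_at_zero" in v.flags


class TestBlankMassCorrect:
    BLANK = BlankModel(f14c_blank=0.60, sigma_f_blank=0.0,
                       mass_blank=15.0, sigma_mass_blank=0.0)

    def test_worked_mass_balance(self):
        v = blank_mass_correct(F14CValue(1.200, 0.0), self.BLANK, 100.0)
        assert v.f14c == pytest.approx((1.200 * 100 - 0.60 * 15) / 85, abs=1e-12)
        assert v.f14c == pytest.approx(1.30588, abs=5e-6)

    def test_zero_blank_mass_is_identity(self):
        blank = BlankModel(f14c_blank=0.60, mass_blank=0.0)
        v = blank_mass_correct(F14CValue(1.2, 0.01), blank, 100.0)
        assert v.f14c == pytest.approx(1.2, abs=1e-15)

    @given(mass=st.floats(min_value=0.1, max_value=49.9))
    @settings(derandomize=True, max_examples=30)
    def test_mixing_fixed_point(self, mass):
        blank = BlankModel(f14c_blank=1.2, mass_blank=mass)
        v = blank_mass_correct(F14CValue(1.2, 0.0), blank, 50.0 + mass)
        assert v.f14c == pytest.approx(1.2, rel=1e-12)

    @given(f_s=st.floats(min_value=0.1, max_value=2.0),
           f_b=st.floats(min_value=0.0, max_value=2.0),
           m_b=st.floats(min_value=0.0, max_value=30.0),
           m_s=st.floats(min_value=40.0, max_value=120.0))
    @settings(derandomize=True, max_examples=100)
    def test_exact_inverse_of_forward_mixing(self, f_s, f_b, m_b, m_s):
        m_total = m_s + m_b
        f_mixed = (f_s * m_s + f_b * m_b) / m_total
        blank = BlankModel(f14c_blank=f_b, mass_blank=m_b)
        v = blank_mass_correct(F14CValue(max(f_mixed, 0.0), 0.0), blank, m_total)
        assert v.f14c == pytest.approx(f_s, abs=1e-12)

    def test_sigma_monotone_in_each_input_sigma(self):
        base = blank_mass_correct(
            F14CValue(1.2, 0.01),
            BlankModel(0.6, 0.01, 15.0, 1.0), 100.0).sigma
        for bumped in (
            blank_mass_correct(F14CValue(1.2, 0.02),
                               BlankModel(0.6, 0.01, 15.0, 1.0), 100.0),
            blank_mass_correct(F14CValue(1.2, 0.01),
                               BlankModel(0.6, 0.05, 15.0, 1.0), 100.0),
            blank_mass_correct(F14CValue(1.2, 0.01),
                               BlankModel(0.6, 0.01, 15.0, 3.0), 100.0),
        ):
            assert bumped.sigma >= base

    def test_monte_carlo_propagation_agrees_with_delta_method(self):
        blank = BlankModel(0.6, 0.02, 15.0, 2.0)
        delta = blank_mass_correct(F14CValue(1.2, 0.01), blank, 100.0)
        mc = blank_mass_correct(F14CValue(1.2, 0.01), blank, 100.0,
                                method="mc", seed=7)
        assert mc.sigma == pytest.approx(delta.sigma, rel=0.1)

    def test_blank_dominating_raises(self):
        blank = BlankModel(f14c_blank=0.6, mass_blank=50.0)
        with pytest.raises(CorrectionError):
            blank_mass_correct(F14CValue(1.2, 0.0), blank, 40.0)

    def test_implausible_blank_mass_rejected(self):
        with pytest.raises(ParameterError):
            BlankModel(f14c_blank=0.6, mass_blank=80.0)


class TestBatchPrecision:
    def test_half_percent_above_mass_threshold(self):
        assert batch_precision(1.300, 100.0) == pytest.approx(0.0065, abs=1e-12)

    def test_low_mass_uses_coarse_precision(self):
        assert batch_precision(1.000, 30.0) == pytest.approx(0.0200, abs=1e-12)

    def test_batch_multiplier_scales_sigma(self):
        policy = PrecisionPolicy(batch_multipliers={"b2": 2.0})
        assert batch_precision(1.0, 100.0, policy, "b2") == pytest.approx(0.0100)
        assert batch_precision(1.0, 100.0, policy, "b1") == pytest.approx(0.0050)

    def test_non_positive_mass_rejected(self):
        with pytest.raises(ParameterError):
            batch_precision(1.0, 0.0)


class TestIO:
    def test_raw_records_round_trip(self, tmp_path):
        path = tmp_path / "raw.csv"
        path.write_text(
            "sample_id,ratio_sample,ratio_standard,delta13c,"
            "carbon_mass_total,batch_id,machine_background\n"
            "s1,1.14,1.0,-25,100,b0,0.001\n"
        )
        (rec,) = read_ams_records(path)
        assert rec.sample_id == "s1"
        assert fraction_modern(rec).f14c == pytest.approx(1.2, abs=1e-12)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "raw.csv"
        path.write_text("sample_id,ratio_sample\ns1,1.14\n")
        with pytest.raises(ParseError):
            read_ams_records(path)

    def test_reduced_table_written(self, tmp_path):
        path = tmp_path / "red.csv"
        write_f14c_table({"s1": F14CValue(1.2, 0.006)}, path)
        assert "s1,1.2,0.006" in path.read_text()


def test_reduce_record_runs_the_full_chain():
    blank = BlankModel(f14c_blank=0.60, mass_blank=15.0)
    # mixed value 1.200 plus background 0.001, delta13C at the reference
    rec = _record(ratio_sample=0.95 * 1.201, ratio_standard=1.0,
                  machine_background=0.001)
    v = reduce_record(rec, blank)
    assert v.f14c == pytest.approx((1.200 * 100 - 9.0) / 85.0, abs=1e-9)
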