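"""Cohort pipeline: per-donor predictions, regression, model object, I/O."""

import numpy as np
import pytest

from bombpulse import (AMSRecord, BirthDateModel, BlankModel, DonorRecord,
                       F14CValue, PipelineConfig, predict_birth_years,
                       read_donor_table, regress, synthetic_bomb_value,
                       write_donor_table)
from bombpulse.errors import ParseError, RegressionError


def _donor(i, birth, f14c, sigma, collection=2010.0):
    return DonorRecord(f"d{i}", birth, collection, f14c=F14CValue(f14c, sigma))


def _falling_limb_cohort(sigma=1e-6, n=23, births=(1966.0, 1993.0)):
    return [
        _donor(i, b, float(synthetic_bomb_value(b)), sigma)
        for i, b in enumerate(np.linspace(*births, n))
    ]


class TestRegress:
    def test_hand_checked_ols(self):
        donors = []
        for i, (x, y) in enumerate([(1960, 1961), (1970, 1969),
                                    (1980, 1980), (1990, 1990)]):
            d = _donor(i, float(x), 1.0, 0.01)
            d.predicted_year = float(y)
            donors.append(d)
        fit = regress(donors)
        assert fit.slope == pytest.approx(0.98, abs=1e-4)
        assert fit.intercept == pytest.approx(39.5, abs=1e-4)
        assert fit.r_squared == pytest.approx(0.9963, abs=1e-4)
        assert fit.n == 4

    def test_identity_line(self):
        donors = []
        for i, x in enumerate([1950.0, 1960.0, 1970.0, 1980.0]):
            d = _donor(i, x, 1.0, 0.01)
            d.predicted_year = x
            donors.append(d)
        fit = regress(donors)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_too_few_points(self):
        donors = []
        for i, x in enumerate([1960.0, 1970.0]):
            d = _donor(i, x, 1.0, 0.01)
            d.predicted_year = x
            donors.append(d)
        with pytest.raises(RegressionError):
            regress(donors)

    def test_zero_variance_predictor(self):
        donors = []
        for i in range(4):
            d = _donor(i, 1970.0, 1.0, 0.01)
            d.predicted_year = 1970.0 + i
            donors.append(d)
        with pytest.raises(RegressionError):
            regress(donors)

    def test_weighted_variant_runs(self):
        donors = []
        for i, x in enumerate(np.linspace(1960, 1990, 6)):
            d = _donor(i, float(x), 1.0, 0.01)
            d.predicted_year = float(x) + (-1) ** i * 0.5
            d.predicted_sigma = 0.5 + 0.1 * i
            donors.append(d)
        fit = regress(donors, weighted=True)
        assert 0.9 < fit.slope < 1.1


class TestPredictBirthYears:
    def test_noiseless_round_trip_on_correct_limb(self, bomb_curve):
        donors = [_donor(0, 1975.0, float(synthetic_bomb_value(1975.0)), 1e-6)]
        config = PipelineConfig(prior_range=(1966.0, 2000.0))
        (done,) = predict_birth_years(donors, bomb_curve, config)
        assert done.predicted_year == pytest.approx(1975.0, abs=2 * 0.05)
        assert done.predicted_sigma is not None and done.predicted_sigma > 0

    def test_nearest_rule_resolves_the_bimodal_ambiguity(self, bomb_curve):
        donors = [_donor(0, 1960.5, 1.300, 0.005)]
        config = PipelineConfig(point_rule="nearest")
        (done,) = predict_birth_years(donors, bomb_curve, config)
        assert done.predicted_year == pytest.approx(1960.25, abs=0.05)

    def test_raw_records_are_reduced_then_calibrated(self, bomb_curve):
        truth = float(synthetic_bomb_value(1975.0))
        blank = BlankModel(f14c_blank=0.60, mass_blank=15.0)
        mixed = (truth * 85.0 + 0.60 * 15.0) / 100.0
        rec = AMSRecord("d0", ratio_sample=0.95 * mixed, ratio_standard=1.0,
                        delta13c=-25.0, carbon_mass_total=100.0)
        donor = DonorRecord("d0", 1975.0, 2010.0, ams=rec)
        config = PipelineConfig(prior_range=(1966.0, 2000.0), blank=blank)
        (done,) = predict_birth_years([donor], bomb_curve, config)
        assert done.f14c.f14c == pytest.approx(truth, abs=1e-9)
        assert done.predicted_year == pytest.approx(1975.0, abs=0.5)

    def test_failing_donor_is_isolated(self, bomb_curve):
        good = _donor(0, 1975.0, float(synthetic_bomb_value(1975.0)), 0.005)
        bad_rec = AMSRecord("d1", ratio_sample=1.0, ratio_standard=1.0,
                            delta13c=-25.0, carbon_mass_total=12.0)
        bad = DonorRecord("d1", 1975.0, 2010.0, ams=bad_rec)
        config = PipelineConfig(blank=BlankModel(f14c_blank=0.6, mass_blank=15.0))
        solo = predict_birth_years([good], bomb_curve, config)
        both = predict_birth_years([good, bad], bomb_curve, config)
        assert both[1].error is not None and "error" in both[1].flags
        assert both[0].predicted_year == solo[0].predicted_year

    def test_order_independence(self, bomb_curve):
        donors = _falling_limb_cohort(sigma=0.005, n=5)
        fwd = predict_birth_years(donors, bomb_curve)
        rev = predict_birth_years(donors[::-1], bomb_curve)
        fwd_map = {d.donor_id: d.predicted_year for d in fwd}
        for d in rev:
            assert d.predicted_year == fwd_map[d.donor_id]


class TestBirthDateModel:
    def test_noiseless_cohort_recovers_the_identity_line(self, bomb_curve_exact):
        # sigma just above the grid's F14C resolution so the posterior
        # resolves the falling limb rather than snapping to a single cell
        donors = _falling_limb_cohort(sigma=1e-3)
        results = BirthDateModel(donors, bomb_curve_exact).fit()
        fit = results.regression
        assert fit.slope == pytest.approx(1.0, abs=1e-3)
        assert fit.intercept == pytest.approx(0.0, abs=2.0)
        assert fit.r_squared >= 0.9999
        assert fit.n == 23

    def test_summary_and_frame(self, bomb_curve):
        donors = _falling_limb_cohort(sigma=0.005, n=6)
        results = BirthDateModel(donors, bomb_curve).fit()
        assert "slope" in results.summary()
        frame = results.to_frame()
        assert len(frame) == 6
        assert set(frame.columns) >= {"donor_id", "predicted_year",
                                      "predicted_sigma", "point_rule"}

    def test_from_dataframe(self, bomb_curve):
        import pandas as pd
        frame = pd.DataFrame({
            "donor_id": ["a", "b", "c", "d"],
            "birth_year": [1970.0, 1975.0, 1980.0, 1985.0],
            "collection_year": [2010.0] * 4,
            "f14c": [float(synthetic_bomb_value(b))
                     for b in (1970.0, 1975.0, 1980.0, 1985.0)],
            "sigma": [0.005] * 4,
        })
        results = BirthDateModel.from_dataframe(frame, bomb_curve).fit()
        assert results.regression.slope == pytest.approx(1.0, abs=0.05)


class TestDonorIO:
    def test_round_trip_and_determinism(self, tmp_path, bomb_curve):
        donors = _falling_limb_cohort(sigma=0.005, n=5)
        done = predict_birth_years(donors, bomb_curve)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_donor_table(done, p1)
        write_donor_table(predict_birth_years(donors, bomb_curve), p2)
        assert p1.read_bytes() == p2.read_bytes()
        again = read_donor_table(p1, midyear_births="never")
        assert [d.donor_id for d in again] == [d.donor_id for d in done]

    def test_documented_whole_year_maps_to_midyear(self, tmp_path):
        path = tmp_path / "donors.csv"
        path.write_text("donor_id,birth_year,collection_year,f14c,sigma\n"
                        "d0,1970,2010,1.3,0.005\n")
        (donor,) = read_donor_table(path)
        assert donor.birth_year == 1970.5
        (literal,) = read_donor_table(path, midyear_births="never")
        assert literal.birth_year == 1970.0

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "donors.csv"
        path.write_text("donor_id,birth_year\nd0,1970\n")
        with pytest.raises(ParseError):
            read_donor_table(path)

    def test_collection_before_birth_rejected(self):
        with pytest.raises(ParseError):
            DonorRecord("d0", 1990.0, 1980.0, f14c=F14CValue(1.2, 0.01))
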