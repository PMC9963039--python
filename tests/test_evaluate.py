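"""Evaluation metrics: RMSE, accuracy band, correlations, paired statistics."""

import numpy as np
import pandas as pd
import pytest

import liftrisk as lr
from liftrisk import evaluate


class TestRmse:
    def test_identity_zero(self):
        assert lr.rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_value(self):
        assert lr.rmse([60.0, 50.0], [50.0, 50.0]) == pytest.approx(np.sqrt(50), rel=1e-12)

    def test_constant_offset(self):
        truth = np.linspace(10, 90, 7)
        assert lr.rmse(truth + 5.0, truth) == pytest.approx(5.0, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lr.rmse([1.0], [1.0, 2.0])

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(0)
        est, tru = rng.uniform(0, 100, 500), rng.uniform(0, 100, 500)
        loop = np.sqrt(sum((e - t) ** 2 for e, t in zip(est, tru)) / 500)
        assert lr.rmse(est, tru) == pytest.approx(loop, rel=1e-12)


class TestWithinBand:
    def test_boundary_inclusive(self):
        # lab risk 65% counts estimates from 55% to 75% as within
        assert lr.within_band_fraction([75.0], [65.0]) == 1.0
        assert lr.within_band_fraction([55.0], [65.0]) == 1.0

    def test_just_outside(self):
        assert lr.within_band_fraction([75.01], [65.0]) == 0.0

    def test_identity_full(self):
        x = np.linspace(0, 100, 11)
        assert lr.within_band_fraction(x, x) == 1.0

    def test_monotone_in_band(self):
        rng = np.random.default_rng(1)
        tru = rng.uniform(20, 80, 200)
        est = tru + rng.normal(0, 8, 200)
        fracs = [lr.within_band_fraction(est, tru, b) for b in (0, 5, 10, 20)]
        assert fracs == sorted(fracs)

    def test_negative_band_rejected(self):
        with pytest.raises(ValueError):
            lr.within_band_fraction([1.0], [1.0], band=-1)


class TestFisherAverage:
    def test_idempotent_on_equal_values(self):
        assert lr.fisher_average([0.5, 0.5]) == pytest.approx(0.5, rel=1e-12)

    def test_hand_value(self):
        # atanh(0.8) = ln 3, tanh(ln(3)/2) = 1/2 exactly
        assert lr.fisher_average([0.0, 0.8]) == pytest.approx(0.5, rel=1e-12)

    def test_single_value_identity(self):
        assert lr.fisher_average([0.73]) == pytest.approx(0.73, rel=1e-12)

    def test_bounded_by_extremes(self):
        rng = np.random.default_rng(2)
        rs = rng.uniform(-0.9, 0.9, 10)
        pooled = lr.fisher_average(rs)
        assert rs.min() <= pooled <= rs.max()

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError):
            lr.fisher_average([0.5, 1.0])


class TestPearsonByParticipant:
    def _results(self, transform):
        rng = np.random.default_rng(3)
        frames = []
        for pid in range(3):
            lab = rng.uniform(0.2, 0.8, 50)
            frames.append(
                pd.DataFrame(
                    {"participant_id": pid, "risk_lab": lab, "risk_trunk": transform(lab, rng)}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_perfect_correlation(self):
        res = self._results(lambda lab, rng: lab)
        assert np.allclose(lr.pearson_by_participant(res, "trunk"), 1.0)

    def test_anticorrelation(self):
        res = self._results(lambda lab, rng: -lab + 1.0)
        assert np.allclose(lr.pearson_by_participant(res, "trunk"), -1.0)

    def test_noise_attenuation(self):
        rng = np.random.default_rng(4)
        lab = rng.uniform(0.2, 0.8, 1000)
        noisy = lab + rng.normal(0, np.std(lab), 1000)
        res = pd.DataFrame({"participant_id": 0, "risk_lab": lab, "risk_trunk": noisy})
        r = lr.pearson_by_participant(res, "trunk")[0]
        assert r == pytest.approx(np.sqrt(0.5), abs=0.05)

    def test_zero_variance_flagged(self):
        res = pd.DataFrame(
            {"participant_id": 0, "risk_lab": [0.5] * 10, "risk_trunk": np.linspace(0, 1, 10)}
        )
        with pytest.warns(UserWarning, match="zero variance"):
            r = lr.pearson_by_participant(res, "trunk")
        assert np.isnan(r[0])


class TestCompareConditions:
    def test_paired_t_hand_value(self):
        # differences [1, 2, 3]: t = 2 / (1 / sqrt(3)) = 2 sqrt(3)
        base = np.array([10.0, 11.0, 12.0])
        out = lr.compare_conditions(base + np.array([1.0, 2.0, 3.0]), base)
        assert out["t"] == pytest.approx(2 * np.sqrt(3), rel=1e-9)

    def test_identical_vectors_null_case(self):
        v = np.array([5.0, 6.0, 7.0, 8.0])
        with pytest.warns(UserWarning):
            out = lr.compare_conditions(v, v)
        assert out["t"] == 0.0 and out["cohens_d"] == 0.0

    def test_cohens_d_pooled_definition(self):
        # means 15.8 / 4.7, SDs 2.3 / 1.1 -> d = 11.1 / sqrt((2.3^2 + 1.1^2)/2)
        a = np.array([15.8 - 2.3, 15.8, 15.8 + 2.3])
        b = np.array([4.7 - 1.1, 4.7, 4.7 + 1.1])
        out = lr.compare_conditions(a, b)
        assert out["cohens_d"] == pytest.approx(11.1 / np.sqrt((2.3**2 + 1.1**2) / 2), rel=1e-9)

    def test_normality_p_reported(self):
        rng = np.random.default_rng(5)
        a = rng.normal(15, 2, 10)
        b = rng.normal(5, 1, 10)
        out = lr.compare_conditions(a, b)
        assert 0 <= out["ks_p_a"] <= 1 and 0 <= out["ks_p_b"] <= 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            lr.compare_conditions([1.0, 2.0], [1.0, 2.0])


class TestTrunkRiskDrivers:
    def test_shuffled_independence(self):
        rng = np.random.default_rng(6)
        n = 10_000
        res = pd.DataFrame(
            {
                "risk_trunk": rng.uniform(0.3, 0.7, n),
                "n_lifts": rng.integers(800, 2001, n),
                "mean_bend_angle": rng.uniform(20, 90, n),
            }
        )
        out = lr.trunk_risk_drivers(res)
        assert abs(out["r_vs_lift_count"]) < 0.05
        assert abs(out["r_vs_bend_angle"]) < 0.05

    def test_constant_lookup_risk_tracks_lift_count(self):
        from liftrisk import workday

        n = np.arange(800, 2001, 10)
        risk = np.array([workday.lift_counter_baseline(int(k)) for k in n])
        res = pd.DataFrame({"risk_trunk": risk, "n_lifts": n, "mean_bend_angle": 45.0})
        with pytest.warns(UserWarning):  # bend angle constant -> undefined r
            out = lr.trunk_risk_drivers(res)
        assert out["r_vs_lift_count"] > 0.99

    def test_lift_counter_monotone_in_count(self):
        from scipy.stats import spearmanr

        from liftrisk import workday

        n = np.arange(800, 2001, 50)
        risk = np.array([workday.lift_counter_baseline(int(k)) for k in n])
        assert spearmanr(n, risk).statistic == 1.0


class TestSummarize:
    def test_summary_structure(self, smoke_config):
        res = lr.run_pipeline(smoke_config)
        s = res.summary
        assert set(s["per_participant"]) == {"0", "1", "2"}
        entry = s["per_participant"]["0"]
        assert {"rmse_trunk", "rmse_trunkforce", "within10_trunk", "r_trunk"} <= set(entry)
        assert 0 <= entry["within10_trunk"] <= 1
        assert s["pooled"]["rmse_trunk_mean"] >= 0
        assert abs(s["pooled"]["r_trunkforce_pooled"]) <= 1
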