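"""Driver features, selection-inflated subsampling, and carryover regression."""

import numpy as np
import pandas as pd
import pytest

from swbweight import (
    SyntheticConfig,
    carryover_regression,
    correlation_percentile_curve,
    drivers_regression,
    generate_cohort,
    max_correlation_subsample,
    person_driver_features,
)
from swbweight.drivers import InsufficientDataError

from conftest import make_reportset, report_row


def person_frame(durs, scores, pid="p1"):
    return pd.DataFrame(
        {
            "person_id": pid,
            "method": "EMA",
            "day_index": 1 + np.arange(len(durs)) // 5,
            "duration_min": durs,
            "happiness": scores,
        }
    )


class TestDriverFeatures:
    def test_constant_duration_r_missing_diff_zero(self):
        f = person_frame([60, 60, 60, 60], [2, 4, 6, 8])
        feats = person_driver_features(f)
        assert feats.sd_duration == 0
        assert np.isnan(feats.r_intensity_duration)  # undefined, not 0
        assert feats.diff_total == 0

    def test_perfect_linearity(self):
        feats = person_driver_features(person_frame([10, 20, 30], [1, 2, 3]))
        assert feats.r_intensity_duration == pytest.approx(1.0)

    def test_pearson_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        d = rng.integers(10, 250, 100).astype(float)
        s = rng.integers(0, 11, 100).astype(float)
        feats = person_driver_features(person_frame(d, s))
        manual = np.mean((d - d.mean()) * (s - s.mean())) / (np.std(d) * np.std(s))
        assert feats.r_intensity_duration == pytest.approx(manual, abs=1e-12)


class TestMaxCorrelationSubsample:
    def test_globally_perfect_correlation_is_invariant(self):
        # scores exactly linear in duration: every subset has r = 1
        f = person_frame(np.arange(10, 70, 10), np.arange(1, 7))
        sel = max_correlation_subsample(f, seed=0)
        assert sel.r == pytest.approx(1.0)

    def test_selected_abs_r_at_least_median_candidate(self):
        rng = np.random.default_rng(6)
        f = person_frame(rng.integers(10, 250, 40), rng.integers(0, 11, 40))
        sel = max_correlation_subsample(f, seed=1)
        finite = sel.candidate_r[np.isfinite(sel.candidate_r)]
        assert abs(sel.r) >= np.median(np.abs(finite))
        assert sel.abs_r_percentile >= 50

    def test_selection_inflates_null_correlation(self):
        # true rho = 0, Q = 40: the max-|r| half beats the full sample most seeds
        rng = np.random.default_rng(7)
        wins = 0
        for seed in range(200):
            d = rng.integers(10, 250, 40).astype(float)
            s = rng.integers(0, 11, 40).astype(float)
            full_r = abs(np.corrcoef(d, s)[0, 1])
            sel = max_correlation_subsample(person_frame(d, s), seed=seed)
            wins += abs(sel.r) > full_r
        assert wins / 200 > 0.8

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        f = person_frame(rng.integers(10, 250, 30), rng.integers(0, 11, 30))
        a = max_correlation_subsample(f, seed=3)
        b = max_correlation_subsample(f, seed=3)
        assert np.array_equal(a.indices, b.indices) and a.r == b.r

    def test_too_few_reports_rejected(self):
        with pytest.raises(InsufficientDataError):
            max_correlation_subsample(person_frame([10, 20, 30, 40], [1, 2, 3, 4]))


class TestPercentileCurve:
    def test_ten_persons_ten_bins_is_sorted_diff_sequence(self):
        cfg = SyntheticConfig(n_persons=10, n_days=10, rho=0.0, rho_between_person_sd=0.4, seed=9)
        rs = generate_cohort(cfg)
        curve = correlation_percentile_curve(rs, method="EMA", n_bins=10, seed=0)
        assert (curve["n"] == 1).all()
        assert curve["mean_abs_r"].is_monotonic_increasing

    def test_heterogeneous_rho_top_bin_exceeds_bottom(self):
        cfg = SyntheticConfig(n_persons=60, n_days=14, rho=0.0, rho_between_person_sd=0.3, seed=10)
        curve = correlation_percentile_curve(generate_cohort(cfg), method="EMA", seed=1)
        assert curve["mean_abs_diff"].iloc[-1] > curve["mean_abs_diff"].iloc[0]


class TestDriversRegression:
    def synthetic_features(self, n=200, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        r = rng.uniform(-0.8, 0.8, n)
        sd_s = np.full(n, 1.5)
        sd_d = np.full(n, 80.0)
        mu_d = 100.0
        diff = r * sd_s * sd_d / mu_d + noise * rng.standard_normal(n)
        return pd.DataFrame(
            dict(person_id=[f"p{i}" for i in range(n)], method="EMA", measure="happiness",
                 n=40, r_intensity_duration=r, sd_intensity=sd_s, sd_duration=sd_d,
                 diff_total=diff, diff_daily=diff)
        )

    def test_identity_outcome_recovers_r_exactly(self):
        # constant SDs: signed diff is proportional to r alone
        with pytest.warns(UserWarning, match="constant predictor"):
            reg = drivers_regression(self.synthetic_features(), outcome="signed")
        assert reg["r_squared"] == pytest.approx(1.0, abs=1e-10)
        assert reg["dominance"][0] == "r"

    def test_pure_noise_outcome_low_r2(self):
        feats = self.synthetic_features(seed=1)
        rng = np.random.default_rng(2)
        feats["diff_total"] = rng.standard_normal(len(feats))
        with pytest.warns(UserWarning, match="constant predictor"):
            reg = drivers_regression(feats, outcome="signed")
        assert reg["r_squared"] < 0.1

    def test_duplicated_rows_leave_r2_unchanged(self):
        feats = self.synthetic_features(noise=0.3, seed=3)
        with pytest.warns(UserWarning):
            a = drivers_regression(feats, outcome="signed")
            b = drivers_regression(pd.concat([feats, feats]), outcome="signed")
        assert a["r_squared"] == pytest.approx(b["r_squared"], abs=1e-12)

    def test_r2_invariant_to_affine_predictor_rescaling(self):
        cfg = SyntheticConfig(n_persons=40, n_days=14, rho=0.0, rho_between_person_sd=0.3, seed=11)
        from swbweight import driver_features_table

        feats = driver_features_table(generate_cohort(cfg), "happiness", "EMA")
        a = drivers_regression(feats)
        feats2 = feats.copy()
        feats2["sd_duration"] = feats2["sd_duration"] / 60.0 + 2.0  # minutes -> shifted hours
        b = drivers_regression(feats2)
        assert a["r_squared"] == pytest.approx(b["r_squared"], abs=1e-12)


class TestCarryover:
    def test_planted_carryover_score_dominates_duration(self):
        cfg = SyntheticConfig(n_persons=80, n_days=14, phi_carryover=0.5, seed=12)
        res = carryover_regression(generate_cohort(cfg), "happiness", "DRM")
        assert res["stronger_predictor"] == "prev_score"
        assert abs(res["params"]["prev_score"]) > abs(res["params"]["prev_duration"])

    def test_null_carryover_coefficient_near_zero(self):
        cfg = SyntheticConfig(n_persons=60, n_days=21, phi_carryover=0.0, seed=14)
        res = carryover_regression(generate_cohort(cfg), "happiness")
        assert abs(res["params"]["prev_score"]) < 2 * res["bse"]["prev_score"]

    def test_degenerate_constant_scores_flagged(self):
        rows = [report_row(method="DRM", seq=s, dur=60, hap=5,
                           clock_start=480 + 60 * (s - 1), clock_end=540 + 60 * (s - 1))
                for s in (1, 2)]
        with pytest.raises(InsufficientDataError, match="zero variance"):
            carryover_regression(make_reportset(rows))
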