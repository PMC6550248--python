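import json
import math

import numpy as np
import pandas as pd
import pytest

from phenoqc.bursts import daily_metrics, segment_bursts
from phenoqc.schedules import ACCELEROMETER, GPS
from phenoqc.simulate import (
    MissingnessConfig,
    SimulationConfig,
    TruthConfig,
    _apportion_items,
    expected_coverage,
    is_bimodal,
    simulate_pings,
    simulate_study,
    simulate_subject,
    simulate_weekly_table,
    zero_missingness_config,
)
from phenoqc.weekly import build_weekly

from conftest import light_config


class TestSimulatePings:
    def test_compliant_accelerometer_day(self, rng):
        ts = simulate_pings(ACCELEROMETER, MissingnessConfig(), 1, rng)
        df = daily_metrics(ts, ACCELEROMETER, 0.0, 1)
        assert df.loc[0, "b_hat"] == 720
        assert df.loc[0, "p_hat"] == 432_000
        assert df.loc[0, "coverage"] == 1.0

    def test_total_dropout_gives_empty_stream(self, rng):
        ts = simulate_pings(GPS, MissingnessConfig(burst_dropout=1.0), 5, rng)
        assert ts.size == 0

    def test_bursts_never_span_day_boundaries(self, rng):
        ts = simulate_pings(GPS, MissingnessConfig(), 3, rng)
        day = (ts // 86_400).astype(int)
        bs = segment_bursts(ts, GPS.threshold)
        assert np.array_equal(
            (bs.starts // 86_400).astype(int), (bs.ends // 86_400).astype(int)
        )
        assert day.max() == 2

    def test_burst_dropout_thins_coverage_proportionally(self, rng):
        ts = simulate_pings(
            ACCELEROMETER, MissingnessConfig(burst_dropout=0.5), 20, rng
        )
        df = daily_metrics(ts, ACCELEROMETER, 0.0, 20)
        mean_cov = df["coverage"].mean()
        se = df["coverage"].std(ddof=1) / math.sqrt(len(df))
        assert abs(mean_cov - 0.5) < 4 * se + 1e-3

    def test_expected_coverage_formula(self):
        m = MissingnessConfig(burst_dropout=0.25, truncation_low=0.56, ping_retention=0.8)
        assert expected_coverage(ACCELEROMETER, m) == pytest.approx(0.75 * 0.78 * 0.8)


class TestApportionment:
    @pytest.mark.parametrize("k", [1, 4, 5, 23])
    def test_mean_within_half_unit_of_target(self, k, rng):
        items = tuple(f"q{i}" for i in range(k))
        for target in rng.uniform(-0.5, 3.5, 50):
            resp = _apportion_items(float(target), items)
            clipped = min(max(target, 0.0), 3.0)
            mean = sum(resp.values()) / k
            assert abs(mean - clipped) <= 1 / (2 * k) + 1e-12
            assert all(v in (0, 1, 2, 3) for v in resp.values())


class TestSubjectSimulation:
    def test_same_seed_is_reproducible(self):
        cfg = light_config(n_subjects=2, n_weeks=2)
        a = simulate_subject(cfg, 0)
        b = simulate_subject(cfg, 0)
        for sensor in a.sensors:
            assert np.array_equal(a.sensors[sensor], b.sensors[sensor])
        assert a.mu == b.mu
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert [e.submit_ts for e in a.events] == [e.submit_ts for e in b.events]

    def test_full_adherence_gives_three_surveys_per_week(self):
        cfg = zero_missingness_config(
            n_subjects=1, n_weeks=4,
            schedules=light_config().schedules,
        )
        sub = simulate_subject(cfg, 0)
        weekly = build_weekly(
            sub.daily, sub.events, {sub.subject_id: sub.enrollment_s}, n_weeks=4
        )
        assert weekly["T"].tolist() == [3, 3, 3, 3]
        assert weekly["A"].notna().all()

    def test_weekly_scores_match_truth_within_rounding(self):
        cfg = light_config(n_subjects=1, n_weeks=4)
        sub = simulate_subject(cfg, 0)
        weekly = build_weekly(
            sub.daily, sub.events, {sub.subject_id: sub.enrollment_s}, n_weeks=4
        )
        merged = weekly.merge(sub.truth, on=["subject_id", "week"], suffixes=("", "_true"))
        # mood has 5 items; per-survey rounding error is at most 1/(2*5)
        err = (merged["Y_mood"] - merged["Y_mood_true"].clip(0, 3)).abs()
        assert err.max() <= 0.1 + 1e-12
        assert np.allclose(merged["A"], merged["A_true"], equal_nan=True)
        assert np.allclose(merged["T"], merged["T_true"], equal_nan=True)

    def test_latent_outcome_follows_generative_equation(self):
        cfg = light_config(n_subjects=1, n_weeks=5)
        sub = simulate_subject(cfg, 0)
        truth = sub.truth
        beta = np.array(cfg.truth.beta)
        # the latent level at week j is exactly beta0 + mu + beta . X_{j-l*}
        for _, row in truth[truth["week"] > cfg.truth.true_lag].iterrows():
            src = truth[truth["week"] == row["week"] - cfg.truth.true_lag].iloc[0]
            x = np.array([src[c] for c in ("A", "G", "V", "C", "T")])
            if np.isnan(x).any():
                continue
            assert row["latent"] == pytest.approx(
                cfg.truth.beta0 + sub.mu + float(beta @ x), rel=1e-12
            )


class TestStudyDirectory:
    def test_layout_manifest_and_determinism(self, tmp_path):
        cfg = light_config(n_subjects=2, n_weeks=2)
        out1 = simulate_study(cfg, tmp_path / "a")
        out2 = simulate_study(cfg, tmp_path / "b")
        m1 = json.loads((out1 / "manifest.json").read_text())
        m2 = json.loads((out2 / "manifest.json").read_text())
        assert m1["files"] == m2["files"]  # SHA-256 digests byte-identical
        assert m1["n_subjects"] == 2
        assert len(m1["subjects"]) == 2
        for sub in m1["subjects"]:
            assert set(sub["files"]) == {"accelerometer", "gps"}
            for rel in sub["files"].values():
                assert (out1 / rel).exists()
        assert (out1 / "surveys.csv").exists()
        assert (out1 / "ground_truth" / "weekly.csv").exists()

    def test_refuses_nonempty_output_directory(self, tmp_path):
        target = tmp_path / "study"
        target.mkdir()
        (target / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            simulate_study(light_config(n_subjects=1, n_weeks=1), target)
        simulate_study(light_config(n_subjects=1, n_weeks=1), target, force=True)


class TestViewLatencyBimodality:
    def test_mixture_flagged_bimodal(self):
        cfg = SimulationConfig()
        sv = cfg.survey
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            fast = r.random(500) < sv.mixture_weight
            sample = np.where(
                fast,
                r.lognormal(math.log(sv.view_medians[0]), sv.view_sigmas[0], 500),
                r.lognormal(math.log(sv.view_medians[1]), sv.view_sigmas[1], 500),
            )
            hits += int(is_bimodal(sample))
        assert hits >= 38  # >= 95% of replicates

    def test_single_component_not_flagged(self):
        r = np.random.default_rng(0)
        assert not is_bimodal(r.lognormal(math.log(300.0), 0.9, 500))


def test_weekly_table_generator_lag_structure(rng):
    truth = TruthConfig(true_lag=2)
    tab = simulate_weekly_table(5, 8, truth, rng)
    assert tab.loc[tab["week"] <= 2, "Y_overall"].isna().all()
    assert tab.loc[tab["week"] > 2, "Y_overall"].notna().all()
    assert len(tab) == 40
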