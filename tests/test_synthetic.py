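"""The coupled epidemic-emotion-rumor generator."""

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest

import infodemic as inf
from infodemic.errors import AlignmentError, InvalidConfigError
from infodemic.labels import EMOTIONS, Emotion


class TestConfig:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"epidemic_growth_rate": -0.1},
            {"comment_volume_mean": 0.0},
            {"n_coders": 2},
            {"coder_accuracy": 0.0},
            {"coder_accuracy": 1.2},
            {"rumor_lag_days": 11},
            {"shock_day": 0},
            {"shock_day": 49},
            {"emotion_base_probs": (0.5, 0.5, 0.0, 0.0, 0.1)},
            {"emotion_base_probs": (0.2, 0.2, 0.2, 0.2)},
            {"backlog_release_fractions": (0.9, 0.2)},
        ],
    )
    def test_invalid_configs_rejected(self, overrides):
        with pytest.raises(InvalidConfigError):
            inf.SyntheticConfig(seed=1, **overrides)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = inf.SyntheticConfig(seed=5, n_days=40, shock_day=20, rumor_lag_days=-2)
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        back = inf.SyntheticConfig.from_file(path)
        assert back == cfg
        assert back.config_hash() == cfg.config_hash()

    def test_seed_is_mandatory_in_file(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("n_days: 30\n")
        with pytest.raises(InvalidConfigError, match="seed"):
            inf.SyntheticConfig.from_file(path)

    def test_unknown_keys_rejected(self):
        with pytest.raises(InvalidConfigError, match="unknown"):
            inf.SyntheticConfig.from_dict({"seed": 1, "typo_field": 3})


class TestEpidemic:
    def test_seeded_determinism(self, small_config):
        a = inf.simulate_epidemic(small_config)
        b = inf.simulate_epidemic(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_clinical_ratio_exact(self):
        cfg = inf.SyntheticConfig(seed=2, noise_scale=0.0)
        cases = inf.simulate_epidemic(cfg)
        hb = cases[cases.region == "hubei"]
        np.testing.assert_allclose(
            hb.clinical_count / hb.nucleic_count, 0.91, rtol=1e-12
        )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_backlog_conserved(self, seed):
        cfg = inf.SyntheticConfig(seed=seed, n_days=50, shock_day=23)
        hb = inf.simulate_epidemic(cfg).query("region == 'hubei'")
        # total true cases (generator ledger) equal total reported cases
        assert hb.reported_total.sum() == pytest.approx(
            (hb.nucleic_count + hb.clinical_count).sum(), rel=1e-12
        )

    def test_clinical_withheld_then_dumped(self, small_config):
        hb = inf.simulate_epidemic(small_config).query("region == 'hubei'").reset_index(drop=True)
        s = small_config.shock_day
        np.testing.assert_array_equal(
            hb.reported_total[:s], hb.nucleic_count[:s]
        )
        backlog = hb.clinical_count[:s].sum()
        extra = hb.reported_total[s : s + 2].sum() - (
            hb.nucleic_count[s : s + 2] + hb.clinical_count[s : s + 2]
        ).sum()
        assert extra == pytest.approx(backlog, rel=1e-9)
        # shock day towers over its neighbours (the reporting spike)
        assert hb.reported_total[s] > 2 * hb.reported_total[s - 1]

    def test_other_region_has_no_shock(self, small_cases):
        other = small_cases.query("region == 'other'")
        np.testing.assert_array_equal(other.reported_total, other.nucleic_count)
        assert (other.clinical_count == 0).all()

    def test_rise_then_fall(self):
        cfg = inf.SyntheticConfig(seed=2, noise_scale=0.0)
        hb = inf.simulate_epidemic(cfg).query("region == 'hubei'")
        mu = hb.nucleic_count.to_numpy()
        p = cfg.epidemic_peak_day
        assert np.all(np.diff(mu[: p + 1]) > 0)
        assert np.all(np.diff(mu[p:]) < 0)


class TestComments:
    def test_seeded_determinism(self, small_config, small_cases):
        a = inf.simulate_comments(small_config, small_cases)
        b = inf.simulate_comments(small_config, small_cases)
        pd.testing.assert_frame_equal(a.table, b.table)
        pd.testing.assert_frame_equal(a.truth_counts, b.truth_counts)

    def test_missing_days_raise_alignment_error(self, small_config, small_cases):
        truncated = small_cases[pd.to_datetime(small_cases.date).dt.day != 25]
        with pytest.raises(AlignmentError):
            inf.simulate_comments(small_config, truncated)

    def test_perfect_coders_always_agree(self, small_cases, small_config):
        cfg = dataclasses.replace(small_config, coder_accuracy=1.0)
        comments = inf.simulate_comments(cfg, small_cases)
        t = comments.table
        assert (t.coder_1 == t.coder_2).all() and (t.coder_2 == t.coder_3).all()

    def test_coder_accuracy_calibration(self, small_config, small_cases):
        """Per-coder agreement with the latent truth is the configured
        accuracy, within 3 binomial standard errors (>= 10,000 comments)."""
        comments = inf.simulate_comments(small_config, small_cases)
        names = np.array([lab.value for lab in EMOTIONS])
        truth = names[comments.true_codes]
        n = truth.size
        assert n >= 10_000
        a = small_config.coder_accuracy
        se = np.sqrt(a * (1 - a) / n)
        for j in range(1, small_config.n_coders + 1):
            agreement = (comments.table[f"coder_{j}"].to_numpy() == truth).mean()
            assert abs(agreement - a) <= 3 * se

    def test_uncoupled_uniform_mixture_recovers_base_probs(self):
        """With zero case coupling and a uniform base mixture, empirical
        label shares approach 0.2 within 3 standard errors."""
        cfg = inf.SyntheticConfig(
            seed=9,
            emotion_base_probs=(0.2,) * 5,
            emotion_case_coupling=0.0,
            comment_volume_mean=10_000.0,
        )
        cases = inf.simulate_epidemic(cfg)
        truth = inf.simulate_emotion_days(cfg, cases)
        counts = truth[[lab.value for lab in EMOTIONS]].to_numpy().sum(axis=0)
        n = counts.sum()
        se = np.sqrt(0.2 * 0.8 / n)
        np.testing.assert_allclose(counts / n, 0.2, atol=3 * se)

    def test_emotion_ordering_matches_default_mixture(self, small_comments):
        totals = {
            lab: small_comments.truth_counts[lab.value].sum() for lab in EMOTIONS
        }
        assert totals[Emotion.NEUTRAL] > totals[Emotion.ANGER] > totals[Emotion.FEAR]
        assert totals[Emotion.FEAR] > totals[Emotion.HAPPINESS]
        assert totals[Emotion.FEAR] > totals[Emotion.SADNESS]


class TestRumors:
    def _series(self, config):
        cases = inf.simulate_epidemic(config)
        truth = inf.simulate_emotion_days(config, cases)
        return inf.truth_emotion_series(truth)

    def test_seeded_determinism(self, small_config):
        series = self._series(small_config)
        a = inf.simulate_rumors(small_config, series)
        b = inf.simulate_rumors(small_config, series)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_window_mismatch_rejected(self, small_config):
        series = self._series(small_config)
        short = {
            lab: inf.DailySeries(s.start_date, s.values[:-5])
            for lab, s in series.items()
        }
        with pytest.raises(InvalidConfigError):
            inf.simulate_rumors(small_config, short)

    def test_neutral_is_modal_tag(self, small_config):
        rumors = inf.simulate_rumors(small_config, self._series(small_config))
        tags = rumors.table.emotion_tag.value_counts()
        assert tags.idxmax() == "neutral"

    def test_zero_strength_stays_inside_envelope_at_stated_lag(self):
        """No coupling: |r| at the (single, pre-stated) injected lag falls
        below the 95% white-noise envelope in >= 90% of replicates."""
        from infodemic.experiments import null_coupling_experiment

        res = null_coupling_experiment(n_reps=60, n_days=100, seed=5)
        assert res.stated_lag_clean_rate >= 0.90

    def test_strong_lag_zero_coupling_recovered(self):
        """End-to-end: strength 0.9 at lag 0 over 200 days peaks at lag 0."""
        cfg = inf.SyntheticConfig(
            seed=6, n_days=200, rumor_lag_days=0, rumor_coupling_strength=0.9
        )
        series = self._series(cfg)
        rumors = inf.simulate_rumors(cfg, series)
        neg = inf.DailySeries(
            cfg.start_date,
            series[Emotion.ANGER].values + series[Emotion.FEAR].values,
        )
        res = inf.ccf_scan(
            inf.log_stabilize(neg), inf.log_stabilize(rumors.daily_counts)
        )
        assert res.peak_lag == 0
        assert res.peak_r > 0.5

    def test_injected_lead_shifts_the_peak(self):
        """Rumors leading emotions by 2 days peak at +2 under the
        convention r(k) = corr(emotion_{t+k}, rumor_t)."""
        cfg = inf.SyntheticConfig(
            seed=8, n_days=200, rumor_lag_days=2, rumor_coupling_strength=0.8
        )
        series = self._series(cfg)
        rumors = inf.simulate_rumors(cfg, series)
        neg = inf.DailySeries(
            cfg.start_date,
            series[Emotion.ANGER].values + series[Emotion.FEAR].values,
        )
        res = inf.ccf_scan(
            inf.log_stabilize(neg), inf.log_stabilize(rumors.daily_counts)
        )
        assert res.peak_lag == 2


class TestWriteInputs:
    def test_csv_round_trip(self, tmp_path, small_config):
        paths = inf.write_inputs(small_config, tmp_path)
        cases = pd.read_csv(paths["cases"])
        comments = pd.read_csv(paths["comments"])
        rumors = pd.read_csv(paths["rumors"])
        assert set(cases.columns) == {
            "date", "region", "nucleic_count", "clinical_count", "reported_total"
        }
        assert {"comment_id", "date", "coder_1", "coder_2", "coder_3"} <= set(
            comments.columns
        )
        assert set(rumors.columns) == {"rumor_id", "date", "emotion_tag"}
        # ISO-8601 dates
        assert str(cases.date.iloc[0]) == small_config.start_date.isoformat()
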