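"""Synthetic-study generator: design fidelity, calibration, determinism."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from pregsignal.config import MODELED_BEHAVIORS, PERIODS, StudyConfig
from pregsignal.hormones import detect_luteal_onset
from pregsignal.synthetic import (
    calibrate_rates,
    generate_agonistic,
    generate_color,
    generate_focals,
    generate_hormone_series,
    generate_roster,
    generate_study,
    sample_ztnb,
    ztnb_mean,
    ztnb_mu_from_mean,
)


class TestRoster:
    def test_default_design_has_five_conceiving_females(self, default_study):
        assert len(default_study.roster) == 5
        ages = default_study.roster["age"]
        assert ages.min() >= 8 and ages.max() <= 17
        assert ages.mean() == pytest.approx(11.6)

    def test_single_female(self):
        cfg = StudyConfig(
            n_females=1, ages=(10,), conception_offsets=(35,),
            focals_per_period=None, photos_per_period=None,
        )
        roster, truth = generate_roster(cfg, np.random.default_rng(0))
        assert len(roster) == 1
        assert list(truth["conception_dates"]) == ["F1"]

    def test_empty_roster_refused(self):
        with pytest.raises(ValueError):
            StudyConfig(n_females=0, ages=None, conception_offsets=None,
                        focals_per_period=None, photos_per_period=None)

    def test_delivery_consistent_with_conception(self, default_study):
        truth = default_study.truth
        for _, row in default_study.roster.iterrows():
            f = row["female_id"]
            gest = (row["delivery_date"] - truth["conception_dates"][f]).days
            assert gest == truth["gestation_days"][f]
            assert 160 <= gest <= 195


class TestHormoneGeneration:
    def test_scan_finds_planted_rise_exactly_on_clean_baseline(self):
        """Noise-free daily baseline: the first qualifying sample is the plant.

        With baseline noise the 2-SD rule can fire one sample early (a
        noise draw beats its own 4-sample threshold with prob ~0.09), so
        the exact-position property is stated for the clean case; noisy
        recovery is bounded by the classifier test below.
        """
        cfg = StudyConfig(rng_seed=0)
        cfg.cycle.gap_prob = 0.0
        cfg.cycle.cadence_days = 1
        cfg.cycle.baseline_pdg_sd = 0.0
        conception = date(2014, 1, 5)
        for seed in range(20):
            df, truth = generate_hormone_series(
                cfg, {"F1": conception}, np.random.default_rng(seed)
            )
            i = detect_luteal_onset(df["pdg_ug_g"].to_numpy())
            assert df["date"].iloc[i] == truth["rise_dates"]["F1"]

    def test_zero_noise_strong_rise_always_detected(self):
        cfg = StudyConfig(rng_seed=0)
        cfg.cycle.baseline_pdg_sd = 0.0
        cfg.cycle.noise_cv = 0.0
        cfg.cycle.pdg_month1 = 3.0 * cfg.cycle.baseline_pdg_mean
        df, truth = generate_hormone_series(
            cfg, {"F1": date(2014, 1, 5)}, np.random.default_rng(1)
        )
        assert detect_luteal_onset(df["pdg_ug_g"].to_numpy()) is not None
        assert truth["detectability_flags"]["F1"] == []

    def test_undetectable_rise_flagged(self):
        cfg = StudyConfig(rng_seed=0)
        cfg.cycle.pdg_month1 = cfg.cycle.baseline_pdg_mean + cfg.cycle.baseline_pdg_sd
        _, truth = generate_hormone_series(
            cfg, {"F1": date(2014, 1, 5)}, np.random.default_rng(1)
        )
        assert truth["detectability_flags"]["F1"] == ["rise_below_detectability"]

    def test_pregnancy_month_directions(self):
        """month2 PdG below month1; E1C/PdG ratio higher in month2 (200 reps)."""
        cfg = StudyConfig(rng_seed=0)
        conception = date(2014, 1, 5)
        m1p, m2p, m1r, m2r = [], [], [], []
        for seed in range(200):
            df, _ = generate_hormone_series(
                cfg, {"F1": conception}, np.random.default_rng(seed)
            )
            days = pd.to_datetime(df["date"]).dt.date
            off = np.array([(d - conception).days for d in days])
            pdg = df["pdg_ug_g"].to_numpy()
            ratio = df["e1c_ng_g"].to_numpy() / pdg
            in1, in2 = (off >= 2) & (off < 30), (off >= 30) & (off < 60)
            m1p.append(pdg[in1].mean())
            m2p.append(pdg[in2].mean())
            m1r.append(ratio[in1].mean())
            m2r.append(ratio[in2].mean())
        assert np.mean(m2p) < np.mean(m1p)
        assert np.mean(m2r) > np.mean(m1r)


class TestZtnb:
    def test_mean_inversion_roundtrip(self):
        for target in (2.0, 5.0, 40.0, 157.0):
            mu = ztnb_mu_from_mean(target, 1.5)
            assert ztnb_mean(mu, 1.5) == pytest.approx(target, rel=1e-8)

    def test_sampler_never_returns_zero_and_hits_mean(self, rng):
        mu = ztnb_mu_from_mean(4.0, 1.5)
        draws = sample_ztnb(rng, np.full(20000, mu), 1.5)
        assert draws.min() >= 1
        assert draws.mean() == pytest.approx(4.0, rel=0.05)


class TestFocals:
    def test_default_design_emits_153_focals(self, default_study):
        counts = default_study.focals.groupby("period").size()
        assert counts["PCP"] == 46
        assert counts["month1"] == 57
        assert counts["month2"] == 50
        assert len(default_study.focals) == 153

    def test_every_focal_inside_study_window(self, default_study):
        cfg = default_study.config
        days = default_study.focals["date"]
        assert days.min() >= cfg.study_start and days.max() <= cfg.study_end

    def test_zero_probability_behavior_stays_zero(self, default_study):
        f = default_study.focals
        # Table-calibrated zero cells: presentations/inspections everywhere,
        # mounts and copulation calls during pregnancy
        assert (f["female_presentation_count"] == 0).all()
        assert (f["olfactory_inspection_count"] == 0).all()
        preg = f[f["period"].isin(["month1", "month2"])]
        assert (preg["mount_count"] == 0).all()
        assert (preg["copulation_call_count"] == 0).all()

    def test_occurrence_converges_to_configured_p_without_random_effects(self):
        """Law of large numbers at ~10,000 focals with RE SDs forced to 0."""
        cfg = StudyConfig(
            n_females=5,
            focals_per_period={p: (400,) * 5 for p in PERIODS},
            re_sd_female_occ=0.0,
            re_sd_date_occ=0.0,
            re_sd_female_count=0.0,
            re_sd_date_count=0.0,
            rng_seed=11,
        )
        conceptions = {f"F{i+1}": c for i, c in enumerate(cfg.conception_dates())}
        focals, _ = generate_focals(cfg, conceptions, np.random.default_rng(11))
        assert len(focals) == 6000
        rates = calibrate_rates(cfg).set_index(["behavior", "period"])
        for beh in ("female_approach", "mount", "grooming_female"):
            for period in PERIODS:
                p = rates.loc[(beh, period), "p_occurrence"]
                frac = (focals.loc[focals["period"] == period, f"{beh}_count"] > 0).mean()
                assert frac == pytest.approx(p, abs=0.03)

    def test_durations_positive_only_when_grooming_occurs(self, default_study):
        f = default_study.focals
        occ = f["grooming_female_count"] > 0
        assert (f.loc[occ, "grooming_female_duration_s"] > 0).all()
        assert (f.loc[~occ, "grooming_female_duration_s"] == 0).all()

    def test_contact_is_superset_of_female_grooming(self, default_study):
        f = default_study.focals
        assert (f["contact_count"] >= f["grooming_female_count"]).all()

    def test_ground_truth_emitted(self, default_study):
        truth = default_study.truth
        for key in ("conception_dates", "rates", "re_sds",
                    "occurrence_logit_effects", "rank"):
            assert key in truth


class TestCalibration:
    def test_expected_totals_match_targets(self):
        """rate * focals reproduces the configured per-period event totals."""
        cfg = StudyConfig()
        rates = calibrate_rates(cfg).set_index(["behavior", "period"])
        alloc = cfg.focal_allocation()
        for beh, totals in cfg.behavior_totals.items():
            for period, total in zip(PERIODS, totals):
                row = rates.loc[(beh, period)]
                expect = row["p_occurrence"] * row["zt_mean"] * sum(alloc[period])
                assert expect == pytest.approx(total, rel=1e-9, abs=1e-9)

    def test_occurrence_capped_for_zero_fraction(self):
        rates = calibrate_rates(StudyConfig())
        assert (rates["p_occurrence"] <= 0.25 + 1e-12).all()


class TestColor:
    def test_photo_counts_match_design(self, default_study):
        counts = default_study.color.groupby("period").size()
        assert counts["PCP"] == 28
        assert counts["month1"] == 35
        assert counts["month2"] == 25

    def test_zero_noise_reproduces_period_means(self):
        cfg = StudyConfig(rng_seed=5)
        cfg.color.log_sd = 0.0
        study = generate_study(cfg)
        for period in PERIODS:
            lw0, mw0 = cfg.color.lw_mw(period)
            sub = study.color[study.color["period"] == period]
            rg = (sub["lw"] - sub["mw"]) / (sub["lw"] + sub["mw"])
            assert rg.to_numpy() == pytest.approx(
                (lw0 - mw0) / (lw0 + mw0), abs=1e-6
            )

    def test_luminance_darkens_after_conception(self):
        """Monte-Carlo direction check over 500 replicates."""
        cfg = StudyConfig()
        conceptions = {f"F{i+1}": c for i, c in enumerate(cfg.conception_dates())}
        diffs = []
        for seed in range(500):
            color = generate_color(cfg, conceptions, np.random.default_rng(seed))
            lum = (color["lw"] + color["mw"]) / 2.0
            by = lum.groupby(color["period"]).mean()
            diffs.append(by["PCP"] - by["month1"])
        diffs = np.asarray(diffs)
        assert diffs.mean() > 0
        assert (diffs > 0).mean() > 0.95

    def test_nonpositive_mean_rejected(self):
        from pregsignal.config import ColorParams

        with pytest.raises(ValueError):
            StudyConfig(
                color=ColorParams(luminance={"PCP": -1.0, "month1": 0.9, "month2": 0.88})
            )


class TestAgonistic:
    def test_infinite_steepness_means_ranks_always_win(self):
        cfg = StudyConfig(hierarchy_steepness=1e6, n_interactions=300, rng_seed=2)
        study = generate_study(cfg)
        rank = study.truth["rank"]
        for _, row in study.interactions.iterrows():
            assert rank[row["winner_id"]] < rank[row["loser_id"]]

    def test_zero_steepness_is_symmetric(self):
        cfg = StudyConfig(hierarchy_steepness=0.0, n_interactions=4000, rng_seed=3)
        study = generate_study(cfg)
        rank = study.truth["rank"]
        wins_by_higher = np.mean(
            [rank[w] < rank[l] for w, l in
             zip(study.interactions["winner_id"], study.interactions["loser_id"])]
        )
        assert wins_by_higher == pytest.approx(0.5, abs=0.03)

    def test_needs_two_females(self):
        cfg = StudyConfig(n_females=1, ages=(10,), conception_offsets=(35,),
                          focals_per_period=None, photos_per_period=None)
        roster = pd.DataFrame({"female_id": ["F1"], "age": [10]})
        with pytest.raises(ValueError):
            generate_agonistic(cfg, roster, {"F1": 1}, np.random.default_rng(0))


class TestDeterminism:
    def test_same_seed_same_study(self):
        a = generate_study(StudyConfig(rng_seed=42))
        b = generate_study(StudyConfig(rng_seed=42))
        for name in ("roster", "hormones", "focals", "color", "interactions"):
            assert_frame_equal(getattr(a, name), getattr(b, name))
        assert a.truth["conception_dates"] == b.truth["conception_dates"]

    def test_different_seed_differs(self):
        a = generate_study(StudyConfig(rng_seed=1))
        b = generate_study(StudyConfig(rng_seed=2))
        assert not a.focals.equals(b.focals)


def test_roundtrip_yaml_config(tmp_path):
    cfg = StudyConfig(rng_seed=99)
    path = tmp_path / "config.yaml"
    cfg.to_yaml(path)
    back = StudyConfig.from_yaml(path)
    assert back == cfg
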