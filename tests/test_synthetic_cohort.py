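"""Tests of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riclpm import (
    CohortConfig,
    TruthParams,
    apply_cohort_flow,
    default_truth,
    disaggregate_tsk_items,
    generate_cohort,
    generate_latent_panel,
    generate_met_day,
    impose_missingness,
    summarize_day,
    truth_to_riclpm_values,
)
from riclpm.synthetic_cohort import CohortDataset, write_cohort


class TestTruthParams:
    def test_non_pd_wave1_block_rejected_with_block_name(self):
        with pytest.raises(ValueError, match="wave-1 within"):
            TruthParams(
                grand_means=np.zeros((2, 4)),
                ri_variances=(1.0, 1.0), ri_covariance=0.0,
                wave1_within_cov=np.array([[1.0, 2.0], [2.0, 1.0]]),
                lagged_coefs=tuple(np.zeros((2, 2)) for _ in range(3)),
                residual_variances=((1, 1), (1, 1), (1, 1)),
            )

    def test_negative_residual_variance_rejected(self):
        with pytest.raises(ValueError, match="transition 2"):
            TruthParams(
                grand_means=np.zeros((2, 4)),
                ri_variances=(1.0, 1.0), ri_covariance=0.0,
                wave1_within_cov=np.eye(2),
                lagged_coefs=tuple(np.zeros((2, 2)) for _ in range(3)),
                residual_variances=((1, 1), (-1, 1), (1, 1)),
            )


class TestGenerateLatentPanel:
    def test_degenerate_between_variance(self, truth):
        """Zero random-intercept variances: observed = mean + within."""
        degen = TruthParams(
            grand_means=truth.grand_means,
            ri_variances=(0.0, 0.0), ri_covariance=0.0,
            wave1_within_cov=truth.wave1_within_cov,
            lagged_coefs=truth.lagged_coefs,
            residual_variances=truth.residual_variances,
        )
        panel = generate_latent_panel(degen, 200, seed=1)
        assert (panel["b_tsk"] == 0).all() and (panel["b_pa"] == 0).all()
        np.testing.assert_allclose(
            panel["tsk_wk6"],
            degen.grand_means[0, 2] + panel["w_tsk_wk6"],
        )

    def test_seeded_determinism(self, truth):
        a = generate_latent_panel(truth, 50, seed=99)
        b = generate_latent_panel(truth, 50, seed=99)
        pd.testing.assert_frame_equal(a, b)

    def test_observed_is_mean_plus_between_plus_within(self, truth):
        panel = generate_latent_panel(truth, 100, seed=2)
        np.testing.assert_allclose(
            panel["pa_wk3"],
            truth.grand_means[1, 1] + panel["b_pa"] + panel["w_pa_wk3"],
        )

    def test_nonpositive_n_rejected(self, truth):
        with pytest.raises(ValueError):
            generate_latent_panel(truth, 0, seed=1)


class TestDisaggregateTskItems:
    def test_floor_and_ceiling(self):
        assert (disaggregate_tsk_items(13, 0) == 1).all()
        assert (disaggregate_tsk_items(52, 0) == 4).all()

    @given(total=st.integers(13, 52), seed=st.integers(0, 1000))
    @settings(max_examples=60, deadline=None)
    def test_sum_conservation_and_range(self, total, seed):
        items = disaggregate_tsk_items(total, seed)
        assert items.sum() == total
        assert ((1 <= items) & (items <= 4)).all()
        assert len(items) == 13

    @pytest.mark.parametrize("bad", [12, 53, 0])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            disaggregate_tsk_items(bad, 0)


class TestGenerateMetDay:
    def test_all_sedentary_day(self, desk_config):
        day = generate_met_day((0, 0, 0), desk_config, seed=4)
        summary = summarize_day(day)
        assert (summary.minutes_light, summary.minutes_moderate,
                summary.minutes_heavy) == (0, 0, 0)

    def test_recovers_published_median_targets(self, desk_config):
        day = generate_met_day((54, 24, 0), desk_config, seed=5)
        s = summarize_day(day)
        assert (s.minutes_light, s.minutes_moderate, s.minutes_heavy) == (54, 24, 0)

    def test_active_epoch_count_by_brute_scan(self, desk_config):
        day = generate_met_day((60, 30, 2), desk_config, seed=6)
        active = (day["met"].to_numpy() > 1.5).sum()  # sedentary cut 1.5 MET
        assert active == 92

    def test_infeasible_targets_rejected(self, desk_config):
        with pytest.raises(ValueError, match="exceed"):
            generate_met_day((1200, 300, 60), desk_config, seed=0)

    @given(
        light=st.integers(0, 300), moderate=st.integers(0, 200),
        heavy=st.integers(0, 60), seed=st.integers(0, 100),
    )
    @settings(max_examples=25, deadline=None)
    def test_round_trip_conservation(self, light, moderate, heavy, seed):
        cfg = CohortConfig.desk(seed=0)
        day = generate_met_day((light, moderate, heavy), cfg, seed=seed)
        s = summarize_day(day)
        assert (s.minutes_light, s.minutes_moderate, s.minutes_heavy) == (
            light, moderate, heavy,
        )


def _panel_only_dataset(truth, n, seed):
    latent = generate_latent_panel(truth, n, seed)
    rows = []
    for j, week in enumerate((1, 3, 6, 12)):
        for i in range(n):
            rows.append({
                "patient_id": i + 1, "wave": j + 1, "week": week,
                "tsk_total": float(latent.loc[i, f"tsk_wk{week}"]),
                "tsk_missing": False,
                "pa_total": float(latent.loc[i, f"pa_wk{week}"]),
            })
    return CohortDataset(flow={}, panel=pd.DataFrame(rows),
                         items=pd.DataFrame(columns=["patient_id", "wave"]),
                         epochs=None)


class TestImposeMissingness:
    def test_zero_rates_leave_dataset_unchanged(self, truth):
        ds = _panel_only_dataset(truth, 30, seed=8)
        cfg = CohortConfig(tsk_wave_missing_rates=(0, 0, 0, 0),
                           epoch_missing_rate=0.0)
        out = impose_missingness(ds, cfg, seed=1)
        assert not out.panel["tsk_missing"].any()
        pd.testing.assert_frame_equal(out.panel, ds.panel)

    def test_rate_one_removes_every_wave_four_record(self, truth):
        ds = _panel_only_dataset(truth, 30, seed=8)
        cfg = CohortConfig(tsk_wave_missing_rates=(0, 0, 0, 1.0))
        out = impose_missingness(ds, cfg, seed=1)
        w4 = out.panel[out.panel["wave"] == 4]
        assert w4["tsk_missing"].all()
        assert w4["tsk_total"].isna().all()

    def test_realized_rates_match_published_targets(self, truth):
        """At n = 10,000 the realized per-wave missing fractions sit within
        0.02 of the published 22.8/24.8/28.2/36.2%."""
        ds = _panel_only_dataset(truth, 10_000, seed=12)
        cfg = CohortConfig()
        out = impose_missingness(ds, cfg, seed=3)
        for wave, rate in zip((1, 2, 3, 4), cfg.tsk_wave_missing_rates):
            realized = out.panel.loc[out.panel["wave"] == wave, "tsk_missing"].mean()
            assert abs(realized - rate) < 0.02


class TestCohortFlow:
    def test_published_counts_end_at_116(self):
        ledger = apply_cohort_flow(CohortConfig())
        assert ledger["assessed_for_eligibility"] == 188
        assert ledger["questionnaire_completers"] == 149
        assert ledger["did_not_wear_accelerometer"] == 33
        assert ledger["analysis_sample"] == 116
        assert not ledger["empty_analysis_set"]

    def test_no_exclusions(self):
        cfg = CohortConfig(n_assessed=10, n_died=0,
                           n_questionnaire_completers=10, n_no_accelerometer=0)
        assert apply_cohort_flow(cfg)["analysis_sample"] == 10

    def test_full_exclusion_flagged_empty(self):
        cfg = CohortConfig(n_assessed=5, n_died=0,
                           n_questionnaire_completers=5, n_no_accelerometer=5)
        with pytest.warns(UserWarning, match="empty"):
            ledger = apply_cohort_flow(cfg)
        assert ledger["analysis_sample"] == 0
        assert ledger["empty_analysis_set"]

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_assessed=100, n_questionnaire_completers=120,
                         n_no_accelerometer=0)


class TestGenerateCohort:
    def test_dataset_invariants(self, truth):
        ds = generate_cohort(truth, CohortConfig(seed=7))
        n = ds.flow["analysis_sample"]
        assert len(ds.panel) == n * 4
        # stored items sum to every non-missing TSK total
        merged = ds.items.merge(ds.panel, on=["patient_id", "wave"])
        sums = merged[[f"item_{k}" for k in range(1, 14)]].sum(axis=1)
        np.testing.assert_allclose(sums, merged["tsk_total"])
        assert not merged["tsk_missing"].any()
        assert ds.panel["tsk_total"].dropna().between(13, 52).all()
        assert (ds.panel["pa_total"] >= 0).all()

    def test_seeded_determinism_end_to_end(self, truth):
        a = generate_cohort(truth, CohortConfig(seed=42))
        b = generate_cohort(truth, CohortConfig(seed=42))
        pd.testing.assert_frame_equal(a.panel, b.panel)
        pd.testing.assert_frame_equal(a.items, b.items)
        assert a.flow == b.flow

    def test_category_minutes_sum_to_total(self, truth):
        ds = generate_cohort(truth, CohortConfig(seed=7))
        np.testing.assert_allclose(
            ds.panel[["pa_light", "pa_moderate", "pa_heavy"]].sum(axis=1),
            ds.panel["pa_total"], rtol=1e-9,
        )

    def test_epoch_streams_aggregate_near_panel_targets(self, truth):
        small = CohortConfig.desk(
            n_assessed=12, n_died=0, n_questionnaire_completers=10,
            n_no_accelerometer=2, seed=13, epoch_missing_rate=0.0,
            tsk_wave_missing_rates=(0, 0, 0, 0),
        )
        ds = generate_cohort(truth, small, include_epochs=True)
        pid = ds.epochs["patient_id"].iloc[0]
        week1 = ds.epochs[ds.epochs["patient_id"] == pid]
        first_day = pd.to_datetime(week1["timestamp"]).dt.date.min()
        day1 = week1[pd.to_datetime(week1["timestamp"]).dt.date == first_day]
        s = summarize_day(day1)
        target = ds.panel[(ds.panel["patient_id"] == pid) & (ds.panel["wave"] == 1)]
        # day targets are quantized to the 1-minute epoch grid
        assert abs(s.minutes_light - target["pa_light"].iloc[0]) <= 0.5
        assert abs(s.minutes_moderate - target["pa_moderate"].iloc[0]) <= 0.5
        assert abs(s.minutes_heavy - target["pa_heavy"].iloc[0]) <= 0.5

    def test_moment_fidelity_against_implied(self, truth):
        """Empirical moments of the generated panel match the RI-CLPM
        implied moments (loose single-set check; the acceptance suite runs
        the full multi-set version)."""
        from riclpm import build_riclpm, implied_moments

        model = build_riclpm()
        values = {k: v for k, v in truth_to_riclpm_values(truth).items()
                  if not k.startswith("rcov")}
        mp = implied_moments(model, values)
        panel = generate_latent_panel(truth, 50_000, seed=77)
        x = panel[list(model.selection)].to_numpy()
        emp = np.cov(x, rowvar=False)
        mc_se = np.sqrt(
            (np.outer(np.diag(mp.sigma), np.diag(mp.sigma)) + mp.sigma**2)
            / len(x)
        )
        assert (np.abs(emp - mp.sigma) < 4 * mc_se).all()

    def test_write_cohort_artifacts(self, truth, tmp_path):
        ds = generate_cohort(truth, CohortConfig(seed=1))
        paths = write_cohort(ds, tmp_path)
        assert set(paths) == {"panel", "items", "flow"}
        reread = pd.read_csv(paths["panel"])
        assert len(reread) == len(ds.panel)
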