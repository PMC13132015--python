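"""Mixed-effects fits, FDR, overnight change, Steiger's test."""

import subprocess
import sys
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from wakeosc.stats import (
    build_table,
    fdr_correct,
    fit_lme,
    overnight_change,
    per_channel_lme,
    steiger_z,
)
from wakeosc.synthetic import CohortParams, simulate_cohort


class TestBuildTable:
    def test_fragments_merge_to_single_row(self):
        meta = dict(
            Participant="P1", Session="S1", Task="oddball", Time="evening",
            Age=10.0, Group="control", Sex="female",
        )
        frags = [dict(meta, Amplitude=30.0), dict(meta, Exponent=1.5)]
        table = build_table(frags)
        assert len(table) == 1
        assert table.loc[0, "Amplitude"] == 30.0
        assert table.loc[0, "Exponent"] == 1.5

    def test_conflicting_duplicates_rejected(self):
        meta = dict(
            Participant="P1", Session="S1", Task="oddball", Time="evening",
            Age=10.0, Group="control", Sex="female",
        )
        with pytest.raises(ValueError, match="conflict"):
            build_table([dict(meta, Amplitude=30.0), dict(meta, Amplitude=31.0)])

    def test_missing_factor_named(self):
        with pytest.raises(ValueError, match="Age"):
            build_table([{"Participant": "P1", "Session": "S1",
                          "Task": "oddball", "Time": "evening",
                          "Group": "control", "Sex": "female"}])


class TestFitLme:
    def test_noise_free_recovery_exact(self):
        params = CohortParams(
            n_participants=40, sd_participant=0, sd_session=0, sd_residual=0,
            seed=5,
        )
        table = simulate_cohort(params)
        est = {e.term: e.beta for e in fit_lme(table, "Amplitude")}
        assert est["Age"] == pytest.approx(params.beta_age, abs=1e-6)
        assert est["Time"] == pytest.approx(params.beta_time, abs=1e-6)
        assert est["Time:Age"] == pytest.approx(params.beta_age_x_time, abs=1e-6)
        assert est["Group"] == pytest.approx(params.beta_group, abs=1e-6)
        assert est["Sex"] == pytest.approx(params.beta_sex, abs=1e-6)

    def test_df_is_rows_minus_fixed_params(self):
        table = simulate_cohort(CohortParams(n_participants=30, seed=8))
        ests = fit_lme(table, "Amplitude")
        assert ests[0].df == len(table) - len(ests)

    def test_row_order_invariance(self):
        table = simulate_cohort(CohortParams(n_participants=30, seed=2))
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = {e.term: e.beta for e in fit_lme(table, "Amplitude")}
        b = {e.term: e.beta for e in fit_lme(shuffled, "Amplitude")}
        for term in a:
            assert a[term] == pytest.approx(b[term], abs=1e-4)

    def test_agrees_with_lme4_oracle(self, tmp_path):
        """Independent cross-check against R's lmer on the same cohort."""
        table = simulate_cohort(CohortParams(n_participants=60, seed=13))
        csv = tmp_path / "cohort.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            """
            suppressMessages(library(lme4))
            d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
            d$TimeCode <- as.numeric(d$Time == "morning")
            d$GroupCode <- as.numeric(d$Group == "ADHD")
            d$SexCode <- as.numeric(d$Sex == "male")
            d$Task <- relevel(factor(d$Task), ref = "oddball")
            m <- lmer(Amplitude ~ Task + TimeCode*Age + GroupCode + SexCode
                      + (1|Participant) + (1|Participant:Session),
                      data = d, REML = FALSE)
            fe <- fixef(m)
            cat(fe[["Age"]], fe[["TimeCode"]], fe[["TimeCode:Age"]], sep = "\\n")
            """
        )
        proc = subprocess.run(
            ["Rscript", str(script), str(csv)],
            capture_output=True, text=True, timeout=300,
        )
        assert proc.returncode == 0, proc.stderr
        r_age, r_time, r_interaction = map(float, proc.stdout.split())
        est = {e.term: e.beta for e in fit_lme(table, "Amplitude")}
        assert est["Age"] == pytest.approx(r_age, abs=0.01)
        assert est["Time"] == pytest.approx(r_time, abs=0.01)
        assert est["Time:Age"] == pytest.approx(r_interaction, abs=0.01)

    def test_single_participant_rejected(self):
        table = simulate_cohort(CohortParams(n_participants=2, seed=1))
        solo = table[table["Participant"] == "P000"]
        with pytest.raises(ValueError):
            fit_lme(solo, "Amplitude")


class TestPerChannelLme:
    def test_identical_channels_identical_betas(self):
        table = simulate_cohort(CohortParams(n_participants=20, seed=4))
        long = pd.concat(
            [table.assign(Channel=ch) for ch in range(3)], ignore_index=True
        )
        frame = per_channel_lme(long, "Amplitude")
        ages = frame[frame["term"] == "Age"]
        assert ages["beta"].nunique() == 1 or np.allclose(
            ages["beta"], ages["beta"].iloc[0]
        )

    def test_planted_topographic_effect_recovered(self):
        rng = np.random.default_rng(6)
        frames = []
        base = simulate_cohort(
            CohortParams(n_participants=25, beta_group=0.0, sd_residual=1.0,
                         seed=6)
        )
        target = set(range(10))
        for ch in range(30):
            f = base.copy()
            f["Amplitude"] = f["Amplitude"] + rng.normal(0, 0.5, len(f))
            if ch in target:
                f["Amplitude"] += 5.0 * (f["Group"] == "ADHD")
            f["Channel"] = ch
            frames.append(f)
        frame = per_channel_lme(pd.concat(frames, ignore_index=True), "Amplitude")
        hits = frame[(frame["term"] == "Group") & frame["significant"]]
        found = set(hits["Channel"])
        assert len(found & target) >= 8
        assert len(found - target) <= 2


class TestFdrCorrect:
    def test_hand_computed_step_up(self):
        # thresholds (i/4)*0.05 = .0125/.025/.0375/.05; p(4)=.04<=.05 -> all
        mask, _ = fdr_correct([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert mask.all()

    def test_all_ones_none_rejected(self):
        mask, p_adj = fdr_correct([1.0, 1.0, 1.0], q=0.05)
        assert not mask.any()
        assert (p_adj == 1.0).all()

    def test_single_p_reduces_to_raw_threshold(self):
        mask, _ = fdr_correct([0.04], q=0.05)
        assert mask.all()

    def test_monotone_in_q_and_rank(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        small, _ = fdr_correct(p, q=0.01)
        large, _ = fdr_correct(p, q=0.10)
        assert set(np.flatnonzero(small)) <= set(np.flatnonzero(large))
        _, p_adj = fdr_correct(p)
        order = np.argsort(p)
        assert (np.diff(p_adj[order]) >= -1e-12).all()

    def test_null_false_discovery_proportion_controlled(self):
        rng = np.random.default_rng(1)
        fdp = []
        for _ in range(200):
            p = rng.random(100)  # all null
            mask, _ = fdr_correct(p, q=0.05)
            fdp.append(mask.any())
        # P(any rejection) under the global null is at most q
        assert np.mean(fdp) <= 0.05 + 0.03

    def test_empty_input(self):
        mask, p_adj = fdr_correct([])
        assert mask.size == 0 and p_adj.size == 0


class TestOvernightChange:
    def test_constant_difference_flagged_undefined(self):
        table = simulate_cohort(
            CohortParams(n_participants=10, sd_participant=0, sd_session=0,
                         sd_residual=0, beta_time=0.0, beta_age_x_time=0.0,
                         seed=2)
        )
        _, results = overnight_change(table, measures=("Amplitude",))
        assert np.isnan(results[0].r)

    def test_noise_free_linear_relation_gives_r_one(self):
        table = simulate_cohort(
            CohortParams(n_participants=50, sd_participant=0, sd_session=0,
                         sd_residual=0, beta_time=-4.0, beta_age_x_time=0.5,
                         seed=3)
        )
        _, results = overnight_change(table, measures=("Amplitude",))
        assert results[0].r == pytest.approx(1.0, abs=1e-9)

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(9)
        rows = []
        n = 200
        age = rng.uniform(5, 25, n)
        z = (age - age.mean()) / age.std()
        diff = 0.5 * z + np.sqrt(1 - 0.25) * rng.normal(size=n)
        for i in range(n):
            for time, value in (("evening", 0.0), ("morning", diff[i])):
                rows.append(
                    {"Participant": f"P{i}", "Time": time, "Age": age[i],
                     "Amplitude": value}
                )
        table = pd.DataFrame(rows)
        _, results = overnight_change(table, measures=("Amplitude",))
        assert results[0].r == pytest.approx(0.5, abs=0.1)

    def test_participant_missing_timepoint_excluded(self):
        table = simulate_cohort(CohortParams(n_participants=10, seed=4))
        table = table[
            ~((table["Participant"] == "P000") & (table["Time"] == "morning"))
        ]
        diff, _ = overnight_change(table, measures=("Amplitude",))
        assert "P000" not in set(diff["Participant"])


class TestSteigerZ:
    def test_equal_correlations_give_zero(self):
        assert steiger_z(0.5, 0.5, 0.3, 100).z == 0.0

    def test_antisymmetry(self):
        a = steiger_z(0.6, 0.3, 0.2, 80)
        b = steiger_z(0.3, 0.6, 0.2, 80)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            steiger_z(0.9, -0.9, 0.9, 50)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            steiger_z(0.5, 0.4, 0.3, 3)

    def test_statistic_grows_with_sample_size(self):
        z_small = steiger_z(0.6, 0.3, 0.2, 50).z
        z_large = steiger_z(0.6, 0.3, 0.2, 200).z
        assert z_large > z_small > 0
        # z scales with sqrt(n - 3) for fixed correlations
        assert z_large / z_small == pytest.approx(
            np.sqrt(197 / 47), rel=1e-9
        )
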