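"""Synthetic cohorts: generative agents, determinism, round-trip I/O."""

import numpy as np
import pandas as pd
import pytest

import inequitylearn as il
from inequitylearn.metrics import rejection_rates
from inequitylearn.simulate import (
    GenerativeAgent,
    REALISTIC_PRIORS,
    SchemaError,
    default_priors,
    generate_cohort,
    invert_fs_profile,
    read_dataset,
    write_dataset,
)


def _static_agent(alpha, beta, tau=5.0, omega=0.0):
    # a static-preference learner: learning phase changes nothing
    return GenerativeAgent(alpha, beta, tau, il.get_model(2),
                           [alpha, beta, tau], omega=omega)


class TestSimulateSubject:
    def test_western_baseline_pattern(self):
        # envious but not guilty: punish disadvantageous offers only
        agent = _static_agent(alpha=5.0, beta=0.0, tau=2.0)
        df, _ = il.simulate_subject(agent, "Dis-I-Averse", seed=0)
        rates = rejection_rates(df, "baseline").set_index("offer_type")["rate"]
        assert rates["90:10"] > 0.9 and rates["70:30"] > 0.9
        assert rates["50:50"] < 0.1 and rates["30:70"] < 0.1 and rates["10:90"] < 0.1

    def test_fair_offers_rarely_rejected(self):
        # moderate aversion: the FS indifference point 50a/(1+a) stays below
        # the noisy fair band (shares 41-59), so accepting always dominates
        agent = _static_agent(alpha=3.0, beta=3.0, tau=1.0)
        df, _ = il.simulate_subject(agent, "Dis-I-Averse", seed=1)
        rates = rejection_rates(df, "baseline").set_index("offer_type")["rate"]
        assert rates["50:50"] <= 0.2

    def test_no_contagion_null(self):
        # omega=0: transfer is distributionally identical to baseline; pool
        # subjects so binomial noise is small
        base_rates, trans_rates = [], []
        for s in range(20):
            agent = _static_agent(alpha=2.0, beta=0.5, tau=0.15, omega=0.0)
            df, _ = il.simulate_subject(agent, "Adv-Dis-I-Averse", seed=s)
            base_rates.append(rejection_rates(df, "baseline").set_index("offer_type")["rate"])
            trans_rates.append(rejection_rates(df, "transfer").set_index("offer_type")["rate"])
        diff = (pd.concat(trans_rates, axis=1).mean(axis=1)
                - pd.concat(base_rates, axis=1).mean(axis=1))
        # 100 trials per cell pooled: 3 SE of a worst-case binomial is ~0.15
        assert np.all(np.abs(diff) < 0.15)

    def test_full_contagion_raises_advantageous_rejection(self, m6_agent):
        dfs = [il.simulate_subject(m6_agent, "Adv-Dis-I-Averse", seed=s)[0]
               for s in range(10)]
        df = pd.concat(dfs, ignore_index=True).assign(
            subject=lambda d: d.groupby(level=0).ngroup() // 150
        )
        pooled = df.groupby(["phase", "offer_type"])["action"].apply(
            lambda a: (a == "reject").mean()
        )
        assert pooled["transfer"]["10:90"] > pooled["baseline"]["10:90"] + 0.3

    def test_phase_structure(self, m6_subject_records):
        counts = m6_subject_records.groupby("phase")["trial"].count()
        assert counts["baseline"] == 25
        assert counts["learning"] == 100
        assert counts["transfer"] == 25
        learning = m6_subject_records[m6_subject_records["phase"] == "learning"]
        assert learning["teacher_action"].notna().all()
        assert set(learning["reward"].unique()) <= {0.0, 1.0}

    def test_learned_preferences_track_teacher(self, m6_agent):
        _, learned_adv = il.simulate_subject(m6_agent, "Adv-Dis-I-Averse", seed=3)
        _, learned_dis = il.simulate_subject(m6_agent, "Dis-I-Averse", seed=3)
        # guilt is inferred only from an advantageous-inequity-averse teacher
        assert learned_adv[1] > 2.0
        assert learned_dis[1] < 1.0

    def test_invalid_inputs(self, m6_agent):
        with pytest.raises(ValueError, match="unknown condition"):
            il.simulate_subject(m6_agent, "Control", seed=0)
        with pytest.raises(ValueError, match="unknown experiment"):
            il.simulate_subject(m6_agent, "Dis-I-Averse", experiment=3, seed=0)
        with pytest.raises(ValueError, match="omega"):
            GenerativeAgent(1, 1, 1, il.get_model(6), [1, 1, 1, 1], omega=1.5)


class TestInvertFsProfile:
    def test_recovers_generating_preferences(self):
        from scipy.special import expit

        # tau small enough that the five probed probabilities stay interior,
        # where the map is well conditioned
        shares = np.array([10.0, 30.0, 50.0, 70.0, 90.0])
        alpha, beta, tau = 1.5, 2.0, 0.05
        u = shares - alpha * np.maximum(50 - shares, 0) - beta * np.maximum(shares - 50, 0)
        a_hat, b_hat = invert_fs_profile(expit(-tau * u), tau)
        assert a_hat == pytest.approx(alpha, abs=1e-3)
        assert b_hat == pytest.approx(beta, abs=1e-3)


class TestCohorts:
    def test_counts_and_keys(self, small_cohort):
        records, truth = small_cohort.records, small_cohort.truth
        assert records["subject"].nunique() == 6  # 3 per condition
        assert len(records) == 6 * 150  # 25 + 100 + 25 trials each
        assert not records.duplicated(["subject", "phase", "trial"]).any()
        assert len(truth) == 6
        assert set(truth["condition"].value_counts()) == {3}

    def test_truth_within_priors(self, small_cohort):
        truth = small_cohort.truth
        for name, (lo, hi) in REALISTIC_PRIORS.items():
            if name in truth.columns:
                assert truth[name].between(lo, hi).all()

    def test_default_priors_are_fitting_boxes(self):
        priors = default_priors(il.get_model(6))
        assert priors["eta"] == (0.0, 5.0)
        assert priors["alpha0"] == (0.0, 10.0)
        assert priors["omega"] == (0.0, 1.0)

    def test_empty_prior_box_rejected(self):
        with pytest.raises(ValueError, match="empty prior box"):
            generate_cohort(1, model=6, param_priors={"eta": (2.0, 1.0)}, master_seed=0)

    def test_teacher_feedback_frequency_matches_profile(self, small_cohort):
        learning = small_cohort.records.query("phase == 'learning'")
        adv = learning[learning["condition"] == "Adv-Dis-I-Averse"]
        frac = (adv[adv["offer_type"] == "30:70"]["teacher_action"] == "reject").mean()
        n = (adv["offer_type"] == "30:70").sum()
        assert abs(frac - 0.9) < 3 * np.sqrt(0.9 * 0.1 / n)


class TestRoundTrip:
    def test_byte_identical_under_same_seed(self, tmp_path):
        a = generate_cohort(2, model=6, param_priors=REALISTIC_PRIORS, master_seed=11)
        b = generate_cohort(2, model=6, param_priors=REALISTIC_PRIORS, master_seed=11)
        write_dataset(a, tmp_path / "a")
        write_dataset(b, tmp_path / "b")
        assert (tmp_path / "a/trials.csv").read_bytes() == (tmp_path / "b/trials.csv").read_bytes()
        assert (tmp_path / "a/ground_truth.csv").read_bytes() == (
            tmp_path / "b/ground_truth.csv"
        ).read_bytes()

    def test_round_trip_equality(self, small_cohort, tmp_path):
        write_dataset(small_cohort, tmp_path / "ds")
        back = read_dataset(tmp_path / "ds")
        pd.testing.assert_frame_equal(
            back.records, small_cohort.records, check_dtype=False
        )
        pd.testing.assert_frame_equal(back.truth, small_cohort.truth, check_dtype=False)

    def test_missing_column_named_in_error(self, small_cohort, tmp_path):
        write_dataset(small_cohort, tmp_path / "ds")
        trials = tmp_path / "ds" / "trials.csv"
        df = pd.read_csv(trials, comment="#").drop(columns=["feedback_available"])
        df.to_csv(trials, index=False)
        with pytest.raises(SchemaError, match="feedback_available"):
            read_dataset(tmp_path / "ds")
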