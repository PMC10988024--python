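"""Composite scoring, ANOVA partitioning, and FDR-corrected correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neuralign import (
    agreement_by_timeslot,
    correlate_with_fdr,
    composite_scores,
    generate_behavior,
    generate_latents,
    map_statements_to_slots,
    mixed_anova,
    rm_anova,
)
from neuralign.behavior import reverse_score
from neuralign.preprocess import Event

from _oracles import bh_stepup, splitplot_f_bruteforce, splitplot_ss
from conftest import small_sim_config


@pytest.fixture(scope="module")
def behavior_table():
    cfg = small_sim_config()
    gt = generate_latents(cfg)
    return generate_behavior(gt, cfg, seed=5), gt, cfg


class TestCompositeScores:
    def test_positive_affect_of_all_sevens(self, behavior_table):
        table, _, _ = behavior_table
        df = table.df.copy()
        for m in ("empathy", "sympathy", "compassion"):
            df[f"emotion_{m}_t1"] = 7
        from neuralign.behavior import BehaviorTable

        scores = composite_scores(BehaviorTable(df, table.n_statements))
        assert (scores["positive_affect_t1"] == 7).all()

    def test_reverse_scoring_involution_and_example(self):
        assert reverse_score(7, 1, 7) == 1
        x = np.array([1, 3, 6])
        np.testing.assert_array_equal(reverse_score(reverse_score(x, 1, 7), 1, 7), x)

    def test_negative_affect_mean(self, behavior_table):
        table, _, _ = behavior_table
        df = table.df.copy()
        for m, v in zip(("anger", "hate", "fear", "shame", "guilt"), (1, 2, 3, 4, 5)):
            df[f"emotion_{m}_t2"] = v
        from neuralign.behavior import BehaviorTable

        scores = composite_scores(BehaviorTable(df, table.n_statements))
        assert (scores["negative_affect_t2"] == 3).all()

    def test_reverse_scored_items_enter_positively(self, behavior_table):
        # negativity contains reverse-keyed items; flipping a subject's raw
        # reverse-keyed answer down must push the composite up
        table, _, _ = behavior_table
        from neuralign.behavior import SCALES, BehaviorTable

        rev = SCALES["negativity"][3][0]
        df = table.df.copy()
        col = f"negativity{rev + 1}_t1"
        lo = composite_scores(BehaviorTable(df.assign(**{col: 7}), table.n_statements))
        hi = composite_scores(BehaviorTable(df.assign(**{col: 1}), table.n_statements))
        assert (hi["negativity_t1"] > lo["negativity_t1"]).all()

    def test_item_order_invariance(self, behavior_table):
        table, _, _ = behavior_table
        from neuralign.behavior import BehaviorTable

        df = table.df.copy()
        a, b = "threat1_t1", "threat3_t1"
        df[a], df[b] = table.df[b].to_numpy(), table.df[a].to_numpy()
        s1 = composite_scores(table)
        s2 = composite_scores(BehaviorTable(df, table.n_statements))
        np.testing.assert_array_equal(s1["threat_t1"], s2["threat_t1"])

    def test_missing_item_excludes_subject_from_scale(self, behavior_table):
        table, _, _ = behavior_table
        from neuralign.behavior import BehaviorTable

        df = table.df.copy()
        df.loc[df.index[0], "warmth2_t1"] = np.nan
        scores = composite_scores(BehaviorTable(df, table.n_statements))
        assert np.isnan(scores.loc[scores.index[0], "warmth_t1"])
        assert np.isnan(scores.loc[scores.index[0], "warmth_delta"])
        assert scores["warmth_t1"].notna().iloc[1:].all()


class TestAgreementByTimeslot:
    def test_constant_agreement(self, behavior_table):
        table, gt, cfg = behavior_table
        from neuralign.behavior import BehaviorTable

        df = table.df.copy()
        for i in range(cfg.n_statements):
            df[f"agreement_s{i + 1}"] = 3
        slot_map = map_statements_to_slots(gt.events)
        ag = agreement_by_timeslot(BehaviorTable(df, cfg.n_statements), slot_map)
        for s in range(3):
            assert (ag[f"agreement_slot{s}"] == 3).all()
        assert (ag["agreement_diff"] == 0).all()

    def test_block_difference(self, behavior_table):
        table, gt, cfg = behavior_table
        from neuralign.behavior import BehaviorTable

        slot_map = map_statements_to_slots(gt.events)
        df = table.df.copy()
        for i in range(cfg.n_statements):
            df[f"agreement_s{i + 1}"] = 3 if slot_map[i] == 0 else 1
        ag = agreement_by_timeslot(BehaviorTable(df, cfg.n_statements), slot_map)
        assert (ag["agreement_diff"] == -2).all()

    def test_midpoint_slot_map_contiguous_and_complete(self, behavior_table):
        _, gt, cfg = behavior_table
        slot_map = map_statements_to_slots(gt.events)
        assert len(slot_map) == cfg.n_statements
        assert set(slot_map) == {0, 1, 2}
        assert (np.diff(slot_map) >= 0).all()  # contiguous blocks


class TestMixedAnova:
    def test_study_design_degrees_of_freedom(self):
        # 120 subjects in groups of 39/40/41, 3 timeslots: interaction df (4, 234)
        rng = np.random.default_rng(0)
        groups = ["a"] * 39 + ["b"] * 40 + ["c"] * 41
        res = mixed_anova(rng.standard_normal((120, 3)), groups)
        inter = next(r for r in res if r.effect == "group x time")
        assert inter.df == (4, 234)
        time = next(r for r in res if r.effect == "time")
        assert time.df == (2, 234)
        grp = next(r for r in res if r.effect == "group")
        assert grp.df == (2, 117)

    def test_small_balanced_instance_matches_bruteforce_ss(self):
        Y = np.array([[1, 2], [2, 4], [3, 3], [5, 6], [4, 8], [6, 5]], dtype=float)
        groups = ["a", "a", "a", "b", "b", "b"]
        res = {r.effect: r for r in mixed_anova(Y, groups)}
        oracle = splitplot_f_bruteforce(Y, groups)
        assert res["group"].F == pytest.approx(oracle["group"], abs=1e-10)
        assert res["time"].F == pytest.approx(oracle["time"], abs=1e-10)
        assert res["group x time"].F == pytest.approx(oracle["inter"], abs=1e-10)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_ss_decomposition_identity_random_unbalanced(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 8, size=3)
        groups = sum([[f"g{k}"] * int(n) for k, n in enumerate(sizes)], [])
        Y = rng.standard_normal((len(groups), 4)) + rng.standard_normal((1, 4))
        res = {r.effect: r for r in mixed_anova(Y, groups)}
        total = splitplot_ss(Y, groups)["total"]
        parts = (res["group"].ss + res["subjects within groups (error)"].ss
                 + res["time"].ss + res["group x time"].ss
                 + res["time x subjects (error)"].ss)
        assert parts == pytest.approx(total, abs=1e-8)

    def test_matches_pingouin_on_balanced_design(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        n, t = 12, 3
        groups = ["a"] * n + ["b"] * n
        Y = rng.standard_normal((2 * n, t))
        df = pd.DataFrame({
            "y": Y.ravel(),
            "subject": np.repeat(np.arange(2 * n), t),
            "time": np.tile(np.arange(t), 2 * n),
            "group": np.repeat(groups, t),
        })
        res = {r.effect: r for r in mixed_anova(Y, groups)}
        out = pg.mixed_anova(df, dv="y", within="time", subject="subject", between="group")
        pg_inter = out[out["Source"] == "Interaction"].iloc[0]
        assert res["group x time"].F == pytest.approx(pg_inter["F"], abs=1e-8)
        pg_grp = out[out["Source"] == "group"].iloc[0]
        assert res["group"].F == pytest.approx(pg_grp["F"], abs=1e-8)

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError):
            mixed_anova(np.zeros((3, 3)), ["a", "a", "b"])


class TestRmAnova:
    def test_time_df_numerator_is_two_for_three_slots(self):
        rng = np.random.default_rng(1)
        res = rm_anova(rng.standard_normal((39, 3)))
        assert res.df[0] == 2
        assert res.df[1] == 38 * 2

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((10, 3)) + np.array([0.0, 0.3, 0.8])
        res = rm_anova(Y)
        df = pd.DataFrame({
            "y": Y.ravel(),
            "subject": np.repeat(np.arange(10), 3),
            "time": np.tile(np.arange(3), 10),
        })
        out = pg.rm_anova(df, dv="y", within="time", subject="subject")
        assert res.F == pytest.approx(out["F"].iloc[0], abs=1e-8)
        assert res.p == pytest.approx(out["p_unc"].iloc[0], abs=1e-8)


class TestCorrelateWithFdr:
    def test_perfect_linear_measure(self):
        x = np.arange(10.0)
        Y = pd.DataFrame({"linear": 2 * x + 1, "noise": np.random.default_rng(3).standard_normal(10)})
        reports = {r.measure: r for r in correlate_with_fdr(x, Y)}
        assert reports["linear"].R == pytest.approx(1.0)

    def test_bh_hand_example(self):
        # p = [0.01, 0.02, 0.2] in a family of 3 → adjusted [0.03, 0.03, 0.2]
        adj = bh_stepup([0.01, 0.02, 0.2])
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.2])

    def test_equal_raw_p_unchanged_by_bh(self):
        adj = bh_stepup([0.07, 0.07, 0.07, 0.07])
        np.testing.assert_allclose(adj, 0.07)

    def test_fdr_matches_bruteforce_stepup(self):
        # implementation route (statsmodels BH) vs enumeration oracle on
        # random p-vectors embedded in real correlation output
        rng = np.random.default_rng(4)
        for _ in range(25):
            n = 25
            x = rng.standard_normal(n)
            m = int(rng.integers(2, 10))
            Y = pd.DataFrame({f"m{j}": x * rng.uniform(-1, 1) + rng.standard_normal(n)
                              for j in range(m)})
            reports = correlate_with_fdr(x, Y)
            p_raw = [r.p_raw for r in reports]
            adj = bh_stepup(p_raw)
            for r, a in zip(reports, adj):
                assert r.p_fdr == pytest.approx(a, abs=1e-12)
                assert r.p_fdr >= r.p_raw - 1e-15

    def test_zero_variance_measure_reported_missing(self):
        x = np.arange(8.0)
        Y = pd.DataFrame({"flat": np.ones(8), "ok": x + 1})
        reports = {r.measure: r for r in correlate_with_fdr(x, Y)}
        assert np.isnan(reports["flat"].R)
        assert not np.isnan(reports["ok"].p_fdr)

    def test_pairwise_complete_handling(self):
        x = np.array([1.0, 2, 3, 4, 5, np.nan])
        Y = pd.DataFrame({"a": [2.0, 4, 6, 8, 10, 12], "b": [1.0, np.nan, 2, 5, 3, 4]})
        reports = {r.measure: r for r in correlate_with_fdr(x, Y)}
        assert reports["a"].n == 5
        assert reports["b"].n == 4
        assert reports["a"].R == pytest.approx(1.0)

    def test_planted_thermometer_effect_flagged_selectively(self):
        # one strong planted effect among nine deltas: only the thermometer
        # survives FDR (single-replicate version of the acceptance study)
        from neuralign import SimulationConfig
        from neuralign.behavior import DELTA_MEASURES

        cfg = SimulationConfig(
            n_groups=1, group_sizes=(39,), behavior_effect=0.9, agreement_effect=0.0,
            shared_snr_schedule=((0.0, 0.0, 0.0),), agreement_trend=(-0.4,),
            agreement_baseline=(2.4,), n_channels=4, n_statements=6,
            statement_duration_range=(4.0, 6.0), sampling_rate=100.0, seed=77,
        )
        gt = generate_latents(cfg)
        table = generate_behavior(gt, cfg, seed=78)
        scores = composite_scores(table)
        deltas = scores[[f"{m}_delta" for m in DELTA_MEASURES]]
        deltas.columns = list(DELTA_MEASURES)
        reports = {r.measure: r for r in correlate_with_fdr(gt.subject_coupling[0], deltas)}
        assert reports["feeling_thermometer"].p_fdr < 0.05
        others = [r for m, r in reports.items() if m != "feeling_thermometer"]
        assert sum(r.p_fdr < 0.05 for r in others) == 0
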