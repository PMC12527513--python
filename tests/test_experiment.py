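"""Tests for the confounded factorial design, scoring, and analyses."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from marcplot.experiment import (
    K_LEVELS,
    MAX_SCORE,
    VIZ_LEVELS,
    ConditionResponse,
    ResponseSheet,
    analyze_durations,
    analyze_scores,
    build_design,
    default_confounding_patterns,
    make_answer_key,
    score_responses,
    scores_to_frame,
    simulate_responses,
    tukey_pairwise,
    validate_pattern,
    _as_duration_frame,
)

ALL_COMBOS = {(v, k) for v in VIZ_LEVELS for k in K_LEVELS}


@pytest.fixture(scope="module")
def key():
    per_k = {
        k: {f"Q{i}": f"answer-{k}-{i}" for i in range(1, 9)} | {"Q5": 0.1}
        for k in K_LEVELS
    }
    return make_answer_key(per_k)


def make_sheet(answers_by_cond, attention=True, total=600.0, pid="P1"):
    conds = tuple(
        ConditionResponse(viz=v, k=k, answers=a, duration_s=60.0)
        for (v, k), a in answers_by_cond.items()
    )
    return ResponseSheet(
        participant_id=pid, conditions=conds, attention_pass=attention,
        total_duration_s=total,
    )


def four_conditions():
    return [("MARCv1", 10), ("MARCv2", 20), ("BP", 50), ("FP", 100)]


class TestDesign:
    def test_twelve_survey_blocks(self):
        plan = build_design(24, seed=0)
        assert plan.n_survey_blocks == 12
        assert plan.n_combinations == 16
        assert plan.conditions_per_participant == 4

    def test_patterns_satisfy_block_invariants(self):
        patterns = default_confounding_patterns()
        assert len(patterns) == 3
        for blocks in patterns:
            validate_pattern(blocks)
            union = set(itertools.chain.from_iterable(blocks.values()))
            assert union == ALL_COMBOS
        # the three partitions are pairwise distinct
        frozen = [
            frozenset(frozenset(c) for c in p.values()) for p in patterns
        ]
        assert len(set(frozen)) == 3

    def test_every_block_has_each_viz_once(self):
        plan = build_design(10, seed=1)
        for _, _, conds in plan.survey_blocks:
            assert sorted(v for v, _ in conds) == sorted(VIZ_LEVELS)

    def test_replicates_at_reference_sample_size(self):
        assert build_design(160, seed=0).n_full_replicates == 10

    @pytest.mark.parametrize("seed", range(0, 100, 2))
    def test_balance_for_any_seed(self, seed):
        """Assignment imbalance is at most 1 for every seed."""
        n = 7 + seed % 190
        plan = build_design(n, seed=seed)
        counts = pd.Series(plan.assignment).value_counts()
        assert counts.max() - (counts.min() if len(counts) == 12 else 0) <= 1
        df = plan.to_frame()
        assert len(df) == 4 * n
        # condition order is a permutation of the block per participant
        for pid, grp in df.groupby("participant_id"):
            assert sorted(grp["order"]) == [0, 1, 2, 3]
            assert len(set(zip(grp["viz"], grp["k"]))) == 4

    def test_deterministic_given_seed(self):
        a, b = build_design(37, seed=9), build_design(37, seed=9)
        assert a.assignment == b.assignment
        assert a.condition_order == b.condition_order

    def test_invalid_pattern_rejected(self):
        patterns = default_confounding_patterns()
        bad = {bid: list(conds) for bid, conds in patterns[0].items()}
        bad[0], bad[1] = bad[1], bad[0]
        bad[0][0], bad[1][0] = bad[1][0], bad[0][0]  # break the partition? swap
        # construct an actually invalid pattern: duplicate a condition
        bad[0][1] = bad[0][0]
        with pytest.raises(ValueError):
            validate_pattern(bad)


class TestScoring:
    def test_perfect_answers_score_seven_q8_ignored(self, key):
        answers = {}
        for cond in four_conditions():
            a = dict(key[cond])
            a["Q8"] = "wrong"
            answers[cond] = a
        outcome = score_responses(make_sheet(answers), key)
        assert not outcome.excluded
        assert [r.score for r in outcome.records] == [MAX_SCORE] * 4

    def test_all_wrong_scores_zero(self, key):
        answers = {
            cond: {f"Q{i}": "nope" for i in range(1, 9)} | {"Q5": 0.4}
            for cond in four_conditions()
        }
        outcome = score_responses(make_sheet(answers), key)
        assert [r.score for r in outcome.records] == [0, 0, 0, 0]

    def test_short_total_duration_excluded(self, key):
        answers = {cond: dict(key[cond]) for cond in four_conditions()}
        outcome = score_responses(make_sheet(answers, total=170.0), key)
        assert outcome.excluded
        assert any("duration" in r for r in outcome.reasons)

    def test_failed_attention_check_excluded(self, key):
        answers = {cond: dict(key[cond]) for cond in four_conditions()}
        outcome = score_responses(make_sheet(answers, attention=False), key)
        assert outcome.excluded

    def test_slider_tolerance_and_range(self, key):
        answers = {cond: dict(key[cond]) for cond in four_conditions()}
        # within tolerance: correct
        answers[("MARCv1", 10)]["Q5"] = 0.1 + 0.049
        # outside tolerance: wrong
        answers[("MARCv2", 20)]["Q5"] = 0.1 + 0.051
        # outside slider range: invalid flag
        answers[("BP", 50)]["Q5"] = 0.7
        outcome = score_responses(make_sheet(answers), key)
        by_cond = {(r.viz, r.k): r.score for r in outcome.records}
        assert by_cond[("MARCv1", 10)] == 7
        assert by_cond[("MARCv2", 20)] == 6
        assert by_cond[("BP", 50)] == 6
        assert outcome.invalid_responses == ("BP/k=50/Q5",)

    def test_scoring_order_invariant(self, key):
        rng = np.random.default_rng(4)
        answers = {
            cond: {
                q: (key[cond][q] if rng.random() < 0.5 else "zz")
                for q in key[cond]
            }
            for cond in four_conditions()
        }
        base = score_responses(make_sheet(answers), key)
        shuffled = dict(reversed(list(answers.items())))
        other = score_responses(make_sheet(shuffled), key)
        assert {(r.viz, r.k): r.score for r in base.records} == {
            (r.viz, r.k): r.score for r in other.records
        }


class TestScoreAnalysis:
    @pytest.fixture(scope="class")
    def score_frame(self, key):
        plan = build_design(160, seed=11)
        sheets = simulate_responses(
            plan, key, seed=12,
            p_correct={"MARCv1": 0.6, "MARCv2": 0.85, "BP": 0.5, "FP": 0.6},
        )
        records = [
            r for s in sheets for r in score_responses(s, key).records
        ]
        return scores_to_frame(records)

    def test_anova_table_structure(self, score_frame):
        res = analyze_scores(score_frame)
        assert list(res.anova.index) == [
            "C(viz)", "C(k)", "C(viz):C(k)", "Residual",
        ]
        assert res.tukey.shape[0] == 6
        assert (res.anova["df"] > 0).all()

    def test_detects_simulated_advantage(self, score_frame):
        res = analyze_scores(score_frame)
        row = res.tukey.query(
            "(group1 == 'MARCv2' and group2 == 'BP')"
            " or (group1 == 'BP' and group2 == 'MARCv2')"
        ).iloc[0]
        sign = 1 if row["group1"] == "MARCv2" else -1
        assert sign * row["diff"] > 0
        assert row["reject"]

    def test_location_invariance_of_f_statistics(self, score_frame):
        res = analyze_scores(score_frame)
        shifted = score_frame.assign(score=score_frame["score"] + 3)
        res2 = analyze_scores(shifted)
        f1 = res.anova["F"].dropna().to_numpy()
        f2 = res2.anova["F"].dropna().to_numpy()
        assert np.allclose(f1, f2, rtol=1e-8)

    def test_tukey_two_groups_matches_t_test(self):
        """With 2 groups the studentized-range p equals the pooled t p."""
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 25), rng.normal(0.4, 1, 30)
        df = pd.DataFrame({
            "viz": ["A"] * 25 + ["B"] * 30,
            "k": 10,
            "score": np.concatenate([a, b]),
        })
        table = tukey_pairwise(df)
        t_res = stats.ttest_ind(a, b, equal_var=True)
        assert table.loc[0, "p_adj"] == pytest.approx(t_res.pvalue, abs=1e-5)
        assert table.loc[0, "q"] == pytest.approx(
            math.sqrt(2) * abs(t_res.statistic), rel=1e-10
        )

    def test_tukey_matches_statsmodels_oneway(self):
        """With a single k level the cell-means MSE is the one-way
        within-group MSE, so results must match pairwise_tukeyhsd."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(13)
        df = pd.DataFrame({
            "viz": np.repeat(list(VIZ_LEVELS), 30),
            "k": 20,
            "score": rng.normal([3, 5, 4, 4.5], 1.2, size=(30, 4)).T.ravel(),
        })
        ours = tukey_pairwise(df)  # pairs in sorted-level order
        ref = pairwise_tukeyhsd(df["score"], df["viz"], alpha=0.05)
        # statsmodels reports group2 - group1 for the same pair ordering
        assert np.allclose(ours["diff"].to_numpy(), -ref.meandiffs, atol=1e-10)
        assert np.allclose(ours["p_adj"].to_numpy(), ref.pvalues, atol=1e-6)
        assert list(ours["reject"]) == list(ref.reject)

    def test_tukey_fast_path_matches_model_path(self, score_frame):
        res = analyze_scores(score_frame)
        fast = tukey_pairwise(score_frame, alpha=res.alpha)
        pd.testing.assert_frame_equal(
            res.tukey.drop(columns="p_adj"), fast.drop(columns="p_adj")
        )

    def test_empty_cells_raise_dof_error(self, score_frame):
        broken = score_frame[
            ~((score_frame["viz"] == "FP") & (score_frame["k"] == 10))
        ]
        # removing one cell entirely
        with pytest.raises(ValueError, match="degrees of freedom|replication"):
            analyze_scores(broken)


class TestDurationAnalysis:
    def test_degenerate_person_variance_matches_ols(self, key):
        import statsmodels.formula.api as smf

        plan = build_design(120, seed=21)
        sheets = simulate_responses(plan, key, seed=22, participant_sd=0.0)
        res = analyze_durations(sheets)
        df = _as_duration_frame(sheets)
        df["k_c"] = df["k"] - df["k"].mean()
        ols = smf.ols(
            "duration_s ~ C(viz, Treatment(reference='MARCv2')) * k_c", data=df
        ).fit()
        assert np.allclose(res.params.values, ols.params.values, atol=0.02)

    def test_recovers_simulated_viz_effect(self, key):
        """+30 s forest-plot effect recovered within its CI in >=90% of reps."""
        plan = build_design(200, seed=31)
        hits = 0
        reps = 20
        for r in range(reps):
            sheets = simulate_responses(
                plan, key, seed=300 + r,
                duration_viz_effects={"MARCv1": 0, "MARCv2": 0, "BP": 0, "FP": 30.0},
            )
            res = analyze_durations(sheets)
            name = [
                i for i in res.params.index if "T.FP]" in i and ":" not in i
            ][0]
            lo, hi = res.conf_int.loc[name]
            hits += lo <= 30.0 <= hi
        assert hits >= 0.9 * reps

    def test_centering_contract(self, key):
        """Shifting k by a constant leaves interaction estimates unchanged."""
        plan = build_design(80, seed=41)
        sheets = simulate_responses(plan, key, seed=42)
        df = _as_duration_frame(sheets)
        res = analyze_durations(df)
        shifted = df.assign(k=df["k"] + 37)
        res2 = analyze_durations(shifted)
        inter = [i for i in res.params.index if ":k_c" in i]
        assert np.allclose(
            res.params[inter].values, res2.params[inter].values, atol=1e-6
        )

    def test_reference_category_configurable(self, key):
        plan = build_design(60, seed=51)
        sheets = simulate_responses(plan, key, seed=52)
        res = analyze_durations(sheets, reference="FP")
        assert res.reference == "FP"
        assert not any("T.FP]" in i for i in res.params.index)
        with pytest.raises(ValueError):
            analyze_durations(sheets, reference="nope")

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame({
            "participant_id": ["a", "b"],
            "viz": ["FP", "BP"],
            "k": [10, 20],
            "duration_s": [60.0, 70.0],
        })
        with pytest.raises(ValueError, match=">= 2 observations"):
            analyze_durations(df)
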