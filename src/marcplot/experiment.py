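"""Confounded-factorial survey-experiment toolkit.

Machinery for a 4 x 4 factorial evaluation of meta-analytic
visualizations: Factor A is the visualization type (MARCv1, MARCv2, bar
plot, forest plot) and Factor B the number of studies k (10, 20, 50,
100). Showing all 16 combinations to one person is infeasible, so the
16 runs are confounded into 4 blocks of 4; each participant views one
block. Three distinct confounding patterns keep interaction contrasts
estimable in part of the sample, giving 12 survey blocks in total, and
every block contains each visualization type exactly once so the
visualization main effect is estimable within person.

The default patterns alias the two 4-level factors through GF(4)
arithmetic: with factor levels coded 0-3 as field elements, pattern
``lam`` assigns combination (a, b) to block ``a + lam * b`` (field
addition is XOR). Every non-zero ``lam`` is a unit, so each block picks
each visualization exactly once, and ``lam = 1, 2, 3`` give three
distinct partitions. Custom patterns can be supplied; the block
invariants are always validated.

Scoring follows the questionnaire contract: seven scored items (Q1-Q7,
each 0/1), an exploratory Q8 that never counts, a slider item Q5 with a
correctness tolerance, and exclusion of participants who fail the
attention check or finish in under 3 minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VIZ_LEVELS",
    "K_LEVELS",
    "DesignPlan",
    "ConditionResponse",
    "ResponseSheet",
    "ScoreRecord",
    "ScoringOutcome",
    "ScoreAnalysis",
    "DurationAnalysis",
    "build_design",
    "default_confounding_patterns",
    "validate_pattern",
    "score_responses",
    "analyze_scores",
    "tukey_pairwise",
    "analyze_durations",
    "simulate_responses",
    "make_answer_key",
]

VIZ_LEVELS = ("MARCv1", "MARCv2", "BP", "FP")
K_LEVELS = (10, 20, 50, 100)
SCORED_QUESTIONS = tuple(f"Q{i}" for i in range(1, 8))
ALL_QUESTIONS = SCORED_QUESTIONS + ("Q8",)
MAX_SCORE = len(SCORED_QUESTIONS)

SLIDER_QUESTION = "Q5"
SLIDER_RANGE = (-0.5, 0.5)
DEFAULT_SLIDER_TOL = 0.05  # one tick of the [-0.5, 0.5] slider
MIN_TOTAL_DURATION_S = 180.0

Condition = tuple[str, int]  # (visualization type, k)


def _gf4_mul(a: int, b: int) -> int:
    """Multiplication in GF(4) on {0,1,2,3} (XOR is addition)."""
    # polynomial multiplication mod x^2 + x + 1
    prod = 0
    x, y = a, b
    while y:
        if y & 1:
            prod ^= x
        y >>= 1
        x <<= 1
        if x & 4:
            x ^= 0b111  # reduce by x^2 + x + 1
    return prod


def default_confounding_patterns() -> list[dict[int, list[Condition]]]:
    """Three GF(4)-aliased partitions of the 16 runs into 4 blocks."""
    patterns = []
    for lam in (1, 2, 3):
        blocks: dict[int, list[Condition]] = {c: [] for c in range(4)}
        for a, viz in enumerate(VIZ_LEVELS):
            for b, k in enumerate(K_LEVELS):
                blocks[a ^ _gf4_mul(lam, b)].append((viz, k))
        patterns.append(blocks)
    return patterns


def validate_pattern(blocks: Mapping[int, Sequence[Condition]]) -> None:
    """Check the block invariants of one confounding pattern."""
    if len(blocks) != 4:
        raise ValueError("a pattern must have exactly 4 blocks")
    seen: set[Condition] = set()
    for bid, conds in blocks.items():
        if len(conds) != 4:
            raise ValueError(f"block {bid} must hold 4 conditions")
        vizzes = [v for v, _ in conds]
        if sorted(vizzes) != sorted(VIZ_LEVELS):
            raise ValueError(
                f"block {bid} must contain each visualization type exactly once"
            )
        seen.update(conds)
    expected = {(v, k) for v in VIZ_LEVELS for k in K_LEVELS}
    if seen != expected:
        raise ValueError("blocks must partition all 16 treatment combinations")


@dataclass(frozen=True)
class DesignPlan:
    """Resolved design: survey blocks and participant assignments.

    ``survey_blocks[i]`` is a (pattern index, block id, conditions)
    triple; ``assignment[pid]`` is the survey-block index for that
    participant and ``condition_order[pid]`` the order in which its four
    conditions are shown.
    """

    n_participants: int
    patterns: tuple
    survey_blocks: tuple
    assignment: dict[int, int]
    condition_order: dict[int, tuple[int, ...]]
    seed: int

    @property
    def n_combinations(self) -> int:
        return len(VIZ_LEVELS) * len(K_LEVELS)

    @property
    def n_survey_blocks(self) -> int:
        return len(self.survey_blocks)

    @property
    def conditions_per_participant(self) -> int:
        return len(self.survey_blocks[0][2])

    @property
    def n_full_replicates(self) -> int:
        """Complete replicates of the 16-run design: one per 16
        participants (each contributing a 4-condition block)."""
        return self.n_participants // self.n_combinations

    def participant_conditions(self, pid: int) -> list[Condition]:
        """Conditions for one participant, in presentation order."""
        conds = self.survey_blocks[self.assignment[pid]][2]
        return [conds[i] for i in self.condition_order[pid]]

    def to_frame(self) -> pd.DataFrame:
        """One row per participant-condition: pattern, block, viz, k, order."""
        rows = []
        for pid in range(self.n_participants):
            sb = self.assignment[pid]
            pattern, block, conds = self.survey_blocks[sb]
            for pos, idx in enumerate(self.condition_order[pid]):
                viz, k = conds[idx]
                rows.append(
                    {
                        "participant_id": pid,
                        "pattern": pattern,
                        "block": block,
                        "viz": viz,
                        "k": k,
                        "order": pos,
                    }
                )
        return pd.DataFrame(rows)


def build_design(
    n_participants: int,
    seed: int = 0,
    patterns: Optional[Sequence[Mapping[int, Sequence[Condition]]]] = None,
) -> DesignPlan:
    """Assign participants evenly and randomly to the 12 survey blocks.

    Participants are dealt round-robin over a seeded random permutation
    of the survey blocks, so block sizes differ by at most one for any
    ``n_participants``; the presentation order of each participant's
    four conditions is randomized independently.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if patterns is None:
        patterns = default_confounding_patterns()
    for p in patterns:
        validate_pattern(p)
    survey_blocks = tuple(
        (pi, bid, tuple(blocks[bid]))
        for pi, blocks in enumerate(patterns)
        for bid in sorted(blocks)
    )
    rng = np.random.default_rng(seed)
    block_order = rng.permutation(len(survey_blocks))
    participant_order = rng.permutation(n_participants)
    assignment = {
        int(pid): int(block_order[i % len(survey_blocks)])
        for i, pid in enumerate(participant_order)
    }
    condition_order = {
        pid: tuple(int(j) for j in rng.permutation(4))
        for pid in range(n_participants)
    }
    return DesignPlan(
        n_participants=n_participants,
        patterns=tuple(
            tuple((bid, tuple(p[bid])) for bid in sorted(p)) for p in patterns
        ),
        survey_blocks=survey_blocks,
        assignment=assignment,
        condition_order=condition_order,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# scoring

@dataclass(frozen=True)
class ConditionResponse:
    viz: str
    k: int
    answers: Mapping[str, object]   # Q1..Q8
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError("durations must be >= 0")


@dataclass(frozen=True)
class ResponseSheet:
    participant_id: str
    conditions: tuple[ConditionResponse, ...]
    attention_pass: bool
    total_duration_s: float

    def __post_init__(self) -> None:
        if len(self.conditions) != 4:
            raise ValueError("a response sheet has exactly 4 conditions")
        if self.total_duration_s < 0:
            raise ValueError("durations must be >= 0")


@dataclass(frozen=True)
class ScoreRecord:
    participant_id: str
    viz: str
    k: int
    score: int

    def __post_init__(self) -> None:
        if not (0 <= self.score <= MAX_SCORE):
            raise ValueError(f"score must be in [0, {MAX_SCORE}]")


@dataclass(frozen=True)
class ScoringOutcome:
    """Either four score records, or an exclusion with its reasons."""

    participant_id: str
    records: tuple[ScoreRecord, ...]
    excluded: bool
    reasons: tuple[str, ...] = ()
    invalid_responses: tuple[str, ...] = ()


def make_answer_key(per_k: Mapping[int, Mapping[str, object]]) -> dict[Condition, dict]:
    """Expand per-dataset (per-k) correct answers to all 16 conditions.

    Correct answers depend only on the underlying dataset, not on how it
    is displayed, so one entry per k level suffices.
    """
    key = {}
    for k, answers in per_k.items():
        missing = [q for q in ALL_QUESTIONS if q not in answers]
        if missing:
            raise ValueError(f"answer key for k={k} missing {missing}")
        for viz in VIZ_LEVELS:
            key[(viz, k)] = dict(answers)
    return key


def score_responses(
    sheet: ResponseSheet,
    key: Mapping[Condition, Mapping[str, object]],
    slider_tol: float = DEFAULT_SLIDER_TOL,
    min_total_duration_s: float = MIN_TOTAL_DURATION_S,
) -> ScoringOutcome:
    """Score one participant's sheet, or exclude it.

    Each of Q1-Q7 contributes 0/1 (Q8 is exploratory and never
    counted). The slider item Q5 is correct iff the answer is within
    ``slider_tol`` of the true value; a slider answer outside the
    [-0.5, 0.5] range is flagged invalid (and scored 0). Exclusion
    applies to a failed attention check or a total duration under
    ``min_total_duration_s``.
    """
    reasons = []
    if not sheet.attention_pass:
        reasons.append("failed attention check")
    if sheet.total_duration_s < min_total_duration_s:
        reasons.append(
            f"total duration {sheet.total_duration_s:.0f}s "
            f"< {min_total_duration_s:.0f}s"
        )
    if reasons:
        return ScoringOutcome(
            participant_id=sheet.participant_id,
            records=(),
            excluded=True,
            reasons=tuple(reasons),
        )
    records = []
    invalid = []
    for cond in sheet.conditions:
        cond_key = key[(cond.viz, cond.k)]
        score = 0
        for q in SCORED_QUESTIONS:
            answer = cond.answers.get(q)
            if q == SLIDER_QUESTION:
                if answer is None:
                    continue
                try:
                    answer = float(answer)
                except (TypeError, ValueError):
                    invalid.append(f"{cond.viz}/k={cond.k}/{q}")
                    continue
                if not (SLIDER_RANGE[0] <= answer <= SLIDER_RANGE[1]):
                    invalid.append(f"{cond.viz}/k={cond.k}/{q}")
                    continue
                if abs(answer - float(cond_key[q])) <= slider_tol:
                    score += 1
            elif answer is not None and answer == cond_key[q]:
                score += 1
        records.append(
            ScoreRecord(
                participant_id=sheet.participant_id,
                viz=cond.viz,
                k=cond.k,
                score=score,
            )
        )
    return ScoringOutcome(
        participant_id=sheet.participant_id,
        records=tuple(records),
        excluded=False,
        invalid_responses=tuple(invalid),
    )


def scores_to_frame(records: Iterable[ScoreRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"participant_id": r.participant_id, "viz": r.viz, "k": r.k,
             "score": r.score}
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# analysis

@dataclass(frozen=True)
class ScoreAnalysis:
    anova: pd.DataFrame
    tukey: pd.DataFrame
    mse: float
    df_resid: float
    alpha: float


def _as_score_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = scores_to_frame(records)
    required = {"viz", "k", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"score data needs columns {sorted(required)}")
    return df


def _cell_mse(df: pd.DataFrame) -> tuple[float, float]:
    """Residual mean square of the full interaction model.

    With both factors categorical and the interaction included, the
    model is the cell-means model, so its residual sum of squares is the
    within-cell sum of squares — no regression fit needed.
    """
    grouped = df.groupby(["viz", "k"], observed=True)["score"]
    ss = float((grouped.transform("mean") - df["score"]).pow(2).sum())
    df_resid = float(len(df) - grouped.ngroups)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    return ss / df_resid, df_resid


def tukey_pairwise(
    records,
    alpha: float = 0.05,
    mse: Optional[float] = None,
    df_resid: Optional[float] = None,
    q_crit: Optional[float] = None,
    pvalues: bool = True,
) -> pd.DataFrame:
    """Tukey-Kramer comparisons of mean score over visualization pairs.

    Uses the residual mean square of the two-factor interaction model
    (computed from cell means unless supplied). Reports the raw mean
    difference, the standardized difference (diff / sqrt(MSE)), the
    studentized-range p-value and a simultaneous CI at family-wise
    level ``alpha``. The rejection decision compares each q statistic
    with the studentized-range critical value, so simulation loops may
    pass a precomputed ``q_crit`` and set ``pvalues=False`` (the
    critical value depends only on alpha, the number of groups and the
    residual degrees of freedom, and the p-value integral is costly).
    """
    df = _as_score_frame(records)
    if mse is None or df_resid is None:
        mse, df_resid = _cell_mse(df)
    groups = df.groupby("viz", observed=True)["score"]
    means, ns = groups.mean(), groups.size()
    levels = list(means.index)
    n_groups = len(levels)
    if q_crit is None:
        q_crit = float(stats.studentized_range.ppf(1 - alpha, n_groups, df_resid))
    rows = []
    for i in range(n_groups):
        for j in range(i + 1, n_groups):
            a, b = levels[i], levels[j]
            diff = float(means[a] - means[b])
            se_pair = math.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q_stat = abs(diff) / se_pair
            p = (
                float(stats.studentized_range.sf(q_stat, n_groups, df_resid))
                if pvalues
                else float("nan")
            )
            half = q_crit * se_pair
            rows.append(
                {
                    "group1": a,
                    "group2": b,
                    "diff": diff,
                    "std_effect": diff / math.sqrt(mse),
                    "q": q_stat,
                    "p_adj": p,
                    "ci_low": diff - half,
                    "ci_high": diff + half,
                    "reject": q_stat > q_crit,
                }
            )
    return pd.DataFrame(rows)


def analyze_scores(records, alpha: float = 0.05) -> ScoreAnalysis:
    """Two-factor ANOVA with interaction plus Tukey pairwise comparisons.

    Fits ``score ~ viz * k`` (both categorical; Type II sums of squares,
    appropriate for the mildly unbalanced confounded design) and runs
    :func:`tukey_pairwise` over the 6 visualization pairs using the
    model's residual mean square.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = _as_score_frame(records)
    for factor in ("viz", "k"):
        if df[factor].nunique() < 2:
            raise ValueError(f"need >= 2 levels of {factor}")
    cells = df.groupby(["viz", "k"], observed=True).size()
    full = pd.MultiIndex.from_product(
        [df["viz"].unique(), df["k"].unique()], names=["viz", "k"]
    )
    cells = cells.reindex(full, fill_value=0)
    if (cells < 2).any():
        empty = cells[cells < 2].index.tolist()
        raise ValueError(
            f"insufficient replication (residual degrees of freedom) in cells {empty}"
        )
    model = smf.ols("score ~ C(viz) * C(k)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    mse = float(model.mse_resid)
    df_resid = float(model.df_resid)
    tukey = tukey_pairwise(df, alpha=alpha, mse=mse, df_resid=df_resid)
    return ScoreAnalysis(
        anova=anova, tukey=tukey, mse=mse, df_resid=df_resid, alpha=alpha,
    )


@dataclass(frozen=True)
class DurationAnalysis:
    params: pd.Series
    conf_int: pd.DataFrame
    random_intercept_var: float
    singular: bool
    converged: bool
    reference: str
    summary: str


def _as_duration_frame(sheets) -> pd.DataFrame:
    if isinstance(sheets, pd.DataFrame):
        df = sheets.copy()
        required = {"participant_id", "viz", "k", "duration_s"}
        if not required.issubset(df.columns):
            raise ValueError(f"duration data needs columns {sorted(required)}")
        return df
    rows = []
    for sheet in sheets:
        for cond in sheet.conditions:
            rows.append(
                {
                    "participant_id": sheet.participant_id,
                    "viz": cond.viz,
                    "k": cond.k,
                    "duration_s": cond.duration_s,
                }
            )
    return pd.DataFrame(rows)


def analyze_durations(sheets, reference: str = "MARCv2") -> DurationAnalysis:
    """Two-level mixed model for page durations.

    Repeated measurements (4 per person) are nested within participants
    via a random intercept; fixed effects are visualization type (dummy
    coded against ``reference``), the centered number of studies, and
    their interactions. With centering, the intercept is the reference
    visualization's mean duration at the average k. Near-singular fits
    (random-intercept variance at the boundary) are reported via the
    ``singular`` flag, never dropped.
    """
    import warnings as _warnings

    import statsmodels.formula.api as smf

    df = _as_duration_frame(sheets)
    counts = df.groupby("participant_id", observed=True).size()
    if (counts < 2).any():
        raise ValueError("need >= 2 observations per participant")
    if reference not in df["viz"].unique():
        raise ValueError(f"reference level {reference!r} not present")
    df["k_c"] = df["k"] - df["k"].mean()
    formula = f"duration_s ~ C(viz, Treatment(reference='{reference}')) * k_c"
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=df, groups=df["participant_id"])
        result = model.fit(reml=True)
    re_var = float(np.asarray(result.cov_re).ravel()[0])
    resid_var = float(result.scale)
    singular = re_var < 1e-8 * max(resid_var, 1.0)
    return DurationAnalysis(
        params=result.fe_params,
        conf_int=result.conf_int().loc[result.fe_params.index],
        random_intercept_var=re_var,
        singular=singular,
        converged=bool(result.converged),
        reference=reference,
        summary=str(result.summary()),
    )


# ---------------------------------------------------------------------------
# simulated respondents

def simulate_responses(
    plan: DesignPlan,
    key: Mapping[Condition, Mapping[str, object]],
    seed: int = 0,
    p_correct: Optional[Mapping[str, float]] = None,
    duration_intercept: float = 120.0,
    duration_viz_effects: Optional[Mapping[str, float]] = None,
    duration_k_slope: float = 0.3,
    participant_sd: float = 20.0,
    residual_sd: float = 15.0,
) -> list[ResponseSheet]:
    """Generate synthetic response sheets for a design plan.

    Answers to each scored question are correct independently with
    probability ``p_correct[viz]`` (default 0.7 for every type); wrong
    multiple-choice answers get a sentinel string, wrong slider answers
    an offset outside the tolerance. Durations follow
    ``intercept + effect[viz] + slope * (k - mean k) + person + noise``
    with a normal person-level intercept — the generating model of the
    duration analysis. Attention checks always pass and total durations
    exceed the exclusion threshold, so every simulated sheet is
    scoreable.
    """
    rng = np.random.default_rng(seed)
    p_correct = dict(p_correct or {v: 0.7 for v in VIZ_LEVELS})
    duration_viz_effects = dict(duration_viz_effects or {v: 0.0 for v in VIZ_LEVELS})
    k_mean = float(np.mean(K_LEVELS))
    sheets = []
    for pid in range(plan.n_participants):
        person = rng.normal(0.0, participant_sd)
        conds = []
        for viz, k in plan.participant_conditions(pid):
            answers = {}
            for q in ALL_QUESTIONS:
                true = key[(viz, k)][q]
                correct = rng.random() < p_correct[viz]
                if q == SLIDER_QUESTION:
                    answers[q] = (
                        float(true)
                        if correct
                        else float(
                            np.clip(float(true) + 0.2, *SLIDER_RANGE)
                        )
                    )
                else:
                    answers[q] = true if correct else "__wrong__"
            duration = max(
                duration_intercept
                + duration_viz_effects[viz]
                + duration_k_slope * (k - k_mean)
                + person
                + rng.normal(0.0, residual_sd),
                1.0,
            )
            conds.append(
                ConditionResponse(viz=viz, k=k, answers=answers, duration_s=duration)
            )
        total = sum(c.duration_s for c in conds) + MIN_TOTAL_DURATION_S
        sheets.append(
            ResponseSheet(
                participant_id=f"P{pid:04d}",
                conditions=tuple(conds),
                attention_pass=True,
                total_duration_s=total,
            )
        )
    return sheets
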