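"""Behavioral variables and group-level inference.

Covers the self-report side of the analysis: per-statement agreement ratings
(1 = disagree .. 3 = agree, 22 statements), multi-item questionnaire scales
administered before (T1) and after (T2) the intervention, composite scoring
(reverse-scored items, positive/negative affect composites), agreement
trajectories over the three timeslots, split-plot (mixed) ANOVA, per-group
repeated-measures ANOVA, and Benjamini–Hochberg-corrected Pearson
brain–behavior correlations.

The ANOVA is implemented by explicit sums-of-squares partitioning so the full
decomposition — including both error strata — is available and its identity
SS_total = SS_group + SS_subj(group) + SS_time + SS_interaction + SS_error
can be verified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import Event, statement_sample_count

__all__ = [
    "SCALES",
    "EMOTION_ITEMS",
    "POSITIVE_EMOTIONS",
    "NEGATIVE_EMOTIONS",
    "BehaviorTable",
    "AnovaResult",
    "CorrelationReport",
    "composite_scores",
    "agreement_by_timeslot",
    "map_statements_to_slots",
    "mixed_anova",
    "rm_anova",
    "correlate_with_fdr",
    "correlation_table_text",
    "reverse_score",
]

logger = logging.getLogger(__name__)

GROUPS = ("paradoxical", "inconsistent", "control")

#: scale -> (n_items, low, high, reverse-scored item indices)
SCALES: dict[str, tuple[int, int, int, tuple[int, ...]]] = {
    "negativity": (7, 1, 7, (1, 4)),
    "threat": (4, 1, 7, ()),
    "feeling_thermometer": (1, 1, 10, ()),
    "dehumanization": (1, 1, 10, ()),
    "warmth": (4, 1, 5, ()),
    "competence": (4, 1, 5, ()),
    "measures_against": (3, 1, 7, ()),
}

EMOTION_ITEMS = (
    "empathy", "sympathy", "compassion", "anger", "hate", "fear", "shame", "guilt",
)
POSITIVE_EMOTIONS = ("empathy", "sympathy", "compassion")
NEGATIVE_EMOTIONS = ("anger", "hate", "fear", "shame", "guilt")
EMOTION_RANGE = (1, 7)

#: the T2−T1 measures entering the FDR family of the correlation analysis
DELTA_MEASURES = (
    "negativity", "threat", "feeling_thermometer", "dehumanization",
    "warmth", "competence", "measures_against", "positive_affect", "negative_affect",
)

N_STATEMENTS_DEFAULT = 22


def _item_columns(n_statements: int = N_STATEMENTS_DEFAULT) -> list[str]:
    cols = ["subject_id", "group"]
    cols += [f"agreement_s{i + 1}" for i in range(n_statements)]
    for t in ("t1", "t2"):
        for scale, (n_items, *_rest) in SCALES.items():
            if n_items == 1:
                cols.append(f"{scale}_{t}")
            else:
                cols += [f"{scale}{i + 1}_{t}" for i in range(n_items)]
        cols += [f"emotion_{name}_{t}" for name in EMOTION_ITEMS]
    return cols


@dataclass
class BehaviorTable:
    """Item-level behavioral data, one row per subject.

    Wraps a DataFrame with columns ``subject_id``, ``group``,
    ``agreement_s1..s22`` and item-level questionnaire columns such as
    ``negativity3_t1`` or ``emotion_anger_t2``. Values are validated against
    each scale's printed bounds.
    """

    df: pd.DataFrame
    n_statements: int = N_STATEMENTS_DEFAULT

    def __post_init__(self) -> None:
        missing = set(_item_columns(self.n_statements)) - set(self.df.columns)
        if missing:
            raise ValueError(f"behavior table missing columns: {sorted(missing)[:5]} ...")
        ag = self.agreement_matrix()
        vals = ag[~np.isnan(ag)]
        if vals.size and not np.isin(vals, (1, 2, 3)).all():
            raise ValueError("agreement ratings must be in {1, 2, 3}")
        for scale, (n_items, lo, hi, _rev) in SCALES.items():
            for col in [c for c in self.df.columns if c.startswith(scale)]:
                v = self.df[col].dropna()
                if len(v) and ((v < lo).any() or (v > hi).any()):
                    raise ValueError(f"{col}: values outside [{lo}, {hi}]")
        lo, hi = EMOTION_RANGE
        for col in [c for c in self.df.columns if c.startswith("emotion_")]:
            v = self.df[col].dropna()
            if len(v) and ((v < lo).any() or (v > hi).any()):
                raise ValueError(f"{col}: values outside [{lo}, {hi}]")

    def agreement_matrix(self) -> np.ndarray:
        cols = [f"agreement_s{i + 1}" for i in range(self.n_statements)]
        return self.df[cols].to_numpy(dtype=float)

    @property
    def groups(self) -> pd.Series:
        return self.df["group"]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BehaviorTable":
        df = pd.read_csv(path)
        n = sum(c.startswith("agreement_s") for c in df.columns)
        return cls(df, n_statements=n or N_STATEMENTS_DEFAULT)


def reverse_score(x, lo: int, hi: int):
    """Map a reverse-keyed item onto the positive direction: x → lo + hi − x."""
    return lo + hi - np.asarray(x, dtype=float)


def composite_scores(table: BehaviorTable) -> pd.DataFrame:
    """Per-subject scale scores at T1/T2 and their T2−T1 deltas.

    Multi-item scales are item means after reverse-scoring the reverse-keyed
    items; positive affect is the mean of empathy/sympathy/compassion and
    negative affect the mean of anger/hate/fear/shame/guilt. A subject with
    any missing item on a scale gets NaN for that scale (listwise within
    scale) and is logged.
    """
    out = table.df[["subject_id", "group"]].copy()
    for t in ("t1", "t2"):
        for scale, (n_items, lo, hi, rev) in SCALES.items():
            if n_items == 1:
                vals = table.df[f"{scale}_{t}"].astype(float)
            else:
                items = table.df[[f"{scale}{i + 1}_{t}" for i in range(n_items)]].astype(float)
                items = items.copy()
                for r in rev:
                    items.iloc[:, r] = reverse_score(items.iloc[:, r], lo, hi)
                vals = items.mean(axis=1, skipna=False)
            out[f"{scale}_{t}"] = vals
        for name, members in (("positive_affect", POSITIVE_EMOTIONS),
                              ("negative_affect", NEGATIVE_EMOTIONS)):
            items = table.df[[f"emotion_{m}_{t}" for m in members]].astype(float)
            out[f"{name}_{t}"] = items.mean(axis=1, skipna=False)
    for measure in DELTA_MEASURES:
        out[f"{measure}_delta"] = out[f"{measure}_t2"] - out[f"{measure}_t1"]
        n_miss = int(out[f"{measure}_delta"].isna().sum())
        if n_miss:
            logger.warning("composite_scores: %d subject(s) missing on %s", n_miss, measure)
    return out


def map_statements_to_slots(
    events: Sequence[Event], n_slots: int = 3
) -> np.ndarray:
    """Assign each statement to the timeslot containing its midpoint.

    Midpoints are measured on the pause-free sample grid (statement samples
    concatenated in order), and slot boundaries replicate the neural split:
    ``n_slots`` contiguous slots of ``T // n_slots`` samples, remainder at the
    end assigned to the last slot.
    """
    stmts = [ev for ev in events if ev.label == "statement"]
    if not stmts:
        raise ValueError("no statement events")
    T = statement_sample_count(events)
    L = T // n_slots
    slots = []
    pos = 0
    for ev in stmts:
        mid = pos + (ev.stop - ev.start) / 2.0
        slots.append(min(int(mid // L), n_slots - 1))
        pos += ev.stop - ev.start
    return np.asarray(slots, dtype=int)


def agreement_by_timeslot(
    table: BehaviorTable, statement_slot_map: np.ndarray, n_slots: int = 3
) -> pd.DataFrame:
    """Per-subject mean agreement per timeslot, plus the end − beginning diff."""
    slot_map = np.asarray(statement_slot_map, dtype=int)
    if slot_map.shape[0] != table.n_statements:
        raise ValueError("slot map length must equal the statement count")
    ag = table.agreement_matrix()
    out = table.df[["subject_id", "group"]].copy()
    for s in range(n_slots):
        out[f"agreement_slot{s}"] = ag[:, slot_map == s].mean(axis=1)
    out["agreement_diff"] = out[f"agreement_slot{n_slots - 1}"] - out["agreement_slot0"]
    return out


@dataclass
class AnovaResult:
    """One effect line of an ANOVA table."""

    effect: str
    F: float
    df: tuple[int, int]
    p: float
    ss: float
    ms: float

    def __str__(self) -> str:
        return (f"{self.effect}: F({self.df[0]}, {self.df[1]}) = {self.F:.3f}, "
                f"p = {self.p:.4g}")


def mixed_anova(values: np.ndarray, groups: Sequence) -> list[AnovaResult]:
    """Two-way mixed (split-plot) ANOVA: between-subject group, within-subject time.

    ``values`` is subjects × time; ``groups`` labels each row. Explicit
    sums-of-squares partition (cell means weighted by group size):

    * between-subject stratum: group (tested against subjects-within-groups),
    * within-subject stratum: time and group×time (tested against the
      subject×time residual).

    Returns effect lines for group, time, and group×time plus the two error
    strata (F = NaN for errors). No sphericity correction is applied.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 2:
        raise ValueError("values must be subjects × time")
    g = pd.Series(list(groups))
    if len(g) != Y.shape[0]:
        raise ValueError("groups length must match subject count")
    labels = list(pd.unique(g))
    sizes = {lab: int((g == lab).sum()) for lab in labels}
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if min(sizes.values()) < 2:
        raise ValueError("each group needs >= 2 subjects")
    if np.isnan(Y).any():
        keep = ~np.isnan(Y).any(axis=1)
        logger.warning("mixed_anova: dropping %d incomplete subject(s)", int((~keep).sum()))
        Y, g = Y[keep], g[keep].reset_index(drop=True)
        sizes = {lab: int((g == lab).sum()) for lab in labels}
    N, t = Y.shape
    n_g = np.array([sizes[lab] for lab in labels], dtype=float)
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    group_means = np.array([Y[(g == lab).to_numpy()].mean() for lab in labels])
    time_means = Y.mean(axis=0)
    cell_means = np.array([Y[(g == lab).to_numpy()].mean(axis=0) for lab in labels])

    ss_total = float(((Y - grand) ** 2).sum())
    ss_between_subj = float(t * ((subj_means - grand) ** 2).sum())
    ss_group = float(t * (n_g * (group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group
    ss_time = float(N * ((time_means - grand) ** 2).sum())
    ss_cells = float((n_g[:, None] * (cell_means - grand) ** 2).sum())
    ss_inter = ss_cells - ss_group - ss_time
    ss_error = ss_total - ss_between_subj - ss_time - ss_inter

    n_groups = len(labels)
    df_group = n_groups - 1
    df_subj = N - n_groups
    df_time = t - 1
    df_inter = df_group * df_time
    df_error = df_subj * df_time

    ms_group = ss_group / df_group
    ms_subj = ss_subj_within / df_subj
    ms_time = ss_time / df_time
    ms_inter = ss_inter / df_inter
    ms_error = ss_error / df_error

    def line(effect, ss, df_num, ms, df_den, ms_den):
        F = ms / ms_den
        p = float(stats.f.sf(F, df_num, df_den))
        return AnovaResult(effect, float(F), (df_num, df_den), p, float(ss), float(ms))

    results = [
        line("group", ss_group, df_group, ms_group, df_subj, ms_subj),
        line("time", ss_time, df_time, ms_time, df_error, ms_error),
        line("group x time", ss_inter, df_inter, ms_inter, df_error, ms_error),
        AnovaResult("subjects within groups (error)", float("nan"),
                    (df_subj, 0), float("nan"), float(ss_subj_within), float(ms_subj)),
        AnovaResult("time x subjects (error)", float("nan"),
                    (df_error, 0), float("nan"), float(ss_error), float(ms_error)),
    ]
    return results


def rm_anova(values: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA for the time effect within one group."""
    Y = np.asarray(values, dtype=float)
    if np.isnan(Y).any():
        Y = Y[~np.isnan(Y).any(axis=1)]
    n, t = Y.shape
    if n < 2 or t < 2:
        raise ValueError("need >= 2 subjects and >= 2 time points")
    grand = Y.mean()
    ss_time = float(n * ((Y.mean(axis=0) - grand) ** 2).sum())
    ss_subj = float(t * ((Y.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((Y - grand) ** 2).sum())
    ss_err = ss_total - ss_time - ss_subj
    df_time, df_err = t - 1, (n - 1) * (t - 1)
    F = (ss_time / df_time) / (ss_err / df_err)
    p = float(stats.f.sf(F, df_time, df_err))
    return AnovaResult("time", float(F), (df_time, df_err), p, ss_time, ss_time / df_time)


@dataclass
class CorrelationReport:
    """Pearson correlation of one measure with the brain variable, FDR-adjusted."""

    measure: str
    R: float
    p_raw: float
    p_fdr: float
    n: int


def correlate_with_fdr(
    x: np.ndarray,
    Y: pd.DataFrame,
    family_size: int | None = None,
) -> list[CorrelationReport]:
    """Pearson correlations of ``x`` with each column of ``Y``, BH-corrected.

    Pairwise-complete: rows where either variable is missing are dropped per
    measure. Zero-variance pairs yield an undefined correlation, reported as
    NaN and excluded from the FDR family. ``family_size`` may enlarge the BH
    family beyond the tested measures (p·m/rank is then computed with m =
    family_size); by default it is the number of valid measures.
    """
    x = np.asarray(x, dtype=float)
    reports: list[CorrelationReport] = []
    for col in Y.columns:
        y = Y[col].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        if n < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            logger.warning("correlate_with_fdr: %s undefined (n=%d or zero variance)", col, n)
            reports.append(CorrelationReport(col, float("nan"), float("nan"), float("nan"), n))
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        reports.append(CorrelationReport(col, float(r), float(p), float("nan"), n))
    valid = [rep for rep in reports if not np.isnan(rep.p_raw)]
    if valid:
        pvals = np.array([rep.p_raw for rep in valid])
        m = family_size if family_size is not None else len(valid)
        if m < len(valid):
            raise ValueError("family_size smaller than number of tested measures")
        # BH step-up with family size m: adjust in rank order then enforce monotonicity
        order = np.argsort(pvals)
        adj = pvals[order] * m / (np.arange(len(valid)) + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        if m == len(valid):
            # canonical case: delegate to statsmodels (identical by construction)
            adj_sm = multipletests(pvals, method="fdr_bh")[1]
            adj_check = np.empty_like(adj)
            adj_check[order] = adj
            assert np.allclose(adj_sm, adj_check)
            for rep, a in zip(valid, adj_sm):
                rep.p_fdr = float(a)
        else:
            for idx, a in zip(order, adj):
                valid[idx].p_fdr = float(a)
    return reports


def correlation_table_text(reports: list[CorrelationReport], x_name: str = "ISC") -> str:
    """Plain-text correlation table, R above p per cell."""
    w = max(len(r.measure) for r in reports) + 2
    lines = [f"Correlations with {x_name} (Pearson R, FDR-adjusted p)"]
    for rep in reports:
        star = "*" if rep.p_fdr < 0.05 else " "
        lines.append(f"  {rep.measure:<{w}} R = {rep.R:7.3f}{star}")
        lines.append(f"  {'':<{w}} p_fdr = {rep.p_fdr:7.3f}   (raw p = {rep.p_raw:.3f}, n = {rep.n})")
    return "\n".join(lines)
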