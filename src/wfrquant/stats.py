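"""Inferential layer: mixed-design RM-ANOVA, Bonferroni contrasts, t-tests.

The imaging metrics form a balanced two-way mixed design: one
between-subjects factor (experimental group, 1-4) and one within-subjects
factor (time, baseline vs 24 h).  With only two within-subject levels
sphericity holds trivially and no correction is applied.  Sums of squares
are computed from cell means; the group effect is tested against
subjects-within-groups, time and the group x time interaction against the
within-subjects residual.  Degenerate inputs (zero variance) resolve to
F = 0, p = 1 rather than 0/0.

Infarct volumes are compared with Welch (unequal-variance) two-sample
t-tests; baseline equivalence across groups uses a one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

_TINY = 1e-12


@dataclass
class AnovaEffect:
    name: str
    ss: float
    df: int
    ms: float
    f: float
    p: float


@dataclass
class MixedAnovaResult:
    group: AnovaEffect
    time: AnovaEffect
    interaction: AnovaEffect
    ss_subjects_within: float
    ss_error_within: float
    ss_total: float

    def as_frame(self) -> pd.DataFrame:
        rows = [
            (e.name, e.ss, e.df, e.ms, e.f, e.p)
            for e in (self.group, self.time, self.interaction)
        ]
        return pd.DataFrame(rows, columns=["effect", "SS", "df", "MS", "F", "p"])


def _f_test(ss_eff: float, df_eff: int, ss_err: float, df_err: int, name: str) -> AnovaEffect:
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    scale = max(abs(ss_eff), abs(ss_err), 1.0)
    if ss_eff <= _TINY * scale or ss_eff <= 0:
        return AnovaEffect(name, ss_eff, df_eff, ms_eff, 0.0, 1.0)
    if not np.isfinite(ms_err) or ms_err <= _TINY * scale / max(df_err, 1):
        return AnovaEffect(name, ss_eff, df_eff, ms_eff, np.inf, 0.0)
    f = ms_eff / ms_err
    p = float(sps.f.sf(f, df_eff, df_err))
    return AnovaEffect(name, ss_eff, df_eff, ms_eff, f, p)


def _check_table(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    required = {"subject_id", "group", "session", value_col}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns {sorted(missing)}")
    t = table[["subject_id", "group", "session", value_col]].copy()
    sessions = sorted(t.session.unique())
    absent = [
        (sid, sess)
        for sid in t.subject_id.unique()
        for sess in sessions
        if not (((t.subject_id == sid) & (t.session == sess)).any())
    ]
    if absent:
        raise ValueError(f"missing (subject, session) cells: {absent}")
    counts = t.groupby(["subject_id", "session"]).size()
    if (counts != 1).any():
        raise ValueError("exactly one value per (subject, session) required")
    sizes = t.groupby("group").subject_id.nunique()
    if sizes.nunique() != 1:
        raise ValueError("design must be balanced across groups")
    return t


def rm_anova(table: pd.DataFrame, value_col: str = "value") -> MixedAnovaResult:
    """Two-way mixed ANOVA (between: group; within: session/time).

    ``table`` is tidy with columns subject_id, group, session, ``value_col``,
    one row per (subject, session), balanced groups, two sessions.
    """
    t = _check_table(table, value_col)
    sessions = sorted(t.session.unique())
    if len(sessions) != 2:
        raise ValueError("exactly two within-subject sessions required")
    wide = t.pivot_table(
        index=["group", "subject_id"], columns="session", values=value_col
    )
    y = wide.to_numpy()  # (subjects, 2) grouped by group
    groups = wide.index.get_level_values("group").to_numpy()
    uniq = np.unique(groups)
    a, n_time = len(uniq), 2
    n = int((groups == uniq[0]).sum())

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([y[groups == g].mean() for g in uniq])
    time_means = y.mean(axis=0)
    cell_means = np.array([y[groups == g].mean(axis=0) for g in uniq])

    ss_group = n_time * n * float(((group_means - grand) ** 2).sum())
    ss_subj = n_time * float(
        ((subj_means - np.repeat(group_means, n)) ** 2).sum()
    )
    ss_time = a * n * float(((time_means - grand) ** 2).sum())
    ss_inter = n * float(
        (
            (cell_means - group_means[:, None] - time_means[None, :] + grand) ** 2
        ).sum()
    )
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_group - ss_subj - ss_time - ss_inter
    ss_err = max(ss_err, 0.0)

    df_group, df_subj = a - 1, a * (n - 1)
    df_time, df_inter, df_err = n_time - 1, (a - 1) * (n_time - 1), a * (n - 1)
    return MixedAnovaResult(
        group=_f_test(ss_group, df_group, ss_subj, df_subj, "group"),
        time=_f_test(ss_time, df_time, ss_err, df_err, "time"),
        interaction=_f_test(ss_inter, df_inter, ss_err, df_err, "group x time"),
        ss_subjects_within=ss_subj,
        ss_error_within=ss_err,
        ss_total=ss_total,
    )


@dataclass
class Contrast:
    group: int
    t: float
    p_raw: float
    p_adjusted: float
    significant: bool
    mean_baseline: float
    mean_followup: float


def posthoc_contrasts(
    table: pd.DataFrame, value_col: str = "value", alpha: float = 0.05
) -> list[Contrast]:
    """Per-group paired baseline-vs-follow-up contrasts, Bonferroni-adjusted.

    Adjusted p = min(1, raw p x number of contrasts).
    """
    t = _check_table(table, value_col)
    sessions = sorted(t.session.unique())
    base_name = "baseline" if "baseline" in sessions else sessions[0]
    fup_name = [s for s in sessions if s != base_name][-1]
    groups = sorted(t.group.unique())
    m = len(groups)
    out = []
    for g in groups:
        sub = t[t.group == g].pivot_table(
            index="subject_id", columns="session", values=value_col
        )
        b, f = sub[base_name].to_numpy(), sub[fup_name].to_numpy()
        diff = f - b
        if np.allclose(diff, diff[0]) and np.isclose(diff[0], 0.0):
            tval, praw = 0.0, 1.0
        elif np.allclose(diff, diff[0]):
            tval, praw = np.inf * np.sign(diff[0]), 0.0
        else:
            tval, praw = sps.ttest_rel(f, b)
        padj = min(1.0, float(praw) * m)
        out.append(
            Contrast(
                group=int(g),
                t=float(tval),
                p_raw=float(praw),
                p_adjusted=padj,
                significant=padj < alpha,
                mean_baseline=float(b.mean()),
                mean_followup=float(f.mean()),
            )
        )
    return out


@dataclass
class TTestResult:
    group_a: int
    group_b: int
    t: float
    p: float
    mean_a: float
    mean_b: float


def volume_ttests(volumes_by_group: dict[int, np.ndarray]) -> list[TTestResult]:
    """Pairwise Welch two-sample t-tests on infarct volumes."""
    for g, v in volumes_by_group.items():
        if len(np.atleast_1d(v)) < 2:
            raise ValueError(f"group {g} has fewer than 2 values")
    groups = sorted(volumes_by_group)
    out = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            va = np.asarray(volumes_by_group[ga], dtype=float)
            vb = np.asarray(volumes_by_group[gb], dtype=float)
            if va.std() == 0 and vb.std() == 0:
                if va.mean() == vb.mean():
                    t, p = 0.0, 1.0
                else:
                    t = np.inf * np.sign(va.mean() - vb.mean())
                    p = 0.0
            else:
                t, p = sps.ttest_ind(va, vb, equal_var=False)
            out.append(
                TTestResult(
                    int(ga), int(gb), float(t), float(p), float(va.mean()), float(vb.mean())
                )
            )
    return out


@dataclass
class OneWayResult:
    f: float
    p: float
    group_means: dict[int, float]


def baseline_equivalence(
    table: pd.DataFrame, value_col: str = "value", session: str = "baseline"
) -> OneWayResult:
    """One-way ANOVA of the baseline values across the four groups."""
    t = table[table.session == session]
    groups = sorted(table.group.unique())
    samples = []
    for g in groups:
        v = t[t.group == g][value_col].to_numpy(dtype=float)
        if v.size == 0:
            raise ValueError(f"group {g} has no {session} rows")
        samples.append(v)
    pooled = np.concatenate(samples)
    if np.allclose(pooled, pooled[0]):
        f, p = 0.0, 1.0
    else:
        f, p = sps.f_oneway(*samples)
    return OneWayResult(
        f=float(f),
        p=float(p),
        group_means={int(g): float(s.mean()) for g, s in zip(groups, samples)},
    )


@dataclass
class StatsReport:
    metric: str
    anova: MixedAnovaResult
    contrasts: list[Contrast]
    baseline: OneWayResult
    eliminated_cells: list[tuple[str, str]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "anova": {
                e.name: {"F": e.f, "p": e.p, "df": e.df}
                for e in (self.anova.group, self.anova.time, self.anova.interaction)
            },
            "contrasts": [
                {
                    "group": c.group,
                    "t": c.t,
                    "p_adjusted": c.p_adjusted,
                    "significant": c.significant,
                }
                for c in self.contrasts
            ],
            "baseline_anova": {"F": self.baseline.f, "p": self.baseline.p},
            "eliminated_cells": self.eliminated_cells,
        }


def imaging_stats_report(
    measurements: pd.DataFrame,
    metric: str,
    protocol: str = "sparse",
    phase: str = "initial_dip",
    alpha: float = 0.05,
) -> StatsReport:
    """RM-ANOVA + contrasts + baseline equivalence for one imaging metric.

    ``measurements`` is the tidy table produced by the pipeline (columns
    subject_id, group, session, protocol, phase, metric, value).  Cells where
    the WFR was eliminated enter as 0 (they are flagged in the report).
    """
    sel = measurements[
        (measurements.protocol == protocol)
        & (measurements.phase == phase)
        & (measurements.metric == metric)
    ]
    if sel.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    eliminated = []
    if "eliminated" in sel.columns:
        eliminated = [
            (r.subject_id, r.session)
            for r in sel[sel.eliminated.astype(bool)].itertuples()
        ]
    return StatsReport(
        metric=metric,
        anova=rm_anova(sel),
        contrasts=posthoc_contrasts(sel, alpha=alpha),
        baseline=baseline_equivalence(sel),
        eliminated_cells=eliminated,
    )
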