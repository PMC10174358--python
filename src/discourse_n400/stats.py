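"""Within-subject inferential statistics for simulated N400 tables.

Subjects here are reservoir instances (seeds): every subject contributes one
value to every cell of a fully crossed two-factor design (cell values are
per-subject means over items, computed upstream).  The repeated-measures
ANOVA partitions the sums of squares as

    subject, A, A x subject, B, B x subject, AB, AB x subject

and tests each effect against its own effect-by-subject error term, with no
sphericity correction — df for a 2x2 design with n subjects are (1, n-1) per
effect; for 2x3, the three-level factor and the interaction carry
(2, 2(n-1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TTestResult", "RMAnovaResult", "paired_t", "two_sample_t", "rm_anova", "posthoc_pairwise"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float = float("nan")
    degenerate: bool = False

    def __str__(self):
        if self.degenerate:
            return "t-test degenerate (all differences zero)"
        return f"t({self.df:g}) = {self.t:.3f}, p = {self.p:.3g}"


def paired_t(x, y) -> TTestResult:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1.

    All-zero differences are flagged degenerate (t = 0, p = 1) rather than
    raising, so pipelines over constructed fixtures never crash.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_t requires two equal-length 1-d samples")
    n = x.size
    if n < 2:
        raise ValueError("paired_t requires n >= 2")
    d = x - y
    scale = max(1.0, float(np.max(np.abs(x))), float(np.max(np.abs(y))))
    if np.all(np.abs(d) <= 1e-12 * scale):  # numerically zero differences
        return TTestResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0, degenerate=True)
    res = sps.ttest_rel(x, y)
    return TTestResult(t=float(res.statistic), df=float(n - 1), p=float(res.pvalue), mean_diff=float(d.mean()))


def two_sample_t(x, y) -> TTestResult:
    """Two-sided independent-samples t-test (equal variances assumed)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 2:
        raise ValueError("two_sample_t requires n >= 2 per group")
    if np.ptp(np.concatenate([x, y])) == 0:
        return TTestResult(t=0.0, df=x.size + y.size - 2, p=1.0, mean_diff=0.0, degenerate=True)
    res = sps.ttest_ind(x, y)
    return TTestResult(
        t=float(res.statistic),
        df=float(x.size + y.size - 2),
        p=float(res.pvalue),
        mean_diff=float(x.mean() - y.mean()),
    )


@dataclass
class EffectRecord:
    effect: str
    ss: float
    df: int
    ms: float
    F: float
    p: float
    error_ss: float
    error_df: int
    degenerate: bool = False


@dataclass
class RMAnovaResult:
    """Two-factor within-subject ANOVA: per-effect F tests and cell means."""

    effects: dict = field(default_factory=dict)  # name -> EffectRecord
    cell_means: pd.DataFrame | None = None
    n_subjects: int = 0
    ss_total: float = 0.0
    ss_partition: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "effect": rec.effect,
                "F": rec.F,
                "df1": rec.df,
                "df2": rec.error_df,
                "p": rec.p,
            }
            for rec in self.effects.values()
        ]
        return pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"])

    def summary(self) -> str:
        lines = [f"Repeated-measures ANOVA ({self.n_subjects} subjects)", "-" * 48]
        for rec in self.effects.values():
            note = "  [degenerate: zero error variance]" if rec.degenerate else ""
            lines.append(f"{rec.effect:<14} F({rec.df}, {rec.error_df}) = {rec.F:10.4f}   p = {rec.p:.3g}{note}")
        return "\n".join(lines)


def _check_design(data, subject, a, b, value):
    for col in (subject, a, b, value):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    counts = data.groupby([subject, a, b], observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index[0]
        raise ValueError(
            f"design must have exactly one value per subject x cell; offending subject/cell: {bad}"
        )
    subjects = data[subject].unique()
    a_levels = list(pd.unique(data[a]))
    b_levels = list(pd.unique(data[b]))
    expected = len(subjects) * len(a_levels) * len(b_levels)
    if len(data) != expected:
        missing = expected - len(data)
        raise ValueError(f"design is not fully crossed: {missing} subject x cell values missing")
    return subjects, a_levels, b_levels


def rm_anova(
    data: pd.DataFrame,
    value: str = "value",
    subject: str = "subject_id",
    a: str = "A",
    b: str = "B",
) -> RMAnovaResult:
    """Two-factor fully-within-subject ANOVA from a long-format table.

    Each effect's F statistic uses its own effect-by-subject interaction as
    the error term.  A zero error variance (possible on noise-free
    constructed data) yields F = inf with a degenerate flag instead of an
    exception.
    """
    subjects, a_levels, b_levels = _check_design(data, subject, a, b, value)
    n = len(subjects)
    p_, q_ = len(a_levels), len(b_levels)
    if n < 2:
        raise ValueError("rm_anova requires at least 2 subjects")

    # y[s, i, j]: subject s, A level i, B level j
    pivot = data.pivot_table(index=subject, columns=[a, b], values=value, observed=True)
    y = np.empty((n, p_, q_))
    for i, al in enumerate(a_levels):
        for j, bl in enumerate(b_levels):
            y[:, i, j] = pivot[(al, bl)].loc[subjects].to_numpy()

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))          # subject means
    m_a = y.mean(axis=(0, 2))          # A-level means
    m_b = y.mean(axis=(0, 1))          # B-level means
    m_sa = y.mean(axis=2)              # (subject, A)
    m_sb = y.mean(axis=1)              # (subject, B)
    m_ab = y.mean(axis=0)              # (A, B)

    ss_subject = p_ * q_ * np.sum((m_s - grand) ** 2)
    ss_a = n * q_ * np.sum((m_a - grand) ** 2)
    ss_b = n * p_ * np.sum((m_b - grand) ** 2)
    ss_as = q_ * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = p_ * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_abs = np.sum(
        (
            y
            - m_sa[:, :, None]
            - m_sb[:, None, :]
            - m_ab[None, :, :]
            + m_s[:, None, None]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - grand
        )
        ** 2
    )
    ss_total = np.sum((y - grand) ** 2)

    def make_effect(name, ss, df, err_ss, err_df):
        ms = ss / df
        err_ms = err_ss / err_df
        if err_ms == 0.0:
            if ss == 0.0:
                return EffectRecord(name, ss, df, ms, 0.0, 1.0, err_ss, err_df, degenerate=True)
            return EffectRecord(name, ss, df, ms, float("inf"), 0.0, err_ss, err_df, degenerate=True)
        F = ms / err_ms
        p = float(sps.f.sf(F, df, err_df))
        return EffectRecord(name, ss, df, ms, F, p, err_ss, err_df)

    effects = {
        a: make_effect(a, ss_a, p_ - 1, ss_as, (p_ - 1) * (n - 1)),
        b: make_effect(b, ss_b, q_ - 1, ss_bs, (q_ - 1) * (n - 1)),
        f"{a}:{b}": make_effect(f"{a}:{b}", ss_ab, (p_ - 1) * (q_ - 1), ss_abs, (p_ - 1) * (q_ - 1) * (n - 1)),
    }
    cell_means = (
        data.groupby([a, b], observed=True)[value].mean().rename("mean").reset_index()
    )
    return RMAnovaResult(
        effects=effects,
        cell_means=cell_means,
        n_subjects=n,
        ss_total=float(ss_total),
        ss_partition={
            "subject": float(ss_subject),
            a: float(ss_a),
            f"{a}:subject": float(ss_as),
            b: float(ss_b),
            f"{b}:subject": float(ss_bs),
            f"{a}:{b}": float(ss_ab),
            f"{a}:{b}:subject": float(ss_abs),
        },
    )


def posthoc_pairwise(
    data: pd.DataFrame,
    within: str,
    value: str = "value",
    subject: str = "subject_id",
    conditioning: str | None = None,
) -> pd.DataFrame:
    """Paired t-tests between every pair of levels of ``within``.

    When ``conditioning`` names a second factor, the contrasts are run
    separately at each of its levels.  Returns a frame with unadjusted p
    values plus a Bonferroni-adjusted column (family = all rows returned).
    """
    rows = []
    cond_levels = [None] if conditioning is None else list(pd.unique(data[conditioning]))
    for cl in cond_levels:
        sub = data if cl is None else data[data[conditioning] == cl]
        levels = list(pd.unique(sub[within]))
        wide = sub.pivot_table(index=subject, columns=within, values=value, observed=True)
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                l1, l2 = levels[i], levels[j]
                res = paired_t(wide[l1].to_numpy(), wide[l2].to_numpy())
                rows.append(
                    {
                        "conditioning": cl if cl is not None else "",
                        "level_1": l1,
                        "level_2": l2,
                        "mean_1": float(wide[l1].mean()),
                        "mean_2": float(wide[l2].mean()),
                        "t": res.t,
                        "df": res.df,
                        "p": res.p,
                        "degenerate": res.degenerate,
                    }
                )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out
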