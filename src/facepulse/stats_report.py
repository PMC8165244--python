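"""Inferential statistics on classifier outputs and questionnaire scores.

Pooled-variance two-sample t tests on questionnaire summaries, a Pearson
chi-squared (no continuity correction) on 2x2 classification counts, the
Mann-Whitney U comparison of per-participant ASD probabilities, Spearman
rank correlations with Bonferroni correction across the seven questionnaire
scales, a one-sample t test of repeated-LOOCV accuracies against chance,
and plain-text report assembly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as ss

__all__ = [
    "TTestResult",
    "Chi2Result",
    "pooled_t_from_summary",
    "pooled_t",
    "chi2_2x2",
    "mann_whitney",
    "spearman_with_bonferroni",
    "one_sample_t_vs_chance",
    "build_report",
]

from dataclasses import dataclass

#: The seven questionnaire scales (IRI subscales + TAS-20 factors) forming
#: one Bonferroni family per cohort subset.
QUESTIONNAIRE_SCALES = (
    "perspective_taking",
    "empathic_concern",
    "fantasy",
    "personal_distress",
    "difficulty_identifying_feelings",
    "difficulty_describing_feelings",
    "externally_oriented_thinking",
)
BONFERRONI_FAMILY = len(QUESTIONNAIRE_SCALES)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float


def pooled_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> TTestResult:
    """Pooled-variance (Student) two-sample t test from summary statistics.

    Two-tailed p with df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if s1 == 0 and s2 == 0:
        raise ZeroDivisionError("zero pooled variance")
    t, p = ss.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return TTestResult(t=float(t), df=n1 + n2 - 2, p=float(p))


def pooled_t(x, y) -> TTestResult:
    """Pooled-variance two-sample t test from raw samples."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    t, p = ss.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(t), df=x.size + y.size - 2, p=float(p))


def chi2_2x2(a: int, b: int, c: int, d: int) -> Chi2Result:
    """Pearson chi-squared on a 2x2 table, no continuity correction.

    ``chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` with df = 1.
    """
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ZeroDivisionError("a table margin is zero")
    n = counts.sum()
    chi2 = n * (a * d - b * c) ** 2 / np.prod(margins, dtype=float)
    p = float(ss.chi2.sf(chi2, df=1))
    return Chi2Result(chi2=float(chi2), df=1, p=p)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U for the first sample, two-tailed.

    Exact null distribution when both samples have n <= 8 and no ties;
    midrank tie handling with the tie-corrected normal approximation
    otherwise.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = ss.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_with_bonferroni(
    probabilities: pd.Series, questionnaires: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rho between mean ASD probability and each questionnaire
    scale, per cohort subset (all / ASD / TD), Bonferroni-corrected within
    each subset's family of seven scales.

    ``questionnaires`` is long-form: ``participant, group, scale, score``;
    participants with a missing scale are dropped pairwise.  Subsets with
    fewer than 3 complete pairs are flagged not-computed (NaN rho).
    """
    required = {"participant", "group", "scale", "score"}
    if not required.issubset(questionnaires.columns):
        raise ValueError(f"questionnaire table needs columns {sorted(required)}")
    rows = []
    groups = {"all": None, "ASD": "ASD", "TD": "TD"}
    for subset, group in groups.items():
        q = questionnaires if group is None else questionnaires[
            questionnaires["group"] == group
        ]
        for scale in QUESTIONNAIRE_SCALES:
            qs = q[q["scale"] == scale].dropna(subset=["score"])
            paired = qs[qs["participant"].isin(probabilities.index)]
            x = probabilities.loc[paired["participant"]].to_numpy()
            y = paired["score"].to_numpy(dtype=float)
            if x.size < 3:
                rows.append(
                    {
                        "subset": subset,
                        "scale": scale,
                        "n": int(x.size),
                        "rho": np.nan,
                        "p": np.nan,
                        "p_bonferroni": np.nan,
                        "significant": False,
                    }
                )
                continue
            rho, p = ss.spearmanr(x, y)
            p_adj = min(1.0, p * BONFERRONI_FAMILY)
            rows.append(
                {
                    "subset": subset,
                    "scale": scale,
                    "n": int(x.size),
                    "rho": float(rho),
                    "p": float(p),
                    "p_bonferroni": p_adj,
                    "significant": bool(p_adj < 0.05),
                }
            )
    return pd.DataFrame(rows)


def one_sample_t_vs_chance(accuracies, mu0: float = 0.5) -> TTestResult:
    """Two-tailed one-sample t test of repeated-LOOCV accuracies against
    chance level."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least 2 repetitions")
    if np.std(acc, ddof=1) == 0:
        if np.isclose(acc.mean(), mu0):
            return TTestResult(t=0.0, df=acc.size - 1, p=1.0)
        raise ZeroDivisionError("zero variance across repetitions")
    t, p = ss.ttest_1samp(acc, popmean=mu0)
    return TTestResult(t=float(t), df=acc.size - 1, p=float(p))


# ---------------------------------------------------------------------------
# Report assembly


def _fmt_df(df: pd.DataFrame) -> str:
    return df.to_string(float_format=lambda v: f"{v:.4f}")


def build_report(artifacts: dict, out_dir=None) -> str:
    """Assemble a plain-text report from whatever artifacts are present.

    Recognized keys: ``group_metrics`` (DataFrame), ``threshold_counts``
    (MetricCounts), ``chi2`` (Chi2Result), ``mann_whitney`` (tuple),
    ``accuracy_t`` (TTestResult), ``confusion`` (dict group -> DataFrame),
    ``cosine`` (dict group -> DataFrame), ``correlations`` (DataFrame).
    Missing sections are marked absent.  When ``out_dir`` is given, each
    tabular artifact is also written there as CSV.
    """
    from pathlib import Path

    lines = ["facepulse analysis report", "=" * 26, ""]
    csvs = {}

    def section(title: str, key: str, render) -> None:
        lines.append(title)
        lines.append("-" * len(title))
        if key in artifacts and artifacts[key] is not None:
            lines.append(render(artifacts[key]))
        else:
            lines.append("[section absent: no input]")
        lines.append("")

    def render_metrics(df):
        csvs["group_metrics"] = df
        return _fmt_df(df)

    section("Group classification metrics", "group_metrics", render_metrics)
    section(
        "Threshold (0.5) classification counts",
        "threshold_counts",
        lambda c: f"TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn} (N={c.n})",
    )
    section(
        "Chi-squared on classified proportions",
        "chi2",
        lambda r: f"chi2({r.df}) = {r.chi2:.2f}, p = {r.p:.3f}",
    )
    section(
        "Mann-Whitney U (ASD vs TD probabilities)",
        "mann_whitney",
        lambda uw: f"U = {uw[0]:.1f}, p = {uw[1]:.3f}",
    )
    section(
        "Accuracy vs chance",
        "accuracy_t",
        lambda r: f"t({r.df}) = {r.t:.2f}, p = {r.p:.3g}",
    )

    for group in ("TD", "ASD"):
        section(
            f"Emotion confusion matrix ({group})",
            "confusion",
            lambda d, g=group: _fmt_df(d[g]) if g in d else "[group absent]",
        )
        section(
            f"Emotion cosine similarity ({group})",
            "cosine",
            lambda d, g=group: _fmt_df(d[g]) if g in d else "[group absent]",
        )

    def render_corr(df):
        csvs["correlations"] = df
        return _fmt_df(df)

    section("Spearman correlations (Bonferroni-corrected)", "correlations", render_corr)

    report = "\n".join(lines)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.txt").write_text(report)
        for name, df in csvs.items():
            df.to_csv(out_dir / f"{name}.csv")
        if "confusion" in artifacts and artifacts["confusion"]:
            for g, df in artifacts["confusion"].items():
                df.to_csv(out_dir / f"confusion_{g}.csv")
        if "cosine" in artifacts and artifacts["cosine"]:
            for g, df in artifacts["cosine"].items():
                df.to_csv(out_dir / f"cosine_{g}.csv")
    return report
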