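"""Allele classification and cohort-level statistics for HTT CAG repeat data.

The per-individual statistic throughout is the *sum* of the two CAG allele
sizes: in a Lynch-syndrome cohort it is unknown which HTT allele cosegregates
with the mismatch-repair variant, so single-allele comparisons are not
meaningful and the biallelic sum is used instead.

Allele classes follow the standard HD diagnostic bands:

========================  ===============
class                     CAG repeats
========================  ===============
normal                    <= 26
intermediate              27 - 35
incomplete_penetrance     36 - 39
full_penetrance           >= 40
========================  ===============

Group comparisons use the pooled-variance (Student) two-sample t-test with a
Bonferroni-adjusted significance *threshold*: raw p-values are reported
unadjusted and compared against alpha / m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

NORMAL_MAX = 26
INTERMEDIATE_MIN = 27
INTERMEDIATE_MAX = 35
INCOMPLETE_MIN = 36
INCOMPLETE_MAX = 39
FULL_MIN = 40

ALLELE_CLASSES = (
    "normal",
    "intermediate",
    "incomplete_penetrance",
    "full_penetrance",
)


def classify_allele(cag: int) -> str:
    """Return the diagnostic class of a CAG allele size.

    Parameters
    ----------
    cag
        Integer CAG repeat count, must be >= 1.
    """
    cag = int(cag)
    if cag < 1:
        raise ValueError(f"CAG repeat count must be >= 1, got {cag}")
    if cag <= NORMAL_MAX:
        return "normal"
    if cag <= INTERMEDIATE_MAX:
        return "intermediate"
    if cag <= INCOMPLETE_MAX:
        return "incomplete_penetrance"
    return "full_penetrance"


def is_intermediate(cag) -> bool | np.ndarray:
    """Vectorized test for the intermediate band (27-35 repeats)."""
    arr = np.asarray(cag)
    out = (arr >= INTERMEDIATE_MIN) & (arr <= INTERMEDIATE_MAX)
    return bool(out) if out.ndim == 0 else out


def sum_of_repeats(genotype) -> int:
    """Biallelic sum of CAG repeats for one individual.

    Accepts any object with integer ``allele_a`` and ``allele_b`` attributes
    (a :class:`~httcag.synthetic_cohort.Genotype`, a called genotype, or a
    DataFrame row).
    """
    return int(genotype.allele_a) + int(genotype.allele_b)


@dataclass(frozen=True)
class GroupSummary:
    """n / mean / SD of the sum-of-repeats statistic for one group.

    ``sd`` is the sample standard deviation (n-1 denominator).
    """

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def summarize_group(values: Sequence[float], label: str) -> GroupSummary:
    """Arithmetic mean and sample SD of per-individual sums."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(
            f"group {label!r} needs n >= 2 for a sample SD, got n={arr.size}"
        )
    return GroupSummary(
        label=label, n=int(arr.size), mean=float(arr.mean()), sd=float(arr.std(ddof=1))
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


@dataclass(frozen=True)
class TTestResult:
    """Pooled two-sample t-test with 95% CI of the mean difference."""

    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    alpha_adjusted: float
    significant: bool
    flags: tuple[str, ...] = ()


def pooled_t_test(
    a: GroupSummary,
    b: GroupSummary,
    alpha: float = 0.05,
    m_comparisons: int = 1,
) -> TTestResult:
    """Student's pooled-variance t-test of group ``a`` vs group ``b``.

    The raw two-sided p-value is compared against the Bonferroni-adjusted
    threshold ``alpha / m_comparisons`` (threshold adjustment, not p-value
    inflation). The confidence interval is for ``a.mean - b.mean`` at 95%.
    Swapping the groups negates ``t`` and the CI; ``p`` is unchanged.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    df = a.n + b.n - 2
    diff = a.mean - b.mean
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    alpha_adj = bonferroni_threshold(alpha, m_comparisons)
    flags: tuple[str, ...] = ()
    if sp2 == 0.0:
        if diff == 0.0:
            t, p, ci = 0.0, 1.0, (0.0, 0.0)
            flags = ("zero-pooled-variance",)
        else:
            t = math.inf if diff > 0 else -math.inf
            p, ci = 0.0, (diff, diff)
            flags = ("degenerate-zero-variance-unequal-means",)
    else:
        t, p = sps.ttest_ind_from_stats(
            a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
        )
        t, p = float(t), float(p)
        se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        tcrit = float(sps.t.ppf(0.975, df))
        ci = (diff - tcrit * se, diff + tcrit * se)
    return TTestResult(
        t=t,
        df=df,
        p=p,
        ci_low=ci[0],
        ci_high=ci[1],
        alpha_adjusted=alpha_adj,
        significant=p < alpha_adj,
        flags=flags,
    )


def _carrier_mask(cohort: pd.DataFrame) -> pd.Series:
    return is_intermediate(cohort["allele_a"]) | is_intermediate(cohort["allele_b"])


def intermediate_carrier_tally(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-group count and percentage of intermediate-allele carriers.

    A carrier is an individual with at least one allele of 27-35 repeats.
    Percentages are rounded to one decimal. Expects columns
    ``group``, ``allele_a``, ``allele_b``; group order of first appearance
    is preserved.
    """
    carrier = _carrier_mask(cohort)
    rows = []
    for label in cohort["group"].unique():
        in_group = cohort["group"] == label
        n = int(in_group.sum())
        carriers = int((carrier & in_group).sum())
        rows.append(
            {
                "group": label,
                "carriers": carriers,
                "n": n,
                "percent": round(100.0 * carriers / n, 1),
            }
        )
    return pd.DataFrame(rows)


def exclude_intermediate_carriers(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop every individual carrying any intermediate allele ("without IA")."""
    return cohort.loc[~_carrier_mask(cohort)].reset_index(drop=True)


def table_one(
    cohort: pd.DataFrame,
    ei_by_sample: pd.Series | None = None,
    include_without_ia: bool = True,
) -> pd.DataFrame:
    """Cohort characteristics table: per group n, sum-of-repeats mean +- SD,
    intermediate-carrier tally and (optionally) mean somatic expansion index.

    When ``include_without_ia`` is true each group is followed by a
    sensitivity row recomputed after removal of intermediate-allele carriers.
    """
    sums = cohort["allele_a"] + cohort["allele_b"]
    tally = intermediate_carrier_tally(cohort).set_index("group")
    without = exclude_intermediate_carriers(cohort)
    rows = []
    for label in cohort["group"].unique():
        mask = cohort["group"] == label
        summ = summarize_group(sums[mask], label)
        row = {
            "group": label,
            "analysis": "all",
            "n": summ.n,
            "mean_sum": round(summ.mean, 2),
            "sd_sum": round(summ.sd, 2),
            "carriers": int(tally.loc[label, "carriers"]),
            "carrier_pct": float(tally.loc[label, "percent"]),
        }
        if ei_by_sample is not None:
            row["mean_ei"] = round(
                float(ei_by_sample.loc[cohort.loc[mask, "sample_id"]].mean()), 3
            )
        rows.append(row)
        if include_without_ia:
            wmask = without["group"] == label
            wsums = without.loc[wmask, "allele_a"] + without.loc[wmask, "allele_b"]
            wsumm = summarize_group(wsums, label)
            wrow = {
                "group": label,
                "analysis": "without_ia",
                "n": wsumm.n,
                "mean_sum": round(wsumm.mean, 2),
                "sd_sum": round(wsumm.sd, 2),
                "carriers": 0,
                "carrier_pct": 0.0,
            }
            if ei_by_sample is not None:
                wrow["mean_ei"] = round(
                    float(
                        ei_by_sample.loc[without.loc[wmask, "sample_id"]].mean()
                    ),
                    3,
                )
            rows.append(wrow)
    return pd.DataFrame(rows)


def compare_to_controls(
    cohort: pd.DataFrame,
    control_label: str = "controls",
    alpha: float = 0.05,
    m_comparisons: int | None = None,
    include_without_ia: bool = True,
) -> pd.DataFrame:
    """Pooled t-tests of every case group against the control group.

    The primary analysis Bonferroni-adjusts the threshold for the number of
    case groups (``m_comparisons`` defaults to that count). The without-IA
    sensitivity re-analysis is reported against the unadjusted alpha, as a
    single follow-up comparison.
    """
    if control_label not in set(cohort["group"]):
        raise ValueError(f"control group {control_label!r} not present")
    case_labels = [g for g in cohort["group"].unique() if g != control_label]
    if m_comparisons is None:
        m_comparisons = max(len(case_labels), 1)

    def _summaries(frame: pd.DataFrame) -> dict[str, GroupSummary]:
        sums = frame["allele_a"] + frame["allele_b"]
        return {
            label: summarize_group(sums[frame["group"] == label], label)
            for label in frame["group"].unique()
        }

    datasets = [("all", cohort, m_comparisons)]
    if include_without_ia:
        datasets.append(("without_ia", exclude_intermediate_carriers(cohort), 1))
    rows = []
    for analysis, frame, m in datasets:
        summaries = _summaries(frame)
        for label in case_labels:
            res = pooled_t_test(
                summaries[label], summaries[control_label], alpha=alpha, m_comparisons=m
            )
            rows.append(
                {
                    "analysis": analysis,
                    "group_a": label,
                    "group_b": control_label,
                    "n_a": summaries[label].n,
                    "n_b": summaries[control_label].n,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "alpha_adjusted": res.alpha_adjusted,
                    "significant": res.significant,
                }
            )
    return pd.DataFrame(rows)
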