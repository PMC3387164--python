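"""Group-comparison statistics for sensitization / antifungal assay tables.

The pipeline mirrors standard practice for small-animal immunology data:
each group is screened with the Shapiro–Wilk normality test; if every group
passes at the chosen significance level the groups are compared by one-way
ANOVA with Tukey honest-significant-difference pairwise verdicts, otherwise
by the Kruskal–Wallis rank test (omnibus only — no post-hoc is applied).

Percent summaries follow the reporting convention of sensitization studies:
the difference between a treated and a reference group is expressed as a
fraction of the larger (treated) mean, and fungal growth inhibition is
``100 * (1 - treated/control)`` survival.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


class StatsError(ValueError):
    """Raised for degenerate or insufficient group data."""


@dataclass(frozen=True)
class GroupData:
    """Measurements for one experimental group (e.g. control/wild/mutant)."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise StatsError(f"group {self.label!r}: need at least 2 values")
        if not all(np.isfinite(self.values)):
            raise StatsError(f"group {self.label!r}: non-finite value")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class PairwiseVerdict:
    pair: tuple[str, str]
    statistic: float  # mean difference (Tukey)
    p_value: float
    significant: bool


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of the normality screen and the group comparison."""

    normality: dict[str, tuple[float, float]]  # label -> (W statistic, p)
    test_used: str  # "anova_tukey" or "kruskal_wallis"
    omnibus: tuple[float, float]  # (F, p) or (H, p)
    pairwise: tuple[PairwiseVerdict, ...]
    alpha: float
    note: str = ""

    def verdict(self, a: str, b: str) -> PairwiseVerdict:
        key = tuple(sorted((a, b)))
        for v in self.pairwise:
            if tuple(sorted(v.pair)) == key:
                return v
        raise KeyError(f"no pairwise verdict for {a!r} vs {b!r}")


def relative_percent_difference(ref_mean: float, other_mean: float) -> float:
    """Difference of two group means as a percent of the reference mean.

    ``100 * (ref - other) / ref`` — the reference is the larger (treated)
    mean, so "serum IgE increased by 40%" means the treated mean exceeds
    the control by 40% *of the treated mean*.
    """
    if ref_mean <= 0:
        raise StatsError("reference mean must be positive")
    return 100.0 * (ref_mean - other_mean) / ref_mean


def format_percent(value: float) -> str:
    """Report rounding: nearest integer percent, except magnitudes below 15
    keep two decimals (so small contrasts like 12.81% stay resolvable)."""
    if abs(value) < 15:
        return f"{value:.2f}"
    return f"{round(value):d}"


def compare_groups(groups: Sequence[GroupData], alpha: float = 0.05) -> ComparisonResult:
    """Normality-screened group comparison.

    Shapiro–Wilk per group at ``alpha``; all pass -> one-way ANOVA plus
    Tukey HSD pairwise verdicts at ``alpha``; any failure -> Kruskal–Wallis
    omnibus (no post-hoc).  Groups need n >= 3 for the normality test;
    zero-variance groups are rejected.
    """
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise StatsError("duplicate group labels")
    for g in groups:
        if g.n < 3:
            raise StatsError(f"group {g.label!r}: need n >= 3 for normality testing")
        if np.ptp(g.values) == 0:
            raise StatsError(f"group {g.label!r}: zero variance")
    order = sorted(range(len(groups)), key=lambda i: labels[i])
    groups = [groups[i] for i in order]

    normality = {}
    all_normal = True
    for g in groups:
        w, p = stats.shapiro(np.asarray(g.values))
        normality[g.label] = (float(w), float(p))
        if p <= alpha:
            all_normal = False

    samples = [np.asarray(g.values, dtype=float) for g in groups]
    if all_normal:
        f_stat, f_p = stats.f_oneway(*samples)
        endog = np.concatenate(samples)
        labels_long = np.concatenate([[g.label] * g.n for g in groups])
        tukey = pairwise_tukeyhsd(endog, labels_long, alpha=alpha)
        uniq = [str(g) for g in tukey.groupsunique]
        pairs = list(combinations(uniq, 2))
        pairwise = tuple(
            PairwiseVerdict(
                pair=pair,
                statistic=float(md),
                p_value=float(p),
                significant=bool(rej),
            )
            for pair, md, p, rej in zip(
                pairs, tukey.meandiffs, tukey.pvalues, tukey.reject
            )
        )
        return ComparisonResult(
            normality=normality,
            test_used="anova_tukey",
            omnibus=(float(f_stat), float(f_p)),
            pairwise=pairwise,
            alpha=alpha,
        )
    h_stat, h_p = stats.kruskal(*samples)
    return ComparisonResult(
        normality=normality,
        test_used="kruskal_wallis",
        omnibus=(float(h_stat), float(h_p)),
        pairwise=(),
        alpha=alpha,
        note="nonparametric route: omnibus Kruskal-Wallis only, no post-hoc",
    )


def inhibition_summary(
    doses: Sequence[tuple[float, float, float]]
) -> list[tuple[float, float]]:
    """Per-dose percent growth inhibition from survival counts.

    ``doses`` holds ``(dose, treated_count, control_count)`` tuples; the
    inhibition at each dose is ``100 * (1 - treated/control)``.
    """
    out = []
    for dose, treated, control in doses:
        if control <= 0:
            raise StatsError(f"dose {dose}: control count must be positive")
        out.append((dose, 100.0 * (1.0 - treated / control)))
    return out


def read_group_table(path: str | Path) -> list[GroupData]:
    """Read a long-format TSV with columns ``group`` and ``value``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"group", "value"} <= set(df.columns):
        raise StatsError("table must have 'group' and 'value' columns")
    return [
        GroupData(label=str(label), values=tuple(sub["value"].astype(float)))
        for label, sub in df.groupby("group", sort=True)
    ]


def comparison_frame(result: ComparisonResult) -> pd.DataFrame:
    """Tabular view of a ComparisonResult (for TSV output)."""
    rows = [
        {
            "kind": "normality",
            "group": label,
            "statistic": w,
            "p_value": p,
            "significant": p <= result.alpha,
        }
        for label, (w, p) in result.normality.items()
    ]
    rows.append(
        {
            "kind": "omnibus_" + result.test_used,
            "group": "all",
            "statistic": result.omnibus[0],
            "p_value": result.omnibus[1],
            "significant": result.omnibus[1] < result.alpha,
        }
    )
    for v in result.pairwise:
        rows.append(
            {
                "kind": "tukey",
                "group": f"{v.pair[0]} vs {v.pair[1]}",
                "statistic": v.statistic,
                "p_value": v.p_value,
                "significant": v.significant,
            }
        )
    return pd.DataFrame(rows)
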