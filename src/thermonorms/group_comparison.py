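"""Per-temperature comparisons of growth rates between strain groups.

At each temperature of the assay grid, replicate-level growth rates are
pooled within groups (by lineage, by environment of origin, or by explicit
strain sets) and compared with a one-way ANOVA or a two-sample t-test at a
fixed significance level (default alpha = 0.05, no multiple-testing
correction across temperatures; a Holm adjustment is available but off by
default). Replicates are the unit of analysis: with three strains per
group, pooling replicates is what provides within-group degrees of
freedom. For two groups the classic ANOVA and the equal-variance t-test
are the same test (t^2 = F, identical p).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.oneway import anova_oneway

from .errors import ValidationError

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
GROUPINGS = ("lineage", "environment")


@dataclass(eq=False)
class ComparisonResult:
    """Per-temperature test results for one grouping.

    ``table`` has one row per grid temperature with >= 2 populated groups
    (temperature_c, statistic, p_value, significant, degenerate, n_groups);
    ``group_stats`` holds the per-group means behind each row.
    """

    grouping: str
    alpha: float
    method: str
    table: pd.DataFrame
    group_stats: pd.DataFrame
    skipped: list[str] = field(default_factory=list)


def _attach_groups(fits: pd.DataFrame, meta: pd.DataFrame, grouping: str) -> pd.DataFrame:
    if grouping not in GROUPINGS:
        raise ValidationError(f"grouping must be one of {GROUPINGS}, got {grouping!r}")
    merged = fits.merge(meta[["strain_id", "lineage", "environment"]], on="strain_id", how="left")
    if merged["lineage"].isna().any():
        missing = sorted(set(merged.loc[merged["lineage"].isna(), "strain_id"]))
        raise ValidationError(f"fits contain strains absent from metadata: {missing}")
    return merged.rename(columns={grouping: "group"})


def _collect_groups(sub: pd.DataFrame) -> dict[str, np.ndarray]:
    """Group -> replicate mu values, keeping only groups with >= 2 values."""
    out = {}
    for group, grp in sub.groupby("group"):
        vals = grp["mu"].to_numpy(float)
        if len(vals) >= 2:
            out[str(group)] = vals
    return out


def _run_tests(
    by_temp: dict[float, dict[str, np.ndarray]],
    alpha: float,
    statistic_fn,
    holm: bool,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    rows, stats_rows, skipped = [], [], []
    for temp in sorted(by_temp):
        groups = by_temp[temp]
        if len(groups) < 2:
            msg = f"temperature {temp:g} C has <2 populated groups; omitted"
            log.warning(msg)
            skipped.append(msg)
            continue
        values = list(groups.values())
        pooled = np.concatenate(values)
        degenerate = bool(np.ptp(pooled) == 0)
        if degenerate:
            stat, p = math.nan, math.nan
        else:
            stat, p = statistic_fn(values)
        rows.append(
            {
                "temperature_c": temp,
                "statistic": stat,
                "p_value": p,
                "significant": bool(p < alpha) if not math.isnan(p) else False,
                "degenerate": degenerate,
                "n_groups": len(groups),
            }
        )
        for name, vals in groups.items():
            stats_rows.append(
                {
                    "temperature_c": temp,
                    "group": name,
                    "mean_mu": float(vals.mean()),
                    "sd_mu": float(vals.std(ddof=1)),
                    "n": len(vals),
                }
            )
    table = pd.DataFrame(rows)
    if holm and not table.empty:
        defined = table["p_value"].notna()
        if defined.any():
            reject, p_adj, _, _ = multipletests(
                table.loc[defined, "p_value"], alpha=alpha, method="holm"
            )
            table.loc[defined, "p_adjusted"] = p_adj
            table.loc[defined, "significant"] = reject
    return table, pd.DataFrame(stats_rows), skipped


def per_temperature_anova(
    fits: pd.DataFrame,
    meta: pd.DataFrame,
    grouping: str = "lineage",
    alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
    holm: bool = False,
    include_groups: Iterable[str] | None = None,
) -> ComparisonResult:
    """One-way ANOVA across groups at each temperature on replicate mu.

    ``fits`` is the per-replicate fits table (strain_id, temperature_c, mu);
    groups come from metadata via ``grouping`` (lineage or environment).
    ``include_groups`` restricts the comparison (e.g. to T vs H, leaving a
    laboratory strain out). Temperatures with fewer than two populated
    groups are omitted with a warning; a temperature where every pooled
    value is identical is flagged degenerate with an undefined p.
    """
    merged = _attach_groups(fits, meta, grouping)
    if include_groups is not None:
        merged = merged[merged["group"].isin(set(include_groups))]

    def classic(values):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.f_oneway(*values)
        return float(res.statistic), float(res.pvalue)

    def welch_fn(values):
        res = anova_oneway(values, use_var="unequal", welch_correction=True)
        return float(res.statistic), float(res.pvalue)

    by_temp = {
        float(temp): _collect_groups(sub)
        for temp, sub in merged.groupby("temperature_c")
    }
    table, group_stats, skipped = _run_tests(
        by_temp, alpha, welch_fn if welch else classic, holm
    )
    return ComparisonResult(
        grouping=grouping,
        alpha=alpha,
        method="welch_anova" if welch else "anova",
        table=table,
        group_stats=group_stats,
        skipped=skipped,
    )


def per_temperature_ttest(
    fits: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = True,
    holm: bool = False,
    labels: tuple[str, str] = ("A", "B"),
) -> ComparisonResult:
    """Two-sided two-sample t-test per temperature between two strain sets.

    ``equal_var=False`` selects the Welch (unequal-variance) variant.
    """
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise ValidationError(f"strain sets overlap: {sorted(group_a & group_b)}")
    sub = fits[fits["strain_id"].isin(group_a | group_b)].copy()
    sub["group"] = np.where(sub["strain_id"].isin(group_a), labels[0], labels[1])

    def ttest(values):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.ttest_ind(values[0], values[1], equal_var=equal_var)
        return float(res.statistic), float(res.pvalue)

    by_temp = {}
    for temp, grp in sub.groupby("temperature_c"):
        groups = _collect_groups(grp)
        # keep label order stable so the statistic's sign is meaningful
        by_temp[float(temp)] = {
            lab: groups[lab] for lab in labels if lab in groups
        }
    table, group_stats, skipped = _run_tests(by_temp, alpha, ttest, holm)
    return ComparisonResult(
        grouping="strain_sets",
        alpha=alpha,
        method="ttest" if equal_var else "welch_ttest",
        table=table,
        group_stats=group_stats,
        skipped=skipped,
    )


def count_significant_temperatures(result: ComparisonResult) -> int:
    """Number of grid temperatures flagged significant at the result's alpha."""
    if result.table.empty:
        return 0
    return int(result.table["significant"].sum())


def plot_comparison(result: ComparisonResult, ax=None):
    """Group mean curves over temperature with significance markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for group, grp in result.group_stats.groupby("group"):
        grp = grp.sort_values("temperature_c")
        se = grp["sd_mu"] / np.sqrt(grp["n"])
        ax.plot(grp["temperature_c"], grp["mean_mu"], marker="o", label=str(group))
        ax.fill_between(
            grp["temperature_c"], grp["mean_mu"] - 1.96 * se, grp["mean_mu"] + 1.96 * se,
            alpha=0.2,
        )
    sig = result.table[result.table["significant"]]
    if not sig.empty:
        top = result.group_stats.groupby("temperature_c")["mean_mu"].max()
        ax.plot(
            sig["temperature_c"], top.loc[sig["temperature_c"]].to_numpy() * 1.05,
            "r.", ms=10, label=f"p < {result.alpha:g}",
        )
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("mean specific growth rate µ (h$^{-1}$)")
    ax.legend(title=result.grouping)
    return ax
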