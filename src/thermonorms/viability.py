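"""Heat tolerance and sporulation statistics from CFU assays.

Viable counts after incubation at increasing temperatures fall roughly
exponentially, i.e. they lie on a straight line in a semilogarithmic plot.
The heat-sensitivity constant of a strain is the slope of that line,

    k = d ln(CFU) / dT   [per °C],

estimated either from the two extreme assay temperatures (``endpoint``,
the default, matching a single straight line through the ends) or by
least-squares over all temperatures with surviving counts
(``least_squares``). Temperatures with zero CFU (complete kill) carry no
log-survival information and are excluded with a flag rather than
substituted with a pseudo-count, since any pseudo-count choice would
dominate k. K denotes the arithmetic group mean of strain-level k values.

Sporulation is quantified as the spore fraction spore CFU / total CFU,
capped at 1 (small spore excesses over the total are routine plating
noise). Colony-diameter summaries (mean/SD of three colonies) complete the
heat-tolerance phenotyping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .plate_io import CfuDataset, ColonyTable

log = logging.getLogger(__name__)

K_METHODS = ("endpoint", "least_squares")


@dataclass(frozen=True)
class SensitivityEstimate:
    """Semilog heat-sensitivity slope for one strain."""

    strain_id: str
    k: float  # d ln(CFU)/dT, per °C
    intercept: float  # ln CFU at T = 0 on the fitted line
    temperatures: tuple[float, ...]  # temperatures used in the fit
    n_points: int
    method: str
    excluded_temperatures: tuple[float, ...] = ()  # complete-kill temps
    complete_kill: bool = False


@dataclass(frozen=True)
class SporulationRecord:
    """Spore fraction for a single assay record."""

    strain_id: str
    temperature_c: float
    replicate: int
    fraction: float  # NaN when total CFU = 0
    capped: bool
    undefined: bool


def _per_temperature_log_counts(records: pd.DataFrame) -> tuple[pd.Series, list[float]]:
    """Mean ln(total CFU) per temperature over replicates with positive
    counts; also the temperatures excluded because every replicate was 0."""
    positive = records[records["total_cfu_ml"] > 0].copy()
    positive["ln_n"] = np.log(positive["total_cfu_ml"].astype(float))
    ln_by_temp = positive.groupby("temperature_c")["ln_n"].mean()
    excluded = sorted(set(records["temperature_c"]) - set(ln_by_temp.index))
    return ln_by_temp, [float(x) for x in excluded]


def heat_sensitivity_k(
    records: pd.DataFrame | CfuDataset,
    method: str = "endpoint",
    literal_difference: bool = False,
) -> SensitivityEstimate:
    """Estimate the semilog heat-sensitivity slope k for one strain.

    Parameters
    ----------
    records
        CFU records of a single strain (a :class:`CfuDataset` restricted to
        one strain, or its underlying frame).
    method
        ``endpoint`` uses the two extreme temperatures with surviving
        counts: k = (ln N(T2) - ln N(T1)) / (T2 - T1); ``least_squares``
        regresses ln(CFU) on temperature over all replicate-level points
        with CFU > 0 (the maximum-likelihood slope under lognormal count
        noise).
    literal_difference
        Audit-only variant computing ln(N2 - N1)/(T2 - T1), the difference
        form sometimes printed for k; it is dimensionally inconsistent with
        a semilog survival line and returns NaN when N2 <= N1. Only valid
        with ``method='endpoint'``.
    """
    if isinstance(records, CfuDataset):
        records = records.data
    if method not in K_METHODS:
        raise ValidationError(f"unknown k method {method!r}; expected one of {K_METHODS}")
    strains = set(records["strain_id"])
    if len(strains) != 1:
        raise ValidationError(f"heat_sensitivity_k expects one strain, got {sorted(strains)}")
    strain = strains.pop()

    ln_by_temp, excluded = _per_temperature_log_counts(records)
    if len(ln_by_temp) < 2:
        raise ValidationError(
            f"strain {strain}: need >= 2 temperatures with positive CFU, have {len(ln_by_temp)}"
        )
    temps = ln_by_temp.index.to_numpy(float)
    if np.ptp(temps) == 0:
        raise ValidationError(f"strain {strain}: all assay temperatures identical")

    if method == "endpoint":
        t1, t2 = float(temps.min()), float(temps.max())
        ln1, ln2 = float(ln_by_temp[t1]), float(ln_by_temp[t2])
        if literal_difference:
            n1, n2 = math.exp(ln1), math.exp(ln2)
            k = math.log(n2 - n1) / (t2 - t1) if n2 > n1 else math.nan
        else:
            k = (ln2 - ln1) / (t2 - t1)
        intercept = ln1 - k * t1 if math.isfinite(k) else math.nan
        used = (t1, t2)
        n_points = 2
    else:
        if literal_difference:
            raise ValidationError("literal_difference applies only to the endpoint method")
        pts = records[records["total_cfu_ml"] > 0]
        res = stats.linregress(
            pts["temperature_c"].to_numpy(float),
            np.log(pts["total_cfu_ml"].to_numpy(float)),
        )
        k, intercept = float(res.slope), float(res.intercept)
        used = tuple(float(x) for x in temps)
        n_points = len(pts)

    return SensitivityEstimate(
        strain_id=str(strain),
        k=k,
        intercept=intercept,
        temperatures=used,
        n_points=n_points,
        method=method,
        excluded_temperatures=tuple(excluded),
        complete_kill=bool(excluded),
    )


def group_mean_k(
    estimates: list[SensitivityEstimate], grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Arithmetic mean K of strain-level k per group, with n and SD.

    Every estimated strain must be mapped to exactly one group; groups in
    the mapping without any estimate are omitted with a warning.
    """
    unmapped = [e.strain_id for e in estimates if e.strain_id not in grouping]
    if unmapped:
        raise ValidationError(f"strains without a group assignment: {unmapped}")
    by_group: dict[str, list[float]] = {}
    for est in estimates:
        by_group.setdefault(grouping[est.strain_id], []).append(est.k)
    for group in set(grouping.values()) - set(by_group):
        log.warning("group %r has no sensitivity estimates; omitted", group)
    rows = []
    for group in sorted(by_group):
        ks = np.array(by_group[group], dtype=float)
        rows.append(
            {
                "group": group,
                "K": float(ks.mean()),
                "sd_k": float(ks.std(ddof=1)) if len(ks) >= 2 else math.nan,
                "n": len(ks),
            }
        )
    return pd.DataFrame(rows)


def sporulation_fraction(record: Mapping) -> SporulationRecord:
    """Spore fraction of one assay record: min(spore/total, 1).

    A zero total leaves the fraction undefined (NaN, flagged). The fraction
    is invariant to the plating dilution because dilution rescales both
    counts by the same factor.
    """
    total = float(record["total_cfu_ml"])
    spore = float(record["spore_cfu_ml"])
    if total < 0 or spore < 0:
        raise ValidationError("CFU counts must be non-negative")
    if total == 0:
        return SporulationRecord(
            strain_id=str(record["strain_id"]),
            temperature_c=float(record["temperature_c"]),
            replicate=int(record.get("replicate", 1)),
            fraction=math.nan,
            capped=False,
            undefined=True,
        )
    raw = spore / total
    return SporulationRecord(
        strain_id=str(record["strain_id"]),
        temperature_c=float(record["temperature_c"]),
        replicate=int(record.get("replicate", 1)),
        fraction=min(raw, 1.0),
        capped=raw > 1.0,
        undefined=False,
    )


def sporulation_summary(cfu: CfuDataset | pd.DataFrame) -> pd.DataFrame:
    """Per strain x temperature mean spore fraction with replicate spread."""
    data = cfu.data if isinstance(cfu, CfuDataset) else cfu
    records = [sporulation_fraction(rec) for rec in data.to_dict("records")]
    frame = pd.DataFrame([r.__dict__ for r in records])
    rows = []
    for (strain, temp), grp in frame.groupby(["strain_id", "temperature_c"], sort=True):
        defined = grp.loc[~grp["undefined"], "fraction"]
        rows.append(
            {
                "strain_id": strain,
                "temperature_c": temp,
                "mean_fraction": float(defined.mean()) if len(defined) else math.nan,
                "sd_fraction": float(defined.std(ddof=1)) if len(defined) >= 2 else math.nan,
                "n": int(len(defined)),
                "n_undefined": int(grp["undefined"].sum()),
                "n_capped": int(grp["capped"].sum()),
            }
        )
    return pd.DataFrame(rows)


def colony_size_summary(table: ColonyTable | pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of colony diameters per strain x temperature x time.

    A condition where every measured diameter is 0 is flagged no-growth
    (diameter 0 encodes "no growth observed").
    """
    data = table.data if isinstance(table, ColonyTable) else table
    rows = []
    for (strain, temp, time), grp in data.groupby(
        ["strain_id", "temperature_c", "time_h"], sort=True
    ):
        d = grp["diameter_mm"].to_numpy(float)
        rows.append(
            {
                "strain_id": strain,
                "temperature_c": temp,
                "time_h": time,
                "mean_diameter_mm": float(d.mean()),
                "sd_diameter_mm": float(d.std(ddof=1)) if len(d) >= 2 else math.nan,
                "n": len(d),
                "no_growth": bool(np.all(d == 0)),
            }
        )
    return pd.DataFrame(rows)


def plot_viability(
    cfu: CfuDataset,
    grouping: Mapping[str, str],
    estimates: list[SensitivityEstimate] | None = None,
    ax=None,
):
    """Semilog survival plot: CFU points per group with fitted k lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = cfu.data
    groups = sorted({grouping.get(s) for s in data["strain_id"] if s in grouping})
    cmap = plt.get_cmap("tab10")
    for gi, group in enumerate(groups):
        strains = [s for s, g in grouping.items() if g == group]
        sub = data[data["strain_id"].isin(strains) & (data["total_cfu_ml"] > 0)]
        ax.semilogy(
            sub["temperature_c"], sub["total_cfu_ml"],
            "o", color=cmap(gi), alpha=0.6, label=str(group),
        )
        if estimates:
            ks = [e for e in estimates if e.strain_id in strains]
            if ks:
                t = np.linspace(data["temperature_c"].min(), data["temperature_c"].max(), 50)
                mean_k = np.mean([e.k for e in ks])
                mean_b = np.mean([e.intercept for e in ks])
                ax.semilogy(t, np.exp(mean_b + mean_k * t), "-", color=cmap(gi), lw=1.5)
    ax.set_xlabel("incubation temperature (°C)")
    ax.set_ylabel("CFU/ml")
    ax.legend(title="group")
    return ax
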