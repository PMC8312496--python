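"""Reaction norms to temperature and the 75%-of-maximum thermal niche.

A reaction norm maps the assayed temperature grid to a strain's mean
specific growth rate mu(T). The thermal niche is the temperature interval
over which the piecewise-linear interpolant of the norm stays at or above a
fraction ``f`` (default 0.75) of the maximal growth rate at the optimum.
Crossings are sought outward from the outermost optima; when a grid edge is
still above the threshold the corresponding bound is clamped to the edge
and flagged as censored. The niche is computed on the growth rate mu, not
on doubling time (a niche on Td would invert under the threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import NoGrowthError, ValidationError
from .growth_fitting import ReplicateSummary

DEFAULT_NICHE_FRACTION = 0.75
#: grid temperatures within (1 - plateau_tol) of the maximum count as optima
DEFAULT_PLATEAU_TOL = 0.05


@dataclass(eq=False)
class ReactionNorm:
    """Per-strain map temperature -> mean growth rate with replicate spread."""

    strain_id: str
    temperatures: np.ndarray
    mean_mu: np.ndarray
    sd_mu: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.mean_mu = np.asarray(self.mean_mu, dtype=float)
        self.sd_mu = np.asarray(self.sd_mu, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not (len(self.temperatures) == len(self.mean_mu) == len(self.sd_mu) == len(self.n)):
            raise ValidationError("reaction norm arrays must have equal length")
        if len(self.temperatures) < 2:
            raise ValidationError("a reaction norm needs at least 2 temperatures")
        if np.unique(self.temperatures).size != self.temperatures.size:
            raise ValidationError(f"duplicate temperatures in norm for {self.strain_id}")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValidationError("temperature grid must be strictly increasing")
        if np.any(self.mean_mu < 0):
            raise ValidationError("mean growth rates must be >= 0")

    @property
    def no_growth(self) -> bool:
        return bool(np.all(self.mean_mu == 0))

    @property
    def mu_max(self) -> float:
        return float(self.mean_mu.max())


@dataclass(frozen=True)
class ThermalNiche:
    """Optimum temperature(s) and the f-of-maximum thermal niche of a norm."""

    strain_id: str
    f: float
    mu_max: float
    optima: tuple[float, ...]
    t_lo: float
    t_hi: float
    breadth: float
    censored_low: bool
    censored_high: bool


def build_reaction_norm(summaries: Sequence[ReplicateSummary]) -> ReactionNorm:
    """Assemble one strain's norm from its replicate summaries.

    The grid is sorted ascending regardless of input order; temperatures
    with a no-growth consensus contribute mu = 0.
    """
    if len(summaries) < 2:
        raise ValidationError("need summaries at >= 2 distinct temperatures")
    strains = {s.strain_id for s in summaries}
    if len(strains) > 1:
        raise ValidationError(f"summaries mix strains: {sorted(strains)}")
    temps = np.array([s.temperature_c for s in summaries], dtype=float)
    if np.unique(temps).size != temps.size:
        raise ValidationError(f"duplicate temperature entries for strain {summaries[0].strain_id}")
    order = np.argsort(temps)
    mu = np.array([0.0 if s.no_growth else s.mean_mu for s in summaries], dtype=float)
    sd = np.array([s.sd_mu for s in summaries], dtype=float)
    n = np.array([s.n for s in summaries], dtype=int)
    return ReactionNorm(
        strain_id=summaries[0].strain_id,
        temperatures=temps[order],
        mean_mu=mu[order],
        sd_mu=sd[order],
        n=n[order],
    )


def norms_from_summary_table(summary: pd.DataFrame) -> dict[str, ReactionNorm]:
    """One ReactionNorm per strain from a replicate-summary table."""
    norms: dict[str, ReactionNorm] = {}
    for strain, grp in summary.groupby("strain_id", sort=True):
        summaries = [
            ReplicateSummary(**{k: rec[k] for k in ReplicateSummary.__dataclass_fields__})
            for rec in grp.to_dict("records")
        ]
        norms[str(strain)] = build_reaction_norm(summaries)
    return norms


def find_optima(norm: ReactionNorm, plateau_tol: float = DEFAULT_PLATEAU_TOL) -> list[float]:
    """All grid temperatures whose mean mu is within ``plateau_tol`` of the
    maximum, ascending. Empty for an all-zero (no-growth) norm; a strictly
    unimodal norm with plateau_tol = 0 yields a singleton."""
    if not 0 <= plateau_tol < 1:
        raise ValidationError("plateau_tol must be in [0, 1)")
    if norm.no_growth:
        return []
    cutoff = (1.0 - plateau_tol) * norm.mu_max
    return [float(t) for t, m in zip(norm.temperatures, norm.mean_mu) if m >= cutoff]


def _cross_left(t: np.ndarray, v: np.ndarray, start: int, thr: float) -> tuple[float, bool]:
    """First downward threshold crossing left of index ``start``."""
    for j in range(start, 0, -1):
        if v[j - 1] < thr:
            frac = (v[j] - thr) / (v[j] - v[j - 1])
            return float(t[j] - frac * (t[j] - t[j - 1])), False
    return float(t[0]), True


def _cross_right(t: np.ndarray, v: np.ndarray, start: int, thr: float) -> tuple[float, bool]:
    for j in range(start, len(t) - 1):
        if v[j + 1] < thr:
            frac = (v[j] - thr) / (v[j] - v[j + 1])
            return float(t[j] + frac * (t[j + 1] - t[j])), False
    return float(t[-1]), True


def compute_thermal_niche(
    norm: ReactionNorm,
    f: float = DEFAULT_NICHE_FRACTION,
    plateau_tol: float = DEFAULT_PLATEAU_TOL,
) -> ThermalNiche:
    """Thermal niche of a norm at threshold ``f * mu_max``.

    The lower bound is where the piecewise-linear interpolant first drops
    below the threshold moving left from the leftmost optimum (clamped and
    censored at the grid edge when the edge value is still above threshold);
    the upper bound is symmetric right of the rightmost optimum.
    """
    if not 0 < f < 1:
        raise ValidationError("niche fraction f must be in (0, 1)")
    if norm.no_growth:
        raise NoGrowthError(f"norm for {norm.strain_id} is all-zero; no niche definable")
    optima = find_optima(norm, plateau_tol=plateau_tol)
    thr = f * norm.mu_max
    t, v = norm.temperatures, norm.mean_mu
    i_lo = int(np.searchsorted(t, optima[0]))
    i_hi = int(np.searchsorted(t, optima[-1]))
    t_lo, cen_lo = _cross_left(t, v, i_lo, thr)
    t_hi, cen_hi = _cross_right(t, v, i_hi, thr)
    return ThermalNiche(
        strain_id=norm.strain_id,
        f=f,
        mu_max=norm.mu_max,
        optima=tuple(optima),
        t_lo=t_lo,
        t_hi=t_hi,
        breadth=t_hi - t_lo,
        censored_low=cen_lo,
        censored_high=cen_hi,
    )


def niche_table(
    norms: Mapping[str, ReactionNorm],
    meta: pd.DataFrame | None = None,
    f: float = DEFAULT_NICHE_FRACTION,
    plateau_tol: float = DEFAULT_PLATEAU_TOL,
) -> pd.DataFrame:
    """Thermal-niche summary table over many strains.

    All-zero norms yield a row with NaN niche fields and no_growth = True
    rather than an error, so one dead strain does not abort a run.
    """
    rows = []
    for strain, norm in norms.items():
        row: dict = {"strain_id": strain, "f": f, "no_growth": norm.no_growth}
        if norm.no_growth:
            row.update(
                mu_max=0.0, optima="", optimum_min=math.nan, optimum_max=math.nan,
                t_lo=math.nan, t_hi=math.nan, breadth=math.nan,
                censored_low=False, censored_high=False,
            )
        else:
            niche = compute_thermal_niche(norm, f=f, plateau_tol=plateau_tol)
            row.update(
                mu_max=niche.mu_max,
                optima=";".join(f"{x:g}" for x in niche.optima),
                optimum_min=niche.optima[0],
                optimum_max=niche.optima[-1],
                t_lo=niche.t_lo,
                t_hi=niche.t_hi,
                breadth=niche.breadth,
                censored_low=niche.censored_low,
                censored_high=niche.censored_high,
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    if meta is not None:
        table = table.merge(meta[["strain_id", "lineage", "environment"]], on="strain_id", how="left")
    return table


def plot_reaction_norm(norm: ReactionNorm, niche: ThermalNiche | None = None, ax=None):
    """Render a norm as mean +/- SD over temperature, optionally with the
    niche band and threshold line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(
        norm.temperatures, norm.mean_mu, yerr=np.nan_to_num(norm.sd_mu),
        marker="o", capsize=3, label=norm.strain_id,
    )
    if niche is not None:
        ax.axvspan(niche.t_lo, niche.t_hi, alpha=0.15, color="tab:orange")
        ax.axhline(niche.f * niche.mu_max, ls="--", lw=0.8, color="tab:orange")
        for opt in niche.optima:
            ax.axvline(opt, ls=":", lw=0.8, color="k")
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("specific growth rate µ (h$^{-1}$)")
    return ax
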