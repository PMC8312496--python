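"""Specific growth rate estimation from OD time series.

The estimator realizes the classical exponential growth model: during
balanced exponential growth, blank-corrected optical density follows
``OD(t) = OD0 * exp(mu * t)``, so ln(OD) is linear in time with slope mu
(the specific growth rate, h^-1) and the doubling time is Td = ln2 / mu.
Because a full growth curve also contains lag and stationary phases, mu is
estimated by a windowed log-linear regression: among all contiguous windows
of at least ``min_points`` samples whose ln(OD) least-squares fit reaches
R^2 >= ``min_r2``, the window with the maximal slope is selected (ties go to
the larger window, then the earlier start). Curves whose blank-corrected OD
never rises by ``growth_threshold``-fold over baseline are declared
no-growth (mu = 0, Td undefined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .plate_io import PlateDataset

#: OD floor applied after blank subtraction, so logs are always defined.
DEFAULT_DETECTION_LIMIT = 0.005
DEFAULT_MIN_POINTS = 5  # 2 h of data at 30-min sampling
DEFAULT_MIN_R2 = 0.98
DEFAULT_GROWTH_THRESHOLD = 1.5
#: relative slope difference below which two windows count as tied
_TIE_RTOL = 1e-12


@dataclass(eq=False)
class GrowthCurve:
    """One strain x replicate x temperature OD time series."""

    strain_id: str
    replicate: int
    temperature_c: float
    times: np.ndarray
    od: np.ndarray
    blank: float | None = None
    od_raw: np.ndarray | None = None  # pre-blanking values, kept for reporting

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValidationError("times and od must have identical length")
        if self.times.size < 2:
            raise ValidationError("a growth curve needs at least 2 time points")


@dataclass(frozen=True)
class GrowthFit:
    """Result of the exponential-phase fit for one curve.

    ``mu`` is the natural-log slope (h^-1); ``td_h`` = ln2/mu, NaN when
    no_growth. The window fields give the fitted region; ``low_quality``
    marks the fallback taken when growth was evident but no window reached
    the R^2 criterion.
    """

    strain_id: str
    replicate: int
    temperature_c: float
    mu: float
    td_h: float
    window_start_h: float
    window_end_h: float
    n_window: int
    r2: float
    max_od: float
    no_growth: bool
    low_quality: bool = False


@dataclass(frozen=True)
class ReplicateSummary:
    """Replicate aggregate for one strain x temperature."""

    strain_id: str
    temperature_c: float
    n: int
    mean_mu: float
    sd_mu: float
    mean_td_h: float
    n_no_growth: int
    no_growth: bool


def preprocess_curve(
    curve: GrowthCurve, detection_limit: float = DEFAULT_DETECTION_LIMIT
) -> GrowthCurve:
    """Blank-subtract and floor a curve so that ln(OD) is defined.

    The blank defaults to the per-series minimum OD when the curve carries
    none (instrument exports are not always blank-corrected). The original
    OD values are retained on ``od_raw``.
    """
    if detection_limit <= 0:
        raise ValidationError("detection_limit must be > 0")
    if np.unique(curve.times).size < 2:
        raise ValidationError("all time points are identical; cannot preprocess")
    if not np.all(np.diff(curve.times) > 0):
        raise ValidationError(
            f"times not strictly increasing in series ({curve.strain_id}, "
            f"rep {curve.replicate}, {curve.temperature_c} C)"
        )
    blank = float(curve.od.min()) if curve.blank is None else float(curve.blank)
    corrected = np.maximum(curve.od - blank, detection_limit)
    return replace(curve, od=corrected, blank=blank, od_raw=curve.od.copy())


def _window_regressions(t: np.ndarray, y: np.ndarray, min_points: int):
    """Slope and R^2 of the least-squares line for every contiguous window
    of >= min_points samples, via prefix sums (O(1) per window).

    Returns parallel arrays (start index, window size, slope, r2).
    """
    n = len(t)
    cx = np.concatenate(([0.0], np.cumsum(t)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cxx = np.concatenate(([0.0], np.cumsum(t * t)))
    cyy = np.concatenate(([0.0], np.cumsum(y * y)))
    cxy = np.concatenate(([0.0], np.cumsum(t * y)))

    starts, sizes, slopes, r2s = [], [], [], []
    for w in range(min_points, n + 1):
        i = np.arange(0, n - w + 1)
        sx = cx[i + w] - cx[i]
        sy = cy[i + w] - cy[i]
        sxx = cxx[i + w] - cxx[i]
        syy = cyy[i + w] - cyy[i]
        sxy = cxy[i + w] - cxy[i]
        ssxx = sxx - sx * sx / w
        ssyy = syy - sy * sy / w
        ssxy = sxy - sx * sy / w
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(ssxx > 0, ssxy / np.where(ssxx > 0, ssxx, 1.0), np.nan)
            r2 = np.where(ssyy > 0, slope * slope * ssxx / np.where(ssyy > 0, ssyy, 1.0), 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        starts.append(i)
        sizes.append(np.full_like(i, w))
        slopes.append(slope)
        r2s.append(r2)
    return (
        np.concatenate(starts),
        np.concatenate(sizes),
        np.concatenate(slopes),
        np.concatenate(r2s),
    )


def _select_window(starts, sizes, slopes, r2s, mask):
    """Max-slope window among ``mask``; ties to larger window, earlier start."""
    idx = np.flatnonzero(mask & np.isfinite(slopes))
    if idx.size == 0:
        return None
    best_slope = slopes[idx].max()
    tol = _TIE_RTOL * max(1.0, abs(best_slope))
    tied = idx[slopes[idx] >= best_slope - tol]
    # prefer the largest window, then the earliest start
    order = np.lexsort((starts[tied], -sizes[tied]))
    return int(tied[order[0]])


def fit_exponential_phase(
    curve: GrowthCurve,
    min_points: int = DEFAULT_MIN_POINTS,
    min_r2: float = DEFAULT_MIN_R2,
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
) -> GrowthFit:
    """Estimate mu from the max-slope log-linear window of a preprocessed curve.

    The curve must already be blank-corrected and floored (all OD > 0); see
    :func:`preprocess_curve`. The growth/no-growth decision compares robust
    peak and baseline levels (medians of the three largest and the three
    earliest corrected values) so that a single noisy sample cannot flip it.
    """
    if min_points < 3:
        raise ValidationError("min_points must be >= 3")
    t, od = curve.times, curve.od
    if len(t) < min_points:
        raise ValidationError(
            f"curve has {len(t)} points, fewer than min_points={min_points}"
        )
    if np.any(od <= 0):
        raise ValidationError("curve contains non-positive OD; run preprocess_curve first")

    max_od = float(od.max())
    k = min(3, len(od))
    baseline = float(np.median(od[:k]))
    peak = float(np.median(np.sort(od)[-k:]))
    if peak / baseline < growth_threshold:
        return GrowthFit(
            curve.strain_id, curve.replicate, curve.temperature_c,
            mu=0.0, td_h=math.nan, window_start_h=math.nan, window_end_h=math.nan,
            n_window=0, r2=math.nan, max_od=max_od, no_growth=True,
        )

    y = np.log(od)
    starts, sizes, slopes, r2s = _window_regressions(t, y, min_points)
    pick = _select_window(starts, sizes, slopes, r2s, r2s >= min_r2)
    low_quality = False
    if pick is None:  # growth evident but no window reaches min_r2
        pick = _select_window(starts, sizes, slopes, r2s, np.ones_like(r2s, dtype=bool))
        low_quality = True
    if pick is None or slopes[pick] <= 0:
        return GrowthFit(
            curve.strain_id, curve.replicate, curve.temperature_c,
            mu=0.0, td_h=math.nan, window_start_h=math.nan, window_end_h=math.nan,
            n_window=0, r2=math.nan, max_od=max_od, no_growth=True,
        )
    i, w = int(starts[pick]), int(sizes[pick])
    mu = float(slopes[pick])
    return GrowthFit(
        curve.strain_id, curve.replicate, curve.temperature_c,
        mu=mu, td_h=math.log(2.0) / mu,
        window_start_h=float(t[i]), window_end_h=float(t[i + w - 1]),
        n_window=w, r2=float(r2s[pick]), max_od=max_od,
        no_growth=False, low_quality=low_quality,
    )


def summarize_replicates(fits: Sequence[GrowthFit]) -> ReplicateSummary:
    """Aggregate replicate fits of one strain x temperature.

    The mean is taken over all replicate mu values (no-growth replicates
    contribute mu = 0); the no-growth consensus requires a strict majority
    of no-growth replicates; Td is summarized as ln2 / mean(mu).
    """
    if not fits:
        raise ValidationError("summarize_replicates requires at least one fit")
    strains = {f.strain_id for f in fits}
    temps = {f.temperature_c for f in fits}
    if len(strains) > 1 or len(temps) > 1:
        raise ValidationError(
            f"mixed strain/temperature in replicate set: {strains} x {temps}"
        )
    mu = np.array([f.mu for f in fits], dtype=float)
    n = len(mu)
    n_ng = sum(f.no_growth for f in fits)
    mean_mu = float(mu.mean())
    sd_mu = float(mu.std(ddof=1)) if n >= 2 else math.nan
    return ReplicateSummary(
        strain_id=fits[0].strain_id,
        temperature_c=fits[0].temperature_c,
        n=n,
        mean_mu=mean_mu,
        sd_mu=sd_mu,
        mean_td_h=math.log(2.0) / mean_mu if mean_mu > 0 else math.nan,
        n_no_growth=n_ng,
        no_growth=n_ng * 2 > n,
    )


# ---------------------------------------------------------------------------
# dataset-level helpers


def curves_from_dataset(
    dataset: PlateDataset, detection_limit: float = DEFAULT_DETECTION_LIMIT
) -> list[GrowthCurve]:
    """Extract and preprocess every series of a plate dataset.

    Uses the per-plate blank from metadata when declared, otherwise the
    per-series minimum OD.
    """
    curves = []
    for strain, rep, temp, t, od in dataset.iter_series():
        raw = GrowthCurve(strain, rep, temp, t, od, blank=dataset.blank_for(strain))
        curves.append(preprocess_curve(raw, detection_limit=detection_limit))
    return curves


def fit_plate_dataset(
    dataset: PlateDataset,
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
    min_points: int = DEFAULT_MIN_POINTS,
    min_r2: float = DEFAULT_MIN_R2,
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
) -> pd.DataFrame:
    """Fit every series and return the per-replicate fits table."""
    rows = []
    for curve in curves_from_dataset(dataset, detection_limit=detection_limit):
        fit = fit_exponential_phase(
            curve, min_points=min_points, min_r2=min_r2, growth_threshold=growth_threshold
        )
        rows.append(fit.__dict__)
    return pd.DataFrame(rows)


def summarize_fit_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a fits table to one row per strain x temperature."""
    rows = []
    for (strain, temp), grp in fits.groupby(["strain_id", "temperature_c"], sort=True):
        group_fits = [
            GrowthFit(**{k: rec[k] for k in GrowthFit.__dataclass_fields__})
            for rec in grp.to_dict("records")
        ]
        rows.append(summarize_replicates(group_fits).__dict__)
    return pd.DataFrame(rows)
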