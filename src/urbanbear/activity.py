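"""Diel activity analysis: seasonal mean curves and bounded sine fits.

Collar activity sensors log head-movement counts (0-255) every 5 minutes.
For a bear-season, counts are averaged by time-of-day bin (288 bins) and a
sine curve

    y = a * sin(b * x + c) + d

is fitted by bounded nonlinear least squares, where x is clock time mapped
to [0, 2pi) with midnight at 0.  The two shape parameters carry the
ecological signal: b is the number of activity peaks per 24 h and c shifts
their timing.  Nocturnal activity looks like b ~ 1 with c ~ -pi/2 (one bout
around midnight); crepuscular activity like b ~ 2 with c ~ pi/2 (bouts at
dawn and dusk).  Bounds follow the sensor range and the identifiable window:
0 <= a, d <= 255, 0 <= b <= 5, -pi/2 <= c <= pi/2.

Because the bounded objective has many local minima in (b, c), the fit is
multi-started over a b0 x c0 grid and the lowest-SSE solution is kept, with
ties broken toward smaller b, then smaller |c|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .telemetry import SeasonCalendar

N_BINS = 288  # 5-minute bins over 24 h

BOUNDS_LO = np.array([0.0, 0.0, -np.pi / 2, 0.0])
BOUNDS_HI = np.array([255.0, 5.0, np.pi / 2, 255.0])
_B_STARTS = np.arange(0.5, 5.01, 0.5)
_C_STARTS = np.array([-np.pi / 2, 0.0, np.pi / 2])
DEGENERATE_AMPLITUDE = 1e-6


@dataclass
class DielCurve:
    """Mean head-movement count by 5-minute time-of-day bin over a season."""

    x: np.ndarray            # bin-midpoint clock time in radians, length 288
    mean: np.ndarray         # per-bin mean count; NaN where no data
    n_days: int

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.mean)


@dataclass
class SineFit:
    a: float
    b: float
    c: float
    d: float
    sse: float
    converged: bool
    n_starts: int
    degenerate: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.sin(self.b * x + self.c) + self.d


def bin_midpoints() -> np.ndarray:
    """Clock-time bin midpoints on [0, 2pi); midnight maps to 0."""
    minutes = np.arange(N_BINS) * 5.0 + 2.5
    return 2.0 * np.pi * minutes / 1440.0


def diel_mean_curve(
    activity: pd.DataFrame,
    bear_id,
    year: int,
    season: str,
    cal: SeasonCalendar | None = None,
) -> DielCurve:
    """Per-bin mean count for one bear-season.

    Bins with no observations are flagged NaN and excluded from any fit.
    Raises if the season window holds no data at all.
    """
    cal = cal or SeasonCalendar()
    start, end = cal.window(season, year)
    df = activity[activity["bear_id"] == bear_id].copy()
    ts = pd.to_datetime(df["timestamp"])
    dates = ts.dt.date
    df = df[(dates >= start) & (dates <= end)]
    if len(df) == 0:
        raise ValueError(f"no activity data for {bear_id} {year} {season}")
    ts = pd.to_datetime(df["timestamp"])
    bins = (ts.dt.hour * 60 + ts.dt.minute).to_numpy() // 5
    counts = df["count"].to_numpy(dtype=float)
    sums = np.bincount(bins, weights=counts, minlength=N_BINS)
    n = np.bincount(bins, minlength=N_BINS)
    mean = np.full(N_BINS, np.nan)
    mean[n > 0] = sums[n > 0] / n[n > 0]
    n_days = int(ts.dt.date.nunique())
    return DielCurve(x=bin_midpoints(), mean=mean, n_days=n_days)


def activity_coverage(
    activity: pd.DataFrame,
    cal: SeasonCalendar | None = None,
) -> pd.DataFrame:
    """Bear-season eligibility for activity data under the 90% span rule."""
    cal = cal or SeasonCalendar()
    df = activity.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["season"] = [cal.season_of(d) for d in df["timestamp"].dt.date]
    df["year"] = df["timestamp"].dt.year
    df = df[df["season"] != "none"]
    rows = []
    for (bear, year, season), grp in df.groupby(["bear_id", "year", "season"]):
        dates = grp["timestamp"].dt.date
        span = (dates.max() - dates.min()).days + 1
        length = cal.season_length_days(season, int(year))
        rows.append(dict(bear_id=bear, year=int(year), season=season,
                         coverage=span / length,
                         eligible=span / length >= cal.coverage_threshold))
    return pd.DataFrame(rows, columns=["bear_id", "year", "season",
                                       "coverage", "eligible"])


def fit_sine(curve: DielCurve) -> SineFit:
    """Bounded multi-start least-squares fit of a*sin(b*x + c) + d.

    Requires at least 24 non-empty bins.  Starts span b0 in {0.5, ..., 5.0}
    by c0 in {-pi/2, 0, pi/2} with a0 = half the data range and d0 = the
    data mean.  Best SSE wins; exact ties go to smaller b, then smaller |c|.
    """
    obs = curve.observed
    if obs.sum() < 24:
        raise ValueError("need at least 24 non-empty bins to fit the sine")
    x = curve.x[obs]
    y = curve.mean[obs]
    a0 = float(np.clip((y.max() - y.min()) / 2.0, 0.0, 255.0))
    d0 = float(np.clip(y.mean(), 0.0, 255.0))

    def resid(p):
        return p[0] * np.sin(p[1] * x + p[2]) + p[3] - y

    best = None
    any_ok = False
    n_starts = 0
    for b0 in _B_STARTS:
        for c0 in _C_STARTS:
            n_starts += 1
            p0 = np.clip([a0, b0, c0, d0], BOUNDS_LO, BOUNDS_HI)
            try:
                res = least_squares(resid, p0, bounds=(BOUNDS_LO, BOUNDS_HI),
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:
                continue
            sse = float(2.0 * res.cost)
            any_ok = any_ok or res.success
            key = (round(sse, 10), round(res.x[1], 8), round(abs(res.x[2]), 8))
            if best is None or key < best[0]:
                best = (key, res.x, sse, res.success)
    p, sse, success = best[1], best[2], best[3]
    fit = SineFit(a=float(p[0]), b=float(p[1]), c=float(p[2]), d=float(p[3]),
                  sse=sse, converged=bool(any_ok), n_starts=n_starts,
                  degenerate=bool(p[0] < DEGENERATE_AMPLITUDE))
    return fit


def classify_pattern(fit: SineFit) -> str:
    """Heuristic label from the fitted shape parameters.

    The windows (|b - 1| <= 0.25 with c <= -pi/4 for nocturnal; |b - 2| <=
    0.25 with c >= pi/4 for crepuscular) are reporting conveniences, not
    estimated quantities.
    """
    if fit.degenerate or fit.a < DEGENERATE_AMPLITUDE:
        return "degenerate"
    if abs(fit.b - 1.0) <= 0.25 and fit.c <= -np.pi / 4:
        return "nocturnal"
    if abs(fit.b - 2.0) <= 0.25 and fit.c >= np.pi / 4:
        return "crepuscular"
    return "other"


def fit_table(
    activity: pd.DataFrame,
    cal: SeasonCalendar | None = None,
    require_coverage: bool = True,
) -> pd.DataFrame:
    """SineFit table (a, b, c, d, sse, converged, label) per eligible bear-season."""
    cal = cal or SeasonCalendar()
    cov = activity_coverage(activity, cal)
    if require_coverage:
        cov = cov[cov["eligible"]]
    rows = []
    for _, r in cov.iterrows():
        curve = diel_mean_curve(activity, r["bear_id"], int(r["year"]),
                                r["season"], cal)
        fit = fit_sine(curve)
        rows.append(dict(bear_id=r["bear_id"], year=int(r["year"]),
                         season=r["season"], a=fit.a, b=fit.b, c=fit.c, d=fit.d,
                         sse=fit.sse, converged=fit.converged,
                         label=classify_pattern(fit)))
    return pd.DataFrame(rows, columns=["bear_id", "year", "season", "a", "b",
                                       "c", "d", "sse", "converged", "label"])
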