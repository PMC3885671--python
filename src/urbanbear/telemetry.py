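"""GPS-fix screening, season assignment, and bear-season eligibility.

Collared bears carry GPS units whose fixes vary in quality.  Before any
space-use analysis, fixes are screened on positional dilution of precision
(PDOP): 3D fixes are kept at PDOP <= 10 and 2D fixes at PDOP <= 5.  Fixes
inside a 48-hour post-release window, or while a bear was absent after
translocation, are also dropped.  Surviving fixes are stratified into a
pre-hyperphagia season (den emergence, 16 April, to mast fruiting, 31 July)
and a hyperphagia season (1 August to 15 October), and a bear-season enters
downstream analyses only when its fixes span at least 90% of the season.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PDOP_MAX_3D = 10.0
PDOP_MAX_2D = 5.0
POST_RELEASE_EXCLUSION_H = 48.0

#: machine-readable reasons attached to every removed row
REASONS = ("pdop_3d", "pdop_2d", "unknown_fix_dim", "post_release", "translocation")


@dataclass(frozen=True)
class SeasonCalendar:
    """Season windows as (month, day) endpoints within one calendar year.

    Defaults follow local mast phenology: pre-hyperphagia runs from den
    emergence (Apr 16) to fruiting of the main mast species (Jul 31);
    hyperphagia from Aug 1 to the onset of pre-denning lethargy (Oct 15).
    """

    pre_start: tuple[int, int] = (4, 16)
    pre_end: tuple[int, int] = (7, 31)
    hyper_start: tuple[int, int] = (8, 1)
    hyper_end: tuple[int, int] = (10, 15)
    coverage_threshold: float = 0.9

    def window(self, season: str, year: int) -> tuple[dt.date, dt.date]:
        if season == "pre_hyperphagia":
            s, e = self.pre_start, self.pre_end
        elif season == "hyperphagia":
            s, e = self.hyper_start, self.hyper_end
        else:
            raise ValueError(f"unknown season {season!r}")
        return dt.date(year, *s), dt.date(year, *e)

    def season_length_days(self, season: str, year: int = 2005) -> int:
        start, end = self.window(season, year)
        return (end - start).days + 1

    def season_of(self, when: dt.date) -> str:
        """Season label for a date, or ``"none"`` outside both windows."""
        y = when.year
        for season in ("pre_hyperphagia", "hyperphagia"):
            start, end = self.window(season, y)
            if start <= when <= end:
                return season
        return "none"


@dataclass
class ScreeningReport:
    """Row counts removed per bear, split by reason."""

    per_bear: pd.DataFrame
    n_input: int
    n_retained: int

    @property
    def fraction_removed(self) -> float:
        if self.n_input == 0:
            return 0.0
        return 1.0 - self.n_retained / self.n_input


def _as_timestamp(col: pd.Series) -> pd.Series:
    return pd.to_datetime(col)


def screen_locations(
    locs: pd.DataFrame,
    events: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Apply PDOP and capture/translocation screening to a location table.

    Parameters
    ----------
    locs
        Columns ``bear_id, timestamp, x_m, y_m, fix_dim, pdop``.  ``fix_dim``
        is ``"2D"`` or ``"3D"``.  Optional boolean columns
        ``post_release_window`` and ``translocation_window`` mark fixes the
        event log places inside an exclusion window; alternatively pass
        ``events``.
    events
        Optional event log with columns ``bear_id, timestamp, event`` where
        ``event`` is ``release``, ``translocation_out`` or
        ``translocation_return``.  Releases exclude the following 48 h;
        a translocation excludes fixes until the matching return.

    Returns
    -------
    (screened, report)
        ``screened`` is the retained subset (original row order, with a
        ``season``-free copy of the input columns); ``report`` counts removed
        rows per bear and reason.  Removed rows are never silently dropped:
        the per-reason tally accounts for every one.
    """
    df = locs.copy()
    df["timestamp"] = _as_timestamp(df["timestamp"])
    n_input = len(df)
    reason = pd.Series("", index=df.index, dtype=object)

    dim = df["fix_dim"].astype(str).str.upper()
    pdop = df["pdop"].astype(float)
    bad_dim = ~dim.isin(["2D", "3D"])
    fail_3d = (dim == "3D") & (pdop > PDOP_MAX_3D)
    fail_2d = (dim == "2D") & (pdop > PDOP_MAX_2D)
    reason[bad_dim] = "unknown_fix_dim"
    reason[fail_3d & (reason == "")] = "pdop_3d"
    reason[fail_2d & (reason == "")] = "pdop_2d"

    post_release = _window_mask(df, events, "post_release_window", _release_windows)
    transloc = _window_mask(df, events, "translocation_window", _translocation_windows)
    reason[post_release & (reason == "")] = "post_release"
    reason[transloc & (reason == "")] = "translocation"

    keep = reason == ""
    screened = df[keep].copy()

    removed = df[~keep].assign(reason=reason[~keep])
    tally = (
        removed.groupby(["bear_id", "reason"]).size().unstack(fill_value=0)
        if len(removed)
        else pd.DataFrame()
    )
    per_bear = (
        df.groupby("bear_id").size().rename("n_input").to_frame().join(tally).fillna(0)
    )
    for r in REASONS:
        if r not in per_bear.columns:
            per_bear[r] = 0
    per_bear["n_removed"] = per_bear[list(REASONS)].sum(axis=1).astype(int)
    per_bear["fraction_removed"] = per_bear["n_removed"] / per_bear["n_input"]
    report = ScreeningReport(per_bear=per_bear.reset_index(), n_input=n_input,
                             n_retained=len(screened))
    return screened, report


def _window_mask(df, events, flag_col, window_fn) -> pd.Series:
    if flag_col in df.columns:
        return df[flag_col].astype(bool)
    mask = pd.Series(False, index=df.index)
    if events is None or len(events) == 0:
        return mask
    ev = events.copy()
    ev["timestamp"] = _as_timestamp(ev["timestamp"])
    for bear, wins in window_fn(ev).items():
        sel = df["bear_id"] == bear
        ts = df.loc[sel, "timestamp"]
        m = pd.Series(False, index=ts.index)
        for lo, hi in wins:
            m |= (ts >= lo) & (ts < hi)
        mask.loc[sel] = m
    return mask


def _release_windows(ev: pd.DataFrame) -> dict:
    out: dict = {}
    width = pd.Timedelta(hours=POST_RELEASE_EXCLUSION_H)
    for _, row in ev[ev["event"] == "release"].iterrows():
        out.setdefault(row["bear_id"], []).append((row["timestamp"], row["timestamp"] + width))
    return out


def _translocation_windows(ev: pd.DataFrame) -> dict:
    out: dict = {}
    for bear, grp in ev.groupby("bear_id"):
        grp = grp.sort_values("timestamp")
        open_t = None
        wins = []
        for _, row in grp.iterrows():
            if row["event"] == "translocation_out":
                open_t = row["timestamp"]
            elif row["event"] == "translocation_return" and open_t is not None:
                wins.append((open_t, row["timestamp"]))
                open_t = None
        if open_t is not None:  # never returned: exclude to the end of time
            wins.append((open_t, pd.Timestamp.max))
        if wins:
            out[bear] = wins
    return out


def assign_seasons(locs: pd.DataFrame, cal: SeasonCalendar | None = None) -> pd.DataFrame:
    """Label each fix with its season; fixes outside both windows get ``"none"``."""
    cal = cal or SeasonCalendar()
    df = locs.copy()
    df["timestamp"] = _as_timestamp(df["timestamp"])
    dates = df["timestamp"].dt.date
    df["season"] = [cal.season_of(d) for d in dates]
    df["year"] = df["timestamp"].dt.year
    return df


def coverage_filter(
    locs: pd.DataFrame, cal: SeasonCalendar | None = None
) -> pd.DataFrame:
    """Eligible (bear_id, year, season) combinations under the 90% span rule.

    A bear-season is eligible when the inclusive calendar span from first to
    last retained fix covers at least ``cal.coverage_threshold`` of the
    season duration.  Returns a table with the span diagnostics so the
    decision is auditable.
    """
    cal = cal or SeasonCalendar()
    df = locs[locs["season"].isin(["pre_hyperphagia", "hyperphagia"])]
    rows = []
    for (bear, year, season), grp in df.groupby(["bear_id", "year", "season"]):
        dates = grp["timestamp"].dt.date
        span = (dates.max() - dates.min()).days + 1
        length = cal.season_length_days(season, int(year))
        frac = span / length
        rows.append(
            dict(bear_id=bear, year=int(year), season=season,
                 span_days=span, season_days=length, coverage=frac,
                 eligible=frac >= cal.coverage_threshold)
        )
    out = pd.DataFrame(rows, columns=["bear_id", "year", "season", "span_days",
                                      "season_days", "coverage", "eligible"])
    return out.sort_values(["bear_id", "year", "season"]).reset_index(drop=True)
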