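"""Synthetic data generator for an urban bear telemetry study.

Emulates the data streams of a multi-year GPS-collar study of black bears
around a small mountain town: an address/structure point layer whose density
peaks in the urban core, 30-minute GPS tracks whose attraction switches
between the urban core and a wildland range with natural-food conditions,
5-minute head-movement activity counts following seasonal diel templates,
and capture/fate/litter records with staggered entry and censoring.

All randomness descends from a single seed through
:class:`numpy.random.SeedSequence` spawning, one child stream per generator
and per bear-year, so any sub-stream is reproducible in isolation.

The movement model is a discrete-time biased random walk: each step pulls
the bear a fraction ``attraction`` of the way toward the active attractor
and adds isotropic Gaussian noise with scale ``step_sd_m``.  The active
attractor is the urban core during hyperphagia of poor natural-food years
and the wildland center otherwise, which reproduces the qualitative
good/poor contrast in urban use without claiming a mechanistic movement
model.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .telemetry import SeasonCalendar

# study-wide natural-food calendar (good mast vs. failure years)
DEFAULT_FOOD_YEARS = {2005: "good", 2006: "good", 2007: "poor",
                      2008: "good", 2009: "poor", 2010: "good"}

#: diel activity templates y = a*sin(b*x + c) + d per food year.  (b, c) are
#: (1.92, 1.57) in good years (crepuscular, two peaks) and (1.05, -1.32) in
#: poor years (nocturnal, one peak); amplitude and offset keep counts well
#: inside the sensor's 0-255 range.
DEFAULT_ACTIVITY_TEMPLATES = {
    "good": dict(a=50.0, b=1.92, c=1.57, d=80.0),
    "poor": dict(a=50.0, b=1.05, c=-1.32, d=80.0),
}


@dataclass
class Landscape:
    """Point layers of a small urban area embedded in wildland."""

    address_points: np.ndarray          # (n, 2) planar meters
    structure_points: np.ndarray        # (m, 2) planar meters
    urban_center: tuple[float, float]
    wildland_center: tuple[float, float]
    extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax

    def address_density(self, xy: np.ndarray, radius_m: float = 564.19) -> np.ndarray:
        """Moving-window address density (per km^2) at query points."""
        from scipy.spatial import cKDTree

        xy = np.atleast_2d(xy)
        if len(self.address_points) == 0:
            return np.zeros(len(xy))
        tree = cKDTree(self.address_points)
        counts = tree.query_ball_point(xy, r=radius_m, return_length=True)
        return counts / (np.pi * (radius_m / 1000.0) ** 2)


@dataclass
class BearSpec:
    bear_id: str
    gender: str                   # "M" or "F"
    age: int                      # years at first monitored year, >= 1
    years_monitored: list = field(default_factory=list)  # [(year, "good"|"poor")]

    def __post_init__(self):
        if self.age < 1:
            raise ValueError("bear age must be >= 1 year")
        if self.gender not in ("M", "F"):
            raise ValueError("gender must be 'M' or 'F'")


@dataclass
class SimConfig:
    """Tunable parameters of all four generators (planar meters, intervals)."""

    seed: int = 0
    extent_km: float = 10.0                 # square landscape side
    max_address_density: float = 865.0      # per km^2 at the urban core
    address_scale_m: float = 900.0          # Gaussian decay scale of density
    structure_fraction: float = 0.8         # structures per address point
    urban_center: tuple[float, float] = (3000.0, 3000.0)
    wildland_center: tuple[float, float] = (7500.0, 7500.0)

    step_sd_m: float = 300.0
    attraction: float = 0.12                # per-step pull toward attractor
    urban_attraction_poor_hyperphagia: bool = True

    fix_interval_min: int = 30
    screening_fail_fraction: float = 0.11   # fixes violating the PDOP rule
    frac_3d: float = 0.85                   # dimension mix among clean fixes

    activity_interval_min: int = 5
    activity_templates: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ACTIVITY_TEMPLATES.items()})
    activity_noise_sd: float = 12.0

    # per bi-monthly-interval hazard and censoring by food year
    interval_hazard: dict = field(default_factory=lambda: {"good": 0.0002, "poor": 0.02})
    interval_censor_prob: float = 0.01
    litter_mean: dict = field(default_factory=lambda: {"good": 2.4, "poor": 2.0})

    def validate(self) -> None:
        if self.extent_km <= 0 or self.extent_km ** 2 < 4.0:
            raise ValueError("landscape extent must cover at least 4 km^2")
        for p in (self.screening_fail_fraction, self.frac_3d,
                  self.interval_censor_prob, self.structure_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for fy, h in self.interval_hazard.items():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"interval hazard for {fy!r} outside [0, 1]")
        for fy, t in self.activity_templates.items():
            if not (0 <= t["a"] <= 255 and 0 <= t["b"] <= 5
                    and -np.pi / 2 <= t["c"] <= np.pi / 2 and 0 <= t["d"] <= 255):
                raise ValueError(f"activity template for {fy!r} outside sine-fit bounds")
            if t["d"] - t["a"] < 0 or t["d"] + t["a"] > 255:
                raise ValueError(
                    f"template for {fy!r} pushes mean counts outside [0, 255]")


def _streams(config: SimConfig, label: str, n: int = 1):
    """Deterministic child RNG streams for one generator.

    Stream splitting: the study seed plus a CRC32 of the generator label
    keys a :class:`~numpy.random.SeedSequence`, which is spawned once per
    bear-year (or once for the landscape), so sub-streams never collide and
    are reproducible in isolation.
    """
    import zlib

    root = np.random.SeedSequence(config.seed, spawn_key=(zlib.crc32(label.encode()),))
    return [np.random.default_rng(s) for s in root.spawn(n)]


def gen_landscape(config: SimConfig) -> Landscape:
    """Sample the address/structure layers.

    Addresses follow an inhomogeneous Poisson process whose intensity decays
    as a Gaussian of distance from the urban core, with peak intensity
    ``max_address_density`` per km^2 — generated by thinning a homogeneous
    process at the ceiling rate, so the window density can never exceed the
    configured maximum in expectation.
    """
    config.validate()
    rng, = _streams(config, "landscape")
    side = config.extent_km * 1000.0
    extent = (0.0, 0.0, side, side)
    lam_max = config.max_address_density / 1e6  # per m^2
    n_cand = rng.poisson(lam_max * side * side)
    cand = rng.uniform(0.0, side, size=(n_cand, 2))
    d2 = np.sum((cand - np.asarray(config.urban_center)) ** 2, axis=1)
    accept = rng.random(n_cand) < np.exp(-d2 / (2.0 * config.address_scale_m ** 2))
    addresses = cand[accept]
    keep = rng.random(len(addresses)) < config.structure_fraction
    structures = addresses[keep]
    return Landscape(address_points=addresses, structure_points=structures,
                     urban_center=tuple(config.urban_center),
                     wildland_center=tuple(config.wildland_center), extent=extent)


def _season_times(year: int, interval_min: int, cal: SeasonCalendar) -> pd.DatetimeIndex:
    start = dt.datetime(year, *cal.pre_start)
    end = dt.datetime(year, *cal.hyper_end) + dt.timedelta(days=1)
    return pd.date_range(start, end, freq=f"{interval_min}min", inclusive="left")


def gen_tracks(
    landscape: Landscape,
    bears: list[BearSpec],
    config: SimConfig,
    cal: SeasonCalendar | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate GPS fixes for every monitored bear-year.

    Returns ``(locations, events)``: fixes every ``fix_interval_min`` from
    Apr 16 through Oct 15, each with a fix dimension and PDOP drawn so that
    ``screening_fail_fraction`` of fixes fail the PDOP screening rule, plus
    a release-event log (one release at the start of each first monitored
    year, so the 48-h exclusion is exercised).
    """
    config.validate()
    cal = cal or SeasonCalendar()
    rows, ev_rows = [], []
    streams = _streams(config, "tracks", max(1, sum(len(b.years_monitored) for b in bears)))
    k = 0
    for bear in bears:
        if not bear.years_monitored:
            import warnings

            warnings.warn(f"bear {bear.bear_id} has no monitored years; skipped")
            continue
        first_year = min(y for y, _ in bear.years_monitored)
        for year, foodyr in sorted(bear.years_monitored):
            rng = streams[k]
            k += 1
            times = _season_times(year, config.fix_interval_min, cal)
            n = len(times)
            xy = np.empty((n, 2))
            pos = np.asarray(landscape.wildland_center, dtype=float) + rng.normal(0, 500, 2)
            hyper_start = dt.date(year, *cal.hyper_start)
            urban = np.asarray(landscape.urban_center)
            wild = np.asarray(landscape.wildland_center)
            for i, t in enumerate(times):
                in_hyper = t.date() >= hyper_start
                pull_urban = (foodyr == "poor" and in_hyper
                              and config.urban_attraction_poor_hyperphagia)
                target = urban if pull_urban else wild
                pos = pos + config.attraction * (target - pos) + rng.normal(
                    0.0, config.step_sd_m, 2)
                xy[i] = pos
            dim, pdop = _sample_pdop(rng, n, config)
            if year == first_year:
                ev_rows.append(dict(bear_id=bear.bear_id, timestamp=times[0],
                                    event="release"))
            rows.append(pd.DataFrame(dict(
                bear_id=bear.bear_id, timestamp=times, x_m=xy[:, 0], y_m=xy[:, 1],
                fix_dim=dim, pdop=pdop)))
    locations = (pd.concat(rows, ignore_index=True) if rows
                 else pd.DataFrame(columns=["bear_id", "timestamp", "x_m", "y_m",
                                            "fix_dim", "pdop"]))
    events = pd.DataFrame(ev_rows, columns=["bear_id", "timestamp", "event"])
    return locations, events


def _sample_pdop(rng: np.random.Generator, n: int, config: SimConfig):
    """Two-component pass/fail PDOP mixture calibrated to the screening rule."""
    fail = rng.random(n) < config.screening_fail_fraction
    is3d = rng.random(n) < config.frac_3d
    dim = np.where(is3d, "3D", "2D")
    pdop = np.where(is3d, rng.uniform(1.0, 10.0, n), rng.uniform(1.0, 5.0, n))
    bad = np.where(is3d, rng.uniform(10.5, 20.0, n), rng.uniform(5.5, 15.0, n))
    pdop = np.where(fail, bad, pdop)
    return dim, np.round(pdop, 2)


def gen_activity(
    bears: list[BearSpec],
    config: SimConfig,
    cal: SeasonCalendar | None = None,
) -> pd.DataFrame:
    """Simulate head-movement counts at 5-min resolution.

    The expected count at clock time ``x`` (radians, midnight -> 0) is the
    food year's template ``a*sin(b*x + c) + d``; Gaussian noise is added,
    then counts are rounded and clipped to the sensor range 0-255.
    """
    config.validate()
    cal = cal or SeasonCalendar()
    rows = []
    streams = _streams(config, "activity", max(1, sum(len(b.years_monitored) for b in bears)))
    k = 0
    for bear in bears:
        for year, foodyr in sorted(bear.years_monitored):
            rng = streams[k]
            k += 1
            t = config.activity_templates[foodyr]
            times = _season_times(year, config.activity_interval_min, cal)
            minutes = times.hour * 60 + times.minute
            x = 2.0 * np.pi * minutes.to_numpy() / 1440.0
            mean = t["a"] * np.sin(t["b"] * x + t["c"]) + t["d"]
            noisy = mean + rng.normal(0.0, config.activity_noise_sd, len(times))
            counts = np.clip(np.rint(noisy), 0, 255).astype(int)
            rows.append(pd.DataFrame(dict(bear_id=bear.bear_id, timestamp=times,
                                          count=counts)))
    return (pd.concat(rows, ignore_index=True) if rows
            else pd.DataFrame(columns=["bear_id", "timestamp", "count"]))


def gen_demography(
    bears: list[BearSpec],
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate capture, fate, and litter tables.

    Per bear-year: staggered entry uniform over the 15 bi-monthly intervals,
    geometric time-to-death under the food year's per-interval hazard,
    independent per-interval censoring, and (for adult females) litters of
    1-3 cubs from a Poisson truncated to {1, 2, 3} with food-year-specific
    mean at conception.
    """
    config.validate()
    cap_rows, fate_rows, litter_rows = [], [], []
    streams = _streams(config, "demography", max(1, len(bears)))
    for bear, rng in zip(bears, streams):
        dead = False
        for year, foodyr in sorted(bear.years_monitored):
            if dead:
                break
            age = bear.age + (year - min(y for y, _ in bear.years_monitored))
            entry = int(rng.integers(1, 16))  # staggered entry interval 1..15
            cap_rows.append(dict(bear_id=bear.bear_id, year=year, gender=bear.gender,
                                 age=age, food_year=foodyr, entry_interval=entry))
            h = config.interval_hazard[foodyr]
            outcome, when = "survived", 15
            for interval in range(entry, 16):
                if rng.random() < config.interval_censor_prob:
                    outcome, when = "censored", interval
                    break
                if rng.random() < h:
                    outcome, when = "died", interval
                    dead = True
                    break
            fate_rows.append(dict(bear_id=bear.bear_id, year=year, outcome=outcome,
                                  interval=when))
            if bear.gender == "F" and age >= 3 and rng.random() < 0.4:
                mu = config.litter_mean[foodyr]
                litter_rows.append(dict(
                    bear_id=bear.bear_id, year=year,
                    sow_age_at_conception=age - 1, food_year_at_conception=foodyr,
                    litter_size=_truncated_poisson(rng, mu)))
    captures = pd.DataFrame(cap_rows, columns=["bear_id", "year", "gender", "age",
                                               "food_year", "entry_interval"])
    fates = pd.DataFrame(fate_rows, columns=["bear_id", "year", "outcome", "interval"])
    litters = pd.DataFrame(litter_rows, columns=["bear_id", "year",
                                                 "sow_age_at_conception",
                                                 "food_year_at_conception",
                                                 "litter_size"])
    return captures, fates, litters


def _truncated_poisson(rng: np.random.Generator, mean: float) -> int:
    from scipy import stats

    support = np.array([1, 2, 3])
    p = stats.poisson.pmf(support, mean)
    p = p / p.sum()
    return int(rng.choice(support, p=p))


# ---------------------------------------------------------------------------
# writers

def write_locations_csv(locations: pd.DataFrame, path) -> None:
    df = locations.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def write_activity_csv(activity: pd.DataFrame, path) -> None:
    df = activity.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def write_addresses_geojson(landscape: Landscape, path) -> None:
    features = [
        dict(type="Feature", geometry=dict(type="Point", coordinates=[float(x), float(y)]),
             properties={})
        for x, y in landscape.address_points
    ]
    with open(path, "w") as fh:
        json.dump(dict(type="FeatureCollection", features=features), fh)


def write_demography_csvs(captures, fates, litters, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    captures.to_csv(outdir / "captures.csv", index=False)
    fates.to_csv(outdir / "fates.csv", index=False)
    litters.to_csv(outdir / "litters.csv", index=False)
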