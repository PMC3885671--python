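"""Config-driven end-to-end analysis runner.

Orchestrates the full study flow on synthetic (or user-supplied) data:
simulate -> screen GPS fixes -> assign seasons and apply the 90% coverage
rule -> plug-in-bandwidth kernel home ranges with the three urbanization
responses -> diel sine fits -> AICc model averaging for the five responses
(ln Area, ln HDoverlap, ln HDdensity, b, c) -> known-fate survival and the
litter GLM.  Every output is a plain-text table (CSV / GeoJSON / MARK .inp)
plus a manifest recording the seed and a config hash, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import fit_table as sine_fit_table
from .homerange import estimate_home_range, home_range_geojson
from .models import run_model_selection
from .synthetic import (BearSpec, SimConfig, DEFAULT_FOOD_YEARS, gen_activity,
                        gen_demography, gen_landscape, gen_tracks,
                        write_activity_csv, write_addresses_geojson,
                        write_demography_csvs, write_locations_csv)
from .survival import (build_encounter_histories, fit_survival_models,
                       fit_litter_glm, litter_summary, write_mark_inp)
from .telemetry import SeasonCalendar, assign_seasons, coverage_filter, screen_locations

log = logging.getLogger("urbanbear")

RESPONSES = (  # (column, log-transform)
    ("area_km2", True),
    ("hd_overlap_km2", True),
    ("hd_density_mean", True),
    ("b", False),
    ("c", False),
)


@dataclass
class RunConfig:
    """End-to-end run parameters (synthetic study by default)."""

    seed: int = 0
    n_bears: int = 10
    years: list = field(default_factory=lambda: [2007, 2008, 2009])
    food_years: dict = field(default_factory=lambda: dict(DEFAULT_FOOD_YEARS))
    fix_interval_min: int = 60
    activity_interval_min: int = 5
    grid_size: int = 150
    isopleth_level: float = 0.95
    coverage_threshold: float = 0.9
    min_fixes: int = 30
    sim: dict = field(default_factory=dict)   # extra SimConfig overrides
    outdir: str = "urbanbear_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "food_years" in raw:
            raw["food_years"] = {int(k): v for k, v in raw["food_years"].items()}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def make_study(config: RunConfig):
    """Build the synthetic study population and all four data streams."""
    sim = SimConfig(seed=config.seed,
                    fix_interval_min=config.fix_interval_min,
                    activity_interval_min=config.activity_interval_min,
                    **config.sim)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(99,)))
    bears = []
    for i in range(config.n_bears):
        n_years = int(rng.integers(1, len(config.years) + 1))
        start = int(rng.integers(0, len(config.years) - n_years + 1))
        years = config.years[start:start + n_years]
        bears.append(BearSpec(
            bear_id=f"B{i:02d}", gender="M" if rng.random() < 0.5 else "F",
            age=int(rng.integers(1, 12)),
            years_monitored=[(y, config.food_years[y]) for y in years]))
    landscape = gen_landscape(sim)
    locations, events = gen_tracks(landscape, bears, sim)
    activity = gen_activity(bears, sim)
    captures, fates, litters = gen_demography(bears, sim)
    return dict(sim=sim, bears=bears, landscape=landscape, locations=locations,
                events=events, activity=activity, captures=captures,
                fates=fates, litters=litters)


def bear_covariates(bears) -> pd.DataFrame:
    rows = []
    for b in bears:
        first = min(y for y, _ in b.years_monitored)
        for year, fy in b.years_monitored:
            rows.append(dict(bear_id=b.bear_id, year=year, gender=b.gender,
                             age=b.age + (year - first), foodyr=fy))
    return pd.DataFrame(rows)


def run_all(config: RunConfig, study: dict | None = None) -> dict:
    """Execute every stage and write the report bundle to ``config.outdir``.

    Returns a dict of in-memory results.  A stage failure raises after
    already-produced outputs are flushed, with the stage named.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cal = SeasonCalendar(coverage_threshold=config.coverage_threshold)
    results: dict = {}
    stage = "simulate"
    try:
        study = study or make_study(config)
        write_locations_csv(study["locations"], out / "locations.csv")
        write_activity_csv(study["activity"], out / "activity.csv")
        write_addresses_geojson(study["landscape"], out / "addresses.geojson")
        write_demography_csvs(study["captures"], study["fates"], study["litters"], out)
        covars = bear_covariates(study["bears"])

        stage = "screen"
        screened, report = screen_locations(study["locations"], study["events"])
        report.per_bear.to_csv(out / "screening_report.csv", index=False)
        log.info("screening: %d -> %d fixes (%.1f%% removed)", report.n_input,
                 report.n_retained, 100 * report.fraction_removed)
        labeled = assign_seasons(screened, cal)
        eligibility = coverage_filter(labeled, cal)
        eligibility.to_csv(out / "eligibility.csv", index=False)
        results["screening"] = report
        results["eligibility"] = eligibility

        stage = "homerange"
        hr_rows, geo_recs = [], []
        for _, row in eligibility[eligibility["eligible"]].iterrows():
            sel = labeled[(labeled["bear_id"] == row["bear_id"])
                          & (labeled["year"] == row["year"])
                          & (labeled["season"] == row["season"])]
            pts = sel[["x_m", "y_m"]].to_numpy()
            if len(pts) < config.min_fixes:
                continue
            hr, _surf = estimate_home_range(pts, study["landscape"],
                                            level=config.isopleth_level,
                                            grid_size=config.grid_size)
            rec = dict(bear_id=row["bear_id"], year=int(row["year"]),
                       season=row["season"], n_fixes=len(pts),
                       area_km2=hr.area_km2, hd_overlap_km2=hr.hd_overlap_km2,
                       hd_density_mean=hr.hd_density_mean)
            hr_rows.append(rec)
            geo_recs.append(dict(geometry=hr.polygons, **rec))
        hr_metrics_df = pd.DataFrame(hr_rows)
        hr_metrics_df.to_csv(out / "hr_metrics.csv", index=False)
        with open(out / "home_ranges.geojson", "w") as fh:
            json.dump(home_range_geojson(geo_recs), fh)
        results["hr_metrics"] = hr_metrics_df
        log.info("homerange: %d bear-seasons", len(hr_metrics_df))

        stage = "activity"
        sine = sine_fit_table(study["activity"], cal)
        sine.to_csv(out / "sine_fits.csv", index=False)
        results["sine_fits"] = sine

        stage = "models"
        space = hr_metrics_df.merge(
            covars.rename(columns={"year": "year"}), on=["bear_id", "year"])
        space["season"] = space["season"].astype(str)
        act = sine.merge(covars, on=["bear_id", "year"])
        results["model_tables"] = {}
        for col, do_log in RESPONSES:
            tab = space if col in space.columns else act
            if col not in tab.columns or len(tab) < 12 or tab["bear_id"].nunique() < 2:
                warnings.warn(f"too few observations to model {col}; skipped")
                continue
            avg, mset, _fits = run_model_selection(tab, col, log_transform=do_log)
            name = f"ln_{col}" if do_log else col
            avg.to_csv(out / f"model_avg_{name}.csv", index=False)
            mset.to_csv(out / f"model_set_{name}.csv", index=False)
            results["model_tables"][name] = (avg, mset)

        stage = "survival"
        histories = build_encounter_histories(study["captures"], study["fates"])
        write_mark_inp(histories, out / "encounter_histories.inp")
        fits, surv_table = fit_survival_models(histories)
        surv_table.to_csv(out / "survival_table.csv", index=False)
        results["survival"] = surv_table

        stage = "reproduction"
        if len(study["litters"]) >= 5:
            coef, means = fit_litter_glm(study["litters"])
            coef.to_csv(out / "litter_glm.csv", index=False)
            means.to_csv(out / "litter_means.csv", index=False)
            results["litter_glm"] = coef
        results["litter_summary"] = litter_summary(study["litters"])
        with open(out / "litter_summary.json", "w") as fh:
            json.dump(results["litter_summary"], fh, indent=1)

        stage = "manifest"
        manifest = dict(seed=config.seed, config_hash=config.config_hash(),
                        version=__version__,
                        n_bears=config.n_bears, years=config.years)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        results["manifest"] = manifest
    except Exception as exc:  # partial outputs stay on disk for debugging
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
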