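"""Known-fate survival on bi-monthly encounter histories, and litter-size GLM.

Radio-monitored bears have known status in every interval they are at risk,
so survival is a product of conditional interval survivals.  Each study
year is split into 15 bi-monthly intervals from Apr 16 to Nov 30 (the 1st
to the 15th and the 16th to month end); survival through the denning period
(Dec 1 - Apr 15) is fixed at 1.  Bears enter at the interval of capture
(staggered entry), are censored when collars drop or the bear leaves the
study area, and may re-enter on recapture or return.

Interval survival is modeled on the logit scale with covariates gender,
age class (subadult 1-3 vs. adult >= 4), season, food year, and the
season-by-food-year interaction.  The likelihood is the standard known-fate
form: at-risk intervals contribute ln S_i when the animal survives and
ln(1 - S_i) in its death interval; censored intervals contribute nothing.
The candidate set mirrors the space-use analysis (all additive subsets plus
the marginality-respecting interaction, 20 models), ranked by AICc, and
annual survival per gender x age-class x food-year profile is the product
of the 15 interval survivals, model-averaged with unconditional SEs.
"""

from __future__ import annotations

import calendar as _calendar
import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .models import ModelSpec, aicc, akaike_weights, enumerate_models

N_INTERVALS = 15
CODES = ("not_entered", "alive_alive", "alive_dead", "censored")


def interval_calendar(year: int = 2005) -> list[tuple[dt.date, dt.date]]:
    """The 15 bi-monthly intervals (Apr 16 - Nov 30), inclusive endpoints."""
    out = [(dt.date(year, 4, 16), dt.date(year, 4, 30))]
    for month in range(5, 12):
        last = _calendar.monthrange(year, month)[1]
        out.append((dt.date(year, month, 1), dt.date(year, month, 15)))
        out.append((dt.date(year, month, 16), dt.date(year, month, last)))
    return out


def interval_of(date: dt.date) -> int | None:
    """1-based interval index containing a date, or None during denning."""
    for i, (lo, hi) in enumerate(interval_calendar(date.year), start=1):
        if lo <= date <= hi:
            return i
    return None


def interval_season(i: int) -> str:
    """Season label of interval i: pre-hyperphagia through Jul 31, then
    hyperphagia (including the post-Oct-15 pre-denning intervals)."""
    start, _ = interval_calendar(2005)[i - 1]
    return "pre_hyperphagia" if start <= dt.date(2005, 7, 31) else "hyperphagia"


def age_class(age: int) -> str:
    return "subadult" if age <= 3 else "adult"


@dataclass
class EncounterHistory:
    """One bear-year: 15 interval codes plus year-level covariates."""

    bear_id: str
    year: int
    codes: list            # length 15, values in CODES
    gender: str
    age: int
    food_year: str

    def __post_init__(self):
        if len(self.codes) != N_INTERVALS:
            raise ValueError(f"encounter history must have {N_INTERVALS} intervals")
        bad = [c for c in self.codes if c not in CODES]
        if bad:
            raise ValueError(f"unknown interval codes: {bad}")
        deaths = [i for i, c in enumerate(self.codes) if c == "alive_dead"]
        if len(deaths) > 1:
            raise ValueError("at most one death per history")
        if deaths and any(c != "not_entered" for c in self.codes[deaths[0] + 1:]):
            raise ValueError("codes after the death interval must be not_entered")

    @property
    def age_class(self) -> str:
        return age_class(self.age)


def build_encounter_histories(
    captures: pd.DataFrame,
    fates: pd.DataFrame,
) -> list[EncounterHistory]:
    """Assemble per-bear-year histories from capture and fate tables.

    ``captures``: bear_id, year, gender, age, food_year, and either
    ``entry_interval`` (1-15) or ``capture_date``.  ``fates``: bear_id,
    year, outcome in {survived, died, censored}, and ``interval`` or
    ``date``; additional rows with outcome ``reentered`` put the bear back
    at risk (recapture or return from translocation).
    """
    fates = fates.copy()
    histories = []
    for _, cap in captures.iterrows():
        entry = _event_interval(cap, "entry_interval", "capture_date")
        codes = ["not_entered"] * N_INTERVALS
        sub = fates[(fates["bear_id"] == cap["bear_id"])
                    & (fates["year"] == cap["year"])]
        events = []
        for _, f in sub.iterrows():
            if f["outcome"] == "survived":
                continue
            events.append((_event_interval(f, "interval", "date"), f["outcome"]))
        events.sort()
        at_risk, i = True, entry
        for when, what in events:
            if what == "died" and when < entry:
                raise ValueError(
                    f"{cap['bear_id']} {cap['year']}: death interval {when} "
                    f"precedes entry interval {entry}")
            if what == "reentered":
                if not at_risk:  # gap intervals stay not_entered
                    i, at_risk = when, True
                continue
            if not at_risk:
                continue
            for j in range(i, when):
                codes[j - 1] = "alive_alive"
            if what == "died":
                codes[when - 1] = "alive_dead"
                at_risk = False
                i = N_INTERVALS + 1
            elif what == "censored":
                codes[when - 1] = "censored"
                at_risk = False
                i = when + 1
        if at_risk:
            for j in range(i, N_INTERVALS + 1):
                codes[j - 1] = "alive_alive"
        histories.append(EncounterHistory(
            bear_id=cap["bear_id"], year=int(cap["year"]), codes=codes,
            gender=cap["gender"], age=int(cap["age"]), food_year=cap["food_year"]))
    return histories


def _event_interval(row, int_col: str, date_col: str) -> int:
    if int_col in row.index and not pd.isna(row.get(int_col)):
        return int(row[int_col])
    date = pd.to_datetime(row[date_col]).date()
    i = interval_of(date)
    if i is None:
        raise ValueError(f"date {date} falls in the denning period")
    return i


# ---------------------------------------------------------------------------
# likelihood and model fitting

SURV_CANDIDATES = ("gender", "age_class", "season", "foodyr")


def exposure_table(histories: list[EncounterHistory]) -> pd.DataFrame:
    """One row per at-risk bear-interval: covariates + survival indicator."""
    rows = []
    for h in histories:
        for i, code in enumerate(h.codes, start=1):
            if code not in ("alive_alive", "alive_dead"):
                continue
            rows.append(dict(bear_id=h.bear_id, year=h.year, interval=i,
                             gender=h.gender, age_class=h.age_class,
                             season=interval_season(i), foodyr=h.food_year,
                             survived=int(code == "alive_alive")))
    return pd.DataFrame(rows, columns=["bear_id", "year", "interval", "gender",
                                       "age_class", "season", "foodyr", "survived"])


def _surv_design(table: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table))]
    names = ["Intercept"]
    coding = {
        "gender": ("gender", "M", "gender[M]"),
        "age_class": ("age_class", "adult", "age_class[adult]"),
        "season": ("season", "pre_hyperphagia", "season[pre_hyperphagia]"),
        "foodyr": ("foodyr", "good", "foodyr[good]"),
    }
    for term in spec.terms:
        col, ref, label = coding[term]
        cols.append((table[col] == ref).to_numpy(dtype=float))
        names.append(label)
    if spec.interaction:
        s = (table["season"] == "pre_hyperphagia").to_numpy(dtype=float)
        f = (table["foodyr"] == "good").to_numpy(dtype=float)
        cols.append(s * f)
        names.append("season[pre_hyperphagia]:foodyr[good]")
    return np.column_stack(cols), names


def known_fate_loglik(beta: np.ndarray, X: np.ndarray, survived: np.ndarray) -> float:
    """Known-fate log likelihood: sum of ln S_i over survivals and ln(1 - S_i)
    over death intervals, with S_i = expit(x_i' beta)."""
    eta = X @ beta
    # log S = -log(1 + e^-eta); log(1 - S) = -eta - log(1 + e^-eta)
    log_s = -np.logaddexp(0.0, -eta)
    log_q = -eta + log_s
    return float(np.sum(np.where(survived == 1, log_s, log_q)))


@dataclass
class SurvivalFit:
    spec: ModelSpec
    names: list
    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    k: int
    n: int
    aicc: float
    boundary: bool
    converged: bool
    weight: float = np.nan


def fit_known_fate(spec: ModelSpec, table: pd.DataFrame,
                   max_iter: int = 100, tol: float = 1e-10) -> SurvivalFit:
    """Newton-Raphson ML fit of the known-fate (Bernoulli-logit) model.

    Data with no deaths are separable: the intercept runs to the S = 1
    boundary.  Iteration is capped and the fit flagged ``boundary`` so the
    MLE (interval survival 1) is still usable downstream.
    """
    X, names = _surv_design(table, spec)
    y = table["survived"].to_numpy(dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        mu = expit(X @ beta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * w[:, None]) + 1e-12 * np.eye(p)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 30:  # separation: survival at the boundary
            break
    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    hess = X.T @ (X * w[:, None])
    try:
        vcov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        vcov = np.full((p, p), np.nan)
    boundary = bool(np.max(np.abs(beta)) >= 30) or y.min() == 1.0
    ll = known_fate_loglik(beta, X, y)
    return SurvivalFit(spec=spec, names=names, beta=beta, vcov=vcov, loglik=ll,
                       k=p, n=n, aicc=aicc(ll, p, n), boundary=boundary,
                       converged=converged or boundary)


def _profile_design(fit: SurvivalFit, profile: dict) -> np.ndarray:
    """15 x p design for one covariate profile, season varying by interval."""
    rows = []
    for i in range(1, N_INTERVALS + 1):
        x = []
        for name in fit.names:
            if name == "Intercept":
                x.append(1.0)
            elif name == "gender[M]":
                x.append(float(profile["gender"] == "M"))
            elif name == "age_class[adult]":
                x.append(float(profile["age_class"] == "adult"))
            elif name == "season[pre_hyperphagia]":
                x.append(float(interval_season(i) == "pre_hyperphagia"))
            elif name == "foodyr[good]":
                x.append(float(profile["food_year"] == "good"))
            elif name == "season[pre_hyperphagia]:foodyr[good]":
                x.append(float(interval_season(i) == "pre_hyperphagia")
                         * float(profile["food_year"] == "good"))
            else:
                raise ValueError(f"unknown design column {name}")
        rows.append(x)
    return np.asarray(rows)


def model_annual_survival(fit: SurvivalFit, profile: dict) -> tuple[float, float]:
    """Annual survival (product of 15 interval survivals; denning = 1) and
    its delta-method SE on the log scale, for one model and profile."""
    Xp = _profile_design(fit, profile)
    s = expit(Xp @ fit.beta)
    annual = float(np.prod(s))
    grad = ((1.0 - s)[:, None] * Xp).sum(axis=0)  # d ln(annual) / d beta
    var_log = float(grad @ fit.vcov @ grad)
    se = annual * np.sqrt(max(var_log, 0.0)) if np.isfinite(var_log) else np.nan
    return annual, se


def fit_survival_models(
    histories: list[EncounterHistory],
    candidates: tuple[str, ...] = SURV_CANDIDATES,
    interaction: tuple[str, str] | None = ("season", "foodyr"),
) -> tuple[list[SurvivalFit], pd.DataFrame]:
    """Fit the full known-fate candidate set and model-average annual survival.

    Returns ``(fits, table)`` where ``table`` has one row per gender x
    age-class x food-year profile with the unconditional (model-averaged)
    annual survival estimate and SE.  Non-finite fits are dropped with a
    warning and weights renormalized.
    """
    table = exposure_table(histories)
    if len(table) == 0:
        raise ValueError("no at-risk exposures in the encounter histories")
    fits = []
    for spec in enumerate_models(candidates, interaction, response="survival"):
        fit = fit_known_fate(spec, table)
        if np.isfinite(fit.loglik):
            fits.append(fit)
        else:
            warnings.warn(f"model {spec.name} failed to fit; dropped")
    w = akaike_weights(np.array([f.aicc for f in fits]))
    for f, wi in zip(fits, w):
        f.weight = float(wi)

    food_years = sorted(table["foodyr"].unique())
    rows = []
    for gender in ("M", "F"):
        for ac in ("subadult", "adult"):
            for fy in food_years:
                profile = dict(gender=gender, age_class=ac, food_year=fy)
                est = np.array([model_annual_survival(f, profile) for f in fits])
                s, se = est[:, 0], est[:, 1]
                sbar = float(np.sum(w * s))
                se_u = float(np.sum(
                    w * np.sqrt(np.nan_to_num(se) ** 2 + (s - sbar) ** 2)))
                rows.append(dict(gender=gender, age_class=ac, food_year=fy,
                                 annual_survival=sbar, unconditional_se=se_u))
    return fits, pd.DataFrame(rows)


def annual_survival(
    interval_estimates, profile: dict | None = None, cov: np.ndarray | None = None
) -> tuple[float, float]:
    """Annual survival from 15 interval survivals with a delta-method SE.

    ``interval_estimates`` is either a length-15 array of interval survivals
    or a mapping from profile key ``(gender, age_class, food_year)`` to such
    an array (then ``profile`` selects the cell; a missing cell raises an
    error naming it).  ``cov`` is the 15 x 15 covariance of the interval
    estimates (zeros assumed when omitted); the SE propagates through
    ln(annual) = sum ln S_i.
    """
    if isinstance(interval_estimates, dict):
        if profile is None:
            raise ValueError("profile required with a per-cell mapping")
        key = (profile["gender"], profile["age_class"], profile["food_year"])
        if key not in interval_estimates:
            raise KeyError(f"no interval estimates for profile cell {key}")
        interval_estimates = interval_estimates[key]
    s = np.asarray(interval_estimates, dtype=float)
    if len(s) != N_INTERVALS:
        raise ValueError(f"need {N_INTERVALS} interval survivals")
    if np.any(s <= 0):
        raise ValueError("interval survival estimates must be positive")
    annual = float(np.prod(s))
    if cov is None:
        return annual, 0.0
    grad = 1.0 / s
    var_log = float(grad @ np.asarray(cov) @ grad)
    return annual, annual * np.sqrt(max(var_log, 0.0))


# ---------------------------------------------------------------------------
# reproduction

def fit_litter_glm(litters: pd.DataFrame):
    """Poisson log-link GLM of litter size on sow age and food year at
    conception; also reports raw mean litter size by food year.

    Returns ``(coefficients_table, means_by_food_year)``.  With a single
    food-year level the term is dropped with a warning.
    """
    import statsmodels.api as sm

    df = litters.copy()
    if (df["litter_size"] < 1).any():
        raise ValueError("litter sizes must be >= 1")
    y = df["litter_size"].to_numpy(dtype=float)
    cols = [np.ones(len(df)), df["sow_age_at_conception"].to_numpy(dtype=float)]
    names = ["Intercept", "sow_age"]
    if df["food_year_at_conception"].nunique() > 1:
        cols.append((df["food_year_at_conception"] == "good").to_numpy(dtype=float))
        names.append("food_year[good]")
    else:
        warnings.warn("single food-year level: food-year term dropped")
    X = np.column_stack(cols)
    fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    coef = pd.DataFrame(dict(term=names, estimate=fit.params, se=fit.bse))
    means = (df.groupby("food_year_at_conception")["litter_size"]
             .agg(["mean", "sem", "count"]).reset_index())
    return coef, means


def litter_summary(litters: pd.DataFrame) -> dict:
    """Overall litter count, cub total, and mean litter size (2 decimals)."""
    n = len(litters)
    cubs = int(litters["litter_size"].sum())
    mean = cubs / n if n else np.nan
    sem = float(litters["litter_size"].sem()) if n > 1 else np.nan
    return dict(n_litters=n, n_cubs=cubs, mean_litter_size=round(mean, 2),
                sem=round(sem, 2) if np.isfinite(sem) else sem)


# ---------------------------------------------------------------------------
# MARK interoperability

_LD = {"alive_alive": "10", "alive_dead": "11",
       "censored": "00", "not_entered": "00"}


def write_mark_inp(histories: list[EncounterHistory], path) -> None:
    """Known-fate LDLD input: one row per bear-year, 15 LD pairs, one
    frequency column per gender x age-class x food-year group."""
    groups = sorted({(h.gender, h.age_class, h.food_year) for h in histories})
    with open(path, "w") as fh:
        fh.write("/* known-fate LDLD; groups: "
                 + ", ".join("_".join(g) for g in groups) + " */\n")
        for h in histories:
            ld = "".join(_LD[c] for c in h.codes)
            freq = " ".join(
                "1" if (h.gender, h.age_class, h.food_year) == g else "0"
                for g in groups)
            fh.write(f"/* {h.bear_id} {h.year} age {h.age} */ {ld} {freq};\n")


def read_mark_inp(path) -> list[EncounterHistory]:
    """Inverse of :func:`write_mark_inp` under its 00-run convention: a
    00-run following an alive code is a censoring at its first interval."""
    histories = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    header = lines[0]
    groups = [tuple(g.split("_"))
              for g in header.split("groups:")[1].split("*/")[0].strip().split(", ")]
    for ln in lines[1:]:
        comment = ln.split("/*")[1].split("*/")[0].split()
        bear_id, year, age = comment[0], int(comment[1]), int(comment[3])
        rest = ln.split("*/")[1].strip().rstrip(";").split()
        ld, freq = rest[0], [int(v) for v in rest[1:]]
        gender, _, food_year = groups[freq.index(1)]
        pairs = [ld[2 * i:2 * i + 2] for i in range(N_INTERVALS)]
        codes, seen_alive = [], False
        for i, p in enumerate(pairs):
            if p == "10":
                codes.append("alive_alive")
                seen_alive = True
            elif p == "11":
                codes.append("alive_dead")
                seen_alive = False
            else:
                prev_alive = seen_alive and codes and codes[-1] == "alive_alive"
                codes.append("censored" if prev_alive else "not_entered")
                seen_alive = seen_alive and not prev_alive
        histories.append(EncounterHistory(bear_id=bear_id, year=year, codes=codes,
                                          gender=gender, age=age,
                                          food_year=food_year))
    return histories
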