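"""All-subsets mixed-effects modeling with AICc ranking and model averaging.

Each space-use or activity response is modeled against bear gender, age
(continuous), season, food year, and the season-by-food-year interaction,
with a random intercept per bear.  All additive subsets of the four main
effects (2^4 = 16) plus the interaction added to every subset containing
both parents (4 more) give 20 candidate models.  Models are fitted by
maximum likelihood (not REML — likelihoods must be comparable across fixed
effects), ranked by AICc with k counting fixed effects plus the two
variance parameters, and parameter estimates are model-averaged over the
full set with Akaike weights (coefficients set to zero in models that omit
the term), with unconditional standard errors in the Burnham-Anderson form

    SE(beta_bar) = sum_m w_m * sqrt(var_m + (beta_m - beta_bar)^2).

Model fit is summarized as the squared correlation between fitted and
observed values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

DEFAULT_CANDIDATES = ("gender", "age", "season", "foodyr")
DEFAULT_INTERACTION = ("season", "foodyr")
Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class ModelSpec:
    response: str
    terms: tuple[str, ...]            # main-effect terms, spec order
    interaction: bool = False         # include season:foodyr

    def formula_terms(self) -> list[str]:
        out = list(self.terms)
        if self.interaction:
            out.append("season:foodyr")
        return out

    @property
    def name(self) -> str:
        return " + ".join(self.formula_terms()) or "1"


@dataclass
class FitResult:
    spec: ModelSpec
    params: dict                       # term -> estimate (design-column names)
    se: dict
    loglik: float
    k: int
    n: int
    aicc: float
    r2: float
    boundary: bool = False             # random-intercept variance at zero
    weight: float = np.nan
    delta: float = np.nan


def enumerate_models(
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES,
    interaction: tuple[str, str] | None = DEFAULT_INTERACTION,
    response: str = "y",
) -> list[ModelSpec]:
    """All additive subsets, plus interaction models respecting marginality.

    With the default four candidates and one two-way interaction this yields
    exactly 20 specifications in a deterministic order (by size, then by
    candidate order, additive before interaction).
    """
    specs = []
    for size in range(len(candidates) + 1):
        for combo in combinations(candidates, size):
            specs.append(ModelSpec(response=response, terms=combo))
            if interaction and set(interaction) <= set(combo):
                specs.append(ModelSpec(response=response, terms=combo,
                                       interaction=True))
    return specs


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; infinite when n <= k + 1."""
    if n <= k + 1:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _design(table: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table))]
    names = ["Intercept"]
    coding = {
        "gender": ("gender", "M", "gender[M]"),
        "season": ("season", "pre_hyperphagia", "season[pre_hyperphagia]"),
        "foodyr": ("foodyr", "good", "foodyr[good]"),
    }
    for term in spec.terms:
        if term == "age":
            cols.append(table["age"].to_numpy(dtype=float))
            names.append("age")
        else:
            col, ref, label = coding[term]
            cols.append((table[col] == ref).to_numpy(dtype=float))
            names.append(label)
    if spec.interaction:
        s = (table["season"] == "pre_hyperphagia").to_numpy(dtype=float)
        f = (table["foodyr"] == "good").to_numpy(dtype=float)
        cols.append(s * f)
        names.append("season[pre_hyperphagia]:foodyr[good]")
    return np.column_stack(cols), names


def _profiled_ml(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """Exact ML fit of a random-intercept model by profiling.

    With V(lam) = I + lam * 1 1' block-diagonal per group (lam the ratio of
    random-intercept to residual variance), beta and the residual variance
    have closed GLS forms given lam, so the ML problem reduces to a 1-D
    search over lam >= 0.  The Woodbury identity gives
    V_g^-1 = I - lam / (1 + n_g lam) * J and log|V_g| = log(1 + n_g lam),
    so each profile evaluation is O(n p^2).  This is deterministic, handles
    the lam = 0 boundary exactly (where the fit is ordinary least squares),
    and its log likelihood is invariant to shifting the response.
    """
    n, p = X.shape
    idx = {g: np.flatnonzero(groups == g) for g in pd.unique(groups)}
    pre = []
    for g, ii in idx.items():
        Xg, yg = X[ii], y[ii]
        pre.append((len(ii), Xg.T @ Xg, Xg.T @ yg, float(yg @ yg),
                    Xg.sum(axis=0), float(yg.sum()), ii))

    def profile(lam: float):
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        ytvy = 0.0
        logdet = 0.0
        for ng, xtx, xty, yty, xs, ysum, _ in pre:
            c = lam / (1.0 + ng * lam)
            xtvx += xtx - c * np.outer(xs, xs)
            xtvy += xty - c * xs * ysum
            ytvy += yty - c * ysum * ysum
            logdet += np.log1p(ng * lam)
        beta = np.linalg.solve(xtvx, xtvy)
        rss = ytvy - 2.0 * beta @ xtvy + beta @ xtvx @ beta
        sigma2 = max(rss / n, 1e-300)
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
        return ll, beta, sigma2, xtvx

    from scipy import optimize

    res = optimize.minimize_scalar(lambda t: -profile(np.exp(t))[0],
                                   bounds=(np.log(1e-8), np.log(1e4)),
                                   method="bounded", options={"xatol": 1e-10})
    lam_hat = float(np.exp(res.x))
    ll_hat = -res.fun
    ll0 = profile(0.0)[0]
    if ll0 >= ll_hat:       # boundary: no between-bear variance
        lam_hat, ll_hat = 0.0, ll0
    ll, beta, sigma2, xtvx = profile(lam_hat)
    se = np.sqrt(np.diag(np.linalg.inv(xtvx)) * sigma2)
    # BLUP of the random intercepts for fitted values
    yfit = X @ beta
    for ng, *_rest, ii in pre:
        shrink = ng * lam_hat / (1.0 + ng * lam_hat)
        yfit[ii] += shrink * float(np.mean(y[ii] - X[ii] @ beta))
    return beta, se, ll, lam_hat * sigma2, sigma2, yfit


def fit_lmm(spec: ModelSpec, table: pd.DataFrame) -> FitResult:
    """ML fit of a random-intercept (per bear) linear mixed model.

    ``table`` must hold the (already transformed) response column named by
    ``spec.response`` plus ``bear_id, gender, age, season, foodyr``.  The
    fit uses the exact profiled likelihood of :func:`_profiled_ml`.  A
    random-intercept variance estimated at the zero boundary is retained
    and flagged; its fixed effects then coincide with ordinary least
    squares.
    """
    if table["bear_id"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 bears (groups)")
    y = table[spec.response].to_numpy(dtype=float)
    X, names = _design(table, spec)
    n = len(y)
    groups = table["bear_id"].to_numpy()
    beta, se_beta, ll, re_var, sigma2, yfit = _profiled_ml(y, X, groups)
    boundary = re_var < 1e-7 * sigma2
    params = dict(zip(names, beta))
    se = dict(zip(names, se_beta))
    k = X.shape[1] + 2  # fixed effects + random-intercept and residual variances
    r2 = float(np.corrcoef(yfit, y)[0, 1] ** 2) if np.std(yfit) > 0 else 0.0
    return FitResult(spec=spec, params=params, se=se, loglik=ll, k=k, n=n,
                     aicc=aicc(ll, k, n), r2=r2, boundary=boundary)


def akaike_weights(aiccs: np.ndarray) -> np.ndarray:
    delta = aiccs - np.nanmin(aiccs)
    w = np.exp(-0.5 * delta)
    w[~np.isfinite(aiccs)] = 0.0
    return w / w.sum()


def model_average(fits: list[FitResult], full_set: bool = True) -> pd.DataFrame:
    """Model-averaged coefficients with unconditional SEs and 95% CIs.

    ``full_set=True`` (default) averages every term over all models,
    substituting 0 where the term is absent; ``full_set=False`` averages
    only over the models containing the term (natural averaging), with
    weights renormalized.  Returns a table with a flag for whether the 95%
    normal CI excludes zero.
    """
    if not fits:
        raise ValueError("cannot average an empty model set")
    aiccs = np.array([f.aicc for f in fits])
    w = akaike_weights(aiccs)
    dmin = np.nanmin(aiccs)
    for f, wi in zip(fits, w):
        f.weight = float(wi)
        f.delta = float(f.aicc - dmin)
    terms: list[str] = []
    for f in fits:
        for t in f.params:
            if t not in terms:
                terms.append(t)
    rows = []
    for t in terms:
        beta = np.array([f.params.get(t, 0.0) for f in fits])
        var = np.array([f.se.get(t, 0.0) ** 2 for f in fits])
        present = np.array([t in f.params for f in fits])
        if full_set:
            wt = w
        else:
            wt = np.where(present, w, 0.0)
            if wt.sum() == 0:
                continue
            wt = wt / wt.sum()
        bbar = float(np.sum(wt * beta))
        se_u = float(np.sum(wt * np.sqrt(var + (beta - bbar) ** 2)))
        lo, hi = bbar - Z95 * se_u, bbar + Z95 * se_u
        rows.append(dict(term=t, estimate=bbar, unconditional_se=se_u,
                         ci_lower=lo, ci_upper=hi,
                         ci_excludes_zero=bool(lo > 0 or hi < 0)))
    return pd.DataFrame(rows)


def model_set_table(fits: list[FitResult]) -> pd.DataFrame:
    """Ranked model-set summary (one row per model), Akaike weights included."""
    aiccs = np.array([f.aicc for f in fits])
    w = akaike_weights(aiccs)
    rows = [dict(model=f.spec.name, k=f.k, loglik=f.loglik, aicc=f.aicc,
                 delta=f.aicc - np.nanmin(aiccs), weight=wi, r2=f.r2,
                 boundary=f.boundary)
            for f, wi in zip(fits, w)]
    return pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)


def ln_guarded(x: np.ndarray) -> np.ndarray:
    """Natural log with a zero guard: zeros get ln(x + eps), eps = half the
    smallest positive observation (all-zero input raises)."""
    x = np.asarray(x, dtype=float)
    pos = x[x > 0]
    if len(pos) == 0:
        raise ValueError("cannot log-transform an all-zero response")
    eps = 0.5 * pos.min()
    return np.log(np.where(x > 0, x, x + eps))


def run_model_selection(
    table: pd.DataFrame,
    response: str,
    log_transform: bool = False,
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES,
    interaction: tuple[str, str] | None = DEFAULT_INTERACTION,
    full_set: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, list[FitResult]]:
    """Fit the full candidate set for one response.

    Returns ``(averaged_coefficients, model_set_summary, fits)``.  With
    ``log_transform``, the response is natural-logged first with the
    zero-observation guard of :func:`ln_guarded`.
    """
    df = table.copy()
    col = response
    if log_transform:
        col = f"ln_{response}"
        df[col] = ln_guarded(df[response].to_numpy())
    fits = []
    for spec in enumerate_models(candidates, interaction, response=col):
        fits.append(fit_lmm(spec, df))
    return model_average(fits, full_set=full_set), model_set_table(fits), fits
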