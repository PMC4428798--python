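"""Detectability modelling: hourly presence/absence vs environmental conditions.

The response is a binary indicator of whether any dolphin transit event
overlapped the first observation period of each recording hour.  Because
presence in one hour is correlated with presence in neighbouring hours, the
model is a marginal binomial-logit model fitted by generalised estimating
equations (GEE) with an AR-1 working correlation: corr(y_s, y_{s-k}) = α^k
in hourly calendar lags within a time block.  Robust (sandwich) standard
errors and single-df Wald tests drive a backward term elimination.

Data preparation mirrors standard practice for sparse ordinal covariates:
subsample to the first record of each hour, then drop records sitting on a
covariate level with too few observations to support estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.genmod.cov_struct import Autoregressive, Independence

from .errors import ConvergenceError, DataError

DEFAULT_LEVEL_COVARIATES = ("glare", "beaufort")


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


@dataclass
class PreparationLog:
    """Full accounting of rows kept and dropped (kept + dropped = input)."""

    n_input: int
    n_kept: int
    dropped: pd.DataFrame  # original rows with a 'drop_reason' column

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def summary(self) -> str:
        return (
            f"{self.n_input} input rows -> {self.n_kept} kept, "
            f"{self.n_dropped} dropped"
        )


def prepare_dataset(
    records: pd.DataFrame,
    min_level_n: int = 20,
    level_covariates: Sequence[str] = DEFAULT_LEVEL_COVARIATES,
    subsample_hourly: bool = True,
) -> tuple[pd.DataFrame, PreparationLog]:
    """Hourly subsample plus sparse-level filter.

    Keeps the first record of every clock hour (per time block), then
    iteratively removes records whose level of any covariate in
    ``level_covariates`` has ``min_level_n`` or fewer observations, until all
    retained levels are abundant (the filter is therefore idempotent).  Every
    dropped row is logged with its reason.
    """
    if records.empty:
        raise DataError("no records supplied")
    df = records.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values(["time_block_id", "timestamp"], kind="mergesort")
    dropped_parts = []

    if subsample_hourly:
        hour_key = df["timestamp"].dt.floor("h")
        first = ~pd.DataFrame(
            {"b": df["time_block_id"], "h": hour_key}
        ).duplicated()
        dup = df[~first].copy()
        if not dup.empty:
            dup["drop_reason"] = "not the first observation period of its hour"
            dropped_parts.append(dup)
        df = df[first]

    while True:
        drop_mask = pd.Series(False, index=df.index)
        reasons = pd.Series("", index=df.index)
        for cov in level_covariates:
            counts = df[cov].value_counts()
            sparse = counts[counts <= min_level_n].index
            m = df[cov].isin(sparse) & ~drop_mask
            drop_mask |= df[cov].isin(sparse)
            reasons[m] = [
                f"{cov} level {v} has <= {min_level_n} observations"
                for v in df.loc[m, cov]
            ]
        if not drop_mask.any():
            break
        part = df[drop_mask].copy()
        part["drop_reason"] = reasons[drop_mask]
        dropped_parts.append(part)
        df = df[~drop_mask]

    if df.empty:
        raise DataError("preparation removed every record")
    dropped = (
        pd.concat(dropped_parts) if dropped_parts else records.iloc[0:0].copy()
    )
    if "drop_reason" not in dropped.columns:
        dropped["drop_reason"] = pd.Series(dtype=str)
    log = PreparationLog(n_input=len(records), n_kept=len(df), dropped=dropped)
    assert log.n_kept + log.n_dropped == log.n_input
    return df.reset_index(drop=True), log


def add_hour_index(df: pd.DataFrame) -> pd.DataFrame:
    """Integer hours since each time block's first record (calendar lag).

    Gaps — missing hours, overnight breaks — advance the index, so the AR-1
    correlation between records separated by a k-hour calendar gap is α^k.
    """
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    start = out.groupby("time_block_id")["timestamp"].transform("min")
    out["hour_index"] = (
        (out["timestamp"] - start) / pd.Timedelta(hours=1)
    ).round().astype(int)
    return out


# ---------------------------------------------------------------------------
# collinearity screening
# ---------------------------------------------------------------------------


@dataclass
class CollinearityReport:
    retained: list
    dropped: list  # (covariate, vif, reason)
    vif: pd.DataFrame  # screening trail: step, covariate, vif
    correlation: pd.DataFrame


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF_j = 1 / (1 - R²_j) from the auxiliary regression of column j."""
    y = X[:, j]
    Z = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def collinearity_screen(
    df: pd.DataFrame,
    covariates: Sequence[str],
    vif_threshold: float = 3.0,
    priority: Sequence[str] = (),
) -> CollinearityReport:
    """Iteratively remove collinear covariates by variance inflation factor.

    At each step the covariate with the highest VIF above the threshold is
    dropped — except that when several are flagged at once, covariates named
    in ``priority`` are retained in preference to unnamed ones (e.g. keep
    Beaufort when it and cloud cover are mutually collinear).  Perfectly
    collinear columns report an infinite VIF.
    """
    if len(covariates) < 2:
        raise DataError("need at least 2 candidate covariates")
    active = list(covariates)
    dropped, trail = [], []
    corr = df[list(covariates)].corr()
    step = 0
    while len(active) >= 2:
        X = df[active].to_numpy(dtype=float)
        vifs = {c: _vif_one(X, j) for j, c in enumerate(active)}
        for c, v in vifs.items():
            trail.append({"step": step, "covariate": c, "vif": v})
        flagged = [c for c, v in vifs.items() if v > vif_threshold]
        if not flagged:
            break
        non_priority = [c for c in flagged if c not in priority]
        pool = non_priority if non_priority else flagged
        victim = max(pool, key=lambda c: vifs[c])
        if np.isinf(vifs[victim]):
            warnings.warn(
                f"covariate {victim!r} is perfectly collinear; dropped", stacklevel=2
            )
        dropped.append((victim, vifs[victim], f"VIF {vifs[victim]:.2f} > {vif_threshold}"))
        active.remove(victim)
        step += 1
    return CollinearityReport(
        retained=active,
        dropped=dropped,
        vif=pd.DataFrame(trail),
        correlation=corr,
    )


# ---------------------------------------------------------------------------
# GEE fitting
# ---------------------------------------------------------------------------


@dataclass
class GEEFit:
    """A fitted marginal binomial model with working correlation."""

    terms: list
    params: pd.Series
    robust_se: pd.Series
    wald: pd.Series
    pvalues: pd.Series
    scale: float
    alpha: float  # AR-1 working-correlation parameter (0 under independence)
    alpha_se: Optional[float]
    n_obs: int
    n_groups: int
    corstr: str
    converged: bool
    separation_flag: bool = False
    result: object = field(default=None, repr=False)

    def table(self) -> pd.DataFrame:
        """Coefficient table in the conventional GEE-report layout."""
        return pd.DataFrame(
            {
                "Estimate": self.params,
                "Std Err": self.robust_se,
                "Wald": self.wald,
                "Pr(>|W|)": self.pvalues,
            }
        )

    def summary(self) -> str:
        lines = [
            f"Binomial GEE ({self.corstr} working correlation), "
            f"n = {self.n_obs}, groups = {self.n_groups}",
            self.table().to_string(float_format=lambda v: f"{v:.4g}"),
            f"Estimated scale: {self.scale:.4g}",
        ]
        if self.corstr == "ar1":
            se = f" (se ~ {self.alpha_se:.4g})" if self.alpha_se is not None else ""
            lines.append(f"Estimated correlation parameter (alpha): {self.alpha:.4g}{se}")
        return "\n".join(lines)


def design_matrix(df: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Intercept plus one numeric column per term; 'a:b' is the product a*b."""
    X = pd.DataFrame({"(Intercept)": np.ones(len(df))}, index=df.index)
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            X[t] = df[a].to_numpy(dtype=float) * df[b].to_numpy(dtype=float)
        else:
            X[t] = df[t].to_numpy(dtype=float)
    return X


def _is_uniform_grid(df: pd.DataFrame, groups: str, time_col: str) -> bool:
    for _, g in df.groupby(groups):
        d = np.diff(np.sort(g[time_col].to_numpy()))
        if len(d) and not np.all(d == d[0]):
            return False
    return True


def fit_gee(
    df: pd.DataFrame,
    terms: Sequence[str],
    response: str = "presence",
    groups: str = "time_block_id",
    time_col: str = "hour_index",
    corstr: str = "ar1",
    maxiter: int = 100,
) -> GEEFit:
    """Fit the binomial-logit GEE for the given model terms.

    ``corstr`` is ``"ar1"`` (working correlation α^lag in the units of
    ``time_col`` within each group) or ``"independence"``.  Standard errors
    are robust sandwich estimates; per-term Wald statistics are
    ``(β̂/se)²`` referred to χ²₁.  The fit is deterministic.
    """
    if df.empty:
        raise DataError("empty model frame")
    for t in terms:
        for c in t.split(":"):
            if c not in df.columns:
                raise DataError(f"term component {c!r} not in the table")
    if time_col not in df.columns:
        df = add_hour_index(df)
    X = design_matrix(df, terms)
    y = df[response].to_numpy(dtype=float)
    grp = df[groups].to_numpy()
    tt = df[time_col].to_numpy(dtype=int)[:, None]

    if corstr == "ar1":
        cov = Autoregressive(grid=_is_uniform_grid(df, groups, time_col))
    elif corstr == "independence":
        cov = Independence()
    else:
        raise ValueError(f"unsupported working correlation {corstr!r}")

    model = sm.GEE(
        y, X, groups=grp, time=tt, family=sm.families.Binomial(), cov_struct=cov
    )
    # the plain sandwich needs many clusters; with few (e.g. two survey
    # blocks) use the Mancl-DeRouen bias-reduced variant instead
    n_groups = int(pd.Series(grp).nunique())
    cov_type = "bias_reduced" if n_groups < 10 else "robust"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=maxiter, cov_type=cov_type)
    if not getattr(res, "converged", True):
        raise ConvergenceError(f"GEE did not converge in {maxiter} iterations")

    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(np.asarray(res.standard_errors(cov_type=cov_type)), index=X.columns)
    wald = (params / bse) ** 2
    pvals = pd.Series(stats.chi2.sf(wald, df=1), index=X.columns)
    separation = bool(np.any(np.abs(params.to_numpy()) > 10))
    if separation:
        warnings.warn("possible separation: |coefficient| > 10", stacklevel=2)

    alpha = float(np.atleast_1d(cov.dep_params)[0]) if corstr == "ar1" else 0.0
    alpha_se = _alpha_se(res, df, groups, time_col) if corstr == "ar1" else None
    return GEEFit(
        terms=list(terms),
        params=params,
        robust_se=bse,
        wald=wald,
        pvalues=pvals,
        scale=float(res.scale),
        alpha=alpha,
        alpha_se=alpha_se,
        n_obs=len(df),
        n_groups=n_groups,
        corstr=corstr,
        converged=True,
        separation_flag=separation,
        result=res,
    )


def _alpha_se(res, df: pd.DataFrame, groups: str, time_col: str) -> float:
    """Approximate standard error of the lag-1 residual correlation.

    Moment-based: treats the products of consecutive (lag-1) standardised
    Pearson residuals as i.i.d. and reports sd/√m.  An approximation —
    statsmodels does not provide an SE for the working-correlation parameter.
    """
    e = np.asarray(res.resid_pearson) / np.sqrt(res.scale)
    prods = []
    for _, g in df.assign(_e=e).groupby(groups):
        g = g.sort_values(time_col)
        lag = np.diff(g[time_col].to_numpy())
        p = g["_e"].to_numpy()[:-1] * g["_e"].to_numpy()[1:]
        prods.extend(p[lag == 1])
    prods = np.asarray(prods)
    if len(prods) < 2:
        return float("nan")
    return float(prods.std(ddof=1) / np.sqrt(len(prods)))


# ---------------------------------------------------------------------------
# model reduction and the glare/time-of-day confound check
# ---------------------------------------------------------------------------


def _droppable(terms: Sequence[str], pvals: pd.Series, alpha: float):
    """Candidate term to drop: interactions before the main effects they use."""
    inter = [t for t in terms if ":" in t and pvals[t] > alpha]
    if inter:
        return max(inter, key=lambda t: pvals[t])
    locked = {c for t in terms if ":" in t for c in t.split(":")}
    mains = [t for t in terms if ":" not in t and t not in locked and pvals[t] > alpha]
    if mains:
        return max(mains, key=lambda t: pvals[t])
    return None


def reduce_model(
    df: pd.DataFrame,
    full_terms: Sequence[str],
    alpha: float = 0.05,
    **fit_kwargs,
) -> tuple[GEEFit, pd.DataFrame]:
    """Backward elimination by Wald tests.

    Repeatedly refits, dropping the least-significant term with p above
    ``alpha`` (interaction terms are always removed before the main effects
    of their components).  Returns the final fit and the step-by-step trail.
    If every term falls, the intercept-only model is returned with a warning.
    """
    terms = list(full_terms)
    trail = []
    fit = fit_gee(df, terms, **fit_kwargs)
    step = 0
    while terms:
        victim = _droppable(terms, fit.pvalues, alpha)
        trail.append(
            {
                "step": step,
                "terms": "+".join(terms),
                "dropped": victim or "",
                "p_dropped": float(fit.pvalues[victim]) if victim else np.nan,
            }
        )
        if victim is None:
            break
        terms.remove(victim)
        fit = fit_gee(df, terms, **fit_kwargs)
        step += 1
    if not terms:
        warnings.warn("all terms eliminated; returning intercept-only model", stacklevel=2)
        trail.append({"step": step, "terms": "(intercept)", "dropped": "", "p_dropped": np.nan})
    return fit, pd.DataFrame(trail)


@dataclass
class ConfoundCheck:
    fit: GEEFit
    term: str
    term_pvalue: float
    significant: bool
    n_excluded: int
    plot_data: pd.DataFrame  # timestamp, presence_jittered, glare_jittered


def glare_confound_check(
    df: pd.DataFrame,
    final_terms: Sequence[str] = ("glare",),
    exclude_hours: tuple = (9, 13),
    term: str = "glare",
    jitter_seed: int = 0,
    **fit_kwargs,
) -> ConfoundCheck:
    """Refit the final model excluding a midday window.

    Glare-free conditions cluster in the middle of the day, so a glare effect
    could in principle be a time-of-day artefact.  Restricting to hours where
    glare can be either present or absent (default: dropping 09:00-13:00)
    breaks that confounding; the check reports whether the glare term stays
    significant, plus jittered presence- and glare-vs-time series for
    plotting.
    """
    work = df.copy()
    work["timestamp"] = pd.to_datetime(work["timestamp"])
    hour = work["timestamp"].dt.hour
    keep = ~((hour >= exclude_hours[0]) & (hour < exclude_hours[1]))
    sub = work[keep]
    if sub.empty:
        raise DataError("excluding the window leaves no records")
    fit = fit_gee(sub, list(final_terms), **fit_kwargs)
    p = float(fit.pvalues[term])
    rng = np.random.default_rng(jitter_seed)
    plot = pd.DataFrame(
        {
            "timestamp": work["timestamp"],
            "presence_jittered": work["presence"] + rng.uniform(-0.1, 0.1, len(work)),
            "glare_jittered": work["glare"] + rng.uniform(-0.1, 0.1, len(work)),
        }
    )
    return ConfoundCheck(
        fit=fit,
        term=term,
        term_pvalue=p,
        significant=p < 0.05,
        n_excluded=int((~keep).sum()),
        plot_data=plot,
    )
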