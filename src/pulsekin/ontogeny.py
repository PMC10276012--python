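"""Ontogenetic scaling fits and allometric size-normalization.

Each kinematic trait is regressed against bell diameter under four
candidate model families — linear (y ~ x), log-linear (y ~ log x),
power (log y ~ log x) and exponential (log y ~ x) — fit by OLS in the
family's transformed space. Families are compared by BIC evaluated on the
*original* response scale (a log-Jacobian term makes log-y likelihoods
comparable with raw-y likelihoods). The best pooled fit supplies residuals
whose per-species means form the size-normalized trait table used by the
ordination and phylogenetic-signal stages; when the pooled regression is
not significant the residuals reduce to centered trait values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "ModelFit",
    "shapiro_wilk",
    "fit_models",
    "regress_by_group",
    "allometric_normalize",
    "species_trait_table",
    "FAMILIES",
]

FAMILIES = ("linear", "loglinear", "power", "exponential")

_LOG_X = {"loglinear": True, "power": True, "linear": False, "exponential": False}
_LOG_Y = {"power": True, "exponential": True, "linear": False, "loglinear": False}


@dataclass
class ModelFit:
    """One candidate regression of trait on diameter."""

    family: str
    intercept: float
    slope: float
    r2: float
    p: float
    df: int
    bic: float
    n: int
    log_x: bool
    log_y: bool

    def equation(self) -> str:
        a, b = self.intercept, self.slope
        return {
            "linear": f"y = {a:.4g} + {b:.4g} x",
            "loglinear": f"y = {a:.4g} + {b:.4g} ln(x)",
            "power": f"y = {np.exp(a):.4g} x^{b:.4g}",
            "exponential": f"y = {np.exp(a):.4g} e^({b:.4g} x)",
        }[self.family]

    def predict_transformed(self, x: np.ndarray) -> np.ndarray:
        """Mean response in the family's (possibly log) response space."""
        xt = np.log(x) if self.log_x else np.asarray(x, dtype=float)
        return self.intercept + self.slope * xt

    def residuals(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Residuals in the fitted model's transformed response space."""
        yt = np.log(y) if self.log_y else np.asarray(y, dtype=float)
        return yt - self.predict_transformed(x)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p); used to motivate log transforms."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: W undefined")
    w, p = scipy.stats.shapiro(x)
    return float(w), float(p)


def _fit_one(x: np.ndarray, y: np.ndarray, family: str) -> ModelFit:
    log_x, log_y = _LOG_X[family], _LOG_Y[family]
    xt = np.log(x) if log_x else x
    yt = np.log(y) if log_y else y
    X = sm.add_constant(xt)
    res = sm.OLS(yt, X).fit()
    n = len(yt)
    # Gaussian ML log-likelihood with a floored error variance so that
    # exact (zero-residual) fits stay finite and comparable
    s2 = max(res.ssr / n, (1e-10 * max(1.0, float(np.std(yt)))) ** 2)
    llf = -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)
    # log-Jacobian of the response transform makes BICs of log-y and raw-y
    # families comparable on the original y scale
    llf -= np.sum(np.log(y)) if log_y else 0.0
    k = 3  # intercept, slope, error variance
    bic = k * np.log(n) - 2.0 * llf
    return ModelFit(
        family=family,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r2=float(res.rsquared),
        p=float(res.pvalues[1]),
        df=int(res.df_resid),
        bic=float(bic),
        n=n,
        log_x=log_x,
        log_y=log_y,
    )


def fit_models(
    x, y, families: tuple[str, ...] = FAMILIES
) -> tuple[list[ModelFit], ModelFit]:
    """Fit each candidate family; return (all fits, best by BIC)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 points")
    if np.any(x <= 0):
        raise ValueError("diameters must be positive")
    fits = []
    for fam in families:
        if fam not in FAMILIES:
            raise ValueError(f"unknown family {fam!r}")
        if _LOG_Y[fam] and np.any(y <= 0):
            warnings.warn(f"skipping {fam}: non-positive trait values")
            continue
        fits.append(_fit_one(x, y, fam))
    if not fits:
        raise ValueError("no family could be fit")
    # earliest family wins near-ties (degenerate perfect fits)
    best = fits[0]
    for f in fits[1:]:
        if f.bic < best.bic - 1e-9:
            best = f
    return fits, best


def regress_by_group(
    df: pd.DataFrame,
    trait: str,
    group: str,
    size_col: str = "diameter_cm",
    families: tuple[str, ...] = FAMILIES,
    min_n: int = 4,
    ci_points: int = 50,
) -> dict[str, dict]:
    """Independent best-BIC fits per group with 95% CI bands on the mean.

    Groups with fewer than ``min_n`` points are omitted with a warning.
    Returns {group: {"fit": ModelFit, "band": DataFrame(x, fit, lo, hi)}}
    with the band on the original response scale.
    """
    out: dict[str, dict] = {}
    for g, sub in df.groupby(group):
        x = sub[size_col].to_numpy(float)
        y = sub[trait].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_n:
            warnings.warn(f"group {g!r} has n={int(ok.sum())} < {min_n}; omitted")
            continue
        x, y = x[ok], y[ok]
        _, best = fit_models(x, y, families)
        xt = np.log(x) if best.log_x else x
        yt = np.log(y) if best.log_y else y
        res = sm.OLS(yt, sm.add_constant(xt)).fit()
        xg = np.linspace(x.min(), x.max(), ci_points)
        xgt = np.log(xg) if best.log_x else xg
        pred = res.get_prediction(sm.add_constant(xgt))
        ci = pred.conf_int(alpha=0.05)
        mean = pred.predicted_mean
        if best.log_y:
            mean, ci = np.exp(mean), np.exp(ci)
        out[str(g)] = {
            "fit": best,
            "band": pd.DataFrame(
                {size_col: xg, "fit": mean, "lo": ci[:, 0], "hi": ci[:, 1]}
            ),
        }
    return out


def allometric_normalize(
    df: pd.DataFrame,
    trait: str,
    size_col: str = "diameter_cm",
    species_col: str = "species",
    families: tuple[str, ...] = FAMILIES,
) -> tuple[pd.Series, ModelFit]:
    """Size-normalized per-species means of one trait.

    Residuals are taken from the best-BIC regression pooled over all
    records, in that model's transformed response space, then averaged per
    species. When the pooled slope is not significant (p > 0.05) the
    residuals reduce to centered trait values (intercept-only regression in
    the same space), so species means still have a size-free interpretation.
    """
    sub = df[[species_col, size_col, trait]].dropna()
    x = sub[size_col].to_numpy(float)
    y = sub[trait].to_numpy(float)
    _, best = fit_models(x, y, families)
    if best.p > 0.05:
        yt = np.log(y) if best.log_y else y
        resid = yt - float(np.mean(yt))
    else:
        resid = best.residuals(x, y)
    means = (
        pd.Series(resid, index=sub[species_col].to_numpy())
        .groupby(level=0)
        .mean()
        .rename(trait)
    )
    return means, best


def species_trait_table(
    df: pd.DataFrame,
    traits: list[str],
    size_col: str = "diameter_cm",
    species_col: str = "species",
    families: tuple[str, ...] = FAMILIES,
) -> tuple[pd.DataFrame, dict[str, ModelFit]]:
    """Size-normalized species x trait table (one normalized column per trait)."""
    cols = {}
    fits = {}
    for tr in traits:
        cols[tr], fits[tr] = allometric_normalize(
            df, tr, size_col=size_col, species_col=species_col, families=families
        )
    table = pd.DataFrame(cols)
    table.index.name = species_col
    return table, fits
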